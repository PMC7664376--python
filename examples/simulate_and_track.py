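"""Simulate a head-mounted IMU walk around the 68 m rectangle and track it.

Generates a noisy 20 Hz accelerometer/gyro/magnetometer stream for the
benchmark path (25.5 m x 8.5 m rectangle, 5 s standstills), runs the
proposed step-and-heading pipeline (low-pass filter -> peak detection ->
Weinberg step length -> Mahony quaternion heading), and prints the two
standard trajectory error metrics.
"""

import headpdr as hp
from headpdr.steplength import calibrate

# calibrate the Weinberg gain on a 20 m straight walk of known length
cal_seq, cal_truth = hp.simulate_walk(hp.straight_line(20.0), hp.SensorErrorModel(seed=10))
steps = hp.collect_calibration_steps(cal_seq, real_length=cal_truth.total_length)
weinberg = calibrate("weinberg", steps)
print(f"calibrated Weinberg k = {weinberg.params['k']:.4f}")

# simulate and track the benchmark rectangle with low-cost sensor noise
seq, truth = hp.simulate_walk(hp.default_rectangle(), hp.SensorErrorModel(seed=11))
traj = hp.run_pipeline(seq, "proposed", hp.PipelineConfig(weinberg=weinberg))

e2e = hp.end_to_end_error(traj)
abs_err, pct = hp.total_distance_error(truth.total_length, traj)
print(f"steps detected: {traj.n_steps} (truth {truth.n_steps})")
print(f"estimated path length: {traj.length:.2f} m (truth {truth.total_length:.1f} m)")
print(f"end-to-end error: {e2e:.2f} m   <- distance between start and end of the")
print("                         estimated loop; zero for a perfect closed walk")
print(f"total distance error: {abs_err:.2f} m = {pct:.2f}% of the true path length")
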