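"""Benchmark the three step-and-heading pipelines on simulated walks.

Repeats the rectangle walk under the shipped low-cost sensor noise model
and compares the proposed method (Weinberg + Mahony) with the two
comparators: EKF fusion with a borrowed linear step-length model, and
the hybrid gyro/magnetometer azimuth with the hybrid step-length model.
"""

import numpy as np

import headpdr as hp
from headpdr.steplength import calibrate

# per-subject calibration walks
cal_seq, cal_truth = hp.simulate_walk(hp.straight_line(20.0), hp.SensorErrorModel(seed=0))
weinberg = calibrate(
    "weinberg", hp.collect_calibration_steps(cal_seq, real_length=cal_truth.total_length)
)
pairs = []
for f, l, amp in [(1.6, 0.45, 1.6), (1.8, 0.5, 2.0), (2.0, 0.55, 2.5)]:
    sc = hp.straight_line(18.0, step_length=l, step_frequency=f, osc_amplitude=amp)
    seq, _ = hp.simulate_walk(sc, hp.SensorErrorModel(seed=1))
    pairs += hp.collect_calibration_steps(seq, step_length=l)
cfg = hp.PipelineConfig(weinberg=weinberg, zhu_length=calibrate("zhu", pairs))

errors = {m: ([], []) for m in ("proposed", "hasan", "zhu")}
for seed in range(10):
    seq, truth = hp.simulate_walk(hp.default_rectangle(), hp.SensorErrorModel(seed=seed))
    for method, (e2e, pct) in errors.items():
        traj = hp.run_pipeline(seq, method, cfg)
        e2e.append(hp.end_to_end_error(traj))
        pct.append(hp.total_distance_error(truth.total_length, traj)[1])

print("mean errors over 10 simulated 68 m rectangle walks:")
print(f"{'method':10s} {'end-to-end (m)':>15s} {'distance err (%)':>17s}")
for method, (e2e, pct) in errors.items():
    print(f"{method:10s} {np.mean(e2e):15.2f} {np.mean(pct):17.2f}")
print("\nthe proposed pipeline should show the smallest end-to-end error;")
print("the EKF comparator's large distance error reflects its borrowed")
print("(non-calibrated) linear step-length coefficients")
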