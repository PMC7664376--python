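"""Compare the five step-length models on a straight calibration walk.

Each model maps per-step features of the filtered accelerometer norm to
a step length; all are calibrated per subject by least squares on one
walk of known length and evaluated on a second, unseen walk.
"""

import headpdr as hp
from headpdr.steplength import calibrate, predict

scenario = hp.straight_line(20.0)
cal_seq, cal_truth = hp.simulate_walk(scenario, hp.SensorErrorModel(seed=1))
cal_steps = hp.collect_calibration_steps(cal_seq, real_length=cal_truth.total_length)

test_seq, test_truth = hp.simulate_walk(scenario, hp.SensorErrorModel(seed=2))
test_steps = hp.collect_calibration_steps(
    test_seq, real_length=test_truth.total_length, trim=0
)
real = sum(length for _, length in test_steps)

print(f"held-out straight walk, real distance {real:.2f} m")
print(f"{'model':10s} {'estimated (m)':>14s} {'error (m)':>10s} {'error rate':>11s}")
for model in ("linear", "weinberg", "kim", "scarlett", "shin"):
    coeffs = calibrate(model, cal_steps)
    est = sum(predict(ft, coeffs) for ft, _ in test_steps)
    print(f"{model:10s} {est:14.2f} {abs(real - est):10.2f} {100 * abs(real - est) / real:10.2f}%")
print("\nfrequency/variance models (linear, shin) and the Weinberg and Kim")
print("amplitude models all transfer well when calibrated on the same subject")
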