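"""Mahony explicit complementary filter: convergence and bias estimation.

Shows the two properties that make the filter suitable for low-cost
IMUs: an initial attitude error decays at the rate set by the
proportional gain kP, and with integral gain kI > 0 a constant gyro
bias is estimated (and thus cancelled) from static data.
"""

import numpy as np

import headpdr as hp
from headpdr.heading import MahonyState, euler_to_quat, mahony_step, quat_to_euler

# 10 degree initial roll error on a static, level sensor
state = MahonyState(q=euler_to_quat(np.deg2rad(10.0), 0.0, 0.0), kP=1.0, kI=0.0)
accel = np.array([0.0, 0.0, hp.GRAVITY])
print("attitude error decay (static sensor, kP=1):")
for step in range(201):
    if step % 40 == 0:
        roll, pitch, _ = quat_to_euler(state.q)
        print(f"  t = {step * 0.05:5.1f} s   tilt error = {np.rad2deg(np.hypot(roll, pitch)):8.4f} deg")
    state = mahony_step(state, np.zeros(3), accel, 0.05)

# constant gyro bias on x/y is observable from gravity and estimated by kI
bias = (0.02, -0.015, 0.0)
seq = hp.simulate_static(60.0, np.array([1.0, 0, 0, 0]),
                         hp.SensorErrorModel(0.0, 0.0, bias, 0.0, 0.0, seed=0))
state = MahonyState(kP=1.0, kI=0.3)
for i in range(len(seq)):
    state = mahony_step(state, seq.gyro[i], seq.accel[i], seq.dt[i])
print(f"\ninjected gyro bias   : {bias[:2]} rad/s (x, y)")
print(f"estimated after 60 s : ({state.bias_hat[0]:.4f}, {state.bias_hat[1]:.4f}) rad/s")
print("(the z component is unobservable from gravity alone)")
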