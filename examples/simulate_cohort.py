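"""Generate one synthetic subject and an STS repetition, and show what the
generator knows: anthropometry, ground-truth events and physics checks.

The subject's "anatomy" is a jittered T-pose marker layout; every dynamic
trial carries segment poses, joint-angle curves, event frames and
whole-body-consistent plate signals as ground truth.
"""

import numpy as np

import kneests as ks

subject = ks.generate_subject(rng_seed=1)
print(f"subject: mass {subject.body_mass:.1f} kg, "
      f"stature {subject.stature:.0f} mm, "
      f"{len(subject.tpose_positions)} markers (IOR+CAST union)")

trial, truth = ks.generate_sts_trial(subject, artifact=ks.NOISE_FREE)
print(f"trial: {trial.n_frames} frames at {trial.marker_rate:.0f} Hz, "
      f"{trial.plate_forces.shape[1]} analog frames at "
      f"{trial.analog_rate:.0f} Hz")

# ground-truth events (frames at 100 Hz)
print("events:", truth.event_frames)

# the starting posture is the standardized 90 deg knee flexion
kfa0 = truth.joint_angle_curves[("knee", "right")][0, 0]
print(f"knee flexion at frame 0: {kfa0:.3f} deg (standardized start)")

# physics: plate + seat vertical force balances m (g + a_com)
from kneests.geometry import central_difference
from kneests.io import GRAVITY

com_z = truth.aux["com_total_mm"][:, 2] / 1000.0
acc_z = central_difference(com_z, trial.marker_rate, order=2)
total = (truth.aux["feet_force"]["right"][:, 2]
         + truth.aux["feet_force"]["left"][:, 2]
         + truth.aux["seat_force"][:, 2])
residual = total - truth.aux["total_mass"] * (GRAVITY + acc_z)
print(f"vertical force-balance residual: {np.abs(residual[2:-2]).max():.2e} N"
      " (zero = plate signals consistent with the generated kinematics)")

# write the trial in the plain-text exchange format
paths = ks.write_trial_tsv(trial, "scratch/example_trial")
print("wrote:", ", ".join(str(p) for p in paths.values()))
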