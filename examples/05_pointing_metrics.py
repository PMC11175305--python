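"""Score a set of noisy pointing trials with the six evaluation indices.

Three trials from a simulated subject are evaluated for accuracy
(endpoint error, lateral deviation), stability (endpoint deviation,
orbit correlation) and smoothness (jerk cost, normalized mean velocity).
"""

import numpy as np

from emghybrid.metrics import evaluate_trial_set
from emghybrid.synth import SubjectSkill, generate_trial

skill = SubjectSkill(endpoint_bias=np.array([2.0, 0.0]),
                     endpoint_noise_sd=1.5, curvature=4.0,
                     tremor_amp=0.5, duration=2.5)
rng = np.random.default_rng(0)
trials = [generate_trial(skill, np.zeros(2), np.array([20.0, 0.0]), rng=rng)
          for _ in range(3)]

report = evaluate_trial_set(trials)
for key, value in report.to_dict().items():
    print(f"{key:14s} {value:10.4f}")
# e, e_perp_max, s are in degrees (lower = more accurate/stable);
# r_orbit in [-1, 1] (higher = more reproducible paths); jc in
# deg^2 s^-5 (lower = smoother); v_norm in (0, 1] (minimum-jerk
# movements sit at 8/15 ~ 0.533); reaching_time in seconds.
# jc looks enormous because the third derivative scales tremor by
# (2*pi*f)^3: an 0.5-deg 8-Hz tremor utterly dominates the quintic
# backbone. That sensitivity is what makes jc a smoothness index; as a
# subject's tremor decays over training, jc collapses by orders of
# magnitude. Pass presmooth_hz to evaluate_trial_set to low-pass
# measurement noise out of recorded (as opposed to simulated) data.
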