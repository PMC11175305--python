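"""Generate the instruction-mode minimum-jerk trajectory and verify its
smoothness properties against the closed forms.

The robot guides the wrist from rest to the 20-degree flexion target in
T_instruct = 2 s along the jerk-minimizing quintic.
"""

import numpy as np

from emghybrid.config import ModeSchedule, default_target_map
from emghybrid.metrics import (TrialTrajectory, decompose, jerk_cost,
                               normalized_mean_velocity)
from emghybrid.trajectory import (boundary_derivatives, instruct,
                                  jerk_cost_closed_form)

schedule = ModeSchedule(target_map=default_target_map(20.0))
traj = instruct("flexion", np.zeros(2), schedule, fs_out=1000.0)

trial = TrialTrajectory(t=traj.t, P=traj.P, start=np.zeros(2),
                        target=np.array(schedule.target_map["flexion"]))
d = decompose(trial)
bd = boundary_derivatives(traj)

print(f"endpoint angle:        {d.p_par[-1]:.6f} deg (target 20)")
print(f"jerk cost:             {jerk_cost(d):.2f} deg^2 s^-5 "
      f"(closed form {jerk_cost_closed_form(20.0, 2.0):.2f})")
print(f"normalized mean vel.:  {normalized_mean_velocity(d):.4f} "
      f"(theory 8/15 = {8 / 15:.4f})")
print(f"|endpoint velocity|:   {np.linalg.norm(bd['velocity_end']):.2e} deg/s")
# Velocity and acceleration vanish at both ends: the movement starts and
# stops smoothly, which is what makes the quintic the normative model of
# natural reaching.
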