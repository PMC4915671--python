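"""Simulate the limited-lifetime random-dot optic-flow display.

Builds the default display (radial flow at 8 deg/s, coherence modulated at
1.2 Hz), prints its derived constants, steps the dot field through one
coherence cycle, and exports a short trajectory to CSV.
"""

import numpy as np

import flowssvep as fs

spec = fs.StimulusSpec(pattern="radial", speed=8.0)
print(f"dots: {spec.n_dots} (density {spec.dot_density}/deg^2 "
      f"over a {spec.annulus_area:.1f} deg^2 annulus)")
print(f"update rate f2 = {spec.f2:.0f} Hz, coherence modulation f1 = "
      f"{spec.f1} Hz, direction reversal {spec.reversal_frequency} Hz")
print(f"per-update displacement: {spec.displacement_per_update:.4f} deg "
      f"(speed / f2)")

schedule = fs.build_schedule(spec)
print(f"trial: {len(schedule)} update frames = {spec.cycles_per_trial} cycles "
      f"x {spec.frames_per_cycle} frames")

field = fs.init_field(spec, seed=1)
for coherent, sign, _t in list(schedule)[: spec.frames_per_cycle]:
    field = fs.step_dots(field, spec, coherent, sign)
print(f"after one cycle: {field.n_dots} dots, all inside the annulus "
      f"({field.radii().min():.2f}-{field.radii().max():.2f} deg), "
      f"max age {field.ages.max()} updates")

# trajectory export for a sparse field (keeps the CSV small)
small = fs.StimulusSpec(dot_density=0.02, cycles_per_trial=1)
traj = fs.stimulus.simulate_trial(small, seed=2)
traj.to_csv("scratch_trajectory.csv", index=False)
print(f"wrote scratch_trajectory.csv: {len(traj)} rows "
      f"({traj.dot_id.nunique()} dots x {traj.frame.nunique()} frames); "
      "columns = trial, frame, time_s, phase, direction_sign, dot_id, "
      "x_deg, y_deg")
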