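"""Recover a known surgical translation from ideal surface models.

Builds a synthetic maxilla, translates it by a fixed surgical plan
(-2.5 mm sagittal, +7.5 mm vertical, -2.0 mm transversal), and runs the
align-centroid-subtract pipeline with no model degradation.  The tracked
displacement should equal the plan to machine precision: with identical
meshes at both time points the area-weighted centroid moves exactly with
the surface.
"""

import numpy as np

import centroidtrack as ct

mesh = ct.generate_roi_mesh("maxilla", n_faces_target=2000, seed=1)
plan = ct.SimulationPlan("patient_1", "maxilla",
                         translation=[-2.5, 7.5, -2.0], seed=0)
moved = ct.apply_plan(mesh, plan)

record = ct.track_displacement(
    t0=ct.TimepointModels(mesh, mesh, "initial"),
    t1=ct.TimepointModels(moved, moved, "final"),
    frame=ct.CartesianFrame.identity(),
    icp=ct.ICPConfig(n_samples=2000, seed=0),
    roi="maxilla")

error = ct.displacement_error(record, plan.translation)
print(f"planned  (mm): {plan.translation}")
print(f"measured (mm): dx={record.dx:.6f} dy={record.dy:.6f} "
      f"dz={record.dz:.6f}")
print(f"error    (mm): {error}")
print(f"max |error| = {np.abs(error).max():.2e} mm "
      "(machine precision: the method is exact under ideal inputs)")
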