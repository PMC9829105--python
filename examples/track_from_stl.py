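"""The file-based workflow: STL surfaces in, displacement report out.

Writes one synthetic case to disk exactly as a clinical pipeline would
hand it over — four STL surface models (accurate + spatial reference at
two time points), a Cartesian-frame JSON — then reads everything back and
measures the displacement.  Equivalent to:

    centroidtrack simulate --roi mandible --seed 11 --out case/
    centroidtrack track --t0-accurate case/t0_accurate.stl ... --frame case/frame.json
"""

import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np

import centroidtrack as ct

workdir = Path(tempfile.mkdtemp(prefix="centroidtrack_"))
study = ct.StudyConfig()

mesh = ct.generate_roi_mesh("mandible", 1500, seed=11)
plan = ct.sample_plan("mandible", "patient_1", study.envelope, seed=11)
moved = ct.apply_plan(mesh, plan)

models = {
    "t0_accurate": ct.degrade_mesh(
        mesh, replace(study.accurate_degradation, seed=1)),
    "t1_accurate": ct.degrade_mesh(
        moved, replace(study.accurate_degradation, seed=2)),
    "t0_reference": ct.degrade_mesh(
        mesh, replace(study.reference_degradation, seed=3)),
    "t1_reference": ct.degrade_mesh(
        moved, replace(study.reference_degradation, seed=4)),
}
for stem, model in models.items():
    ct.write_stl(model, workdir / f"{stem}.stl")
ct.save_frame(ct.CartesianFrame.identity(), workdir / "frame.json")
print(f"wrote case to {workdir} (ground truth {plan.translation} mm)")

# --- the consuming side: only files from here on -------------------------
frame = ct.load_frame(workdir / "frame.json")
record = ct.track_displacement(
    t0=ct.TimepointModels(ct.read_stl(workdir / "t0_accurate.stl"),
                          ct.read_stl(workdir / "t0_reference.stl"),
                          "initial"),
    t1=ct.TimepointModels(ct.read_stl(workdir / "t1_accurate.stl"),
                          ct.read_stl(workdir / "t1_reference.stl"),
                          "final"),
    frame=frame, icp=study.icp, roi="mandible")

err = ct.displacement_error(record, plan.translation)
print(f"measured (mm): dx={record.dx:+.4f} dy={record.dy:+.4f} "
      f"dz={record.dz:+.4f}")
print(f"error vs plan (mm): {np.round(err, 4)}  "
      f"(alignment RMS {record.alignment_initial.rms:.3f} / "
      f"{record.alignment_final.rms:.3f} mm)")
(workdir / "record.json").write_text(record.to_json(indent=2))
print(f"full report: {workdir / 'record.json'}")
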