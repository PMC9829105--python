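"""The tracking pipeline: align each time point's accurate model onto its
spatial reference, compute the centroid of the aligned accurate surface in
the clinical Cartesian frame, and subtract.

Only translations are quantified — a centroid carries no orientation, so
rotational components of a displacement are invisible to this method by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import TrackingError
from .geometry import CartesianFrame, apply_rigid, to_frame_coords
from .mesh import (Centroid, ComparabilityPolicy, TriangleMesh,
                   check_comparability, surface_centroid)
from .registration import AlignmentReport, ICPConfig, icp_align


@dataclass
class TimepointModels:
    """The two mesh grades describing one ROI at one time point.

    ``accurate`` is the segmentation-grade model whose centroid is tracked;
    ``reference`` is the coarse model that carries the correct spatial
    position, onto which the accurate model is best-fit aligned.
    """

    accurate: TriangleMesh
    reference: TriangleMesh
    label: str = "initial"   # "initial" or "final"


@dataclass
class DisplacementRecord:
    """Per-axis centroid displacement of one ROI between two time points.

    ``(dx, dy, dz)`` are final-minus-initial centroid coordinates in the
    supplied frame: X sagittal, Y vertical, Z transversal (mm).
    """

    roi: str
    dx: float
    dy: float
    dz: float
    centroid_initial: Centroid
    centroid_final: Centroid
    alignment_initial: AlignmentReport
    alignment_final: AlignmentReport
    frame: CartesianFrame
    warnings: list[str] = field(default_factory=list)

    @property
    def displacement(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz])

    def to_dict(self) -> dict:
        return {
            "roi": self.roi,
            "displacement_mm": {"dx": self.dx, "dy": self.dy, "dz": self.dz},
            "centroid_initial": self.centroid_initial.to_dict(),
            "centroid_final": self.centroid_final.to_dict(),
            "alignment_initial": self.alignment_initial.to_dict(),
            "alignment_final": self.alignment_final.to_dict(),
            "frame": self.frame.to_dict(),
            "warnings": self.warnings,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def csv_row(self) -> dict:
        return {"roi": self.roi, "dx": self.dx, "dy": self.dy, "dz": self.dz,
                "rms_t0": self.alignment_initial.rms,
                "rms_t1": self.alignment_final.rms}


def _align_timepoint(tp: TimepointModels, icp: ICPConfig, seed_offset: int,
                     warnings: list[str]
                     ) -> tuple[TriangleMesh, AlignmentReport]:
    cfg = ICPConfig(**{**icp.to_dict(), "seed": icp.seed + seed_offset})
    report = icp_align(tp.accurate, tp.reference, cfg)
    if report.diverged:
        raise TrackingError(
            f"alignment diverged at time point '{tp.label}' "
            f"(initial RMS {report.initial_rms:.3f} mm exceeds gate "
            f"{cfg.divergence_rms_mm} mm)", [report])
    if not report.converged:
        warnings.append(
            f"{tp.label}: alignment stopped at the iteration cap "
            f"({report.iterations}) before the RMS improvement fell below "
            f"tolerance (final RMS {report.rms:.3f} mm)")
    return apply_rigid(tp.accurate, report.transform), report


def track_displacement(t0: TimepointModels, t1: TimepointModels,
                       frame: CartesianFrame,
                       icp: ICPConfig | None = None,
                       policy: ComparabilityPolicy | None = None,
                       reference_policy: ComparabilityPolicy | None = None,
                       centroid_method: str = "area_weighted_surface",
                       rms_warn_mm: float = 0.5,
                       roi: str = "other") -> DisplacementRecord:
    """Measure the translational displacement of one ROI between two time
    points.

    Refuses (raises :class:`TrackingError` with the reports attached) when
    the two accurate meshes are not comparable — centroids of differently
    cropped or differently tessellated surfaces do not measure motion — or
    when either best-fit alignment diverges.  Alignment RMS values above
    ``rms_warn_mm`` are recorded as warnings, not failures.
    """
    icp = icp or ICPConfig()
    policy = policy or ComparabilityPolicy.strict()
    reference_policy = reference_policy or ComparabilityPolicy.reference_grade()

    comp = check_comparability(t0.accurate, t1.accurate, policy)
    if not comp.passed:
        raise TrackingError(
            "accurate meshes are not comparable between time points; "
            f"failing rules: {comp.failing_rules()}", [comp])
    warnings = []
    for tp in (t0, t1):
        ref_comp = check_comparability(tp.accurate, tp.reference,
                                       reference_policy)
        if not ref_comp.passed:
            warnings.append(
                f"{tp.label}: accurate vs reference comparability rules "
                f"failed: {ref_comp.failing_rules()}")

    aligned0, report0 = _align_timepoint(t0, icp, 0, warnings)
    aligned1, report1 = _align_timepoint(t1, icp, 1, warnings)
    for label, rep in (("initial", report0), ("final", report1)):
        if rep.rms > rms_warn_mm:
            warnings.append(f"{label}: alignment RMS {rep.rms:.3f} mm "
                            f"exceeds warn threshold {rms_warn_mm} mm")

    c0 = surface_centroid(aligned0, centroid_method)
    c1 = surface_centroid(aligned1, centroid_method)
    p0 = to_frame_coords(c0.point, frame)
    p1 = to_frame_coords(c1.point, frame)
    delta = p1 - p0
    return DisplacementRecord(
        roi=roi, dx=float(delta[0]), dy=float(delta[1]), dz=float(delta[2]),
        centroid_initial=c0, centroid_final=c1,
        alignment_initial=report0, alignment_final=report1,
        frame=frame, warnings=warnings)


def displacement_error(measured: DisplacementRecord, planned) -> np.ndarray:
    """Per-axis error, measured minus planned (mm).

    Sign convention is fixed: a positive error means the pipeline measured
    more displacement along that axis than was planned.
    """
    planned = np.asarray(planned, dtype=np.float64).reshape(3)
    return measured.displacement - planned
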