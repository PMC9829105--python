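"""Synthetic stand-in for a simulated-surgery validation study.

Real validation of a displacement-tracking pipeline needs ground truth.  A
hypothetical virtual surgical plan (HVSP) provides it: a bone segment is
moved by a known, randomly drawn translation, and the pipeline must recover
that translation.  This module generates everything such a study needs:

* procedural, watertight, rotationally asymmetric ROI meshes at
  craniofacial scale (a maxilla-like flattened dome and a mandible-like
  horseshoe) standing in for segmented patient anatomy;
* random per-axis translation plans bounded by a clinically plausible
  envelope (Proffit-style discrepancy limits);
* a mesh degradation pipeline emulating the gap between a coarse
  threshold-based reference model and an accurate segmentation
  (decimation + vertex jitter + rigid pre-misalignment);
* the end-to-end study driver producing per-case and summary tables.

Everything is seeded; the same master seed reproduces the study bit for
bit.  Replicate runs ("evaluators" in a real study, which differ by manual
GUI work) differ here by the RNG seeds of every stochastic stage while
keeping the plans and anatomy fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy import stats as sps

from .errors import CentroidTrackError, TrackingError
from .geometry import CartesianFrame, RigidTransform, apply_rigid
from .mesh import DEGENERATE_AREA_FLOOR, TriangleMesh
from .registration import ICPConfig
from .tracking import TimepointModels, displacement_error, track_displacement

ROIS = ("maxilla", "mandible")
AXES = ("x", "y", "z")


def _derived_seed(master: int, *key: int) -> int:
    """Stable per-stage seed: SeedSequence over (master, stage key...)."""
    ss = np.random.SeedSequence([int(master)] + [int(k) for k in key])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Procedural ROI meshes


def _latlong_sphere(n_rings: int, n_lon: int) -> tuple[np.ndarray, np.ndarray]:
    """Watertight unit sphere: poles + latitude rings, 2*n_lon*n_rings faces."""
    thetas = np.pi * np.arange(1, n_rings + 1) / (n_rings + 1)
    phis = 2 * np.pi * np.arange(n_lon) / n_lon
    ring = np.stack([
        np.outer(np.sin(thetas), np.cos(phis)),
        np.outer(np.cos(thetas), np.ones(n_lon)),
        np.outer(np.sin(thetas), np.sin(phis)),
    ], axis=-1).reshape(-1, 3)
    vertices = np.vstack([[0.0, 1.0, 0.0], ring, [0.0, -1.0, 0.0]])
    south = len(vertices) - 1

    def vid(i, j):
        return 1 + i * n_lon + (j % n_lon)

    faces = []
    for j in range(n_lon):
        faces.append([0, vid(0, j), vid(0, j + 1)])
        faces.append([south, vid(n_rings - 1, j + 1), vid(n_rings - 1, j)])
    for i in range(n_rings - 1):
        for j in range(n_lon):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append([a, c, b])
            faces.append([b, c, d])
    return vertices, np.asarray(faces, dtype=np.int64)


def _seeded_bumps(dirs: np.ndarray, rng: np.random.Generator,
                  n_bumps: int = 6) -> np.ndarray:
    """Random smooth radial modulation: kills any rotational symmetry."""
    modulation = np.zeros(len(dirs))
    for _ in range(n_bumps):
        center = rng.normal(size=3)
        center /= np.linalg.norm(center)
        amp = rng.uniform(0.04, 0.12)
        width = rng.uniform(0.35, 0.7)
        ang = np.arccos(np.clip(dirs @ center, -1.0, 1.0))
        modulation += amp * np.exp(-(ang / width) ** 2)
    return modulation


def generate_roi_mesh(roi: str, n_faces_target: int = 2000,
                      seed: int = 0) -> TriangleMesh:
    """Deterministic, closed, asymmetric ROI mesh at anatomical scale.

    ``maxilla``: flattened dome (inferior half compressed) with an anterior
    ridge; ``mandible``: parabolically bent ellipsoid (horseshoe) with a
    chin-like prominence.  Both carry seeded surface bumps so no rotation
    maps the surface onto itself, keeping the best-fit alignment fully
    identifiable.  Bounding box is 40-80 mm per axis.
    """
    if roi not in ROIS:
        raise ValueError(f"roi must be one of {ROIS}, got {roi!r}")
    if n_faces_target < 500:
        raise ValueError("n_faces_target must be >= 500")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, ROIS.index(roi)]))
    n_rings = max(4, round(np.sqrt(n_faces_target) / 2))
    n_lon = max(8, round(n_faces_target / (2 * n_rings)))
    dirs, faces = _latlong_sphere(n_rings, n_lon)

    radial = 1.0 + _seeded_bumps(dirs, rng)
    pts = dirs * radial[:, None]
    if roi == "maxilla":
        pts = pts * np.array([27.0, 20.0, 30.0])
        # compress the inferior half (the occlusal side is flatter)
        squash = 0.80 + 0.20 * np.tanh(3.0 * dirs[:, 1])
        pts[:, 1] *= squash
        # anterior alveolar ridge
        ridge = 2.5 * np.exp(-((dirs[:, 1] + 0.45) / 0.35) ** 2) \
            * np.exp(-(dirs[:, 2] / 0.8) ** 2)
        pts[:, 0] += ridge * np.sign(dirs[:, 0] + 0.2)
    else:
        pts = pts * np.array([32.0, 14.0, 26.0])
        # parabolic bend around the vertical axis -> horseshoe opening
        pts[:, 0] = pts[:, 0] + 0.015 * pts[:, 2] ** 2 - 6.0
        # chin-like anterior-inferior prominence
        chin = np.exp(-((dirs[:, 0] - 0.9) / 0.5) ** 2) \
            * np.exp(-((dirs[:, 1] + 0.3) / 0.6) ** 2)
        pts[:, 0] += 4.0 * chin

    # seeded per-axis rescale guarantees the anatomical bbox range
    extent_target = rng.uniform(45.0, 70.0, size=3)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    pts = (pts - lo) / (hi - lo) * extent_target - extent_target / 2.0

    mesh = TriangleMesh(pts, faces, name=f"{roi}_s{seed}")
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Surgical plans


@dataclass
class Envelope:
    """Per-axis bounds (mm) on feasible segment translations."""

    x: tuple[float, float] = (-15.0, 15.0)
    y: tuple[float, float] = (-15.0, 15.0)
    z: tuple[float, float] = (-5.0, 5.0)

    def bounds(self) -> np.ndarray:
        arr = np.array([self.x, self.y, self.z], dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr[:, 0] > arr[:, 1]):
            raise ValueError("envelope bounds must be finite with lo <= hi")
        return arr


@dataclass
class SimulationPlan:
    """One randomly drawn surgical translation for one segment."""

    patient_id: str
    roi: str
    translation: np.ndarray   # mm, (X sagittal, Y vertical, Z transversal)
    seed: int

    def __post_init__(self):
        self.translation = np.asarray(self.translation,
                                      dtype=np.float64).reshape(3)

    def to_dict(self) -> dict:
        return {"patient_id": self.patient_id, "roi": self.roi,
                "translation_mm": self.translation.tolist(),
                "seed": self.seed}


def sample_plan(roi: str, patient_id: str,
                envelope: Envelope | None = None,
                seed: int = 0) -> SimulationPlan:
    """Draw a plan with each component uniform on its envelope interval."""
    envelope = envelope or Envelope()
    bounds = envelope.bounds()
    rng = np.random.default_rng(seed)
    translation = rng.uniform(bounds[:, 0], bounds[:, 1])
    return SimulationPlan(patient_id=patient_id, roi=roi,
                          translation=translation, seed=seed)


def apply_plan(mesh: TriangleMesh, plan: SimulationPlan) -> TriangleMesh:
    """Realize the planned movement: a pure translation of the segment.

    Rotational components are deliberately absent — the centroid method
    cannot measure them, so plans are translation-only by design.
    """
    moved = mesh.translated(plan.translation)
    moved.name = f"{mesh.name}_moved"
    return moved


# ---------------------------------------------------------------------------
# Degradation


@dataclass
class DegradationConfig:
    """Emulates the quality gap between mesh grades.

    ``keep_face_fraction``: decimation target as a fraction of input faces;
    ``vertex_jitter_sd``: isotropic Gaussian noise per vertex (mm);
    ``max_misalignment_mm`` / ``max_misalignment_deg``: bound on a random
    rigid motion applied last (an arbitrary export pose).
    """

    keep_face_fraction: float = 0.3
    vertex_jitter_sd: float = 0.15
    max_misalignment_mm: float = 2.0
    max_misalignment_deg: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.keep_face_fraction <= 1.0:
            raise ValueError("keep_face_fraction must be in (0, 1]")
        if self.vertex_jitter_sd < 0:
            raise ValueError("vertex_jitter_sd must be >= 0")

    def to_dict(self) -> dict:
        return {"keep_face_fraction": self.keep_face_fraction,
                "vertex_jitter_sd": self.vertex_jitter_sd,
                "max_misalignment_mm": self.max_misalignment_mm,
                "max_misalignment_deg": self.max_misalignment_deg,
                "seed": self.seed}


def random_rigid(max_translation_mm: float, max_rotation_deg: float,
                 rng: np.random.Generator) -> RigidTransform:
    """Random rigid motion with uniformly drawn magnitude up to the bounds."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    translation = direction * rng.uniform(0.0, max_translation_mm)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rotation_deg))
    rotation = Rotation.from_rotvec(axis * angle).as_matrix()
    return RigidTransform(rotation, translation)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, keep: int, drop: int):
        self.parent[self.find(drop)] = self.find(keep)


def _edge_collapse_decimate(mesh: TriangleMesh, target_faces: int,
                            rng: np.random.Generator) -> TriangleMesh:
    """Seeded midpoint edge-collapse decimation.

    Per pass, an independent set of edges (shortest first, random
    tie-break) is collapsed to midpoints; faces that lose a distinct vertex
    die.  Repeats until the live face count reaches the target.
    """
    vertices = mesh.vertices.copy()
    faces = mesh.faces.copy()
    uf = _UnionFind(len(vertices))

    def live_faces() -> np.ndarray:
        mapped = np.array([[uf.find(v) for v in f] for f in faces])
        distinct = ((mapped[:, 0] != mapped[:, 1])
                    & (mapped[:, 1] != mapped[:, 2])
                    & (mapped[:, 0] != mapped[:, 2]))
        return mapped[distinct]

    current = live_faces()
    for _ in range(64):  # pass cap; each pass removes many faces
        n_live = len(current)
        if n_live <= target_faces:
            break
        edges = np.concatenate([current[:, [0, 1]], current[:, [1, 2]],
                                current[:, [2, 0]]])
        edges.sort(axis=1)
        edges = np.unique(edges, axis=0)
        lengths = np.linalg.norm(vertices[edges[:, 0]] - vertices[edges[:, 1]],
                                 axis=1)
        order = np.argsort(lengths + rng.uniform(0, 1e-9, len(lengths)))
        touched = np.zeros(len(vertices), dtype=bool)
        removed_budget = n_live - target_faces
        removed = 0
        for u, v in edges[order]:
            if touched[u] or touched[v]:
                continue
            vertices[u] = 0.5 * (vertices[u] + vertices[v])
            uf.union(u, v)
            touched[u] = touched[v] = True
            removed += 2  # typical faces killed per manifold collapse
            if removed >= removed_budget:
                break
        new = live_faces()
        if len(new) == n_live:
            break
        current = new

    # compact: unique representative vertices, dedup faces, drop degenerates
    used, inverse = np.unique(current, return_inverse=True)
    out_faces = inverse.reshape(current.shape)
    out_vertices = vertices[used]
    key = np.sort(out_faces, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    out_faces = out_faces[np.sort(first)]
    tri = out_vertices[out_faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    out_faces = out_faces[areas > DEGENERATE_AREA_FLOOR]
    return TriangleMesh(out_vertices, out_faces, name=f"{mesh.name}_dec")


def degrade_mesh(mesh: TriangleMesh,
                 config: DegradationConfig) -> TriangleMesh:
    """Apply the seeded degradation pipeline: decimate, jitter, misalign."""
    rng = np.random.default_rng(config.seed)
    out = mesh
    if config.keep_face_fraction < 1.0:
        target = int(round(config.keep_face_fraction * mesh.n_faces))
        if target < 100:
            raise CentroidTrackError(
                f"refusing to decimate below 100 faces (target {target})")
        out = _edge_collapse_decimate(out, target, rng)
    if config.vertex_jitter_sd > 0:
        out = TriangleMesh(
            out.vertices + rng.normal(0.0, config.vertex_jitter_sd,
                                      out.vertices.shape),
            out.faces.copy(), name=f"{out.name}_jit")
    if config.max_misalignment_mm > 0 or config.max_misalignment_deg > 0:
        out = apply_rigid(out, random_rigid(config.max_misalignment_mm,
                                            config.max_misalignment_deg, rng))
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Study driver


@dataclass
class StudyConfig:
    """Conditions of the synthetic validation study.

    Defaults reproduce the study design: 10 patients, maxilla + mandible,
    uniform plans inside the discrepancy envelope, a clean accurate model
    in an arbitrary pose (misaligned up to 2 mm / 2 deg) aligned to a
    heavily degraded reference (30 % of faces kept, 0.15 mm vertex jitter)
    that keeps the true spatial position, and 20 replicate seeds standing
    in for repeated evaluator sessions.
    """

    n_patients: int = 10
    n_replicates: int = 20
    rois: tuple[str, ...] = ROIS
    n_faces: int = 2000
    envelope: Envelope = field(default_factory=Envelope)
    accurate_degradation: DegradationConfig = field(
        default_factory=lambda: DegradationConfig(
            keep_face_fraction=1.0, vertex_jitter_sd=0.0,
            max_misalignment_mm=2.0, max_misalignment_deg=2.0))
    reference_degradation: DegradationConfig = field(
        default_factory=lambda: DegradationConfig(
            keep_face_fraction=0.3, vertex_jitter_sd=0.15,
            max_misalignment_mm=0.0, max_misalignment_deg=0.0))
    icp: ICPConfig = field(
        default_factory=lambda: ICPConfig(n_samples=2000, max_iter=60,
                                          tol_mm=5e-5, n_candidates=6))
    centroid_method: str = "area_weighted_surface"
    rms_warn_mm: float = 0.5

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_replicates": self.n_replicates,
            "rois": list(self.rois),
            "n_faces": self.n_faces,
            "envelope": {"x": list(self.envelope.x),
                         "y": list(self.envelope.y),
                         "z": list(self.envelope.z)},
            "accurate_degradation": self.accurate_degradation.to_dict(),
            "reference_degradation": self.reference_degradation.to_dict(),
            "icp": self.icp.to_dict(),
            "centroid_method": self.centroid_method,
            "rms_warn_mm": self.rms_warn_mm,
        }


@dataclass
class StudyResult:
    """Per-case table plus summaries; summaries always recompute from the
    table, never stored separately."""

    cases: pd.DataFrame
    config: StudyConfig
    seed: int
    replicate_stream: int

    def ok_cases(self) -> pd.DataFrame:
        return self.cases[self.cases["ok"]]

    def summary(self) -> pd.DataFrame:
        """Per ROI x axis error statistics (mean, SD, SE, 95 % CI,
        mean absolute error), recomputed from the per-case table."""
        rows = []
        ok = self.ok_cases()
        for roi in sorted(ok["roi"].unique()):
            sub = ok[ok["roi"] == roi]
            for axis in AXES:
                err = sub[f"error_{axis}"].to_numpy()
                n = len(err)
                mean = err.mean()
                sd = err.std(ddof=1) if n > 1 else 0.0
                se = sd / np.sqrt(n) if n > 1 else 0.0
                tcrit = sps.t.ppf(0.975, n - 1) if n > 1 else np.nan
                rows.append({
                    "roi": roi, "axis": axis, "n": n,
                    "mean_error": mean, "sd_error": sd, "se_error": se,
                    "ci_low": mean - tcrit * se, "ci_high": mean + tcrit * se,
                    "mean_abs_error": np.abs(err).mean(),
                })
        return pd.DataFrame(rows)

    def mean_abs_error_per_axis(self) -> dict[str, float]:
        """Per-axis mean |measured - planned| pooled over ROIs and cases."""
        ok = self.ok_cases()
        return {axis: float(np.abs(ok[f"error_{axis}"]).mean())
                for axis in AXES}


# stage codes in the seed-derivation key
_STAGE_MESH, _STAGE_PLAN, _STAGE_ACC, _STAGE_REF, _STAGE_ICP = range(5)


def run_validation_study(config: StudyConfig | None = None, seed: int = 0,
                         replicate_stream: int = 0) -> StudyResult:
    """Run the full synthetic validation study.

    ``replicate_stream`` reseeds every stochastic stage except anatomy and
    plans; two streams over the same seed emulate two independent
    evaluators measuring the same patients.  Cases refused by the tracking
    pipeline are recorded with ``ok=False`` and the study continues.
    """
    config = config or StudyConfig()
    if config.n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    frame = CartesianFrame.identity()
    rows = []
    for p in range(config.n_patients):
        for roi_i, roi in enumerate(config.rois):
            mesh = generate_roi_mesh(
                roi, config.n_faces,
                seed=_derived_seed(seed, _STAGE_MESH, p, roi_i))
            plan = sample_plan(
                roi, f"patient_{p + 1}", config.envelope,
                seed=_derived_seed(seed, _STAGE_PLAN, p, roi_i))
            moved = apply_plan(mesh, plan)
            for rep in range(config.n_replicates):
                key = (p, roi_i, rep, replicate_stream)
                row = {"patient": p + 1, "roi": roi, "replicate": rep,
                       **{f"planned_{a}": plan.translation[i]
                          for i, a in enumerate(AXES)}}
                try:
                    rec = _run_case(mesh, moved, plan, frame, config,
                                    seed, key)
                    err = displacement_error(rec, plan.translation)
                    row.update({
                        **{f"measured_{a}": rec.displacement[i]
                           for i, a in enumerate(AXES)},
                        **{f"error_{a}": err[i] for i, a in enumerate(AXES)},
                        "rms_t0": rec.alignment_initial.rms,
                        "rms_t1": rec.alignment_final.rms,
                        "ok": True, "failure": "",
                    })
                except TrackingError as exc:
                    row.update({
                        **{f"measured_{a}": np.nan for a in AXES},
                        **{f"error_{a}": np.nan for a in AXES},
                        "rms_t0": np.nan, "rms_t1": np.nan,
                        "ok": False, "failure": str(exc),
                    })
                rows.append(row)
    return StudyResult(cases=pd.DataFrame(rows), config=config, seed=seed,
                       replicate_stream=replicate_stream)


def _run_case(mesh, moved, plan, frame, config, seed, key):
    acc0 = degrade_mesh(mesh, replace(
        config.accurate_degradation,
        seed=_derived_seed(seed, _STAGE_ACC, *key, 0)))
    acc1 = degrade_mesh(moved, replace(
        config.accurate_degradation,
        seed=_derived_seed(seed, _STAGE_ACC, *key, 1)))
    ref0 = degrade_mesh(mesh, replace(
        config.reference_degradation,
        seed=_derived_seed(seed, _STAGE_REF, *key, 0)))
    ref1 = degrade_mesh(moved, replace(
        config.reference_degradation,
        seed=_derived_seed(seed, _STAGE_REF, *key, 1)))
    icp = replace(config.icp, seed=_derived_seed(seed, _STAGE_ICP, *key))
    return track_displacement(
        TimepointModels(acc0, ref0, "initial"),
        TimepointModels(acc1, ref1, "final"),
        frame, icp=icp, centroid_method=config.centroid_method,
        rms_warn_mm=config.rms_warn_mm, roi=plan.roi)
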