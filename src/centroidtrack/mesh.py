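"""Triangle-mesh container, STL I/O, centroids, quality metrics and the
comparability checks that must hold before two regions of interest (ROIs)
can be compared by centroid tracking.

The centroid of a cropped bone segment is only a meaningful proxy for its
spatial position when the two time-point meshes cover the *same* surface
with comparable triangulations: identical crop boundaries, similar triangle
counts and even element sizes.  :func:`check_comparability` encodes those
requirements as explicit, reportable rules instead of silent assumptions.

All coordinates are millimetres.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import DegenerateMeshError, MeshValidationError, STLParseError

#: Faces with area at or below this floor (mm^2) are considered degenerate.
DEGENERATE_AREA_FLOOR = 1e-12

#: Vertices closer than this (mm) are merged into one on STL import.
VERTEX_MERGE_TOL = 1e-6

CENTROID_METHODS = ("area_weighted_surface", "vertex_mean", "enclosed_volume")


@dataclass
class TriangleMesh:
    """Indexed triangle surface in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    name : text label, e.g. ``"maxilla_t0_accurate"``
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = "mesh"

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")

    # -- basic accessors -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        tri = self.triangles()
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(bbox_min, bbox_max) of the vertex set."""
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def copy(self, name: str | None = None) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(),
                            name if name is not None else self.name)

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, dtype=float),
                            self.faces.copy(), self.name)

    # -- validation ------------------------------------------------------
    def validate(self, structural_only: bool = False) -> None:
        """Raise :class:`MeshValidationError` on any invariant violation.

        ``structural_only`` skips the minimum-size rule (>= 4 vertices and
        faces) so that geometric helpers can operate on e.g. a single
        triangle; the full check applies to every mesh exchanged between
        pipeline stages.
        """
        if self.n_vertices == 0 or self.n_faces == 0:
            raise MeshValidationError(f"{self.name}: empty mesh")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise MeshValidationError(f"{self.name}: face index out of range")
        repeated = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if repeated.any():
            bad = np.flatnonzero(repeated).tolist()
            raise MeshValidationError(
                f"{self.name}: faces with repeated vertices: {bad[:10]}",
                bad_faces=bad)
        areas = self.face_areas()
        degenerate = areas <= DEGENERATE_AREA_FLOOR
        if degenerate.any():
            bad = np.flatnonzero(degenerate).tolist()
            raise MeshValidationError(
                f"{self.name}: {len(bad)} degenerate (zero-area) faces, "
                f"e.g. {bad[:10]}", bad_faces=bad)
        if not structural_only and (self.n_vertices < 4 or self.n_faces < 4):
            raise MeshValidationError(
                f"{self.name}: mesh too small "
                f"({self.n_vertices} vertices, {self.n_faces} faces)")

    def is_closed(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        edges = _undirected_edges(self.faces, unique=False)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool((counts == 2).all())


@dataclass
class Centroid:
    """A single 3D point summarizing a surface's spatial position."""

    point: np.ndarray
    method: str
    source_mesh: str

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=np.float64).reshape(3)

    def to_dict(self) -> dict:
        return {"point": self.point.tolist(), "method": self.method,
                "source_mesh": self.source_mesh}


@dataclass
class MeshQuality:
    """Summary metrics used by the comparability rules."""

    n_vertices: int
    n_faces: int
    total_area: float          # mm^2
    edge_length_cv: float      # SD/mean over unique undirected edges
    bbox_min: np.ndarray       # mm
    bbox_max: np.ndarray       # mm

    def to_dict(self) -> dict:
        return {
            "n_vertices": self.n_vertices,
            "n_faces": self.n_faces,
            "total_area": self.total_area,
            "edge_length_cv": self.edge_length_cv,
            "bbox_min": np.asarray(self.bbox_min).tolist(),
            "bbox_max": np.asarray(self.bbox_max).tolist(),
        }


# ---------------------------------------------------------------------------
# STL I/O


def _merge_close_vertices(vertices: np.ndarray, faces: np.ndarray,
                          tol: float = VERTEX_MERGE_TOL):
    """Weld vertices that coincide within ``tol`` (grid quantization)."""
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True,
                                  return_inverse=True)
    return vertices[first], inverse[faces]


def read_stl(path, name: str | None = None) -> TriangleMesh:
    """Read a binary or ASCII STL file into an indexed :class:`TriangleMesh`.

    Duplicate vertices within :data:`VERTEX_MERGE_TOL` are merged; facet
    normals stored in the file are discarded (normals are implied by face
    winding).  Raises :class:`STLParseError` on unreadable/truncated files
    and :class:`MeshValidationError` if the merged mesh violates the
    invariants (e.g. zero-area facets).
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 15:
        raise STLParseError(f"{path}: file too short to be STL "
                            f"(only {len(data)} bytes)", str(path), len(data))
    is_ascii = data.lstrip()[:5].lower() == b"solid" and b"facet" in data[:2048]
    if not is_ascii:
        if len(data) < 84:
            raise STLParseError(
                f"{path}: truncated binary STL header at byte {len(data)}",
                str(path), len(data))
        n_facets = int(np.frombuffer(data[80:84], dtype="<u4")[0])
        expected = 84 + 50 * n_facets
        if len(data) < expected:
            raise STLParseError(
                f"{path}: truncated binary STL — header declares {n_facets} "
                f"facets ({expected} bytes) but file ends at byte {len(data)}",
                str(path), len(data))
    try:
        loaded = trimesh.load(io.BytesIO(data), file_type="stl",
                              process=False, force="mesh")
    except Exception as exc:  # trimesh raises assorted types on bad input
        raise STLParseError(f"{path}: STL parse failed near byte "
                            f"{len(data)}: {exc}", str(path), len(data)) from exc
    vertices = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    vertices, faces = _merge_close_vertices(vertices, faces)
    mesh = TriangleMesh(vertices, faces, name or path.stem)
    mesh.validate()
    return mesh


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write ``mesh`` as STL; ``dialect`` is ``"binary"`` or ``"ascii"``.

    The written file round-trips through :func:`read_stl` with geometric
    identity to :data:`VERTEX_MERGE_TOL`.
    """
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    mesh.validate()
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    payload = tm.export(file_type=file_type)
    path = Path(path)
    if isinstance(payload, str):
        path.write_text(payload)
    else:
        path.write_bytes(payload)


# ---------------------------------------------------------------------------
# Centroids


def surface_centroid(mesh: TriangleMesh,
                     method: str = "area_weighted_surface") -> Centroid:
    """Centroid of a surface by one of three definitions.

    ``area_weighted_surface`` (default)
        Area-weighted mean of triangle barycenters.  Invariant under any
        re-triangulation that preserves the surface pointwise, which makes
        it robust to differing mesh densities between time points.
    ``vertex_mean``
        Plain mean of the unique vertex positions; cheap but density-biased.
    ``enclosed_volume``
        Centroid of the enclosed solid via the divergence theorem; requires
        a closed (watertight) mesh.
    """
    if method not in CENTROID_METHODS:
        raise ValueError(f"unknown centroid method {method!r}; "
                         f"choose from {CENTROID_METHODS}")
    mesh.validate(structural_only=True)
    if method == "vertex_mean":
        unique = np.unique(mesh.vertices, axis=0)
        point = unique.mean(axis=0)
    elif method == "area_weighted_surface":
        tri = mesh.triangles()
        areas = mesh.face_areas()
        total = areas.sum()
        if total <= DEGENERATE_AREA_FLOOR:
            raise DegenerateMeshError(
                f"{mesh.name}: total area {total:g} mm^2 below floor")
        barycenters = tri.mean(axis=1)
        point = (areas[:, None] * barycenters).sum(axis=0) / total
    else:  # enclosed_volume
        if not mesh.is_closed():
            raise DegenerateMeshError(
                f"{mesh.name}: enclosed_volume centroid requires a closed "
                "(watertight) mesh")
        tri = mesh.triangles()
        # Signed tetrahedron volumes against the origin.
        v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
        signed = np.einsum("ij,ij->i", v0, np.cross(v1, v2)) / 6.0
        volume = signed.sum()
        if abs(volume) < 1e-9:
            raise DegenerateMeshError(
                f"{mesh.name}: enclosed volume {volume:g} mm^3 too small")
        tet_centroids = (v0 + v1 + v2) / 4.0  # 4th vertex is the origin
        point = (signed[:, None] * tet_centroids).sum(axis=0) / volume
    return Centroid(point=point, method=method, source_mesh=mesh.name)


# ---------------------------------------------------------------------------
# Quality metrics


def _undirected_edges(faces: np.ndarray, unique: bool = True) -> np.ndarray:
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                            faces[:, [2, 0]]])
    edges.sort(axis=1)
    if unique:
        edges = np.unique(edges, axis=0)
    return edges


def mesh_quality(mesh: TriangleMesh) -> MeshQuality:
    """Compute the quality metrics; each undirected edge counts once."""
    mesh.validate(structural_only=True)
    edges = _undirected_edges(mesh.faces)
    lengths = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
    mean = lengths.mean()
    cv = float(lengths.std() / mean) if mean > 0 else 0.0
    bbox_min, bbox_max = mesh.bounds()
    return MeshQuality(
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        total_area=float(mesh.face_areas().sum()),
        edge_length_cv=cv,
        bbox_min=bbox_min,
        bbox_max=bbox_max,
    )


# ---------------------------------------------------------------------------
# Comparability


@dataclass
class ComparabilityPolicy:
    """Thresholds for the four comparability rules.

    ``face_count_ratio_bounds`` / ``area_ratio_bounds`` bound the ratio
    quality(a)/quality(b); ``max_bbox_extent_diff_mm`` bounds the per-axis
    difference of bounding-box extents (each mesh centered on its own
    centroid first); ``max_edge_length_cv`` bounds element-size unevenness.
    """

    face_count_ratio_bounds: tuple[float, float] = (0.9, 1.1)
    area_ratio_bounds: tuple[float, float] = (0.9, 1.1)
    max_bbox_extent_diff_mm: float = 2.0
    max_edge_length_cv: float = 0.6

    @classmethod
    def strict(cls) -> "ComparabilityPolicy":
        """Default policy: two segmentations of the same ROI crop."""
        return cls()

    @classmethod
    def reference_grade(cls) -> "ComparabilityPolicy":
        """Loose policy for an accurate model vs its coarse spatial
        reference, which may be heavily decimated and jittered."""
        return cls(face_count_ratio_bounds=(0.08, 12.0),
                   area_ratio_bounds=(0.7, 1.4),
                   max_bbox_extent_diff_mm=4.0,
                   max_edge_length_cv=1.2)


@dataclass
class RuleResult:
    name: str
    passed: bool
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"name": self.name, "passed": self.passed, "detail": self.detail}


@dataclass
class ComparabilityReport:
    rules: list[RuleResult]
    passed: bool
    mesh_a: str
    mesh_b: str

    def failing_rules(self) -> list[str]:
        return [r.name for r in self.rules if not r.passed]

    def to_dict(self) -> dict:
        return {"mesh_a": self.mesh_a, "mesh_b": self.mesh_b,
                "passed": self.passed,
                "rules": [r.to_dict() for r in self.rules]}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def check_comparability(a: TriangleMesh, b: TriangleMesh,
                        policy: ComparabilityPolicy | None = None
                        ) -> ComparabilityReport:
    """Check whether two meshes may be compared by centroid tracking.

    Failures never raise — every rule verdict is reported so the caller can
    decide (the tracking pipeline refuses failed pairs with the report
    attached).
    """
    policy = policy or ComparabilityPolicy.strict()
    qa, qb = mesh_quality(a), mesh_quality(b)
    rules = []

    lo, hi = policy.face_count_ratio_bounds
    ratio = qa.n_faces / qb.n_faces
    rules.append(RuleResult(
        "face_count_ratio", lo <= ratio <= hi,
        {"ratio": ratio, "bounds": [lo, hi],
         "n_faces_a": qa.n_faces, "n_faces_b": qb.n_faces}))

    lo, hi = policy.area_ratio_bounds
    ratio = qa.total_area / qb.total_area
    rules.append(RuleResult(
        "total_area_ratio", lo <= ratio <= hi,
        {"ratio": ratio, "bounds": [lo, hi]}))

    extent_a = np.asarray(qa.bbox_max) - np.asarray(qa.bbox_min)
    extent_b = np.asarray(qb.bbox_max) - np.asarray(qb.bbox_min)
    diff = np.abs(extent_a - extent_b)
    rules.append(RuleResult(
        "bbox_extents", bool((diff <= policy.max_bbox_extent_diff_mm).all()),
        {"extent_diff_mm": diff.tolist(),
         "threshold_mm": policy.max_bbox_extent_diff_mm}))

    rules.append(RuleResult(
        "edge_length_cv",
        qa.edge_length_cv <= policy.max_edge_length_cv
        and qb.edge_length_cv <= policy.max_edge_length_cv,
        {"cv_a": qa.edge_length_cv, "cv_b": qb.edge_length_cv,
         "threshold": policy.max_edge_length_cv}))

    return ComparabilityReport(rules=rules,
                               passed=all(r.passed for r in rules),
                               mesh_a=a.name, mesh_b=b.name)
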