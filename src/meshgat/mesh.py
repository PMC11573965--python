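"""Triangle-mesh representation, I/O, ROI extraction, signed distance and hole QC.

The mesh is the unit of analysis for the whole pipeline: every tumor ROI is
represented as a triangle surface mesh, screened for structural damage (holes)
before any feature is computed, and optionally queried with a signed distance
field (negative inside the closed surface, positive outside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

log = logging.getLogger(__name__)

SUPPORTED_FORMATS = ("ply", "obj", "off", "stl")


class EmptyMeshError(ValueError):
    """Raised when a parsed or constructed mesh has no faces."""


class DegenerateMeshError(ValueError):
    """Raised when a mesh is too degenerate for the requested operation."""


@dataclass
class TriangleMesh:
    """A triangle surface mesh: ``vertices`` (n, 3) float64, ``faces`` (m, 3) int64.

    Vertex order is preserved from file; faces index into ``vertices``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str | None = None
    mesh_id: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    def validate(self) -> None:
        if len(self.vertices) < 3:
            raise DegenerateMeshError("mesh needs at least 3 vertices")
        if len(self.faces) < 1:
            raise EmptyMeshError("mesh has no faces")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        f = self.faces
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise ValueError("face with repeated vertex index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(), self.label, self.mesh_id
        )

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: _trimesh.Trimesh, **kw) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), **kw)


@dataclass
class SignedDistanceResult:
    """Closest-point query against a mesh surface.

    ``projection`` is the closest surface point, ``offset = p - projection``,
    ``unsigned_distance = |offset|`` and ``signed_distance`` carries the
    inside/outside sign (positive outside).
    """

    projection: np.ndarray
    offset: np.ndarray
    unsigned_distance: float
    signed_distance: float
    surface_normal_at_projection: np.ndarray


@dataclass
class MeshQCReport:
    total_edges: int
    boundary_edges: int
    hole_percentage: float
    passed: bool
    mesh_id: str | None = None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; use one of {SUPPORTED_FORMATS}")
    return fmt


def read_mesh(path: str | Path, format: str | None = None) -> TriangleMesh:
    """Read a triangle mesh from PLY/OBJ/OFF/STL.

    Non-triangular faces are triangulated (fan decomposition); vertex order is
    preserved (no merging or processing).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    tm = _trimesh.load_mesh(str(path), file_type=fmt, process=False)
    if isinstance(tm, _trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise EmptyMeshError(f"no geometry in {path}")
        tm = _trimesh.util.concatenate(geoms)
    faces = np.asarray(tm.faces)
    if faces.size == 0:
        raise EmptyMeshError(f"no faces parsed from {path}")
    mesh = TriangleMesh(np.asarray(tm.vertices), faces, mesh_id=path.stem)
    mesh.validate()
    return mesh


def write_mesh(mesh: TriangleMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh to PLY/OBJ/OFF/STL (ascii for OBJ/OFF, binary PLY/STL)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    mesh.validate()
    tm = mesh.to_trimesh()
    try:
        tm.export(str(path), file_type=fmt)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise IOError(f"cannot write mesh to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Isolate the tumor region: keep image pixels where the mask is foreground.

    Implements the bitwise-AND masking of a grayscale ultrasound image with its
    binary ground-truth mask. Mask may be {0, 1} or {0, 255}.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} shapes differ")
    return np.where(mask > 0, image, 0).astype(image.dtype)


# ---------------------------------------------------------------------------
# Hole quality control
# ---------------------------------------------------------------------------

def _undirected_edges(faces: np.ndarray) -> np.ndarray:
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    return np.sort(e, axis=1)


def hole_percentage(mesh: TriangleMesh, threshold: float = 10.0) -> MeshQCReport:
    """Quantify structural damage as the boundary-edge fraction of all edges.

    A boundary edge belongs to exactly one triangle and is the discrete
    signature of a hole; a watertight mesh scores 0%. ``passed`` is False
    exactly when the percentage exceeds ``threshold`` (strictly), i.e. a mesh
    with *more than* ``threshold`` percent compromised structure is rejected.
    """
    mesh.validate()
    edges = _undirected_edges(mesh.faces)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    total = len(counts)
    boundary = int(np.sum(counts == 1))
    pct = 100.0 * boundary / total
    return MeshQCReport(
        total_edges=total,
        boundary_edges=boundary,
        hole_percentage=pct,
        passed=not (pct > threshold),
        mesh_id=mesh.mesh_id,
    )


def is_watertight(mesh: TriangleMesh) -> bool:
    return hole_percentage(mesh).boundary_edges == 0


def qc_filter(
    meshes: list[TriangleMesh], threshold: float = 10.0
) -> tuple[list[TriangleMesh], list[TriangleMesh], list[MeshQCReport]]:
    """Partition meshes into retained / excluded by the hole-percentage rule."""
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must be in [0, 100]")
    retained, excluded, reports = [], [], []
    for i, mesh in enumerate(meshes):
        rep = hole_percentage(mesh, threshold)
        if rep.mesh_id is None:
            rep.mesh_id = str(i)
        reports.append(rep)
        if rep.passed:
            retained.append(mesh)
        else:
            excluded.append(mesh)
            log.info(
                "excluding mesh %s: %.2f%% boundary edges (> %.2f%%)",
                rep.mesh_id, rep.hole_percentage, threshold,
            )
    return retained, excluded, reports


# ---------------------------------------------------------------------------
# Signed distance field
# ---------------------------------------------------------------------------

def ensure_outward_orientation(mesh: TriangleMesh) -> TriangleMesh:
    """Return a copy with consistent winding and outward-facing normals."""
    tm = mesh.to_trimesh()
    _trimesh.repair.fix_normals(tm)
    if tm.is_volume and tm.volume < 0:  # pragma: no cover - fix_normals handles it
        tm.invert()
    return TriangleMesh(
        np.asarray(tm.vertices), np.asarray(tm.faces), mesh.label, mesh.mesh_id
    )


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point to ``p`` on each triangle of ``tri`` (m,3,3).

    Vectorized region-based point/triangle projection; returns closest points
    (m, 3) and barycentric coordinates (m, 3).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    m = len(tri)
    u = np.empty(m)
    v = np.empty(m)
    w = np.empty(m)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    denom_in = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        # interior (default; overwritten by edge/vertex regions below)
        v_in = np.where(denom_in != 0, vb / np.where(denom_in == 0, 1, denom_in), 0.0)
        w_in = np.where(denom_in != 0, vc / np.where(denom_in == 0, 1, denom_in), 0.0)
    u[:] = 1.0 - v_in - w_in
    v[:] = v_in
    w[:] = w_in

    # edge AC region
    t_ac = np.clip(np.where(d2 - d6 != 0, d2 / np.where((d2 - d6) == 0, 1, d2 - d6), 0), 0, 1)
    reg_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    u[reg_ac] = 1 - t_ac[reg_ac]
    v[reg_ac] = 0.0
    w[reg_ac] = t_ac[reg_ac]
    # edge BC region
    denom_bc = (d4 - d3) + (d5 - d6)
    t_bc = np.clip(
        np.where(denom_bc != 0, (d4 - d3) / np.where(denom_bc == 0, 1, denom_bc), 0), 0, 1
    )
    reg_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    u[reg_bc] = 0.0
    v[reg_bc] = 1 - t_bc[reg_bc]
    w[reg_bc] = t_bc[reg_bc]
    # edge AB region
    t_ab = np.clip(np.where(d1 - d3 != 0, d1 / np.where((d1 - d3) == 0, 1, d1 - d3), 0), 0, 1)
    reg_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    u[reg_ab] = 1 - t_ab[reg_ab]
    v[reg_ab] = t_ab[reg_ab]
    w[reg_ab] = 0.0
    # vertex regions (checked last: they override edges)
    reg_a = (d1 <= 0) & (d2 <= 0)
    u[reg_a], v[reg_a], w[reg_a] = 1.0, 0.0, 0.0
    reg_b = (d3 >= 0) & (d4 <= d3)
    u[reg_b], v[reg_b], w[reg_b] = 0.0, 1.0, 0.0
    reg_c = (d6 >= 0) & (d5 <= d6)
    u[reg_c], v[reg_c], w[reg_c] = 0.0, 0.0, 1.0

    bary = np.stack([u, v, w], axis=1)
    pts = (bary[:, :, None] * tri).sum(axis=1)
    return pts, bary


def _pseudo_normals(mesh: TriangleMesh):
    """Face normals plus angle-weighted vertex and edge pseudo-normals."""
    tri = mesh.triangles()
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(fn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    fn = fn / norms

    # angle-weighted vertex normals
    vn = np.zeros_like(mesh.vertices)
    for corner in range(3):
        i = mesh.faces[:, corner]
        e1 = tri[:, (corner + 1) % 3] - tri[:, corner]
        e2 = tri[:, (corner + 2) % 3] - tri[:, corner]
        cosang = np.einsum("ij,ij->i", e1, e2) / (
            np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1) + 1e-300
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(vn, i, fn * ang[:, None])
    n = np.linalg.norm(vn, axis=1, keepdims=True)
    n[n == 0] = 1.0
    vn = vn / n

    # edge pseudo-normals: sum of adjacent face normals
    edges = _undirected_edges(mesh.faces)
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    en = np.zeros((len(uniq), 3))
    face_idx = np.tile(np.arange(len(mesh.faces)), 3)
    np.add.at(en, inv, fn[face_idx])
    n = np.linalg.norm(en, axis=1, keepdims=True)
    n[n == 0] = 1.0
    en = en / n
    edge_key = {tuple(e): k for k, e in enumerate(uniq)}
    return fn, vn, en, edge_key


def signed_distance(p, mesh: TriangleMesh) -> SignedDistanceResult:
    """Signed distance from point ``p`` to the mesh surface.

    The projection is the exact closest point over all triangles; the sign is
    taken from the angle-weighted pseudo-normal of the nearest surface feature
    (face interior, edge, or vertex), positive outside and negative inside.
    Assumes consistently outward-oriented faces (see
    :func:`ensure_outward_orientation`).
    """
    mesh.validate()
    p = np.asarray(p, dtype=np.float64).reshape(3)
    tri = mesh.triangles()
    pts, bary = _closest_point_on_triangles(p, tri)
    d2 = np.einsum("ij,ij->i", p - pts, p - pts)
    fi = int(np.argmin(d2))
    proj = pts[fi]
    offset = p - proj
    dist = float(np.sqrt(d2[fi]))

    fn, vn, en, edge_key = _pseudo_normals(mesh)
    b = bary[fi]
    eps = 1e-12
    zero = b <= eps
    if not zero.any():
        normal = fn[fi]
    elif zero.sum() == 2:  # vertex
        corner = int(np.flatnonzero(~zero)[0])
        normal = vn[mesh.faces[fi, corner]]
    else:  # edge (one barycentric coordinate is zero)
        corner = int(np.flatnonzero(zero)[0])
        ij = sorted((mesh.faces[fi, (corner + 1) % 3], mesh.faces[fi, (corner + 2) % 3]))
        normal = en[edge_key[tuple(ij)]]

    sign = 1.0 if float(np.dot(offset, normal)) >= 0 else -1.0
    return SignedDistanceResult(
        projection=proj,
        offset=offset,
        unsigned_distance=dist,
        signed_distance=sign * dist,
        surface_normal_at_projection=normal,
    )
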