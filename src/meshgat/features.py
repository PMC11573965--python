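"""The ten mesh features used to characterize tumor shape.

Structural features (sphericity, anisotropy, eigen-entropy, curvature, volume,
surface area) capture how round, elongated or rugged the surface is; distance
features (farthest distance, centroid distance, bounding-box min/max distance)
capture extent. Eigenvalue features come from the covariance of vertex
coordinates: curvature and eigen-entropy from local k-nearest-neighbor
neighborhoods (averaged over vertices), anisotropy from the whole-mesh
covariance — anisotropy describes the directional distribution of the point
set as a whole, while curvature/entropy describe local surface behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree, ConvexHull, QhullError

from .mesh import TriangleMesh, hole_percentage, DegenerateMeshError

log = logging.getLogger(__name__)

FEATURE_NAMES = [
    "sphericity",
    "anisotropy",
    "eigen_entropy",
    "curvature",
    "farthest_distance",
    "centroid_distance",
    "bb_min_distance",
    "bb_max_distance",
    "volume",
    "surface_area",
]

TABLE_COLUMNS = ["unique_id", *FEATURE_NAMES, "target"]
LABELS = ("benign", "malignant")


@dataclass
class FeatureConfig:
    """Knobs for feature extraction.

    k: local neighborhood size for per-vertex covariance (capped at n_vertices).
    bb_mode: 'corner' (vertex-to-box-corner distances) or 'face'
        (vertex-to-box-surface distances).
    anisotropy_mode / curvature, entropy are fixed local: anisotropy may be
        'global' (whole-mesh covariance; default) or 'local'.
    normalize: rescale the mesh to unit bounding-box diagonal before computing
        features (off by default; features are reported in raw mesh units).
    """

    k: int = 30
    bb_mode: str = "corner"
    anisotropy_mode: str = "global"
    normalize: bool = False


@dataclass
class EigenTriple:
    """Normalized covariance eigenvalues, lambda1 >= lambda2 >= lambda3 >= 0, summing to 1."""

    lambda1: float
    lambda2: float
    lambda3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3])


@dataclass
class FeatureVector:
    sphericity: float
    anisotropy: float
    eigen_entropy: float
    curvature: float
    farthest_distance: float
    centroid_distance: float
    bb_min_distance: float
    bb_max_distance: float
    volume: float
    surface_area: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


# ---------------------------------------------------------------------------
# Covariance eigenvalues
# ---------------------------------------------------------------------------

def _normalized_eigvals(cov: np.ndarray) -> np.ndarray:
    """Descending, clamped-at-zero, sum-normalized eigenvalues of (..., 3, 3)."""
    lam = np.linalg.eigvalsh(cov)[..., ::-1]
    lam = np.clip(lam, 0.0, None)
    s = lam.sum(axis=-1, keepdims=True)
    return lam / np.where(s == 0.0, 1.0, s), s[..., 0]


def covariance_eigenvalues(
    points: np.ndarray, mode: str = "global", k: int = 30
) -> EigenTriple | np.ndarray:
    """Normalized covariance eigenvalues of a 3D point set.

    ``global`` returns one :class:`EigenTriple` for the centered point cloud;
    ``local`` returns an (n, 3) array of normalized triples, one per point,
    from its k-nearest-neighbor set (the point included).
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(points) < 4:
        raise DegenerateMeshError("need at least 4 points for covariance eigenvalues")
    if mode == "global":
        centered = points - points.mean(axis=0)
        cov = centered.T @ centered / len(points)
        lam, total = _normalized_eigvals(cov)
        if total == 0.0:
            raise DegenerateMeshError("degenerate point set: zero covariance")
        return EigenTriple(*lam)
    if mode != "local":
        raise ValueError(f"unknown mode {mode!r}")
    k = min(max(k, 4), len(points))
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k)
    nb = points[idx]  # (n, k, 3)
    nb = nb - nb.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", nb, nb) / k
    lam, total = _normalized_eigvals(cov)
    if np.all(total == 0.0):
        raise DegenerateMeshError("all local neighborhoods degenerate")
    if np.any(total == 0.0):
        log.warning("%d degenerate local neighborhoods skipped", int((total == 0).sum()))
        lam = lam[total > 0.0]
    return lam


def _local_triples(mesh: TriangleMesh, k: int) -> np.ndarray:
    mesh.validate()
    return covariance_eigenvalues(mesh.vertices, mode="local", k=k)


def curvature(mesh: TriangleMesh, k: int = 30) -> float:
    """Mean local curvature proxy: average over vertices of lambda3 / sum(lambda).

    0 on a plane; bounded above by 1/3 (isotropic neighborhoods).
    """
    lam = _local_triples(mesh, k)
    return float(np.mean(lam[:, 2]))  # triples are sum-normalized


def anisotropy(mesh: TriangleMesh, mode: str = "global", k: int = 30) -> float:
    """(lambda1 - lambda3) / lambda1: 0 isotropic, 1 fully degenerate.

    Default uses the whole-mesh covariance (directional distribution of the
    vertex cloud); ``mode='local'`` averages the same ratio over per-vertex
    neighborhoods.
    """
    if mode == "global":
        lam = covariance_eigenvalues(mesh.vertices, mode="global").as_array()
        if lam[0] == 0:
            raise DegenerateMeshError("zero leading eigenvalue")
        return float((lam[0] - lam[2]) / lam[0])
    lam = _local_triples(mesh, k)
    ok = lam[:, 0] > 0
    if not ok.any():
        raise DegenerateMeshError("all local neighborhoods degenerate")
    if not ok.all():
        log.warning("skipping %d sites with lambda1 = 0", int((~ok).sum()))
    lam = lam[ok]
    return float(np.mean((lam[:, 0] - lam[:, 2]) / lam[:, 0]))


def eigen_entropy(mesh: TriangleMesh, k: int = 30) -> float:
    """Mean Shannon entropy of the normalized local eigenvalue triples.

    -sum(lambda_i ln lambda_i) with 0 ln 0 := 0; in [0, ln 3]. High values mean
    locally isotropic (rugged) neighborhoods, low values flat or linear ones.
    """
    lam = _local_triples(mesh, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(lam > 0, lam * np.log(lam), 0.0)
    return float(np.mean(-t.sum(axis=1)))


# ---------------------------------------------------------------------------
# Size and distance features
# ---------------------------------------------------------------------------

def volume(mesh: TriangleMesh) -> float:
    """Enclosed volume as |sum of signed tetrahedra (1/6)(v1 x v2) . v3|.

    Exact and translation-invariant for watertight meshes; for open meshes the
    value is the same sum and only approximate.
    """
    mesh.validate()
    tri = mesh.triangles()
    v = np.einsum(
        "ij,ij->i", np.cross(tri[:, 0], tri[:, 1]), tri[:, 2]
    ).sum() / 6.0
    return float(abs(v))


def surface_area(mesh: TriangleMesh) -> float:
    """Total triangle area: sum of 0.5 |(v2 - v1) x (v3 - v1)|."""
    mesh.validate()
    tri = mesh.triangles()
    cr = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cr, axis=1).sum())


def sphericity(mesh: TriangleMesh) -> float:
    """Isoperimetric ratio pi^(1/3) (6V)^(2/3) / Sa; 1 for a sphere, < 1 otherwise."""
    rep = hole_percentage(mesh)
    if rep.boundary_edges > 0:
        raise ValueError(
            "sphericity requires a watertight mesh "
            f"({rep.boundary_edges} boundary edges; run qc_filter first)"
        )
    v = volume(mesh)
    sa = surface_area(mesh)
    if v <= 0 or sa <= 0:
        raise DegenerateMeshError("sphericity undefined for zero volume or area")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / sa)


def bounding_box_distances(mesh: TriangleMesh, mode: str = "corner") -> tuple[float, float]:
    """Shortest and longest distance between mesh vertices and the bounding box.

    'corner': Euclidean distances from every vertex to each of the 8 corners
    of the axis-aligned bounding box (min and max over all pairs).
    'face': distance from each vertex to the nearest box surface for the min,
    to the farthest corner for the max.
    """
    mesh.validate()
    v = mesh.vertices
    lo, hi = v.min(axis=0), v.max(axis=0)
    corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                        for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    d = np.linalg.norm(v[:, None, :] - corners[None, :, :], axis=2)
    if mode == "corner":
        return float(d.min()), float(d.max())
    if mode == "face":
        slab = np.minimum(v - lo, hi - v)  # distance to each pair of box faces
        return float(slab.min()), float(d.max())
    raise ValueError(f"unknown bb mode {mode!r}")


def farthest_distance(mesh: TriangleMesh) -> float:
    """Mesh diameter: maximum pairwise vertex distance (via convex hull)."""
    mesh.validate()
    v = mesh.vertices
    if len(v) > 20:
        try:
            v = v[ConvexHull(v).vertices]
        except QhullError:
            pass  # degenerate (flat/collinear) cloud: brute force below
    d2 = np.sum((v[:, None, :] - v[None, :, :]) ** 2, axis=2)
    return float(np.sqrt(d2.max()))


def centroid_distance(mesh: TriangleMesh) -> float:
    """Mean distance from the area-weighted surface centroid to the vertices."""
    mesh.validate()
    tri = mesh.triangles()
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    if areas.sum() == 0:
        raise DegenerateMeshError("total face area is zero")
    centroids = tri.mean(axis=1)
    center = (centroids * areas[:, None]).sum(axis=0) / areas.sum()
    return float(np.mean(np.linalg.norm(mesh.vertices - center, axis=1)))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def extract_features(mesh: TriangleMesh, config: FeatureConfig | None = None) -> FeatureVector:
    """Compute all ten features, sharing one local eigen-analysis pass."""
    config = config or FeatureConfig()
    mesh.validate()
    work = mesh
    if config.normalize:
        v = mesh.vertices
        diag = np.linalg.norm(v.max(axis=0) - v.min(axis=0))
        if diag == 0:
            raise DegenerateMeshError("degenerate bounding box")
        work = TriangleMesh(v / diag, mesh.faces, mesh.label, mesh.mesh_id)

    lam = _local_triples(work, config.k)
    curv = float(np.mean(lam[:, 2]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(lam > 0, lam * np.log(lam), 0.0)
    entropy = float(np.mean(-t.sum(axis=1)))
    if config.anisotropy_mode == "global":
        aniso = anisotropy(work, mode="global")
    else:
        ok = lam[:, 0] > 0
        aniso = float(np.mean((lam[ok, 0] - lam[ok, 2]) / lam[ok, 0]))

    bb_min, bb_max = bounding_box_distances(work, config.bb_mode)
    return FeatureVector(
        sphericity=sphericity(work),
        anisotropy=aniso,
        eigen_entropy=entropy,
        curvature=curv,
        farthest_distance=farthest_distance(work),
        centroid_distance=centroid_distance(work),
        bb_min_distance=bb_min,
        bb_max_distance=bb_max,
        volume=volume(work),
        surface_area=surface_area(work),
    )


def build_feature_table(
    meshes: list[TriangleMesh], config: FeatureConfig | None = None
) -> pd.DataFrame:
    """One row per mesh: unique_id (1-based), the ten features, and the label."""
    rows = []
    for i, mesh in enumerate(meshes):
        if mesh.label not in LABELS:
            raise ValueError(
                f"mesh {mesh.mesh_id or i} has no benign/malignant label (got {mesh.label!r})"
            )
        fv = extract_features(mesh, config)
        rows.append({"unique_id": i + 1, **fv.as_dict(), "target": mesh.label})
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    return table[TABLE_COLUMNS]
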