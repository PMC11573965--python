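"""Synthetic tumor-mesh generator: smooth/round vs spiculated/irregular surfaces.

Benign-like lesions are modelled as gently lobulated ellipsoids (regular oval
shape, smooth margin); malignant-like lesions as larger, more eccentric
ellipsoids carrying Gaussian radial spikes (spiculation) and high-frequency
surface noise. Every mesh is a radially displaced subdivided icosphere, so it
is closed (watertight) by construction, and fully deterministic per seed.

A ``separation`` dial in [0, 1] interpolates the malignant parameter set from
the benign baseline (0 = the two classes are statistically identical) to full
contrast (1); per-mesh parameter jitter provides within-class variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh as _trimesh

from .mesh import TriangleMesh

__all__ = [
    "ShapeParams",
    "BENIGN_DEFAULTS",
    "MALIGNANT_DEFAULTS",
    "make_benign_mesh",
    "make_malignant_mesh",
    "make_dataset",
    "punch_holes",
]


@dataclass(frozen=True)
class ShapeParams:
    """Parameters of one synthetic tumor surface.

    axes: base ellipsoid semi-axes (mesh units, e.g. millimetres).
    lobulation_amplitude / lobulation_frequency: low-order smooth radial
        modulation (macro-lobulation of the margin).
    spike_count / spike_amplitude / spike_sharpness: number, relative radial
        height and angular width (radians) of Gaussian spiculation bumps at
        random unit directions.
    noise_sd: sd of per-vertex high-frequency radial noise (relative units).
    subdivisions: icosphere subdivision level (3 -> 642 vertices).
    """

    axes: tuple[float, float, float] = (1.0, 0.9, 0.8)
    lobulation_amplitude: float = 0.04
    lobulation_frequency: int = 2
    spike_count: int = 0
    spike_amplitude: float = 0.0
    spike_sharpness: float = 0.25
    noise_sd: float = 0.004
    subdivisions: int = 3


#: Study conditions: the benign class is a smooth, near-oval lesion; the
#: malignant class (at separation 1) is ~35% larger in linear size, clearly
#: eccentric, lobulated, and carries 14 spiculation spikes plus surface noise.
BENIGN_DEFAULTS = ShapeParams()
MALIGNANT_DEFAULTS = ShapeParams(
    axes=(1.9, 1.05, 0.9),
    lobulation_amplitude=0.09,
    lobulation_frequency=3,
    spike_count=14,
    spike_amplitude=0.45,
    spike_sharpness=0.22,
    noise_sd=0.035,
)


def _unit_icosphere(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return np.asarray(ico.vertices, dtype=np.float64), np.asarray(ico.faces, dtype=np.int64)


def _radial_surface(params: ShapeParams, rng: np.random.Generator) -> TriangleMesh:
    a, b, c = params.axes
    if min(a, b, c) <= 0:
        raise ValueError("ellipsoid semi-axes must be positive")
    u, faces = _unit_icosphere(params.subdivisions)

    # ellipsoid radius along each unit direction
    r = 1.0 / np.sqrt((u[:, 0] / a) ** 2 + (u[:, 1] / b) ** 2 + (u[:, 2] / c) ** 2)

    theta = np.arctan2(u[:, 1], u[:, 0])
    phi = np.arccos(np.clip(u[:, 2], -1, 1))
    f = params.lobulation_frequency
    phase = rng.uniform(0, 2 * np.pi, size=2)
    lob = params.lobulation_amplitude * (
        np.cos(f * theta + phase[0]) * np.sin(phi) ** 2
        + 0.5 * np.cos((f + 1) * phi + phase[1])
    )

    bump = np.zeros(len(u))
    if params.spike_count > 0 and params.spike_amplitude > 0:
        dirs = rng.normal(size=(params.spike_count, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        heights = params.spike_amplitude * rng.uniform(0.6, 1.0, size=params.spike_count)
        ang = np.arccos(np.clip(u @ dirs.T, -1, 1))  # (n_vertices, n_spikes)
        bump = (heights * np.exp(-(ang**2) / (2 * params.spike_sharpness**2))).sum(axis=1)

    noise = rng.normal(0.0, params.noise_sd, size=len(u)) if params.noise_sd > 0 else 0.0

    modulation = np.clip(1.0 + lob + bump + noise, 0.05, None)
    vertices = u * (r * modulation)[:, None]
    return TriangleMesh(vertices, faces)


def make_benign_mesh(params: ShapeParams | None = None, seed: int = 0) -> TriangleMesh:
    """A smooth benign-like closed surface; deterministic per seed."""
    params = params or BENIGN_DEFAULTS
    mesh = _radial_surface(params, np.random.default_rng(seed))
    mesh.label = "benign"
    return mesh


def make_malignant_mesh(params: ShapeParams | None = None, seed: int = 0) -> TriangleMesh:
    """A spiculated malignant-like closed surface; deterministic per seed."""
    params = params or MALIGNANT_DEFAULTS
    mesh = _radial_surface(params, np.random.default_rng(seed))
    mesh.label = "malignant"
    return mesh


def _lerp(a: float, b: float, t: float) -> float:
    return a + (b - a) * t


def interpolate_params(separation: float, base: ShapeParams | None = None,
                       target: ShapeParams | None = None) -> ShapeParams:
    """Malignant parameter set at a given class separation in [0, 1]."""
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must be in [0, 1]")
    base = base or BENIGN_DEFAULTS
    target = target or MALIGNANT_DEFAULTS
    return ShapeParams(
        axes=tuple(_lerp(x, y, separation) for x, y in zip(base.axes, target.axes)),
        lobulation_amplitude=_lerp(
            base.lobulation_amplitude, target.lobulation_amplitude, separation
        ),
        lobulation_frequency=target.lobulation_frequency if separation > 0.5
        else base.lobulation_frequency,
        spike_count=int(round(_lerp(base.spike_count, target.spike_count, separation))),
        spike_amplitude=_lerp(base.spike_amplitude, target.spike_amplitude, separation),
        spike_sharpness=_lerp(base.spike_sharpness, target.spike_sharpness, separation),
        noise_sd=_lerp(base.noise_sd, target.noise_sd, separation),
        subdivisions=base.subdivisions,
    )


def _jitter(params: ShapeParams, rng: np.random.Generator, rel: float = 0.12) -> ShapeParams:
    """Per-mesh multiplicative jitter so within-class variance is nonzero."""
    g = lambda: float(rng.lognormal(0.0, rel))
    return replace(
        params,
        axes=tuple(x * g() for x in params.axes),
        lobulation_amplitude=params.lobulation_amplitude * g(),
        spike_amplitude=params.spike_amplitude * g(),
        noise_sd=params.noise_sd * g(),
    )


def make_dataset(
    n_benign: int = 294,
    n_malignant: int = 151,
    separation: float = 0.8,
    seed: int = 0,
    subdivisions: int | None = None,
) -> list[TriangleMesh]:
    """Labeled synthetic mesh list: ``n_benign`` benign then ``n_malignant`` malignant.

    ``separation`` interpolates the malignant parameters from the benign
    baseline (0 = identical class distributions) toward full contrast (1).
    """
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("counts must be nonnegative")
    rng = np.random.default_rng(seed)
    benign_base = BENIGN_DEFAULTS
    malignant_base = interpolate_params(separation)
    if subdivisions is not None:
        benign_base = replace(benign_base, subdivisions=subdivisions)
        malignant_base = replace(malignant_base, subdivisions=subdivisions)
    meshes: list[TriangleMesh] = []
    for i in range(n_benign):
        p = _jitter(benign_base, rng)
        m = _radial_surface(p, np.random.default_rng(rng.integers(2**31)))
        m.label, m.mesh_id = "benign", f"benign_{i:04d}"
        meshes.append(m)
    for i in range(n_malignant):
        p = _jitter(malignant_base, rng)
        m = _radial_surface(p, np.random.default_rng(rng.integers(2**31)))
        m.label, m.mesh_id = "malignant", f"malignant_{i:04d}"
        meshes.append(m)
    return meshes


def punch_holes(mesh: TriangleMesh, fraction: float, seed: int = 0) -> TriangleMesh:
    """Remove a random fraction of faces to emulate damaged (holey) meshes."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m = mesh.copy()
    n_drop = int(round(fraction * m.n_faces))
    if n_drop == 0:
        return m
    drop = rng.choice(m.n_faces, size=n_drop, replace=False)
    keep = np.setdiff1d(np.arange(m.n_faces), drop)
    m.faces = m.faces[keep]
    return m
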