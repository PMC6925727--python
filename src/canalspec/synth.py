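"""Deterministic fixture generators: analytic solids and synthetic canals.

Everything here is seeded and bitwise reproducible: identical parameters
and seed give identical vertex arrays.  The synthetic canal is a tapered
tube along a (possibly laterally curved) +z axis with optional smooth
radial bumps and radial surface noise, standing in for segmented cavity
meshes so the whole pipeline is testable offline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .mesh import TriangleMesh


@dataclass(frozen=True)
class SynthCanalParams:
    """Parameters of the synthetic canal generator (all lengths in mm)."""

    height: float = 10.0
    top_radius: float = 1.5
    bottom_radius: float = 0.5
    axis_curvature: float = 0.0
    bump_amplitude: float = 0.0
    bump_count: int = 0
    noise_sd: float = 0.0
    rings: int = 24
    layers: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_radius <= 0 or self.bottom_radius <= 0:
            raise ValueError("radii must be positive")
        if self.bottom_radius > self.top_radius:
            raise ValueError("canals taper apically: bottom_radius <= top_radius")
        if self.rings < 3 or self.layers < 2:
            raise ValueError("need rings >= 3 and layers >= 2")
        if self.height <= 0:
            raise ValueError("height must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


# -- analytic solids ---------------------------------------------------------

_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
        [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
        [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
    ],
    dtype=np.float64,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def make_icosphere(radius: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
    """Geodesic icosphere: 20 * 4**k faces, every vertex at |v| = radius."""
    if not 0 <= subdivisions <= 6:
        raise ValueError("subdivisions must be in [0, 6]")
    if radius <= 0:
        raise ValueError("radius must be positive")
    verts = _ICO_VERTS.copy()
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        n = len(verts)
        edges = np.sort(
            np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
        )
        uniq, inv = np.unique(edges, axis=0, return_inverse=True)
        mid = 0.5 * (verts[uniq[:, 0]] + verts[uniq[:, 1]])
        verts = np.vstack([verts, mid])
        m01 = n + inv[: len(faces)]
        m12 = n + inv[len(faces) : 2 * len(faces)]
        m20 = n + inv[2 * len(faces) :]
        f = faces
        faces = np.vstack(
            [
                np.stack([f[:, 0], m01, m20], axis=1),
                np.stack([f[:, 1], m12, m01], axis=1),
                np.stack([f[:, 2], m20, m12], axis=1),
                np.stack([m01, m12, m20], axis=1),
            ]
        )
    verts *= radius / np.linalg.norm(verts, axis=1)[:, None]
    return TriangleMesh(verts, faces, name=f"icosphere_r{radius:g}_s{subdivisions}")


def _tube(
    centers: np.ndarray, radii: np.ndarray, rings: int, name: str
) -> TriangleMesh:
    """Close a stack of circular-ish rings into a capped tube.

    ``centers`` is (L, 3) ring centers bottom-to-top, ``radii`` is (L, rings)
    per-ring per-angle radii.  Caps are fans to the end-ring centers.
    """
    L = len(centers)
    theta = 2.0 * np.pi * np.arange(rings) / rings
    ct, st = np.cos(theta), np.sin(theta)
    pts = np.empty((L, rings, 3))
    pts[..., 0] = centers[:, None, 0] + radii * ct
    pts[..., 1] = centers[:, None, 1] + radii * st
    pts[..., 2] = centers[:, None, 2]
    verts = pts.reshape(-1, 3)
    bot_c = len(verts)
    top_c = len(verts) + 1
    verts = np.vstack([verts, centers[0], centers[-1]])

    idx = np.arange(rings)
    nxt = (idx + 1) % rings
    faces = []
    for j in range(L - 1):
        a = j * rings + idx
        b = j * rings + nxt
        c = (j + 1) * rings + idx
        d = (j + 1) * rings + nxt
        # outward orientation: CCW seen from outside
        faces.append(np.stack([a, b, d], axis=1))
        faces.append(np.stack([a, d, c], axis=1))
    # bottom cap (normal -z): fan wound clockwise seen from +z
    faces.append(np.stack([np.full(rings, bot_c), nxt, idx], axis=1))
    # top cap (normal +z)
    top0 = (L - 1) * rings
    faces.append(np.stack([np.full(rings, top_c), top0 + idx, top0 + nxt], axis=1))
    return TriangleMesh(verts, np.vstack(faces), name=name)


def make_cylinder(
    radius: float = 1.0, height: float = 1.0, rings: int = 32, layers: int = 8
) -> TriangleMesh:
    """Closed capped cylinder of the given radius and height, base at z=0."""
    if radius <= 0 or height <= 0:
        raise ValueError("radius and height must be positive")
    z = np.linspace(0.0, height, layers + 1)
    centers = np.zeros((layers + 1, 3))
    centers[:, 2] = z
    radii = np.full((layers + 1, rings), radius)
    return _tube(centers, radii, rings, f"cylinder_r{radius:g}_h{height:g}")


def make_cone(
    top_radius: float = 1.0, height: float = 1.0, rings: int = 32, layers: int = 8
) -> TriangleMesh:
    """Closed cone: apex at the origin, disk of ``top_radius`` at z=height.

    Canal-like: the analytic cross-section radius at height z is
    ``top_radius * z / height``.
    """
    if top_radius <= 0 or height <= 0:
        raise ValueError("top_radius and height must be positive")
    z = np.linspace(0.0, height, layers + 1)
    centers = np.zeros((layers + 1, 3))
    centers[:, 2] = z
    radii = np.outer(np.maximum(z / height, 1e-3) * top_radius, np.ones(rings))
    # collapse the bottom ring to a tiny radius rather than a point so the
    # tube topology stays uniform; the apex cap closes it
    return _tube(centers, radii, rings, f"cone_r{top_radius:g}_h{height:g}")


# -- synthetic canals --------------------------------------------------------


def _canal_radius_field(params: SynthCanalParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-layer centers (L, 3) and per-(layer, ring) radii for the canal."""
    p = params
    L = p.layers + 1
    z = np.linspace(0.0, p.height, L)
    t = z / p.height
    centers = np.zeros((L, 3))
    centers[:, 2] = z
    centers[:, 0] = p.axis_curvature * np.sin(np.pi * t)

    # linear taper, bottom (z=0, apical) to top (z=h, coronal)
    base = p.bottom_radius + (p.top_radius - p.bottom_radius) * t
    theta = 2.0 * np.pi * np.arange(p.rings) / p.rings
    radii = np.tile(base[:, None], (1, p.rings))

    rng = np.random.default_rng(p.seed)
    if p.bump_count > 0 and p.bump_amplitude > 0:
        zb = rng.uniform(0.15 * p.height, 0.85 * p.height, size=p.bump_count)
        tb = rng.uniform(0.0, 2.0 * np.pi, size=p.bump_count)
        s_z = 0.08 * p.height
        s_t = 0.45  # radians
        for k in range(p.bump_count):
            dth = np.angle(np.exp(1j * (theta - tb[k])))
            gauss = np.exp(
                -((z[:, None] - zb[k]) ** 2) / (2 * s_z**2)
                - (dth[None, :] ** 2) / (2 * s_t**2)
            )
            radii += p.bump_amplitude * gauss
    if p.noise_sd > 0:
        noise = rng.normal(0.0, p.noise_sd, size=radii.shape)
        # keep end rings clean so the caps stay planar, and clamp to 10% of
        # the local radius to preserve manifoldness
        noise[0] = 0.0
        noise[-1] = 0.0
        lim = 0.1 * radii
        radii = radii + np.clip(noise, -lim, lim)
    if (radii <= 0).any():
        raise GeometryError("canal parameters produce non-positive radii")
    return centers, radii


def make_synthetic_canal(params: SynthCanalParams) -> TriangleMesh:
    """Deterministic tapered-tube canal with bumps and noise (see params)."""
    centers, radii = _canal_radius_field(params)
    mesh = _tube(centers, radii, params.rings, f"canal_seed{params.seed}")
    return mesh.validate()


def make_canal_pair(
    params_pre: SynthCanalParams,
    enlargement: float = 0.3,
    smoothing: float = 0.3,
) -> tuple[TriangleMesh, TriangleMesh]:
    """A (pre, post) canal pair sharing one axis, emulating preparation.

    ``post`` is ``pre`` with every radius enlarged by ``enlargement`` mm and
    bump/noise amplitudes multiplied by ``smoothing`` (1 keeps them; 0
    removes them).
    """
    if enlargement < 0:
        raise ValueError("enlargement must be >= 0")
    if not 0 <= smoothing <= 1:
        raise ValueError("smoothing must be in [0, 1]")
    pre = make_synthetic_canal(params_pre)
    params_post = dataclasses.replace(
        params_pre,
        top_radius=params_pre.top_radius + enlargement,
        bottom_radius=params_pre.bottom_radius + enlargement,
        bump_amplitude=params_pre.bump_amplitude * smoothing,
        noise_sd=params_pre.noise_sd * smoothing,
    )
    post = make_synthetic_canal(params_post)
    post.name = pre.name + "_post"
    return pre, post
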