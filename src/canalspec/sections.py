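"""Cross-sections and the ideal benchmark canal.

The ideal canal is built from five sections: the (inset) top and bottom
loops plus one key section per coronal/middle/apical segment.  Candidate
sections per segment sit at depths h/3 - a, h/3, h/3 + a below the segment
top (a = 0.05 h); the candidate whose boundary deviates least from its
equal-area circle wins.  Key sections are replaced by their equal-area
circles (even enlargement, minimal volume) and the five rings are lofted
with a smooth skin into a closed mesh sharing the original centroid axis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import Point, Polygon

from .errors import GeometryError
from .mesh import TriangleMesh
from .synth import _tube

log = logging.getLogger(__name__)


@dataclass
class CrossSection:
    """A planar boundary loop of the cavity at one z level.

    ``points`` is the (N, 2) CCW-ordered xy loop; ``z`` its plane height and
    ``depth`` the distance below the mesh top plane.  ``centroid`` is the
    area centroid of the polygon, not the vertex mean.
    """

    z: float
    depth: float
    points: np.ndarray
    area: float
    perimeter: float
    centroid: np.ndarray

    @property
    def N(self) -> int:
        return len(self.points)


@dataclass
class IdealCanalPlan:
    """Five chosen sections [top, coronal, middle, apical, bottom] with the
    candidate bookkeeping of the selection step."""

    sections: list[CrossSection]
    segment_heights: tuple[float, float, float]
    offsets: tuple[float, float, float]
    deviations: dict[str, list[float]]
    candidate_depths: dict[str, list[float]]
    chosen: dict[str, int]
    mesh_name: str = ""
    z_extent: tuple[float, float] | None = None  # full source extent (zmin, zmax)

    def __post_init__(self) -> None:
        if len(self.sections) != 5:
            raise GeometryError("an ideal-canal plan needs exactly five sections")
        depths = [s.depth for s in self.sections]
        if not all(d2 > d1 for d1, d2 in zip(depths, depths[1:])):
            raise GeometryError(f"section depths must increase top-to-bottom: {depths}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "mesh_name": self.mesh_name,
                "segment_heights": list(self.segment_heights),
                "offsets": list(self.offsets),
                "sections": [
                    {
                        "role": role,
                        "z": s.z,
                        "depth": s.depth,
                        "area": s.area,
                        "perimeter": s.perimeter,
                        "centroid": list(map(float, s.centroid)),
                        "r_ideal": ideal_radius(s),
                        "mean_deviation": mean_boundary_deviation(s),
                        "n_points": s.N,
                    }
                    for role, s in zip(
                        ("top", "coronal", "middle", "apical", "bottom"), self.sections
                    )
                ],
                "candidates": {
                    seg: {
                        "depths": self.candidate_depths[seg],
                        "deviations": self.deviations[seg],
                        "chosen": self.chosen[seg],
                    }
                    for seg in ("coronal", "middle", "apical")
                },
            },
            indent=2,
        )


# ---------------------------------------------------------------------------


def _plane_loops(mesh: TriangleMesh, z0: float) -> list[np.ndarray]:
    """All closed intersection loops of the mesh with the plane z = z0,
    each as an (N, 2) xy polyline (unclosed, consecutive points joined)."""
    z = mesh.vertices[:, 2] - z0
    zmin, zmax = mesh.z_extent()
    span = zmax - zmin
    # nudge off exact vertex hits for a well-defined transversal cut
    tol = 1e-9 * max(span, 1.0)
    if np.any(np.abs(z) < tol):
        z = mesh.vertices[:, 2] - (z0 + 3.1416 * tol)

    f = mesh.faces
    zf = z[f]  # (F, 3)
    pos = zf > 0
    npos = pos.sum(axis=1)
    crossing = np.nonzero((npos == 1) | (npos == 2))[0]
    if len(crossing) == 0:
        raise GeometryError(f"plane z={z0:g} does not intersect the mesh")

    seg_edges = []  # per crossing face: two undirected edge keys
    pts: dict[tuple[int, int], np.ndarray] = {}
    for fi in crossing:
        ids = f[fi]
        zz = z[ids]
        cut = []
        for a in range(3):
            b = (a + 1) % 3
            if (zz[a] > 0) != (zz[b] > 0):
                key = (min(ids[a], ids[b]), max(ids[a], ids[b]))
                if key not in pts:
                    t = zz[a] / (zz[a] - zz[b])
                    p = mesh.vertices[ids[a]] + t * (
                        mesh.vertices[ids[b]] - mesh.vertices[ids[a]]
                    )
                    pts[key] = p[:2]
                cut.append(key)
        if len(cut) == 2:
            seg_edges.append((cut[0], cut[1]))

    # chain segments into loops: each edge key touches exactly two segments
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for a, b in seg_edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    unvisited = set(adj)
    loops = []
    while unvisited:
        start = unvisited.pop()
        loop = [start]
        prev = None
        cur = start
        while True:
            nbrs = [e for e in adj[cur] if e != prev]
            if not nbrs:
                break
            nxt = nbrs[0]
            if nxt == start:
                break
            loop.append(nxt)
            unvisited.discard(nxt)
            prev, cur = cur, nxt
        if len(loop) >= 3:
            loops.append(np.array([pts[e] for e in loop]))
    if not loops:
        raise GeometryError(f"no closed intersection loop at z={z0:g}")
    return loops


def extract_cross_section(
    mesh: TriangleMesh,
    height: float,
    axis_point: tuple[float, float] | None = None,
) -> CrossSection:
    """Planar cavity loop at the absolute height z = ``height``.

    Returns the largest-area loop by default; pass ``axis_point`` (xy) to
    select the loop containing that point instead (multi-canal geometry).
    Boundary points are ordered counter-clockwise viewed from above.
    """
    zmin, zmax = mesh.z_extent()
    if not (zmin < height < zmax):
        raise ValueError(
            f"height {height:g} outside the open z-extent ({zmin:g}, {zmax:g})"
        )
    loops = _plane_loops(mesh, height)
    polys = [Polygon(lp) for lp in loops]
    if axis_point is not None:
        pt = Point(*axis_point)
        picked = [i for i, p in enumerate(polys) if p.contains(pt)]
        if not picked:
            raise GeometryError(f"no loop at z={height:g} contains {axis_point}")
        i = picked[0]
    else:
        i = int(np.argmax([p.area for p in polys]))
    loop, poly = loops[i], polys[i]
    if not poly.is_valid:
        poly = poly.buffer(0)
        if not poly.is_valid or poly.is_empty:
            raise GeometryError(f"self-intersecting section loop at z={height:g}")
    # CCW from above
    ring = Polygon(loop)
    if ring.exterior.is_ccw is False:
        loop = loop[::-1]
    c = poly.centroid
    return CrossSection(
        z=float(height),
        depth=float(zmax - height),
        points=loop,
        area=float(poly.area),
        perimeter=float(poly.length),
        centroid=np.array([c.x, c.y]),
    )


def section_from_points(points: np.ndarray, z: float = 0.0, depth: float = 0.0) -> CrossSection:
    """Build a CrossSection from an (N, 2) planar loop (polygon metrics via
    shapely; points reordered CCW if needed)."""
    points = np.asarray(points, dtype=np.float64)
    poly = Polygon(points)
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError("loop is degenerate or self-intersecting")
    if not poly.exterior.is_ccw:
        points = points[::-1]
    c = poly.centroid
    return CrossSection(
        z=z,
        depth=depth,
        points=points,
        area=float(poly.area),
        perimeter=float(poly.length),
        centroid=np.array([c.x, c.y]),
    )


def ideal_radius(section: CrossSection) -> float:
    """Radius of the circle with the section's area: sqrt(A / pi)."""
    if section.area <= 0:
        raise ValueError("section area must be positive")
    return float(np.sqrt(section.area / np.pi))


def mean_boundary_deviation(section: CrossSection) -> float:
    """Mean absolute deviation of boundary radii from the equal-area circle.

    d = (1/N) * sum_i | ||p_i - c|| - r_ideal |; zero exactly when the
    section is circular.
    """
    if section.N < 3:
        raise ValueError("need at least 3 boundary points")
    r = np.linalg.norm(section.points - section.centroid, axis=1)
    return float(np.mean(np.abs(r - ideal_radius(section))))


def select_key_sections(
    mesh: TriangleMesh,
    segment_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    end_inset_fraction: float = 0.01,
    axis_point: tuple[float, float] | None = None,
) -> IdealCanalPlan:
    """Choose the five plan sections for the ideal canal.

    The z-extent is split top-down into coronal/middle/apical segments with
    the given height fractions.  In each segment the three candidates at
    depths h/3 - a, h/3, h/3 + a below the segment top (a = 0.05 h) are
    scored by :func:`mean_boundary_deviation`; the minimum wins, ties going
    to the central candidate.  Top and bottom sections are taken at a small
    inset from the extremes (an exact extreme plane meets the mesh in a
    point, not a loop).
    """
    fr = np.asarray(segment_fractions, dtype=float)
    if fr.shape != (3,) or (fr <= 0).any():
        raise ValueError("segment_fractions must be three positive numbers")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"segment_fractions must sum to 1, got {fr.sum()!r}")

    zmin, zmax = mesh.z_extent()
    H = zmax - zmin
    seg_heights = tuple(float(f * H) for f in fr)
    seg_tops = [zmax, zmax - seg_heights[0], zmax - seg_heights[0] - seg_heights[1]]

    names = ("coronal", "middle", "apical")
    deviations: dict[str, list[float]] = {}
    cand_depths: dict[str, list[float]] = {}
    chosen: dict[str, int] = {}
    keys: list[CrossSection] = []
    offsets = tuple(0.05 * h for h in seg_heights)
    for name, top, h, a in zip(names, seg_tops, seg_heights, offsets):
        depths = [h / 3 - a, h / 3, h / 3 + a]
        secs = []
        for d in depths:
            try:
                secs.append(extract_cross_section(mesh, top - d, axis_point))
            except GeometryError as exc:
                raise GeometryError(
                    f"{name} segment: candidate plane at depth {d:g} below the "
                    f"segment top yields no loop: {exc}"
                ) from exc
        dev = [mean_boundary_deviation(s) for s in secs]
        # score by the scale-free circularity d / r_ideal: the dimensional d
        # of equally shaped sections grows with radius, which on tapered
        # canals would bias selection toward the deepest candidate for pure
        # discretization reasons.  Near-ties go to the central candidate.
        score = [d / ideal_radius(s) for d, s in zip(dev, secs)]
        tol = max(1e-3 * min(score), 1e-6)
        order = [1, 0, 2]
        tied = [i for i in order if score[i] <= min(score) + tol]
        best = tied[0]
        deviations[name] = dev
        cand_depths[name] = [float(top - d) for d in depths]  # store z values
        chosen[name] = best
        keys.append(secs[best])

    eps = end_inset_fraction * H
    s_top = extract_cross_section(mesh, zmax - eps, axis_point)
    s_bot = extract_cross_section(mesh, zmin + eps, axis_point)
    return IdealCanalPlan(
        sections=[s_top, *keys, s_bot],
        segment_heights=seg_heights,
        offsets=offsets,
        deviations=deviations,
        candidate_depths=cand_depths,
        chosen=chosen,
        mesh_name=mesh.name,
        z_extent=(zmin, zmax),
    )


# ---------------------------------------------------------------------------


def _resample_star(section: CrossSection, rings: int) -> np.ndarray:
    """Radii at ``rings`` uniform polar angles about the section centroid.

    Assumes a star-shaped loop (true for canal sections); angles are taken
    CCW from +x so all resampled rings are azimuthally aligned by
    construction.
    """
    d = section.points - section.centroid
    ang = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2 * np.pi)
    rad = np.linalg.norm(d, axis=1)
    order = np.argsort(ang)
    ang, rad = ang[order], rad[order]
    # wrap for periodic interpolation
    ang_w = np.concatenate([ang[-1:] - 2 * np.pi, ang, ang[:1] + 2 * np.pi])
    rad_w = np.concatenate([rad[-1:], rad, rad[:1]])
    theta = 2 * np.pi * np.arange(rings) / rings
    return np.interp(theta, ang_w, rad_w)


def loft_ideal_canal(
    plan: IdealCanalPlan,
    rings: int = 48,
    layers_per_span: int = 8,
    circularize: bool = True,
    interpolation: str = "cubic",
) -> TriangleMesh:
    """Skin the five plan sections into a closed ideal-canal mesh.

    Key sections become their equal-area circles centered at the original
    centroids (``circularize=False`` keeps the actual loops); the top and
    bottom sections always keep their actual shape.  Ring radii and
    centroids are interpolated along z (piecewise cubic by default) so the
    transition between sections is smooth and the centroid axis follows the
    plan.
    """
    if rings < 16:
        raise ValueError("rings must be >= 16")
    if layers_per_span < 4:
        raise ValueError("layers_per_span must be >= 4")
    secs = plan.sections  # top .. bottom
    zs = np.array([s.z for s in secs])[::-1]  # ascending: bottom .. top
    ordered = secs[::-1]
    radii = np.empty((5, rings))
    cents = np.empty((5, 2))
    dtheta = 2 * np.pi / rings
    for i, s in enumerate(ordered):
        cents[i] = s.centroid
        is_key = i in (1, 2, 3)
        if is_key and circularize:
            radii[i] = ideal_radius(s)
        else:
            radii[i] = _resample_star(s, rings)
        # scale so the ring *polygon* carries the section's area exactly —
        # uncorrected inscription loses ~(2 pi / rings)^2 / 12 of the area
        # at every pass, breaking idempotence of the construction
        r = radii[i]
        poly_area = 0.5 * np.sin(dtheta) * np.sum(r * np.roll(r, -1))
        radii[i] = r * np.sqrt(s.area / poly_area)

    L = 4 * layers_per_span + 1
    # span the full source extent (extrapolating past the inset end
    # sections) so lofting an already-lofted ideal reproduces it; rings are
    # placed exactly at the five section heights so the output reproduces
    # the plan centroids there
    z_lo, z_hi = plan.z_extent if plan.z_extent is not None else (zs[0], zs[-1])
    zq = np.concatenate([np.linspace(z_lo, z_hi, L), zs])
    zq = np.unique(np.round(zq / (1e-9 * (z_hi - z_lo))).astype(np.int64)) * (
        1e-9 * (z_hi - z_lo)
    )
    if interpolation == "cubic":
        rq = CubicSpline(zs, radii, axis=0, bc_type="natural")(zq)
        cq = CubicSpline(zs, cents, axis=0, bc_type="natural")(zq)
    elif interpolation == "linear":
        rq = np.stack([np.interp(zq, zs, radii[:, k]) for k in range(rings)], axis=1)
        cq = np.stack([np.interp(zq, zs, cents[:, k]) for k in range(2)], axis=1)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if (rq <= 0).any():
        raise GeometryError("loft produced non-positive radii (pathological plan)")

    centers = np.column_stack([cq, zq])
    mesh = _tube(centers, rq, rings, name=(plan.mesh_name or "canal") + "_ideal")
    return mesh.validate()


def make_ideal_canal(
    mesh: TriangleMesh,
    segment_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    rings: int = 48,
    layers_per_span: int = 8,
    **kwargs,
) -> tuple[TriangleMesh, IdealCanalPlan]:
    """Convenience: select key sections and loft in one call."""
    plan = select_key_sections(mesh, segment_fractions)
    ideal = loft_ideal_canal(plan, rings=rings, layers_per_span=layers_per_span, **kwargs)
    return ideal, plan
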