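"""Triangle-mesh core: validation, measures, discrete curvature, solid angles.

The universal geometric input is a closed, consistently oriented (outward
normals, CCW faces) 2-manifold triangle surface bounding a solid cavity.
Coordinates are millimetres; the canal axis is +z with the coronal (top)
end at larger z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import MeshValidationError

log = logging.getLogger(__name__)

#: vertices closer than this (mm) are considered duplicates
DUPLICATE_TOL = 1e-9
#: faces with area below this (mm^2) are rejected as degenerate
DEGENERATE_AREA = 1e-14


@dataclass
class TriangleMesh:
    """A closed oriented manifold triangle surface.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array, CCW triples with outward normals
    name : free-text label
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")

    # -- basic quantities ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        f = self.faces
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    def face_cross(self) -> np.ndarray:
        """Unnormalized face normals (cross products), outward for valid meshes."""
        a, b, c = self.face_corners()
        return np.cross(b - a, c - a)

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_cross(), axis=1)

    def face_normals(self) -> np.ndarray:
        cr = self.face_cross()
        nrm = np.linalg.norm(cr, axis=1)
        return cr / nrm[:, None]

    def edges_unique(self) -> np.ndarray:
        """Undirected edges, each once, as sorted (lo, hi) vertex pairs."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges_unique()) + self.n_faces

    def z_extent(self) -> tuple[float, float]:
        z = self.vertices[:, 2]
        return float(z.min()), float(z.max())

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.name)

    # -- validation ---------------------------------------------------------

    def validate(self, fix_orientation: bool = True) -> "TriangleMesh":
        """Check the closed-manifold contract, raising on violation.

        A globally inverted mesh (negative signed volume) is flipped with a
        warning when ``fix_orientation`` is true; any other defect raises
        :class:`MeshValidationError`.
        """
        if self.n_vertices < 4 or self.n_faces < 4:
            raise MeshValidationError(
                f"mesh '{self.name}': too small to bound a solid "
                f"({self.n_vertices} vertices, {self.n_faces} faces)"
            )
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise MeshValidationError(f"mesh '{self.name}': face index out of range")
        if (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 2] == self.faces[:, 0])
        ).any():
            raise MeshValidationError(f"mesh '{self.name}': face with repeated vertex")

        areas = self.face_areas()
        bad = np.nonzero(areas < DEGENERATE_AREA)[0]
        if len(bad):
            raise MeshValidationError(
                f"mesh '{self.name}': {len(bad)} zero-area face(s), e.g. index {bad[0]}"
            )

        if self.n_vertices > 1:
            pairs = cKDTree(self.vertices).query_pairs(DUPLICATE_TOL)
            if pairs:
                p = sorted(pairs)[0]
                raise MeshValidationError(
                    f"mesh '{self.name}': duplicate vertices within "
                    f"{DUPLICATE_TOL} mm, e.g. {p[0]} and {p[1]}"
                )

        # every directed edge must occur exactly once, and its reverse exactly
        # once: closed 2-manifold with consistent orientation
        de = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        key = de[:, 0] * self.n_vertices + de[:, 1]
        uniq, counts = np.unique(key, return_counts=True)
        if (counts > 1).any():
            k = uniq[counts > 1][0]
            raise MeshValidationError(
                f"mesh '{self.name}': directed edge "
                f"({k // self.n_vertices}, {k % self.n_vertices}) repeated — "
                "non-manifold or inconsistently oriented"
            )
        rev_key = de[:, 1] * self.n_vertices + de[:, 0]
        missing = np.setdiff1d(key, rev_key)
        if len(missing):
            names = [(int(k // self.n_vertices), int(k % self.n_vertices)) for k in missing[:10]]
            raise MeshValidationError(
                f"mesh '{self.name}': {len(missing)} boundary edge(s) without a "
                f"partner face: {names}"
            )

        vol = enclosed_volume(self, _checked=True)
        if vol <= 0:
            if not fix_orientation:
                raise MeshValidationError(
                    f"mesh '{self.name}': negative signed volume {vol:g} "
                    "(inward normals)"
                )
            log.warning(
                "mesh '%s': signed volume %g negative; flipping orientation",
                self.name,
                vol,
            )
            self.faces = self.faces[:, ::-1].copy()
        return self


@dataclass
class CurvatureField:
    """Per-vertex discrete Gaussian curvature with its 1-ring areas.

    ``K`` is the angle deficit 2*pi - sum(theta) divided by the vertex area
    (mm^-2); ``area`` is the 1-ring vertex area (mm^2).  The area-weighted
    sum of ``K`` equals 2*pi times the Euler characteristic exactly
    (Gauss-Bonnet for angle deficits).
    """

    K: np.ndarray
    area: np.ndarray
    mesh: TriangleMesh = field(repr=False)
    area_mode: str = "barycentric"


def _corner_angles(mesh: TriangleMesh) -> np.ndarray:
    """(m, 3) interior angles of every face at its three corners."""
    a, b, c = mesh.face_corners()
    out = np.empty((mesh.n_faces, 3))
    for k, (p, q, r) in enumerate(((a, b, c), (b, c, a), (c, a, b))):
        u = q - p
        w = r - p
        cosang = np.einsum("ij,ij->i", u, w)
        sinang = np.linalg.norm(np.cross(u, w), axis=1)
        out[:, k] = np.arctan2(sinang, cosang)
    return out


def _mixed_voronoi_areas(mesh: TriangleMesh, angles: np.ndarray) -> np.ndarray:
    """Meyer et al. mixed Voronoi vertex areas (option; barycentric default)."""
    a, b, c = mesh.face_corners()
    corners = (a, b, c)
    areas_f = mesh.face_areas()
    va = np.zeros(mesh.n_vertices)
    obtuse = angles > np.pi / 2
    any_obtuse = obtuse.any(axis=1)
    cot = 1.0 / np.tan(angles)
    for k in range(3):
        i = mesh.faces[:, k]
        j1, j2 = (k + 1) % 3, (k + 2) % 3
        l1 = np.linalg.norm(corners[j2] - corners[k], axis=1)  # edge to corner j2
        l2 = np.linalg.norm(corners[j1] - corners[k], axis=1)  # edge to corner j1
        vor = (l1**2 * cot[:, j1] + l2**2 * cot[:, j2]) / 8.0
        contrib = np.where(
            any_obtuse,
            np.where(obtuse[:, k], areas_f / 2.0, areas_f / 4.0),
            vor,
        )
        np.add.at(va, i, contrib)
    return va


def gaussian_curvature(mesh: TriangleMesh, area_mode: str = "barycentric") -> CurvatureField:
    """Angle-deficit Gaussian curvature K(x) = (2*pi - sum theta_i) / A(x).

    ``area_mode`` selects the 1-ring area: ``"barycentric"`` (one third of
    the incident face areas; makes Gauss-Bonnet exact and is robust on
    obtuse triangles) or ``"mixed"`` (Voronoi-style mixed area).
    """
    angles = _corner_angles(mesh)
    deficit = np.full(mesh.n_vertices, 2.0 * np.pi)
    for k in range(3):
        np.subtract.at(deficit, mesh.faces[:, k], angles[:, k])

    if area_mode == "barycentric":
        va = np.zeros(mesh.n_vertices)
        af = mesh.face_areas() / 3.0
        for k in range(3):
            np.add.at(va, mesh.faces[:, k], af)
    elif area_mode == "mixed":
        va = _mixed_voronoi_areas(mesh, angles)
    else:
        raise ValueError(f"unknown area_mode {area_mode!r}")
    return CurvatureField(K=deficit / va, area=va, mesh=mesh, area_mode=area_mode)


def solid_angle_coefficient(mesh: TriangleMesh, vertex: int) -> float:
    """Interior solid-angle fraction sigma(x) in (0, 1) at a vertex.

    Computed as the area of the spherical polygon cut by the interior cone:
    sum of interior dihedral angles along incident edges minus (m - 2)*pi,
    divided by 4*pi.  Equals 0.5 at smooth (locally flat) points, 0.125 at a
    cube corner.
    """
    if not (0 <= vertex < mesh.n_vertices):
        raise IndexError(f"vertex index {vertex} out of range")
    sig = solid_angle_coefficients(mesh, np.array([vertex]))
    return float(sig[0])


def solid_angle_coefficients(mesh: TriangleMesh, vertices: np.ndarray | None = None) -> np.ndarray:
    """Vectorized :func:`solid_angle_coefficient` for many (default all) vertices."""
    if vertices is None:
        vertices = np.arange(mesh.n_vertices)
    vertices = np.asarray(vertices)

    normals = mesh.face_normals()
    # map each directed edge (a, b) to its face
    de = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    de_face = np.tile(np.arange(mesh.n_faces), 3)
    order = np.lexsort((de[:, 1], de[:, 0]))
    de_sorted = de[order]
    face_sorted = de_face[order]

    def face_of(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        key = de_sorted[:, 0] * mesh.n_vertices + de_sorted[:, 1]
        q = a * mesh.n_vertices + b
        idx = np.searchsorted(key, q)
        return face_sorted[idx]

    edges = mesh.edges_unique()
    # interior dihedral at each undirected edge
    a, b = edges[:, 0], edges[:, 1]
    f1 = face_of(a, b)  # face containing directed edge a->b
    f2 = face_of(b, a)
    ehat = mesh.vertices[b] - mesh.vertices[a]
    ehat = ehat / np.linalg.norm(ehat, axis=1)[:, None]
    n1, n2 = normals[f1], normals[f2]
    beta = np.arctan2(np.einsum("ij,ij->i", np.cross(n1, n2), ehat), np.einsum("ij,ij->i", n1, n2))
    theta = np.pi - beta  # interior dihedral angle in (0, 2*pi)

    theta_sum = np.zeros(mesh.n_vertices)
    np.add.at(theta_sum, a, theta)
    np.add.at(theta_sum, b, theta)
    valence = np.zeros(mesh.n_vertices, dtype=np.int64)
    np.add.at(valence, mesh.faces.ravel(), 1)

    sigma = (theta_sum - (valence - 2) * np.pi) / (4.0 * np.pi)
    return sigma[vertices]


def surface_area(mesh: TriangleMesh) -> float:
    """Total triangle area (mm^2)."""
    return float(mesh.face_areas().sum())


def enclosed_volume(mesh: TriangleMesh, _checked: bool = False) -> float:
    """Signed divergence-theorem volume (mm^3), positive for outward normals."""
    a, b, c = mesh.face_corners()
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def transform_mesh(
    mesh: TriangleMesh,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    scale: float = 1.0,
) -> TriangleMesh:
    """Map vertices x -> scale * R x + t, preserving connectivity."""
    if rotation is None:
        rotation = np.eye(3)
    rotation = np.asarray(rotation, dtype=np.float64)
    if rotation.shape != (3, 3) or np.abs(rotation @ rotation.T - np.eye(3)).max() > 1e-10:
        raise ValueError("rotation must be a 3x3 orthonormal matrix (tol 1e-10)")
    if not scale > 0:
        raise ValueError("scale must be positive")
    if translation is None:
        translation = np.zeros(3)
    translation = np.asarray(translation, dtype=np.float64)
    v = scale * (mesh.vertices @ rotation.T) + translation
    faces = mesh.faces.copy()
    if np.linalg.det(rotation) < 0:  # reflection: re-orient to keep outward normals
        faces = faces[:, ::-1].copy()
    return TriangleMesh(v, faces, name=mesh.name)
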