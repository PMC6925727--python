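"""Galerkin boundary-element assembly and the discrete Steklov eigenproblem.

Five operator matrices are assembled with piecewise-linear hat functions on
a closed triangle mesh: the single-layer ``V``, double-layer ``K`` (and its
Galerkin adjoint ``Kstar = K.T``), regularized hypersingular ``D``, and the
mass matrix ``G``.  The Dirichlet-to-Neumann (Steklov) spectrum is obtained
from the symmetric Steklov-Poincare form

    (D + B^T V^{-1} B) u = lambda G u,      B = M_sigma + K,

where ``M_sigma`` is the sigma-weighted mass matrix (``0.5 G`` for the
almost-everywhere-smooth coefficient, exact on polyhedral surfaces).

Assembly strategy: a far-field triangle rule over all panel pairs, then a
correction pass that replaces the far-field contribution by high-order
tensor quadrature for close pairs and by Sauter-Schwab regularizing
coordinates for touching pairs (coincident / shared edge / shared vertex).
``D`` uses the integration-by-parts weak form: its kernel is the
single-layer kernel contracted with constant per-face surface-curl vectors,
so direct evaluation of the hypersingular kernel is never needed and
``D @ 1 = 0`` holds to rounding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .errors import ConditioningError, SolverError
from .iccg import incomplete_cholesky, pcg
from .mesh import TriangleMesh, solid_angle_coefficients, surface_area
from .quadrature import refhat, sauter_schwab_table, triangle_rule

log = logging.getLogger(__name__)

INV_4PI = 1.0 / (4.0 * np.pi)

#: dense generalized eigensolver is used up to this size, iterative above
DENSE_EIGEN_LIMIT = 3000


@dataclass
class BoundaryOperators:
    """The five Galerkin matrices of the layer potentials on one mesh."""

    V: np.ndarray
    K: np.ndarray
    Kstar: np.ndarray
    D: np.ndarray
    G: np.ndarray
    sigma: np.ndarray
    mesh: TriangleMesh = field(repr=False)
    quadrature: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.V)


@dataclass
class SteklovSpectrum:
    """Ascending Steklov eigenvalues (mm^-1) with G-orthonormal eigenvectors."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (n, m), columns G-orthonormal
    normalization: str = "raw"
    mesh: TriangleMesh | None = field(default=None, repr=False)
    meta: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.eigenvalues)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mesh_name": self.mesh.name if self.mesh is not None else None,
                "normalization": self.normalization,
                "eigenvalues": list(map(float, self.eigenvalues)),
                **{k: v for k, v in self.meta.items() if _jsonable(v)},
            },
            indent=2,
        )

    def to_csv(self) -> str:
        lines = ["index,eigenvalue"]
        lines += [f"{i},{ev:.17g}" for i, ev in enumerate(self.eigenvalues)]
        return "\n".join(lines) + "\n"


def _jsonable(v) -> bool:
    return isinstance(v, (str, int, float, bool, type(None), list, dict))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _face_geometry(mesh: TriangleMesh):
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas2 = np.linalg.norm(cross, axis=1)
    normals = cross / areas2[:, None]
    areas = 0.5 * areas2
    centroids = tri.mean(axis=1)
    radii = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    # constant surface-curl vectors of the three hats: curl phi_a = -e_a / (2|T|)
    # with e_a the edge opposite local vertex a (CCW)
    e0 = tri[:, 2] - tri[:, 1]
    e1 = tri[:, 0] - tri[:, 2]
    e2 = tri[:, 1] - tri[:, 0]
    curls = np.stack([e0, e1, e2], axis=1) / (-2.0 * areas[:, None, None])
    return tri, areas, normals, centroids, radii, curls


def _pair_classes(mesh: TriangleMesh, centroids, radii, near_factor: float):
    """Ordered face-pair lists: shared-edge, shared-vertex, and near pairs."""
    F = mesh.n_faces
    faces = mesh.faces

    # faces incident to each vertex
    vert_faces: list[list[int]] = [[] for _ in range(mesh.n_vertices)]
    for f in range(F):
        for v in faces[f]:
            vert_faces[v].append(f)

    shared: dict[tuple[int, int], int] = {}
    for vf in vert_faces:
        for a in vf:
            for b in vf:
                if a != b:
                    shared[(a, b)] = shared.get((a, b), 0) + 1
    edge_pairs = np.array(
        sorted(p for p, c in shared.items() if c == 2), dtype=np.int64
    ).reshape(-1, 2)
    vertex_pairs = np.array(
        sorted(p for p, c in shared.items() if c == 1), dtype=np.int64
    ).reshape(-1, 2)

    # near non-touching pairs by centroid distance
    touching = set(shared)
    near: list[tuple[int, int]] = []
    block = max(1, int(2e7 // max(F, 1)))
    for s in range(0, F, block):
        d = np.linalg.norm(
            centroids[s : s + block, None, :] - centroids[None, :, :], axis=2
        )
        lim = near_factor * (radii[s : s + block, None] + radii[None, :])
        ii, jj = np.nonzero(d < lim)
        for i, j in zip(ii + s, jj):
            if i != j and (i, j) not in touching:
                near.append((i, j))
    near_pairs = np.array(sorted(near), dtype=np.int64).reshape(-1, 2)
    return edge_pairs, vertex_pairs, near_pairs


def _exact_mass(mesh: TriangleMesh, areas: np.ndarray) -> np.ndarray:
    """Exact P1 mass matrix: local |T|/12 * (1 + delta_ab)."""
    n = mesh.n_vertices
    G = np.zeros((n, n))
    local = (np.ones((3, 3)) + np.eye(3)) / 12.0
    blocks = areas[:, None, None] * local[None, :, :]
    i = np.repeat(mesh.faces, 3, axis=1).reshape(-1, 3, 3)
    j = np.tile(mesh.faces, 3).reshape(-1, 3, 3)
    np.add.at(G, (i, j), blocks)
    return G


def _pair_local(
    tri, areas, normals, curls, faces, pi, pj, xh, yh, w, perm_i=None, perm_j=None
):
    """Local 3x3 V/K blocks and scalar single-layer integrals for pair lists.

    ``xh``/``yh``/``w`` is a reference quadrature on (unit triangle)^2;
    ``perm_i``/``perm_j`` optionally permute each panel's vertex order
    before parameterization (for Sauter-Schwab vertex alignment).  Returns
    (Vloc (P,3,3), Kloc (P,3,3), I0 (P,), gi (P,3), gj (P,3)) where gi/gj
    are the global vertex indices matching the local axes.
    """
    Ti = tri[pi]
    Tj = tri[pj]
    gi = faces[pi]
    gj = faces[pj]
    if perm_i is not None:
        Ti = np.take_along_axis(Ti, perm_i[:, :, None], axis=1)
        gi = np.take_along_axis(gi, perm_i, axis=1)
    if perm_j is not None:
        Tj = np.take_along_axis(Tj, perm_j[:, :, None], axis=1)
        gj = np.take_along_axis(gj, perm_j, axis=1)

    # chi(u, v) = P0 + u (P1 - P0) + v (P2 - P1)
    x = (
        Ti[:, None, 0, :]
        + xh[None, :, 0, None] * (Ti[:, None, 1, :] - Ti[:, None, 0, :])
        + xh[None, :, 1, None] * (Ti[:, None, 2, :] - Ti[:, None, 1, :])
    )
    y = (
        Tj[:, None, 0, :]
        + yh[None, :, 0, None] * (Tj[:, None, 1, :] - Tj[:, None, 0, :])
        + yh[None, :, 1, None] * (Tj[:, None, 2, :] - Tj[:, None, 1, :])
    )
    diff = x - y
    r2 = np.einsum("pqc,pqc->pq", diff, diff)
    r = np.sqrt(r2)
    kV = INV_4PI / r
    dotn = np.einsum("pqc,pc->pq", diff, normals[pj])
    kK = INV_4PI * dotn / (r2 * r)

    hx = refhat(xh)  # (Q, 3)
    hy = refhat(yh)
    H = (hx[:, :, None] * hy[:, None, :]).reshape(len(w), 9)  # (Q, 9)
    Hw = w[:, None] * H
    wv = w  # weights already include the regularizing Jacobians
    scale = 4.0 * areas[pi] * areas[pj]
    Vloc = (scale[:, None] * (kV @ Hw)).reshape(-1, 3, 3)
    Kloc = (scale[:, None] * (kK @ Hw)).reshape(-1, 3, 3)
    I0 = scale * (kV @ wv)
    return Vloc, Kloc, I0, gi, gj


def _tensor_table(degree_x: int, degree_y: int):
    """Product of two triangle rules as a reference pair table."""
    bx, wx = triangle_rule(degree_x)
    by, wy = triangle_rule(degree_y)
    # convert barycentric (l0, l1, l2) to reference coords (u, v): u = l1 + l2, v = l2
    ux = np.stack([bx[:, 1] + bx[:, 2], bx[:, 2]], axis=1)
    uy = np.stack([by[:, 1] + by[:, 2], by[:, 2]], axis=1)
    Q1, Q2 = len(wx), len(wy)
    xh = np.repeat(ux, Q2, axis=0)
    yh = np.tile(uy, (Q1, 1))
    # reference-triangle measure is 1/2 per panel; triangle_rule weights sum
    # to 1 over the physical triangle, i.e. already absorb the 1/2
    w = np.repeat(wx, Q2) * np.tile(wy, Q1) / 4.0
    return xh, yh, w


def _scatter(M: np.ndarray, loc: np.ndarray, gi: np.ndarray, gj: np.ndarray, sign=1.0):
    ii = np.repeat(gi, 3, axis=1).reshape(-1, 3, 3)
    jj = np.tile(gj, 3).reshape(-1, 3, 3)
    np.add.at(M, (ii, jj), sign * loc)


def _scatter_D(D, I0, curls, pi, pj, gi, gj, perm_i, perm_j, sign=1.0):
    ci = curls[pi]
    cj = curls[pj]
    if perm_i is not None:
        ci = np.take_along_axis(ci, perm_i[:, :, None], axis=1)
    if perm_j is not None:
        cj = np.take_along_axis(cj, perm_j[:, :, None], axis=1)
    loc = np.einsum("pac,pbc,p->pab", ci, cj, I0)
    _scatter(D, loc, gi, gj, sign)


def assemble_operators(
    mesh: TriangleMesh,
    quadrature_order: int = 4,
    singular_order: int = 4,
    near_order: int = 6,
    near_factor: float = 2.0,
    block_pairs: int = 4096,
) -> BoundaryOperators:
    """Assemble V, K, Kstar, D, G for a validated closed mesh.

    ``quadrature_order`` is the polynomial degree of the far-field triangle
    rule (>= 3 required), ``near_order`` the degree used for close
    non-touching pairs, and ``singular_order`` the Gauss order per
    coordinate of the Sauter-Schwab rules for touching pairs.
    """
    if mesh.n_vertices < 4:
        raise ValueError("mesh must have at least 4 vertices")
    if quadrature_order < 3:
        raise ValueError("quadrature_order must be >= 3")

    n = mesh.n_vertices
    F = mesh.n_faces
    faces = mesh.faces
    tri, areas, normals, centroids, radii, curls = _face_geometry(mesh)

    V = np.zeros((n, n))
    K = np.zeros((n, n))
    D = np.zeros((n, n))
    G = _exact_mass(mesh, areas)

    # ---- far-field pass over all ordered pairs ----------------------------
    bq, bw = triangle_rule(quadrature_order)
    Q = len(bw)
    # physical quadrature points per face: (F, Q, 3)
    Xq = np.einsum("qa,fac->fqc", bq, tri)
    hat = bq  # hat values at the rule points ARE the barycentric coords

    # sparse scatter matrices P_q: (F, n) with hat weights
    P = []
    rows = np.arange(F)
    for q in range(Q):
        Pq = sp.csr_matrix(
            (np.repeat(hat[q], F).reshape(3, F).T.ravel(),
             (np.repeat(rows, 3), faces.ravel())),
            shape=(F, n),
        )
        P.append(Pq)
    # per-component curl scatter matrices C_c: (F, n)
    C = [
        sp.csr_matrix(
            ((curls[:, :, c]).ravel(), (np.repeat(rows, 3), faces.ravel())),
            shape=(F, n),
        )
        for c in range(3)
    ]

    area_w = areas  # (F,)
    block = max(32, int(4e6 // max(F, 1)))
    for s in range(0, F, block):
        sl = slice(s, min(s + block, F))
        Fb = sl.stop - sl.start
        S_block = np.zeros((Fb, F))  # sum over (q, p) of w U* scaled
        for q in range(Q):
            dx = Xq[sl, q]  # (Fb, 3)
            for p in range(Q):
                diff = dx[:, None, :] - Xq[None, :, p, :]
                r = np.sqrt(np.einsum("bfc,bfc->bf", diff, diff))
                with np.errstate(divide="ignore"):
                    kV = INV_4PI / r
                # identical-face same-point entries are singular; zero them
                # (the coincident pass replaces them)
                if q == p:
                    kV[np.arange(Fb), np.arange(s, sl.stop)] = 0.0
                w_qp = bw[q] * bw[p]
                Sc = w_qp * (area_w[sl, None] * area_w[None, :]) * kV
                S_block += Sc
                # V scatter: P_q(block)^T @ Sc @ P_p
                t = (P[p].T @ Sc.T).T  # (Fb, n)
                V[:, :] += (P[q][sl].T @ t)
                # K kernel
                dotn = np.einsum("bfc,fc->bf", diff, normals)
                with np.errstate(divide="ignore", invalid="ignore"):
                    kK = INV_4PI * dotn / r**3
                if q == p:
                    kK[np.arange(Fb), np.arange(s, sl.stop)] = 0.0
                kK = np.nan_to_num(kK, nan=0.0, posinf=0.0, neginf=0.0)
                Kc = w_qp * (area_w[sl, None] * area_w[None, :]) * kK
                t = (P[p].T @ Kc.T).T
                K[:, :] += (P[q][sl].T @ t)
        # D from accumulated single-layer scalars
        for c in range(3):
            t = (C[c].T @ S_block.T).T  # (Fb, n)
            D[:, :] += C[c][sl].T @ t

    # ---- corrections ------------------------------------------------------
    edge_pairs, vertex_pairs, near_pairs = _pair_classes(
        mesh, centroids, radii, near_factor
    )
    base_table = _tensor_table(quadrature_order, quadrature_order)
    near_table = _tensor_table(near_order, near_order)

    def correct(pi, pj, table, perm_i=None, perm_j=None, base=True, skipK=False):
        for s in range(0, len(pi), block_pairs):
            sl = slice(s, s + block_pairs)
            args = (tri, areas, normals, curls, faces, pi[sl], pj[sl])
            pis = None if perm_i is None else perm_i[sl]
            pjs = None if perm_j is None else perm_j[sl]
            if base:  # subtract the far-field contribution for these pairs
                Vl, Kl, I0, gi, gj = _pair_local(*args, *base_table)
                _scatter(V, Vl, gi, gj, -1.0)
                _scatter(K, Kl, gi, gj, -1.0)
                _scatter_D(D, I0, curls, pi[sl], pj[sl], gi, gj, None, None, -1.0)
            Vl, Kl, I0, gi, gj = _pair_local(*args, *table, perm_i=pis, perm_j=pjs)
            _scatter(V, Vl, gi, gj, 1.0)
            if not skipK:
                _scatter(K, Kl, gi, gj, 1.0)
            _scatter_D(D, I0, curls, pi[sl], pj[sl], gi, gj, pis, pjs, 1.0)

    # near non-touching: replace base rule by high-order tensor rule
    if len(near_pairs):
        correct(near_pairs[:, 0], near_pairs[:, 1], near_table)

    # coincident: base pass already skipped the singular diagonal entries of
    # identical pairs but kept the off-diagonal (q != p) ones; subtract what
    # was added, then add the Sauter-Schwab value.  K kernel vanishes on
    # coplanar pairs, so it is skipped.
    ident = np.arange(F)
    xh, yh, w = sauter_schwab_table("coincident", singular_order)
    for s in range(0, F, block_pairs):
        sl = slice(s, s + block_pairs)
        pi = ident[sl]
        # subtract base contribution (with its zeroed diagonal, recomputed here)
        bq2, bw2 = bq, bw
        Ti = tri[pi]
        xb = np.einsum("qa,pac->pqc", bq2, Ti)
        diff = xb[:, :, None, :] - xb[:, None, :, :]
        r = np.sqrt(np.einsum("pqsc,pqsc->pqs", diff, diff))
        with np.errstate(divide="ignore"):
            kV = INV_4PI / r
        iq = np.arange(Q)
        kV[:, iq, iq] = 0.0
        scale = areas[pi] ** 2
        Vl = scale[:, None, None] * np.einsum(
            "pqs,q,s,qa,sb->pab", kV, bw2, bw2, hat, hat
        )
        I0b = scale * np.einsum("pqs,q,s->p", kV, bw2, bw2)
        gi = faces[pi]
        _scatter(V, Vl, gi, gi, -1.0)
        _scatter_D(D, I0b, curls, pi, pi, gi, gi, None, None, -1.0)
        # add accurate
        Vl, _, I0, gi, gj = _pair_local(
            tri, areas, normals, curls, faces, pi, pi, xh, yh, w
        )
        _scatter(V, Vl, gi, gj, 1.0)
        _scatter_D(D, I0, curls, pi, pi, gi, gj, None, None, 1.0)

    # shared-edge pairs: permute both panels so the shared edge is (v0, v1)
    if len(edge_pairs):
        perm_i, perm_j = _edge_perms(faces, edge_pairs)
        xh, yh, w = sauter_schwab_table("edge", singular_order)
        correct(edge_pairs[:, 0], edge_pairs[:, 1], (xh, yh, w), perm_i, perm_j)

    # shared-vertex pairs: shared vertex first on both panels
    if len(vertex_pairs):
        perm_i, perm_j = _vertex_perms(faces, vertex_pairs)
        xh, yh, w = sauter_schwab_table("vertex", singular_order)
        correct(vertex_pairs[:, 0], vertex_pairs[:, 1], (xh, yh, w), perm_i, perm_j)

    # Galerkin row-sum identity: the double layer applied to the constant
    # equals -sigma weakly, with sigma = 1/2 a.e. on a polyhedral surface.
    # Enforcing it on the (hard-to-integrate) diagonal pins lambda_0 = 0.
    rowG = G.sum(axis=1)
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, -0.5 * rowG - K.sum(axis=1))

    V = 0.5 * (V + V.T)
    D = 0.5 * (D + D.T)
    sigma = solid_angle_coefficients(mesh)
    meta = {
        "quadrature_order": quadrature_order,
        "near_order": near_order,
        "singular_order": singular_order,
        "near_factor": near_factor,
        "n_near_pairs": int(len(near_pairs)),
        "regularization": "sauter-schwab + integration-by-parts hypersingular",
    }
    return BoundaryOperators(
        V=V, K=K, Kstar=K.T.copy(), D=D, G=G, sigma=sigma, mesh=mesh, quadrature=meta
    )


def _edge_perms(faces, pairs):
    perm_i = np.empty((len(pairs), 3), dtype=np.int64)
    perm_j = np.empty((len(pairs), 3), dtype=np.int64)
    for k, (a, b) in enumerate(pairs):
        fa, fb = faces[a], faces[b]
        shared = np.intersect1d(fa, fb)
        s0, s1 = shared
        ia0 = int(np.nonzero(fa == s0)[0][0])
        ia1 = int(np.nonzero(fa == s1)[0][0])
        ia2 = 3 - ia0 - ia1
        perm_i[k] = (ia0, ia1, ia2)
        ib0 = int(np.nonzero(fb == s0)[0][0])
        ib1 = int(np.nonzero(fb == s1)[0][0])
        ib2 = 3 - ib0 - ib1
        perm_j[k] = (ib0, ib1, ib2)
    return perm_i, perm_j


def _vertex_perms(faces, pairs):
    perm_i = np.empty((len(pairs), 3), dtype=np.int64)
    perm_j = np.empty((len(pairs), 3), dtype=np.int64)
    for k, (a, b) in enumerate(pairs):
        fa, fb = faces[a], faces[b]
        s = np.intersect1d(fa, fb)[0]
        ia = int(np.nonzero(fa == s)[0][0])
        ib = int(np.nonzero(fb == s)[0][0])
        perm_i[k] = (ia, (ia + 1) % 3, (ia + 2) % 3)
        perm_j[k] = (ib, (ib + 1) % 3, (ib + 2) % 3)
    return perm_i, perm_j


# ---------------------------------------------------------------------------
# eigen solve
# ---------------------------------------------------------------------------


def _sigma_mass(ops: BoundaryOperators, sigma_mode: str) -> np.ndarray:
    """Weak form of multiplication by sigma(x).

    ``"half"`` uses the almost-everywhere value 1/2 (exact on polyhedral
    surfaces, hence the default); ``"vertex"`` interpolates the per-vertex
    interior solid-angle fractions linearly.
    """
    if sigma_mode == "half":
        return 0.5 * ops.G
    if sigma_mode != "vertex":
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    mesh = ops.mesh
    n = mesh.n_vertices
    areas = 0.5 * np.linalg.norm(
        np.cross(
            mesh.vertices[mesh.faces[:, 1]] - mesh.vertices[mesh.faces[:, 0]],
            mesh.vertices[mesh.faces[:, 2]] - mesh.vertices[mesh.faces[:, 0]],
        ),
        axis=1,
    )
    sig = ops.sigma[mesh.faces]  # (F, 3)
    # int_T phi_a phi_b phi_c = 2|T| a!b!c!/(a+b+c+2)! pattern
    M = np.zeros((n, n))
    loc = np.zeros((len(areas), 3, 3))
    for a in range(3):
        for b in range(3):
            for c in range(3):
                powers = np.zeros(3, dtype=int)
                for k in (a, b, c):
                    powers[k] += 1
                from math import factorial

                coef = (
                    2.0
                    * np.prod([factorial(int(p)) for p in powers])
                    / factorial(int(powers.sum()) + 2)
                )
                loc[:, a, b] += coef * areas * sig[:, c]
    i = np.repeat(mesh.faces, 3, axis=1).reshape(-1, 3, 3)
    j = np.tile(mesh.faces, 3).reshape(-1, 3, 3)
    np.add.at(M, (i, j), loc)
    return M


def steklov_matrix(ops: BoundaryOperators, sigma_mode: str = "half") -> tuple[np.ndarray, np.ndarray]:
    """The dense symmetric Steklov-Poincare matrix S and mass G."""
    B = _sigma_mass(ops, sigma_mode) + ops.K
    # symmetric diagonal equilibration of V before factorization guards thin
    # canal conditioning
    d = 1.0 / np.sqrt(np.diag(ops.V))
    if not np.all(np.isfinite(d)):
        raise ConditioningError("V has non-positive diagonal; mesh may be degenerate")
    Vs = d[:, None] * ops.V * d[None, :]
    try:
        cf = sla.cho_factor(Vs, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(
            "single-layer matrix not positive definite; consider rescaling the "
            "mesh or raising quadrature orders"
        ) from exc
    X = d[:, None] * sla.cho_solve(cf, d[:, None] * B)
    S = ops.D + B.T @ X
    return 0.5 * (S + S.T), ops.G


def solve_steklov(
    ops: BoundaryOperators,
    m: int = 50,
    sigma_mode: str = "half",
    method: str = "auto",
    seed: int = 0,
) -> SteklovSpectrum:
    """Smallest ``m`` Steklov eigenpairs of the assembled operators.

    Dense symmetric generalized solve for n <= 3000 (or ``method="dense"``);
    a LOBPCG path with ICCG-preconditioned inner solves above that.
    """
    n = ops.n
    if not 1 <= m <= n - 1:
        raise ValueError(f"need 1 <= m <= n - 1, got m={m}, n={n}")
    S, G = steklov_matrix(ops, sigma_mode)
    if method == "auto":
        method = "dense" if n <= DENSE_EIGEN_LIMIT else "lobpcg"
    if method == "dense":
        vals, vecs = sla.eigh(S, G, subset_by_index=(0, m - 1))
    elif method == "lobpcg":
        from scipy.sparse.linalg import lobpcg

        rng = np.random.default_rng(seed)
        X0 = rng.standard_normal((n, m))
        X0[:, 0] = 1.0
        vals, vecs = lobpcg(S, X0, B=G, largest=False, tol=1e-8, maxiter=500)
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
        # re-normalize in the G inner product
        nrm = np.sqrt(np.einsum("im,ij,jm->m", vecs, G, vecs))
        vecs = vecs / nrm
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.all(np.isfinite(vals)):
        raise SolverError("eigenvalue solve produced non-finite values")
    meta = {
        "seed": seed,
        "sigma_mode": sigma_mode,
        "method": method,
        **ops.quadrature,
    }
    return SteklovSpectrum(
        eigenvalues=vals,
        eigenvectors=vecs,
        normalization="raw",
        mesh=ops.mesh,
        meta=meta,
    )


def normalize_spectrum(spec: SteklovSpectrum, mode: str = "area") -> SteklovSpectrum:
    """Scale-invariant form: lambda_i * sqrt(surface area) (dimensionless)."""
    if mode == "raw":
        return spec
    if mode != "area":
        raise ValueError(f"unknown normalization mode {mode!r}")
    if spec.normalization == "area":
        return spec
    if spec.mesh is None:
        raise ValueError("area normalization requires the mesh reference")
    s = np.sqrt(surface_area(spec.mesh))
    return SteklovSpectrum(
        eigenvalues=spec.eigenvalues * s,
        eigenvectors=spec.eigenvectors,
        normalization="area",
        mesh=spec.mesh,
        meta=dict(spec.meta),
    )


def compute_spectrum(
    mesh: TriangleMesh,
    m: int = 50,
    normalization: str = "raw",
    quadrature_order: int = 4,
    **kwargs,
) -> SteklovSpectrum:
    """Convenience: assemble + solve + optionally normalize."""
    ops = assemble_operators(mesh, quadrature_order=quadrature_order)
    spec = solve_steklov(ops, m=m, **kwargs)
    return normalize_spectrum(spec, normalization) if normalization == "area" else spec
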