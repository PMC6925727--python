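import numpy as np
import pytest
import scipy.linalg as sla

from canalspec import (
    assemble_operators,
    make_icosphere,
    normalize_spectrum,
    solve_steklov,
    surface_area,
    transform_mesh,
)
from canalspec.bem import _face_geometry, _pair_local, steklov_matrix
from canalspec.quadrature import gauss01, refhat, sauter_schwab_table, triangle_rule

from conftest import cached_operators
from test_mesh import rotation_matrix

BALL_EXACT = np.array([1.0] * 3 + [2.0] * 5 + [3.0] * 7)


# ---------------------------------------------------------------------------
# quadrature oracles
# ---------------------------------------------------------------------------


def duffy_product_rule(k: int):
    """k*k-point product rule on the reference triangle via the Duffy map
    (u, uv): an independent oracle for far-field panel integrals."""
    x, w = gauss01(k)
    u = np.repeat(x, k)
    v = np.tile(x, k) * u
    wt = np.repeat(w * x, k) * np.tile(w, k)  # Jacobian u
    return np.stack([u, v], axis=1), wt


def two_triangle_geometry(T1, T2):
    tri = np.stack([T1, T2])
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    normals = cross / (2 * areas[:, None])
    e0 = tri[:, 2] - tri[:, 1]
    e1 = tri[:, 0] - tri[:, 2]
    e2 = tri[:, 1] - tri[:, 0]
    curls = np.stack([e0, e1, e2], axis=1) / (-2.0 * areas[:, None, None])
    faces = np.array([[0, 1, 2], [3, 4, 5]])
    return tri, areas, normals, curls, faces


def test_far_field_single_layer_against_product_oracle():
    # well separated pair: d ~ 40x the panel diameters
    T1 = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    T2 = np.array([[40.0, 1.0, 3.0], [41.0, 1.2, 3.0], [40.2, 2.0, 3.4]])
    tri, areas, normals, curls, faces = two_triangle_geometry(T1, T2)

    # oracle: 64x64-point product quadrature
    uv, w = duffy_product_rule(64)
    x = T1[0] + np.outer(uv[:, 0], T1[1] - T1[0]) + np.outer(uv[:, 1], T1[2] - T1[1])
    y = T2[0] + np.outer(uv[:, 0], T2[1] - T2[0]) + np.outer(uv[:, 1], T2[2] - T2[1])
    hx = refhat(uv)
    r = np.linalg.norm(x[:, None, :] - y[None, :, :], axis=2)
    kern = 1.0 / (4 * np.pi * r)
    oracle = 4 * areas[0] * areas[1] * np.einsum(
        "q,p,qp,qa,pb->ab", w, w, kern, hx, hx
    )

    # far-field helper with the standard degree-4 rule
    from canalspec.bem import _tensor_table

    Vloc, _, _, _, _ = _pair_local(
        tri, areas, normals, curls, faces,
        np.array([0]), np.array([1]), *_tensor_table_args(),
    )
    assert np.abs(Vloc[0] - oracle).max() / np.abs(oracle).max() < 1e-3

    # and the 1/(4 pi d) * (A1/3)(A2/3) centroid approximation holds too
    d = np.linalg.norm(T1.mean(0) - T2.mean(0))
    approx = (areas[0] / 3) * (areas[1] / 3) / (4 * np.pi * d)
    assert Vloc[0, 0, 0] == pytest.approx(approx, rel=2e-3)


def _tensor_table_args():
    from canalspec.bem import _tensor_table

    return _tensor_table(4, 4)


@pytest.mark.parametrize("case", ["edge", "vertex", "coincident"])
def test_sauter_schwab_self_convergence(case):
    """Orders 5 and 8 of the regularized rules must agree closely."""
    T1 = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.2]])
    if case == "coincident":
        T2 = T1
    elif case == "edge":
        T2 = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.4, -0.9, 0.3]])
    else:
        T2 = np.array([[0.0, 0.0, 0.0], [-1.0, -0.1, 0.0], [-0.5, -1.0, 0.4]])

    def value(order):
        xh, yh, w = sauter_schwab_table(case, order)
        x = T1[0] + np.outer(xh[:, 0], T1[1] - T1[0]) + np.outer(xh[:, 1], T1[2] - T1[1])
        y = T2[0] + np.outer(yh[:, 0], T2[1] - T2[0]) + np.outer(yh[:, 1], T2[2] - T2[1])
        r = np.linalg.norm(x - y, axis=1)
        return float(np.sum(w / (4 * np.pi * r)))

    v5, v8, v10 = value(5), value(8), value(10)
    rel = 1e-4 if case == "coincident" else 1e-6
    assert v5 == pytest.approx(v10, rel=rel)
    assert abs(v8 - v10) <= abs(v5 - v10) + 1e-15  # converging in order
    assert v10 > 0


def test_sauter_schwab_vertex_case_against_subdivision_oracle():
    """Vertex-adjacent panels admit a cheap non-singular refinement oracle."""
    T1 = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.2]])
    T2 = np.array([[0.0, 0.0, 0.0], [-1.0, -0.1, 0.0], [-0.5, -1.0, 0.4]])
    bq, bw = triangle_rule(6)

    def gauss_pair(A, B):
        x = bq @ A
        y = bq @ B
        area = lambda T: 0.5 * np.linalg.norm(np.cross(T[1] - T[0], T[2] - T[0]))
        r = np.linalg.norm(x[:, None] - y[None, :], axis=2)
        return area(A) * area(B) * np.einsum("q,p,qp->", bw, bw, 1 / (4 * np.pi * r))

    def subdiv(T):
        m01, m12, m20 = (T[0] + T[1]) / 2, (T[1] + T[2]) / 2, (T[2] + T[0]) / 2
        return [
            np.array([T[0], m01, m20]), np.array([T[1], m12, m01]),
            np.array([T[2], m20, m12]), np.array([m01, m12, m20]),
        ]

    def brute(A, B, depth):
        cA, cB = A.mean(0), B.mean(0)
        size = max(
            np.linalg.norm(A - cA, axis=1).max(), np.linalg.norm(B - cB, axis=1).max()
        )
        if depth == 0 or np.linalg.norm(cA - cB) > 2.5 * size:
            return gauss_pair(A, B)
        return sum(brute(a, b, depth - 1) for a in subdiv(A) for b in subdiv(B))

    oracle = brute(T1, T2, 4)
    xh, yh, w = sauter_schwab_table("vertex", 8)
    x = T1[0] + np.outer(xh[:, 0], T1[1] - T1[0]) + np.outer(xh[:, 1], T1[2] - T1[1])
    y = T2[0] + np.outer(yh[:, 0], T2[1] - T2[0]) + np.outer(yh[:, 1], T2[2] - T2[1])
    r = np.linalg.norm(x - y, axis=1)
    area = lambda T: 0.5 * np.linalg.norm(np.cross(T[1] - T[0], T[2] - T[0]))
    val = 4 * area(T1) * area(T2) * np.sum(w / (4 * np.pi * r))
    assert val == pytest.approx(oracle, rel=1e-5)


# ---------------------------------------------------------------------------
# operator structure
# ---------------------------------------------------------------------------


class TestOperatorStructure:
    def test_galerkin_adjointness(self, ops_ico2):
        K, Ks = ops_ico2.K, ops_ico2.Kstar
        assert np.linalg.norm(Ks - K.T) <= 1e-10 * np.linalg.norm(K)

    def test_symmetry(self, ops_ico2):
        for M in (ops_ico2.V, ops_ico2.D, ops_ico2.G):
            assert np.abs(M - M.T).max() <= 1e-10 * np.abs(M).max()

    def test_spd(self, ops_ico2):
        assert sla.eigvalsh(ops_ico2.G).min() > 0
        assert sla.eigvalsh(ops_ico2.V).min() > 0

    def test_hypersingular_annihilates_constants(self, ops_ico2):
        D = ops_ico2.D
        ones = np.ones(ops_ico2.n)
        assert np.linalg.norm(D @ ones) <= 1e-8 * np.linalg.norm(D)

    def test_mass_row_sums_are_barycentric_areas(self, ico2, ops_ico2):
        areas = ico2.face_areas()
        expect = np.zeros(ico2.n_vertices)
        for k in range(3):
            np.add.at(expect, ico2.faces[:, k], areas / 3.0)
        assert np.abs(ops_ico2.G.sum(axis=1) - expect).max() < 1e-12

    def test_steklov_matrix_symmetric(self, ops_ico2):
        B = 0.5 * ops_ico2.G + ops_ico2.K
        X = sla.solve(ops_ico2.V, B, assume_a="pos")
        S = ops_ico2.D + B.T @ X
        assert np.abs(S - S.T).max() <= 1e-8 * np.abs(S).max()

    def test_argument_errors(self, ico2):
        with pytest.raises(ValueError, match="quadrature_order"):
            assemble_operators(ico2, quadrature_order=2)


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------


class TestSpectrum:
    def test_ball_spectrum(self, spec_ico2):
        ev = spec_ico2.eigenvalues
        assert np.abs(ev[1:4] - 1.0).max() < 0.05
        assert np.abs(ev[4:9] - 2.0).max() < 0.07 * 2.0

    def test_lambda0_zero_constant_eigenvector(self, spec_ico2):
        ev = spec_ico2.eigenvalues
        assert abs(ev[0]) <= 1e-6 * ev[1]
        u0 = spec_ico2.eigenvectors[:, 0]
        assert np.abs(u0 - u0.mean()).max() <= 1e-4 * np.abs(u0.mean())

    def test_nonnegative(self, spec_ico2):
        ev = spec_ico2.eigenvalues
        assert np.all(ev >= -1e-8 * ev[-1])

    def test_g_orthonormal(self, spec_ico2, ops_ico2):
        U = spec_ico2.eigenvectors
        gram = U.T @ ops_ico2.G @ U
        assert np.abs(gram - np.eye(U.shape[1])).max() < 1e-8

    def test_scaling_law(self, ico2, spec_ico2):
        ev0 = spec_ico2.eigenvalues[1:10]
        for s in (0.5, 2.0, 10.0):
            scaled = transform_mesh(ico2, scale=s).validate()
            ops = cached_operators(scaled, f"ico2_scale_{s}")
            ev = solve_steklov(ops, m=10).eigenvalues[1:10]
            assert np.abs(ev - ev0 / s).max() <= 1e-8 * np.abs(ev0 / s).max()

    def test_rigid_invariance(self):
        mesh = make_icosphere(1.0, 1).validate()
        ev0 = solve_steklov(assemble_operators(mesh), m=8).eigenvalues[1:]
        rng = np.random.default_rng(2024)
        for _ in range(10):
            R = rotation_matrix(rng)
            t = rng.standard_normal(3)
            moved = transform_mesh(mesh, rotation=R, translation=t).validate()
            ev = solve_steklov(assemble_operators(moved), m=8).eigenvalues[1:]
            assert np.abs(ev - ev0).max() <= 1e-8 * np.abs(ev0).max()

    def test_m_bounds(self, ops_ico2):
        with pytest.raises(ValueError, match="m"):
            solve_steklov(ops_ico2, m=ops_ico2.n)

    def test_lobpcg_path_matches_dense(self, ops_ico2):
        dense = solve_steklov(ops_ico2, m=6).eigenvalues
        iterative = solve_steklov(ops_ico2, m=6, method="lobpcg", seed=1).eigenvalues
        assert np.abs(iterative[1:] - dense[1:]).max() < 1e-5 * dense[-1]

    def test_vertex_sigma_mode_sane(self, ops_ico2):
        # the per-vertex solid-angle mode biases eigenvalues by O(h) (the
        # a.e. value 1/2 is exact on polyhedra, hence the default); it must
        # still give an ordered spectrum in the right ballpark
        half = solve_steklov(ops_ico2, m=8).eigenvalues[1:]
        vert = solve_steklov(ops_ico2, m=8, sigma_mode="vertex").eigenvalues[1:]
        assert np.all(np.diff(vert) >= -1e-10)
        assert np.abs(vert - half).max() < 0.25 * half.max()


class TestNormalization:
    def test_raw_identity(self, spec_ico2):
        out = normalize_spectrum(spec_ico2, "raw")
        assert out is spec_ico2

    def test_scale_invariance(self, ico2, spec_ico2):
        scaled = transform_mesh(ico2, scale=3.0).validate()
        ops = cached_operators(scaled, "ico2_scale_3")
        spec_s = solve_steklov(ops, m=10)
        a = normalize_spectrum(spec_ico2, "area").eigenvalues[:10]
        b = normalize_spectrum(spec_s, "area").eigenvalues[:10]
        assert np.abs(a - b).max() <= 1e-8 * np.abs(a).max()

    def test_normalized_lambda0_still_zero(self, spec_ico2):
        out = normalize_spectrum(spec_ico2, "area")
        assert abs(out.eigenvalues[0]) <= 1e-6 * out.eigenvalues[1]

    def test_area_factor(self, spec_ico2, ico2):
        out = normalize_spectrum(spec_ico2, "area")
        factor = np.sqrt(surface_area(ico2))
        assert np.allclose(out.eigenvalues, spec_ico2.eigenvalues * factor)


class TestSerialization:
    def test_json_fields(self, spec_ico2):
        import json

        data = json.loads(spec_ico2.to_json())
        assert data["normalization"] == "raw"
        assert data["mesh_name"].startswith("icosphere")
        assert len(data["eigenvalues"]) == spec_ico2.m
        assert "seed" in data

    def test_csv(self, spec_ico2):
        lines = spec_ico2.to_csv().strip().split("\n")
        assert lines[0] == "index,eigenvalue"
        assert len(lines) == spec_ico2.m + 1
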