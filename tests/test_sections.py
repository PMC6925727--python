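import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canalspec import (
    GeometryError,
    enclosed_volume,
    extract_cross_section,
    ideal_radius,
    loft_ideal_canal,
    make_cone,
    make_cylinder,
    make_ideal_canal,
    make_synthetic_canal,
    mean_boundary_deviation,
    select_key_sections,
)
from canalspec.sections import IdealCanalPlan, section_from_points

from conftest import canal_params


def circle_points(n, r=1.0, cx=0.0, cy=0.0, phase=0.0):
    t = phase + 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)])


class TestExtract:
    def test_cylinder_midheight(self):
        cyl = make_cylinder(1.0, 10.0, rings=64, layers=8).validate()
        s = extract_cross_section(cyl, 5.0)
        assert s.area == pytest.approx(np.pi, rel=0.01)
        assert s.perimeter == pytest.approx(2 * np.pi, rel=0.01)
        assert np.linalg.norm(s.centroid) < 1e-9

    def test_cone_analytic_radius(self):
        cone = make_cone(1.0, 3.0, rings=64, layers=16).validate()
        s = extract_cross_section(cone, 1.5)  # analytic radius 0.5
        assert s.area == pytest.approx(np.pi / 4, rel=0.01)

    def test_out_of_range_height(self):
        cyl = make_cylinder(1.0, 10.0).validate()
        with pytest.raises(ValueError, match="extent"):
            extract_cross_section(cyl, 11.0)
        with pytest.raises(ValueError, match="extent"):
            extract_cross_section(cyl, 10.0)  # boundary not strictly inside

    def test_ccw_orientation(self):
        cyl = make_cylinder(1.0, 10.0, rings=32).validate()
        p = extract_cross_section(cyl, 5.0).points
        shoelace = 0.5 * np.sum(
            p[:, 0] * np.roll(p[:, 1], -1) - np.roll(p[:, 0], -1) * p[:, 1]
        )
        assert shoelace > 0


class TestIdealRadius:
    def test_unit_circle(self):
        s = section_from_points(circle_points(256))
        assert ideal_radius(s) == pytest.approx(1.0, rel=1e-4)

    def test_area_4pi(self):
        s = section_from_points(circle_points(512, r=2.0))
        assert ideal_radius(s) == pytest.approx(2.0, rel=1e-4)

    def test_regular_64gon(self):
        s = section_from_points(circle_points(64))
        # polygon-area oracle: A = n/2 sin(2 pi/n)
        area = 64 / 2 * np.sin(2 * np.pi / 64)
        assert s.area == pytest.approx(area, rel=1e-12)
        assert ideal_radius(s) == pytest.approx(np.sqrt(area / np.pi), rel=1e-12)
        # closed form sqrt(n sin(2 pi/n) / (2 pi)) at n = 64
        assert ideal_radius(s) == pytest.approx(0.9991969, abs=1e-6)


class TestMeanDeviation:
    def test_circle_near_zero(self):
        s = section_from_points(circle_points(4096, r=1.0, cx=0.3, cy=-0.2))
        assert mean_boundary_deviation(s) <= 1e-6

    def test_ellipse_matches_direct_summation(self):
        t = 2 * np.pi * np.arange(360) / 360
        pts = np.column_stack([2 * np.cos(t), np.sin(t)])
        s = section_from_points(pts)
        r_ideal = np.sqrt(s.area / np.pi)
        dists = np.sqrt((pts[:, 0] - s.centroid[0]) ** 2 + (pts[:, 1] - s.centroid[1]) ** 2)
        oracle = sum(abs(float(d) - r_ideal) for d in dists) / 360.0
        assert mean_boundary_deviation(s) == pytest.approx(oracle, abs=1e-12)

    def test_square_hand_enumeration(self):
        # side-2 square: 4 corners at sqrt(2), 4 edge midpoints at 1
        pts = np.array(
            [[1, 1], [0, 1], [-1, 1], [-1, 0], [-1, -1], [0, -1], [1, -1], [1, 0]],
            dtype=float,
        )
        s = section_from_points(pts)
        r = np.sqrt(4.0 / np.pi)
        expect = (4 * abs(np.sqrt(2) - r) + 4 * abs(1 - r)) / 8
        assert mean_boundary_deviation(s) == pytest.approx(expect, abs=1e-12)

    @given(
        angle=st.floats(0, 2 * np.pi),
        dx=st.floats(-5, 5),
        dy=st.floats(-5, 5),
    )
    @settings(max_examples=25, deadline=None)
    def test_rigid_inplane_invariance(self, angle, dx, dy):
        t = 2 * np.pi * np.arange(100) / 100
        pts = np.column_stack([1.5 * np.cos(t), 0.8 * np.sin(t) + 0.1 * np.sin(3 * t)])
        base = mean_boundary_deviation(section_from_points(pts))
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        moved = pts @ R.T + [dx, dy]
        assert mean_boundary_deviation(section_from_points(moved)) == pytest.approx(
            base, abs=1e-12
        )


class TestSelect:
    def test_cone_ties_break_to_middle(self):
        cone = make_cone(1.0, 9.0, rings=4096, layers=6).validate()
        plan = select_key_sections(cone)
        for seg in ("coronal", "middle", "apical"):
            assert max(plan.deviations[seg]) <= 1e-6
            assert plan.chosen[seg] == 1  # central candidate at h/3

    def test_segment_arithmetic(self):
        canal = make_synthetic_canal(canal_params(bump_amplitude=0.0))
        plan = select_key_sections(canal, (1 / 3, 1 / 3, 1 / 3))
        assert plan.segment_heights == pytest.approx((10 / 3,) * 3)
        assert plan.offsets == pytest.approx((0.05 * 10 / 3,) * 3)
        # coronal candidates at depth h/3 -+ a below z = 10
        z = plan.candidate_depths["coronal"]
        h = 10 / 3
        assert z == pytest.approx([10 - (h / 3 - 0.05 * h), 10 - h / 3, 10 - (h / 3 + 0.05 * h)])

    def test_bump_at_chosen_plane_shifts_selection(self):
        # add a one-sided lobe exactly at the coronal candidate that wins on
        # the smooth tube: the selection must move to a bump-free candidate
        smooth = make_synthetic_canal(canal_params(bump_amplitude=0.0, rings=64, layers=80))
        plan0 = select_key_sections(smooth)
        won = plan0.chosen["coronal"]
        zb = plan0.candidate_depths["coronal"][won]  # z of the winning plane

        from canalspec.synth import _canal_radius_field, _tube

        p = canal_params(bump_amplitude=0.0, rings=64, layers=80)
        centers, radii = _canal_radius_field(p)
        z = centers[:, 2]
        theta = 2 * np.pi * np.arange(p.rings) / p.rings
        # one-sided lobe: breaks circularity only near that plane
        lobe = np.exp(-np.angle(np.exp(1j * theta)) ** 2 / (2 * 0.5**2))
        bump = 0.4 * np.exp(-((z[:, None] - zb) ** 2) / (2 * 0.05**2)) * lobe[None, :]
        bumped = _tube(centers, radii + bump, p.rings, "bumped").validate()
        plan1 = select_key_sections(bumped)
        assert plan1.chosen["coronal"] != won
        assert (
            plan1.deviations["coronal"][plan1.chosen["coronal"]]
            < plan1.deviations["coronal"][won]
        )

    def test_bad_fractions(self, ico2):
        with pytest.raises(ValueError, match="sum to 1"):
            select_key_sections(ico2, (0.5, 0.4, 0.2))
        with pytest.raises(ValueError, match="positive"):
            select_key_sections(ico2, (1.2, -0.1, -0.1))


class TestLoft:
    def cylinder_plan(self, r=1.0, h=10.0):
        zs = np.linspace(0.0, h, 5)[::-1]  # top to bottom
        secs = [
            section_from_points(circle_points(512, r=r), z=z, depth=h - z) for z in zs
        ]
        return IdealCanalPlan(
            sections=secs,
            segment_heights=(h / 3,) * 3,
            offsets=(0.05 * h / 3,) * 3,
            deviations={k: [0.0] * 3 for k in ("coronal", "middle", "apical")},
            candidate_depths={k: [0.0] * 3 for k in ("coronal", "middle", "apical")},
            chosen={k: 1 for k in ("coronal", "middle", "apical")},
            mesh_name="cylplan",
        )

    def test_five_equal_circles_give_cylinder(self):
        plan = self.cylinder_plan()
        mesh = loft_ideal_canal(plan, rings=64)
        assert enclosed_volume(mesh) == pytest.approx(np.pi * 10.0, rel=0.02)

    def test_decreasing_radii_monotone_sections(self):
        h = 10.0
        zs = np.linspace(0.0, h, 5)[::-1]
        radii = [2.0, 1.7, 1.4, 1.1, 0.8][::-1]  # decreasing downward
        secs = [
            section_from_points(circle_points(512, r=r), z=z, depth=h - z)
            for z, r in zip(zs, reversed(radii))
        ]
        plan = IdealCanalPlan(
            sections=secs,
            segment_heights=(h / 3,) * 3,
            offsets=(0.05 * h / 3,) * 3,
            deviations={k: [0.0] * 3 for k in ("coronal", "middle", "apical")},
            candidate_depths={k: [0.0] * 3 for k in ("coronal", "middle", "apical")},
            chosen={k: 1 for k in ("coronal", "middle", "apical")},
        )
        mesh = loft_ideal_canal(plan, rings=48)
        # radii decrease from top (z=h) to bottom: areas sampled at
        # increasing depth must decrease monotonically
        areas = [
            extract_cross_section(mesh, z).area for z in np.linspace(9.5, 0.5, 20)
        ]
        assert all(a > b for a, b in zip(areas, areas[1:]))

    def test_output_is_valid_closed_mesh(self, bumpy_canal):
        ideal, plan = make_ideal_canal(bumpy_canal, rings=32, layers_per_span=6)
        assert ideal.euler_characteristic() == 2
        assert enclosed_volume(ideal) > 0

    def test_key_section_centroids_reproduced(self, bumpy_canal):
        ideal, plan = make_ideal_canal(bumpy_canal, rings=32, layers_per_span=6)
        for s in plan.sections[1:4]:
            out = extract_cross_section(ideal, s.z)
            assert np.linalg.norm(out.centroid - s.centroid) < 1e-6

    def test_equal_area_circle_preserves_area(self, bumpy_canal):
        # criterion-3 proxy: the replacement circle carries the area exactly
        plan = select_key_sections(bumpy_canal)
        for s in plan.sections:
            assert np.pi * ideal_radius(s) ** 2 == pytest.approx(s.area, rel=1e-9)

    def test_key_ring_area_matches_section_area(self, bumpy_canal):
        plan = select_key_sections(bumpy_canal)
        ideal = loft_ideal_canal(plan, rings=48, layers_per_span=6)
        for s in plan.sections[1:4]:
            out = extract_cross_section(ideal, s.z)
            assert out.area == pytest.approx(s.area, rel=2e-3)

    def test_parameter_validation(self, bumpy_canal):
        plan = select_key_sections(bumpy_canal)
        with pytest.raises(ValueError, match="rings"):
            loft_ideal_canal(plan, rings=8)
        with pytest.raises(ValueError, match="layers_per_span"):
            loft_ideal_canal(plan, layers_per_span=2)

    def test_linear_interpolation_mode(self, bumpy_canal):
        plan = select_key_sections(bumpy_canal)
        mesh = loft_ideal_canal(plan, rings=32, interpolation="linear")
        assert mesh.euler_characteristic() == 2
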