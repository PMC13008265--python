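"""Geometry: capsule closed forms, rotation method, axis/width/profile recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rodcell import (
    capsule_profile,
    extract_radial_profile,
    fit_symmetry_axis,
    generate_scene,
    geometry_mean_radius,
    geometry_rotation,
    measure_scene,
    measure_width,
    population_mean_radius,
    project,
    render_brightfield,
    segment_cells,
)
from rodcell.geometry import RadialProfile, smooth_profile

from conftest import rectangle_coords


class TestCapsuleClosedForm:
    def test_reference_capsule(self):
        g = geometry_mean_radius(2.0, 14.0)
        assert g.surface_area == pytest.approx(56 * math.pi, rel=1e-12)
        assert g.volume == pytest.approx((40 + 32 / 3) * math.pi, rel=1e-12)
        assert g.sa_vol == pytest.approx(g.surface_area / g.volume, rel=0)

    def test_sphere_limit(self):
        g = geometry_mean_radius(2.0, 4.0)
        assert g.surface_area == pytest.approx(16 * math.pi, rel=1e-12)
        assert g.volume == pytest.approx(32 * math.pi / 3, rel=1e-12)
        assert g.sa_vol == pytest.approx(3 / 2.0, rel=1e-12)

    def test_cylinder_limit_sa_vol(self):
        # for L >> R the capsule SA:Vol approaches the open cylinder's 2/R
        g = geometry_mean_radius(2.0, 4000.0)
        assert g.sa_vol == pytest.approx(2 / 2.0, rel=1e-3)

    def test_non_capsule_rejected(self):
        with pytest.raises(ValueError, match="not a capsule"):
            geometry_mean_radius(2.0, 3.0)

    @given(R=st.floats(0.5, 5.0), extra=st.floats(0.0, 20.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_savol_identity_and_positivity(self, R, extra):
        g = geometry_mean_radius(R, 2 * R + extra)
        assert g.surface_area > 0 and g.volume > 0
        assert g.sa_vol * g.volume == pytest.approx(g.surface_area, rel=1e-12)

    def test_savol_strictly_decreasing_in_R_at_fixed_L(self):
        L = 20.0
        ratios = [geometry_mean_radius(R, L).sa_vol for R in np.linspace(0.5, 9.9, 40)]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))


class TestRotationMethod:
    def test_capsule_profile_converges_to_closed_form(self):
        ref = geometry_mean_radius(2.0, 14.0)
        g = geometry_rotation(capsule_profile(2.0, 14.0, 401))
        assert abs(g.volume - ref.volume) / ref.volume < 0.01
        assert abs(g.surface_area - ref.surface_area) / ref.surface_area < 0.02

    def test_volume_error_decreases_with_samples(self):
        ref = geometry_mean_radius(2.0, 14.0).volume
        errs = [
            abs(geometry_rotation(capsule_profile(2.0, 14.0, n)).volume - ref) / ref
            for n in (51, 101, 201, 401)
        ]
        assert all(a > b for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 0.01

    def test_open_cylinder_exact(self):
        R, L, n = 1.5, 10.0, 41
        prof = RadialProfile(x=np.linspace(0, L, n), r=np.full(n, R))
        g = geometry_rotation(prof)
        assert g.volume == pytest.approx(math.pi * R**2 * L, rel=1e-12)
        # lateral surface only: flat ends contribute nothing to 2πr ds
        assert g.surface_area == pytest.approx(2 * math.pi * R * L, rel=1e-12)

    def test_hemisphere_volume(self):
        R, n = 2.0, 801
        x = np.linspace(0, R, n)
        prof = RadialProfile(x=x, r=np.sqrt(np.clip(R**2 - x**2, 0, None)))
        g = geometry_rotation(prof)
        assert g.volume == pytest.approx(2 / 3 * math.pi * R**3, rel=0.01)
        assert g.surface_area == pytest.approx(2 * math.pi * R**2, rel=0.01)


class TestSymmetryAxis:
    def test_axis_aligned_rectangle(self):
        axis = fit_symmetry_axis(rectangle_coords(140, 40), pixel_size=0.1)
        assert axis.direction == pytest.approx((1.0, 0.0), abs=1e-9)
        assert axis.length == pytest.approx(14.0, abs=0.1)

    def test_rotated_rectangle_length_invariant(self):
        axis = fit_symmetry_axis(
            rectangle_coords(140, 40, angle=math.radians(30)), pixel_size=0.1
        )
        assert axis.length == pytest.approx(14.0, rel=0.02)

    def test_round_cell_rejected(self):
        ys, xs = np.mgrid[0:40, 0:40]
        disc = (xs - 20) ** 2 + (ys - 20) ** 2 <= 18**2
        pts = np.column_stack([xs[disc] + 0.5, ys[disc] + 0.5]) * 0.1
        with pytest.raises(ValueError, match="too round"):
            fit_symmetry_axis(pts, pixel_size=0.1)

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            fit_symmetry_axis(np.random.default_rng(0).random((10, 2)), 0.1)


class TestRadialProfile:
    def _capsule_coords(self, R=2.0, L=14.0, px=0.1):
        scene = generate_scene(
            1, seed=1, radius_range=(R, R), length_range=(L, L), pixel_size=px
        )
        from rodcell.synth import cell_footprint

        fp = cell_footprint(scene.cells[0], scene)
        ys, xs = np.nonzero(fp)
        return np.column_stack([xs + 0.5, ys + 0.5]) * px

    def test_midcell_and_cap_values_match_analytic(self):
        pts = self._capsule_coords()
        axis = fit_symmetry_axis(pts, 0.1)
        prof = extract_radial_profile(pts, axis, 0.1, n_samples=141)
        mid = np.interp(prof.length / 2, prof.x, prof.r)
        assert mid == pytest.approx(2.0, abs=0.05)
        # 1 µm in from the tip the spherical cap gives r = √(R²−(R−1)²) = √3
        near_tip = np.interp(1.0, prof.x, prof.r)
        assert near_tip == pytest.approx(math.sqrt(3), abs=0.1)

    def test_rectangle_profile_constant_in_interior(self):
        pts = rectangle_coords(140, 40)
        axis = fit_symmetry_axis(pts, 0.1)
        prof = extract_radial_profile(pts, axis, 0.1, n_samples=101)
        interior = prof.r[5:-5]
        assert np.allclose(interior, 2.0, atol=0.06)

    def test_profile_symmetric_under_reflection(self):
        pts = self._capsule_coords()
        axis = fit_symmetry_axis(pts, 0.1)
        prof = extract_radial_profile(pts, axis, 0.1, n_samples=101)
        # tip stations are dominated by half-pixel binning; compare interior
        assert np.allclose(prof.r[3:-3], prof.r[::-1][3:-3], atol=0.12)

    def test_tips_closed(self):
        pts = self._capsule_coords()
        axis = fit_symmetry_axis(pts, 0.1)
        prof = extract_radial_profile(pts, axis, 0.1)
        assert prof.r[0] == 0.0 and prof.r[-1] == 0.0
        sm = smooth_profile(prof)
        assert sm.r[0] == 0.0 and sm.r[-1] == 0.0


class TestWidth:
    def test_capsule_width_recovers_truth(self):
        pts = TestRadialProfile()._capsule_coords()
        axis = fit_symmetry_axis(pts, 0.1)
        w = measure_width(pts, axis, 0.1)
        assert w == pytest.approx(4.0, abs=0.05)

    def test_rectangle_width_exact(self):
        pts = rectangle_coords(140, 40)
        axis = fit_symmetry_axis(pts, 0.1)
        assert measure_width(pts, axis, 0.1) == pytest.approx(4.0, abs=1e-9)

    def test_width_rotation_invariant(self):
        base = rectangle_coords(140, 40)
        rot = rectangle_coords(140, 40, angle=math.radians(37))
        w0 = measure_width(base, fit_symmetry_axis(base, 0.1), 0.1)
        w37 = measure_width(rot, fit_symmetry_axis(rot, 0.1), 0.1)
        assert w37 == pytest.approx(w0, rel=0.02)

    def test_manual_like_mode_reads_stated_station(self):
        pts = rectangle_coords(140, 40)
        axis = fit_symmetry_axis(pts, 0.1)
        w = measure_width(pts, axis, 0.1, mode="manual_like", at_fraction=0.5)
        assert w == pytest.approx(4.0, abs=0.05)


class TestPopulationMeanRadius:
    def test_constant_widths(self):
        assert population_mean_radius([4.0] * 60) == 2.0

    def test_symmetric_pair_with_lowered_floor(self):
        with pytest.warns(UserWarning, match="under-sampled"):
            R = population_mean_radius([3.8, 4.2], floor=50)
        assert R == pytest.approx(2.0)

    def test_sampling_distribution(self):
        rng = np.random.default_rng(11)
        widths = rng.normal(4.0, 0.1, size=50)
        R = population_mean_radius(widths)
        sem = 0.1 / math.sqrt(50) / 2
        assert abs(R - 2.0) < 3 * sem


class TestMeasureScene:
    @pytest.fixture(scope="class")
    def capsule_field(self):
        scene = generate_scene(
            12, seed=21, radius_range=(1.8, 2.2), length_range=(10.0, 16.0),
            binucleate_fraction=0.0, image_shape=(900, 900), pixel_size=0.1,
            z_planes=1,
        )
        bf = render_brightfield(scene)
        mask = segment_cells(project(bf, "single_plane"), 0.1)
        return scene, mask

    def test_method_equivalence_per_cell(self, capsule_field):
        _, mask = capsule_field
        df = measure_scene(mask, radius_mode="per_cell")
        ok = df[df["method"].notna()].pivot(
            index="cell_id", columns="method", values=["SA_um2", "Vol_um3"]
        )
        rel_sa = (
            (ok["SA_um2"]["rotation"] - ok["SA_um2"]["mean_radius"]).abs()
            / ok["SA_um2"]["mean_radius"]
        )
        rel_vol = (
            (ok["Vol_um3"]["rotation"] - ok["Vol_um3"]["mean_radius"]).abs()
            / ok["Vol_um3"]["mean_radius"]
        )
        frac = ((rel_sa <= 0.05) & (rel_vol <= 0.05)).mean()
        assert frac >= 0.9

    def test_recovered_savol_matches_truth(self, capsule_field):
        scene, mask = capsule_field
        df = measure_scene(mask)
        rot = df[df["method"] == "rotation"]
        truth_savol = np.mean(
            [geometry_mean_radius(c.radius, c.length).sa_vol for c in scene.cells]
        )
        assert rot["SAvol_per_um"].mean() == pytest.approx(truth_savol, rel=0.02)

    def test_empty_mask_empty_table(self):
        from rodcell import LabeledMask

        empty = LabeledMask(labels=np.zeros((32, 32), dtype=np.int32), pixel_size=0.1)
        df = measure_scene(empty)
        assert len(df) == 0
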