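"""Morphometrics on constructed masks and on the rendered study."""

import numpy as np
import pytest

import porebiofilm as pb
from porebiofilm.architecture import (
    angular_thickness,
    bb_perimeter_and_tortuosity,
    classify_bb,
    coverage_series,
    delineate_streamers,
    streamer_length,
    streamer_porosity,
    streamer_width,
)

from conftest import annulus_mask


@pytest.fixture()
def one_grain_geometry():
    """1x1 mm at 5 µm/px with a single centred grain of radius 0.15 mm."""
    return pb.DeviceGeometry(1.0, 1.0, 5.0, (pb.Grain(0, 0.5, 0.5, 0.15),))


def _center(geom):
    return geom.grain_center_px(geom.grains[0])


class TestClassifyBB:
    def test_full_annulus_reaches_rendered_radius(self, one_grain_geometry):
        geom = one_grain_geometry
        c = _center(geom)
        mask = annulus_mask(geom.shape, c, 30, 40)  # 50 µm coat
        cls = classify_bb(mask, geom)
        assert cls.outer_radius_mm[0] == pytest.approx(0.20, abs=0.01)
        assert cls.per_grain_masks[0].sum() == mask.sum()

    @pytest.mark.parametrize("offset,expect_bb", [(0, True), (-1, False)])
    def test_35_percent_ring_rule_is_inclusive(self, one_grain_geometry, offset, expect_bb):
        """A first ring at exactly 35% coverage is BB; one pixel fewer is not."""
        geom = one_grain_geometry
        c = _center(geom)
        rows = np.arange(geom.shape[0])[:, None]
        cols = np.arange(geom.shape[1])[None, :]
        d = np.hypot(rows - c[0], cols - c[1])
        ring = (d > 30) & (d <= 32)  # first 10 µm annulus
        coords = np.argwhere(ring)
        n = len(coords)
        k = int(np.ceil(0.35 * n)) + offset
        mask = np.zeros(geom.shape, bool)
        mask[tuple(coords[:k].T)] = True
        cls = classify_bb(mask, geom)
        assert (cls.outer_radius_mm[0] > 0.15) == expect_bb

    def test_bare_grain_has_empty_record(self, one_grain_geometry):
        cls = classify_bb(np.zeros(one_grain_geometry.shape, bool), one_grain_geometry)
        assert cls.outer_radius_mm[0] == pytest.approx(0.15)
        assert not cls.bb_mask.any()


class TestAngularThickness:
    def test_uniform_annulus_constant_profile(self, one_grain_geometry):
        geom = one_grain_geometry
        mask = annulus_mask(geom.shape, _center(geom), 30, 40)
        prof = angular_thickness(mask, geom, geom.grains[0])
        assert np.all(np.abs(prof - 50.0) <= 5.0)  # 50 µm ± 1 px

    def test_half_coated_grain_zero_downstream(self, one_grain_geometry):
        geom = one_grain_geometry
        c = _center(geom)
        cols = np.arange(geom.shape[1])[None, :]
        mask = annulus_mask(geom.shape, c, 30, 40) & (np.broadcast_to(cols, geom.shape) < c[1])
        prof = angular_thickness(mask, geom, geom.grains[0])
        downstream = np.r_[prof[:880], prof[2720:]]
        upstream = prof[920:2680]
        assert np.all(downstream == 0)
        assert np.all(upstream > 0)

    def test_empty_mask_gives_zero_profile(self, one_grain_geometry):
        prof = angular_thickness(np.zeros(one_grain_geometry.shape, bool),
                                 one_grain_geometry, one_grain_geometry.grains[0])
        assert not prof.any()


class TestTortuosity:
    def test_closed_smooth_annulus_scores_one(self, one_grain_geometry):
        geom = one_grain_geometry
        mask = annulus_mask(geom.shape, _center(geom), 30, 40)
        p_mm, tort = bb_perimeter_and_tortuosity(mask, geom, geom.grains[0])
        assert tort == pytest.approx(1.0, abs=0.02)

    def test_fingered_boundary_matches_arclength_oracle(self, one_grain_geometry):
        """P_BB of a sinusoidally fingered coat vs the analytic arc length
        of rho(theta) = r_out(1 + ...): within 1%; tortuosity > 1."""
        from scipy.integrate import quad

        geom = one_grain_geometry
        c = _center(geom)
        rows = np.arange(geom.shape[0])[:, None]
        cols = np.arange(geom.shape[1])[None, :]
        d = np.hypot(rows - c[0], cols - c[1])
        theta = np.arctan2(-(rows - c[0]), cols - c[1])
        outer = 40.0 + 3.0 * np.sin(8 * theta)
        mask = (d > 30) & (d <= outer)
        rho = lambda th: 40.0 + 3.0 * np.sin(8 * th)
        drho = lambda th: 24.0 * np.cos(8 * th)
        arclen_px, _ = quad(lambda th: np.hypot(rho(th), drho(th)), 0, 2 * np.pi,
                            limit=400)
        p_mm, tort = bb_perimeter_and_tortuosity(mask, geom, geom.grains[0])
        assert p_mm == pytest.approx(arclen_px * geom.pixel_size_mm, rel=0.01)
        assert tort > 1.05

    def test_sparse_arcs_score_below_one(self, one_grain_geometry):
        geom = one_grain_geometry
        c = _center(geom)
        rows = np.arange(geom.shape[0])[:, None]
        cols = np.arange(geom.shape[1])[None, :]
        d = np.hypot(rows - c[0], cols - c[1])
        theta = np.degrees(np.arctan2(-(rows - c[0]), cols - c[1])) % 360
        arcs = np.zeros(geom.shape, bool)
        for start in (10, 100, 190, 280):  # 4 arcs of 20 deg = 22% coverage
            arcs |= (theta >= start) & (theta < start + 20)
        mask = (d > 30) & (d <= 33) & arcs
        _, tort = bb_perimeter_and_tortuosity(mask, geom, geom.grains[0])
        assert 0 < tort < 1


class TestDelineation:
    @pytest.mark.parametrize("gap_um,n_expected", [(40, 1), (45, 2), (46, 2)])
    def test_linkage_threshold(self, bare_geometry, gap_um, n_expected):
        mask = np.zeros(bare_geometry.shape, bool)
        mask[100:120, 10:60] = True
        mask[100:120, 60 + gap_um:110 + gap_um] = True
        ss = delineate_streamers(mask, bare_geometry)
        assert ss.n_streamers == n_expected

    def test_chain_merging_is_transitive(self, bare_geometry):
        mask = np.zeros(bare_geometry.shape, bool)
        for start in (10, 60, 110):  # consecutive gaps of 19 um
            mask[100:120, start:start + 31] = True
        ss = delineate_streamers(mask, bare_geometry)
        assert ss.n_streamers == 1
        assert ss.member_counts[1] == 3

    def test_single_cluster_is_one_streamer(self, bare_geometry):
        mask = np.zeros(bare_geometry.shape, bool)
        mask[50:70, 50:150] = True
        ss = delineate_streamers(mask, bare_geometry)
        assert ss.n_streamers == 1
        np.testing.assert_array_equal(ss.mask(1), mask)

    def test_anchor_is_nearest_upstream_grain(self):
        geom = pb.DeviceGeometry(2.0, 2.0, 5.0, (
            pb.Grain(0, 0.4, 1.0, 0.15), pb.Grain(1, 1.6, 1.0, 0.15),
        ))
        mask = np.zeros(geom.shape, bool)
        mask[195:205, 130:200] = True  # lobe just downstream of grain 0
        ss = delineate_streamers(mask, geom)
        assert ss.anchor_grain[1] == 0


class TestStreamerMetrics:
    def test_bar_length(self, one_grain_geometry):
        mask = np.zeros(one_grain_geometry.shape, bool)
        mask[20:26, 40:140]= True  # 100 x 6 px at 5 um/px
        L = streamer_length(mask, one_grain_geometry)
        assert L == pytest.approx(0.5, abs=0.010)  # ± 2 px

    def test_u_band_measures_midline_not_chord(self, bare_geometry):
        rows = np.arange(bare_geometry.shape[0])[:, None]
        cols = np.arange(bare_geometry.shape[1])[None, :]
        d = np.hypot(rows - 100, cols - 150)
        mask = (np.abs(d - 80) <= 8) & (rows >= 100)
        L_mm = streamer_length(mask, bare_geometry)
        midline = np.pi * 80 * bare_geometry.pixel_size_mm
        chord = 160 * bare_geometry.pixel_size_mm
        assert L_mm == pytest.approx(midline, rel=0.15)
        assert L_mm > 1.2 * chord

    def test_bar_width_is_twice_halfwidth(self, one_grain_geometry):
        mask = np.zeros(one_grain_geometry.shape, bool)
        mask[20:26, 40:140] = True
        W = streamer_width(mask, one_grain_geometry)
        assert W == pytest.approx(0.030, abs=0.005)  # 6 px ± 1 px

    def test_wedge_width_matches_mean_halfwidth(self, bare_geometry):
        rows = np.arange(bare_geometry.shape[0])[:, None]
        cols = np.arange(bare_geometry.shape[1])[None, :]
        s = cols - 50
        half = 12.0 * (1 - s / 200.0)
        mask = (s >= 0) & (s <= 200) & (np.abs(rows - 150) <= half)
        W_mm = streamer_width(mask, bare_geometry)
        # analytic mean of the 2*halfwidth profile = 24 px / 2
        assert W_mm == pytest.approx(12.0 * bare_geometry.pixel_size_mm, rel=0.2)

    def test_solid_streamer_porosity(self, one_grain_geometry):
        mask = np.zeros(one_grain_geometry.shape, bool)
        mask[20:40, 40:140] = True
        bf, vf = streamer_porosity(mask, one_grain_geometry)
        assert bf == pytest.approx(1.0, abs=0.02)
        assert vf == pytest.approx(0.0, abs=0.02)

    def test_sparse_fill_fraction_recovered(self, bare_geometry):
        rng = np.random.default_rng(0)
        mask = np.zeros(bare_geometry.shape, bool)
        block = rng.random((20, 200)) < 0.10
        mask[100:120, 50:250] = block
        bf, _ = streamer_porosity(mask, bare_geometry)
        assert bf == pytest.approx(0.10, abs=0.04)

    def test_empty_mask_rejected(self, one_grain_geometry):
        for fn in (streamer_length, streamer_width, streamer_porosity):
            with pytest.raises(ValueError):
                fn(np.zeros(one_grain_geometry.shape, bool), one_grain_geometry)


class TestPipelineInvariants:
    def test_partition_bb_streamer_disjoint_and_covering(self, desk_study):
        res = desk_study["result"]
        m = desk_study["masks"].masks[-1]
        bb = res["bb_masks"][-1]
        st = res["streamer_masks"][-1]
        assert not (bb & st).any()
        np.testing.assert_array_equal(bb | st, m)  # exact partition

    def test_width_never_exceeds_length(self, desk_study):
        s = desk_study["result"]["streamers"]
        assert (s.L_mm >= s.W_mm).all()

    def test_closed_grain_tortuosity_at_least_one(self, desk_study):
        """Any closed boundary enclosing the grain is at least as long as the
        smooth reference circle."""
        bb = desk_study["result"]["bb"].query("frame == 22")
        assert (bb.tortuosity >= 1.0 - 1e-6).all()

    def test_profile_area_consistency(self, desk_study):
        """Annular integral of the measured thickness profile matches the BB
        mask area within 2% (final frame)."""
        geom = desk_study["geometry"]
        res = desk_study["result"]
        px = geom.pixel_size_mm
        dtheta = 2 * np.pi / 3600
        for gi, g in enumerate(geom.grains):
            prof_mm = res["profiles"][-1][gi] / 1000.0
            inner = g.radius_mm + px  # occluded ring at the grain edge
            outer = np.maximum(g.radius_mm + prof_mm, inner)
            integral = float(np.sum(0.5 * (outer**2 - inner**2) * dtheta))
            area = res["bb"].query(f"frame == 22 and grain_id == {g.grain_id}").area_mm2.item()
            assert area == pytest.approx(integral, rel=0.02)

    def test_coverage_partition_identity(self, desk_study):
        cov = desk_study["result"]["coverage"]
        np.testing.assert_allclose(cov.TB, cov.BB + cov.streamer)
        assert ((cov[["TB", "BB", "streamer"]] >= 0).all() &
                (cov[["TB", "BB", "streamer"]] <= 1).all()).all()

    def test_empty_masks_give_zero_coverage(self, desk_geometry):
        zeros = [np.zeros(desk_geometry.shape, bool)]
        cov = coverage_series(np.array([0.0]), zeros, zeros, desk_geometry)
        assert cov[["TB", "BB", "streamer"]].to_numpy().sum() == 0
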