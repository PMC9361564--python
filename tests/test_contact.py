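import numpy as np
import pytest

from mcsquant import (ConsistencyError, ContactConfig, ShapeMismatchError,
                      UndefinedRatioError, aggregate_image, brute_force_contact,
                      compute_distance_map, compute_min_distance, compute_overlap,
                      contact_pipeline, contact_ratio, extract_boundary,
                      parallel_bar_scene, profile_contacts, quantify_patch)
from mcsquant.contact import DistanceGrid
from mcsquant.mask_io import ReportRow

from conftest import make_scene, profiles_equal


class TestBoundary:
    def test_filled_square_has_perimeter_ring(self, filled_square):
        edge = extract_boundary(filled_square)
        assert edge.sum() == 16
        assert not edge[4, 4]  # center is interior

    def test_single_pixel_is_its_own_boundary(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        np.testing.assert_array_equal(extract_boundary(m), m)

    def test_empty_mask_gives_empty_edge(self):
        assert not extract_boundary(np.zeros((4, 4), dtype=bool)).any()

    def test_image_border_pixels_are_boundary(self):
        m = np.ones((4, 4), dtype=bool)
        edge = extract_boundary(m)
        assert edge.sum() == 12 and not edge[1:3, 1:3].any()


class TestOverlap:
    def test_disjoint_masks_give_empty_overlap(self):
        a = np.zeros((4, 4), dtype=bool); a[:2] = True
        b = np.zeros((4, 4), dtype=bool); b[3:] = True
        assert not compute_overlap(a, b).any()

    def test_identical_masks_overlap_everywhere(self, filled_square):
        np.testing.assert_array_equal(compute_overlap(filled_square, filled_square),
                                      filled_square)

    def test_half_overlapping_squares_share_block(self):
        a = np.zeros((8, 8), dtype=bool); a[2:6, 0:4] = True
        b = np.zeros((8, 8), dtype=bool); b[2:6, 2:6] = True
        ov = compute_overlap(a, b)
        assert ov.sum() == 8 and ov[2:6, 2:4].all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            compute_overlap(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


def _bars(gap, height=6, T=10):
    mito, er, _ = parallel_bar_scene(gap, height, T)
    return mito > 0, er


class TestMinDistance:
    def test_straight_gap_distance(self):
        mito, er = _bars(2)
        overlap = compute_overlap(mito, er)
        edge_m, edge_e = extract_boundary(mito), extract_boundary(er)
        md = compute_min_distance(edge_e, edge_m, overlap, 10)
        vals = md.values[edge_e]
        np.testing.assert_allclose(vals, 3.0)

    def test_sentinel_when_nothing_in_range(self):
        # facing edges are 3 px apart, beyond T=1: every pixel holds the sentinel 2
        mito, er = _bars(2)
        overlap = compute_overlap(mito, er)
        md = compute_min_distance(extract_boundary(er), extract_boundary(mito), overlap, 1)
        assert (md.values == 2.0).all()

    def test_overlap_er_pixels_keep_sentinel(self):
        m = np.zeros((6, 6), dtype=bool); m[1:4, 1:4] = True
        md = compute_min_distance(extract_boundary(m), extract_boundary(m),
                                  compute_overlap(m, m), 5)
        assert (md.values == 6.0).all()


class TestDistanceMap:
    def test_parallel_bars_map_to_gap_plus_one(self):
        mito, er = _bars(3, height=8)
        T = 10
        overlap = compute_overlap(mito, er)
        edge_m, edge_e = extract_boundary(mito), extract_boundary(er)
        md = compute_min_distance(edge_e, edge_m, overlap, T)
        dm = compute_distance_map(edge_m, edge_e, overlap, md, T)
        np.testing.assert_allclose(dm.values[edge_m], 4.0)

    def test_one_to_one_rule_rejects_far_pairs(self):
        """An ER pixel with a mitochondria neighbour at distance 1 cannot
        support a second contact at distance >= 2 (one-to-one relaxation)."""
        # mito A adjacent to the ER column; mito B 3 px to the right of it
        mito = np.zeros((5, 8), dtype=bool)
        er = np.zeros((5, 8), dtype=bool)
        er[2, 1] = True
        mito[2, 2] = True      # d = 1 -> MinDistance = 1
        mito[2, 5] = True      # d = 4 >= MinDistance + 1 -> inadmissible
        T = 10
        overlap = compute_overlap(mito, er)
        edge_m, edge_e = extract_boundary(mito), extract_boundary(er)
        md = compute_min_distance(edge_e, edge_m, overlap, T)
        dm = compute_distance_map(edge_m, edge_e, overlap, md, T)
        assert dm.values[2, 2] == 1.0
        assert dm.values[2, 5] == T + 1  # sentinel: candidate rejected
        profile = profile_contacts(dm, edge_m, T)
        assert profile.len_con == 1 and profile.n_con == 1

    def test_mito_edge_inside_overlap_maps_to_zero(self):
        mito = np.zeros((6, 6), dtype=bool); mito[1:5, 1:3] = True
        er = np.zeros((6, 6), dtype=bool); er[1:5, 2:5] = True
        T = 5
        overlap = compute_overlap(mito, er)
        edge_m, edge_e = extract_boundary(mito), extract_boundary(er)
        md = compute_min_distance(edge_e, edge_m, overlap, T)
        dm = compute_distance_map(edge_m, edge_e, overlap, md, T)
        assert (dm.values[overlap & edge_m] == 0).all()

    def test_threshold_mismatch_rejected(self):
        g = DistanceGrid(np.full((3, 3), 6.0), 5)
        with pytest.raises(ConsistencyError):
            compute_distance_map(np.zeros((3, 3), bool), np.zeros((3, 3), bool),
                                 np.zeros((3, 3), bool), g, 10)


class TestProfile:
    def test_empty_er_gives_zero_profile(self, filled_square):
        profile, _, _ = contact_pipeline(filled_square, np.zeros_like(filled_square), 10)
        assert profile.len_con == 0 and not profile.length_per_bin.any()
        assert profile.len_mito == 16

    def test_identical_masks_put_everything_in_bin_zero(self, filled_square):
        profile, _, _ = contact_pipeline(filled_square, filled_square, 10)
        assert profile.length_per_bin[0] == profile.len_con == profile.len_mito == 16

    def test_parallel_bar_counts_match_oracle(self):
        mito, er, expected = parallel_bar_scene(4, 20, 10)
        profile, _, _ = contact_pipeline(mito, er, 10)
        np.testing.assert_array_equal(profile.length_per_bin, expected)
        assert profile.length_per_bin[5] >= 18  # interior rows all contact
        assert profiles_equal(profile, brute_force_contact(mito, er, 10))


class TestRatios:
    def test_full_overlap_cumulative_ratio_is_one(self, filled_square):
        profile, _, _ = contact_pipeline(filled_square, filled_square, 10)
        ratios = contact_ratio(profile)
        assert ratios.at(10) == 1.0

    def test_empty_er_all_ratios_zero(self, filled_square):
        profile, _, _ = contact_pipeline(filled_square, np.zeros_like(filled_square), 10)
        ratios = contact_ratio(profile)
        assert not ratios.per_bin.any() and ratios.at(10) == 0.0

    def test_bin_arithmetic(self):
        from mcsquant.contact import ContactProfile
        bins = np.zeros(11, dtype=int); bins[4] = 18
        profile = ContactProfile(length_per_bin=bins, len_con=18, n_con=18,
                                 n_segments=1, len_mito=84)
        assert contact_ratio(profile).per_bin[4] == pytest.approx(18 / 84)

    def test_no_boundary_raises_instead_of_silent_zero(self):
        from mcsquant.contact import ContactProfile
        profile = ContactProfile(length_per_bin=np.zeros(11, dtype=int), len_con=0,
                                 n_con=0, n_segments=0, len_mito=0)
        with pytest.raises(UndefinedRatioError):
            contact_ratio(profile)


class TestQuantifyPatch:
    def test_no_mitochondria_flags_undefined_ratio(self):
        er = np.zeros((32, 32), dtype=bool); er[4:10, 4:10] = True
        row = quantify_patch(np.zeros((32, 32), dtype=np.int32), er, ContactConfig())
        assert row.n_instances == 0 and row.ratio_per_bin is None
        assert row.cumulative_ratio is None

    def test_disk_and_ribbon_at_gap_two(self):
        mito, er, expected = parallel_bar_scene(2, 12, 10)
        row = quantify_patch(mito, er, ContactConfig())
        assert row.length_per_bin == tuple(expected)
        assert row.ratio_per_bin[3] == pytest.approx(12 / row.len_mito_px)

    def test_determinism(self):
        mito, er = make_scene(11)
        cfg = ContactConfig()
        assert quantify_patch(mito, er, cfg) == quantify_patch(mito, er, cfg)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            quantify_patch(np.zeros((4, 4), dtype=np.int32), np.zeros((5, 5), bool),
                           ContactConfig())


class TestAggregate:
    def _patch_row(self, patch_id, len_mito, bin1, image_id="img", T=10):
        lengths = [0] * (T + 1); lengths[1] = bin1
        return ReportRow(image_id=image_id, patch_id=patch_id, pair="ER-Mito",
                         n_instances=2, total_perimeter_px=float(len_mito),
                         mean_perimeter_px=len_mito / 2, total_area_px=100.0,
                         mean_elongation=1.2, len_mito_px=len_mito, n_contact_px=bin1,
                         n_contact_segments=1, length_per_bin=tuple(lengths),
                         ratio_per_bin=tuple(v / len_mito for v in lengths),
                         cumulative_cut=3)

    def test_sum_then_ratio_not_mean_of_ratios(self):
        rows = [self._patch_row("p0", 100, 10), self._patch_row("p1", 300, 90)]
        agg = aggregate_image(rows)
        assert agg.ratio_per_bin[1] == pytest.approx(0.25)
        assert agg.ratio_per_bin[1] != pytest.approx(0.20)  # the ratio-then-mean trap
        assert agg.len_mito_px == 400 and agg.length_per_bin[1] == 100

    def test_single_patch_aggregate_matches_patch(self):
        row = self._patch_row("p0", 84, 18)
        agg = aggregate_image([row])
        assert agg.length_per_bin == row.length_per_bin
        assert agg.ratio_per_bin == row.ratio_per_bin
        assert agg.len_mito_px == row.len_mito_px
        assert agg.patch_id == "aggregate"

    def test_zero_mito_patch_contributes_nothing(self):
        empty = ReportRow(image_id="img", patch_id="p2", pair="ER-Mito", n_instances=0,
                          total_perimeter_px=0.0, mean_perimeter_px=None,
                          total_area_px=0.0, mean_elongation=None, len_mito_px=0,
                          n_contact_px=0, n_contact_segments=0,
                          length_per_bin=(0,) * 11, ratio_per_bin=None, cumulative_cut=3)
        with_empty = aggregate_image([self._patch_row("p0", 100, 10), empty])
        without = aggregate_image([self._patch_row("p0", 100, 10)])
        assert with_empty.ratio_per_bin == without.ratio_per_bin
        assert with_empty.len_mito_px == without.len_mito_px

    def test_mixed_image_ids_rejected(self):
        with pytest.raises(ConsistencyError):
            aggregate_image([self._patch_row("p0", 100, 10, image_id="a"),
                             self._patch_row("p1", 100, 10, image_id="b")])


class TestOracleEquivalence:
    @pytest.mark.parametrize("threshold", [3, 10])
    def test_random_scenes_agree_exactly(self, threshold):
        for seed in range(40):
            mito, er = make_scene(seed)
            fast, _, _ = contact_pipeline(mito, er, threshold)
            assert profiles_equal(fast, brute_force_contact(mito, er, threshold)), seed

    def test_empty_masks_give_zero_profile(self):
        z = np.zeros((16, 16), dtype=bool)
        profile = brute_force_contact(z, z, 10)
        assert profile.len_mito == 0 and profile.len_con == 0


class TestInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_and_bounds(self, seed):
        mito, er = make_scene(seed)
        profile, _, _ = contact_pipeline(mito, er, 10)
        assert profile.length_per_bin.sum() == profile.len_con <= profile.len_mito
        assert profile.n_segments <= profile.len_con
        if profile.len_mito:
            r = contact_ratio(profile)
            assert (r.per_bin >= 0).all() and r.at(10) <= 1.0 + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_cumulative_length_monotone_in_threshold(self, seed):
        mito, er = make_scene(seed)
        lens = []
        for T in (3, 5, 10):
            profile, _, _ = contact_pipeline(mito, er, T)
            lens.append(profile.len_con)
        assert lens[0] <= lens[1] <= lens[2]

    @pytest.mark.parametrize("seed", range(6))
    def test_profile_invariant_under_joint_symmetries(self, seed):
        mito, er = make_scene(seed, shape=(80, 80))
        base, _, _ = contact_pipeline(mito, er, 10)

        def prof(m, e):
            p, _, _ = contact_pipeline(m, e, 10)
            return p

        pad = ((5, 3), (2, 7))
        translated = prof(np.pad(mito, pad), np.pad(er, pad))
        assert profiles_equal(base, translated)
        assert profiles_equal(base, prof(mito[:, ::-1], er[:, ::-1]))
        assert profiles_equal(base, prof(mito[::-1, :], er[::-1, :]))
        assert profiles_equal(base, prof(np.rot90(mito), np.rot90(er)))
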