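import numpy as np
import pytest

from cnvae.segmentation import (
    BreakpointSet,
    assign_clones,
    clone_profile,
    estimate_sigma,
    find_breakpoints,
    round_half_away,
    segment_cell_profile,
)
from oracles import all_segmentations_best, exhaustive_segmentation, \
    single_changepoint_scan


def _chrom(n, name="1"):
    return np.array([name] * n)


class TestFindBreakpoints:
    def test_flat_noisy_track_yields_no_breakpoints(self):
        r = np.random.default_rng(0)
        track = 2.0 + r.normal(0, 0.05, size=100)
        bset = find_breakpoints(track, _chrom(100))
        assert bset.breakpoints["1"] == []

    def test_single_step_found_within_one_bin(self):
        r = np.random.default_rng(3)
        track = np.r_[np.full(50, 2.0), np.full(50, 4.0)] + r.normal(0, 0.1, 100)
        bset = find_breakpoints(track, _chrom(100))
        assert len(bset.breakpoints["1"]) == 1
        assert abs(bset.breakpoints["1"][0] - 50) <= 1
        # and agrees with the exhaustive single-split likelihood scan
        t, _ = single_changepoint_scan(track, estimate_sigma(track))
        assert bset.breakpoints["1"][0] == t

    def test_two_steps_recovered_with_accurate_levels(self):
        r = np.random.default_rng(5)
        truth = np.r_[np.full(40, 2.0), np.full(30, 4.0), np.full(30, 1.0)]
        track = truth + r.normal(0, 0.1, 100)
        bset = find_breakpoints(track, _chrom(100))
        assert len(bset.breakpoints["1"]) == 2
        assert abs(bset.breakpoints["1"][0] - 40) <= 1
        assert abs(bset.breakpoints["1"][1] - 70) <= 1
        for (lo, hi), level in zip(bset.segments("1"), [2.0, 4.0, 1.0]):
            assert track[lo:hi].mean() == pytest.approx(level, abs=0.3)

    def test_noiseless_piecewise_constant_equals_brute_force(self):
        r = np.random.default_rng(11)
        for _ in range(10):
            n = int(r.integers(20, 61))
            n_bp = int(r.integers(0, 4))
            bps = sorted(r.choice(np.arange(2, n - 2), size=n_bp, replace=False))
            # guard: distinct, separated levels
            levels = r.choice([1.0, 2.0, 3.0, 4.0], size=n_bp + 1)
            while np.any(np.diff(levels) == 0):
                levels = r.choice([1.0, 2.0, 3.0, 4.0], size=n_bp + 1)
            track = np.empty(n)
            for lo, hi, lv in zip([0] + bps, bps + [n], levels):
                track[lo:hi] = lv
            sigma = 0.05
            penalty_cost = 3.0 * np.log(n)
            got = find_breakpoints(track, _chrom(n), sigma=sigma).breakpoints["1"]
            expected = all_segmentations_best(track, penalty_cost, sigma)
            assert got == expected == bps

    def test_breakpoints_respect_chromosome_boundaries(self):
        # noiseless: a level change exactly at the chromosome boundary
        # must produce no interior breakpoint on either side
        track = np.r_[np.full(30, 2.0), np.full(30, 5.0)]
        chrom = np.array(["1"] * 30 + ["2"] * 30)
        bset = find_breakpoints(track, chrom)
        assert bset.breakpoints["1"] == [] and bset.breakpoints["2"] == []
        assert bset.chrom_sizes == {"1": 30, "2": 30}

    def test_breakpoint_indices_stay_inside_their_chromosome(self):
        r = np.random.default_rng(4)
        track = np.r_[
            np.full(20, 2.0), np.full(20, 4.0),  # step inside chrom 1
            np.full(25, 1.0), np.full(15, 3.0),  # step inside chrom 2
        ] + r.normal(0, 0.1, 80)
        chrom = np.array(["1"] * 40 + ["2"] * 40)
        bset = find_breakpoints(track, chrom)
        for c, size in bset.chrom_sizes.items():
            assert all(0 < b < size for b in bset.breakpoints[c])
        assert any(abs(b - 20) <= 1 for b in bset.breakpoints["1"])
        assert any(abs(b - 25) <= 1 for b in bset.breakpoints["2"])

    def test_short_chromosome_has_no_breakpoints(self):
        bset = find_breakpoints(np.array([2.0]), _chrom(1))
        assert bset.breakpoints["1"] == []


class TestSegmentCellProfile:
    def _bset(self, sizes, bps):
        return BreakpointSet(
            breakpoints=bps, chrom_sizes=sizes,
        )

    def test_median_then_round(self):
        bset = self._bset({"1": 3}, {"1": []})
        prof_int, prof_real = segment_cell_profile(
            np.array([3.9, 4.1, 4.0]), _chrom(3), bset
        )
        np.testing.assert_array_equal(prof_int, [4, 4, 4])
        np.testing.assert_allclose(prof_real, 4.0)

    def test_single_bin_segment_keeps_value(self):
        bset = self._bset({"1": 2}, {"1": [1]})
        prof_int, prof_real = segment_cell_profile(
            np.array([1.2, 3.6]), _chrom(2), bset
        )
        np.testing.assert_allclose(prof_real, [1.2, 3.6])
        np.testing.assert_array_equal(prof_int, [1, 4])

    def test_half_values_round_away_from_zero(self):
        bset = self._bset({"1": 2}, {"1": []})
        prof_int, _ = segment_cell_profile(np.array([1.4, 1.6]), _chrom(2), bset)
        np.testing.assert_array_equal(prof_int, [2, 2])  # median 1.5 -> 2

    def test_clipping_to_max_cn(self):
        bset = self._bset({"1": 2}, {"1": []})
        prof_int, _ = segment_cell_profile(
            np.array([9.0, 9.5]), _chrom(2), bset, max_cn=6
        )
        np.testing.assert_array_equal(prof_int, [6, 6])

    def test_idempotent_on_piecewise_constant_profile(self):
        track = np.array([2.0] * 10 + [4.0] * 10)
        bset = self._bset({"1": 20}, {"1": [10]})
        prof_int, prof_real = segment_cell_profile(track, _chrom(20), bset)
        np.testing.assert_allclose(prof_real, track)
        prof_int2, prof_real2 = segment_cell_profile(prof_real, _chrom(20), bset)
        np.testing.assert_allclose(prof_real2, prof_real)
        np.testing.assert_array_equal(prof_int2, prof_int)


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.5, 1.0), (1.5, 2.0), (2.5, 3.0), (2.4, 2.0), (2.6, 3.0), (0.0, 0.0)],
    )
    def test_round_half_away_from_zero(self, value, expected):
        assert round_half_away(np.array([value]))[0] == expected


class TestCloneProfile:
    def test_mean_of_member_segment_copies(self):
        members = np.array([[4.0], [4.0], [3.0]])
        assert clone_profile(members)[0] == pytest.approx(11 / 3)

    def test_single_member_clone_is_identity(self):
        member = np.array([[2.0, 4.0, 1.0]])
        np.testing.assert_allclose(clone_profile(member), member[0])

    def test_empty_clone_is_fatal(self):
        with pytest.raises(ValueError, match="non-empty"):
            clone_profile(np.empty((0, 5)))


class TestAssignClones:
    def test_non_diploid_clusters_become_clones(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        clones = assign_clones(labels, diploid_cluster=1)
        assert set(clones) == {0, 2}
        np.testing.assert_array_equal(clones[0], [0, 1])
        np.testing.assert_array_equal(clones[2], [4, 5])

    def test_all_diploid_gives_empty_clone_set(self):
        clones = assign_clones(np.zeros(5, dtype=int), diploid_cluster=0)
        assert clones == {}

    def test_fixture_clone_members_are_mostly_true_aneuploid(
        self, medium_pipeline, medium_fixture
    ):
        labels = medium_fixture[5]
        for members in medium_pipeline.clones_.values():
            assert labels[members].mean() >= 0.9


def test_end_to_end_clone_profile_matches_truth(medium_pipeline, medium_fixture):
    """Clone-level Pearson vs ground truth on the mid-scale fixture."""
    from cnvae.evaluation import score

    labels, truth_bins = medium_fixture[5], medium_fixture[6]
    truth_clone = truth_bins[labels].mean(axis=0)
    est_clone = medium_pipeline.cell_profiles_[~medium_pipeline.diploid_mask_].mean(axis=0)
    report = score(est_clone, truth_clone)
    assert report.pearson >= 0.9


def test_clone_mean_over_gain_event_within_category_envelope(
    medium_pipeline, medium_fixture
):
    """Over a shared gain event the clone mean stays inside [3, 6]."""
    adata, truth, events, cfg, binned, labels, truth_bins = medium_fixture
    est_clone = medium_pipeline.cell_profiles_[~medium_pipeline.diploid_mask_].mean(axis=0)
    gain_bins = (truth_bins[labels] >= 3).all(axis=0)
    if gain_bins.any():
        assert est_clone[gain_bins].min() >= 2.5
        assert est_clone[gain_bins].max() <= 6.0
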