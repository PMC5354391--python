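import math

import numpy as np
import pytest

from lockscape.dlocks import (
    COMPARISONS,
    DLock,
    LockBase,
    find_lock_bases,
    rank_dlocks,
    run_comparisons,
    segment_dlocks,
    slr_window_scores,
    summarize_dlocks,
)
from lockscape.genomic_io import FeatureTrack, Genome, Interval
from lockscape.windowing import WindowGrid

from conftest import make_grid, make_track


def tracks_from(S, grid=None, prefix="s"):
    S = np.asarray(S, dtype=float)
    grid = grid or make_grid(S.shape[1])
    return [make_track(S[i], f"{prefix}{i}", grid) for i in range(S.shape[0])]


class TestLockBases:
    def test_single_sample_zero_window_splits_runs(self):
        # candidate runs require >= 1 positive sample per window, so a
        # single sample's zero breaks the stretch into two kept bases
        (t,) = tracks_from([[1, 1, 0, 1]])
        bases = find_lock_bases([t])
        assert bases == [LockBase("chr1", 0, 2), LockBase("chr1", 3, 4)]

    def test_majority_rule_filters_sparse_rows_in_shared_runs(self):
        # two samples: the union keeps the run contiguous, the 50% rule
        # then judges each row over the whole run
        a = [1, 1, 0, 1]
        b = [1, 0, 1, 1]
        assert find_lock_bases(tracks_from([a, b])) == [LockBase("chr1", 0, 4)]

    def test_candidate_rejected_when_one_row_sparse(self):
        a = [1, 1, 1, 1]
        b = [1, 0, 0, 0]  # only 1/4 positive
        assert find_lock_bases(tracks_from([a, b])) == []

    def test_all_zero_chromosome_no_bases(self):
        assert find_lock_bases(tracks_from([[0, 0, 0]])) == []

    def test_runs_split_by_all_zero_windows(self):
        (t,) = tracks_from([[1, 0, 1, 1]])
        assert find_lock_bases([t]) == [LockBase("chr1", 0, 1), LockBase("chr1", 2, 4)]

    def test_masked_windows_break_runs(self):
        (t,) = tracks_from([[1, 1, 1]])
        t.mask[1] = True
        assert find_lock_bases([t]) == [LockBase("chr1", 0, 1), LockBase("chr1", 2, 3)]


class TestSLR:
    def test_equal_scores_give_zero(self):
        c1 = tracks_from([[2.0, 2.0]])
        c2 = tracks_from([[2.0, 2.0]], grid=c1[0].grid)
        st = slr_window_scores(c1, c2, [LockBase("chr1", 0, 2)])
        assert st.slr.tolist() == [0.0, 0.0]

    def test_single_pair_closed_form(self):
        c1 = tracks_from([[1.0]])
        c2 = tracks_from([[math.e]], grid=c1[0].grid)
        st = slr_window_scores(c1, c2, [LockBase("chr1", 0, 1)])
        assert st.slr[0] == pytest.approx(1.0)  # -log(1/e)

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(1)
        grid = make_grid(60)
        c1 = tracks_from(rng.uniform(0, 3, (3, 60)), grid, "a")
        c2 = tracks_from(rng.uniform(0, 3, (4, 60)), grid, "b")
        bases = [LockBase("chr1", 0, 60)]
        f = slr_window_scores(c1, c2, bases)
        r = slr_window_scores(c2, c1, bases)
        np.testing.assert_array_equal(f.slr, -r.slr)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(2)
        grid = make_grid(100)
        S1 = rng.uniform(0, 3, (5, 100))
        S2 = rng.uniform(0, 3, (5, 100))
        eps = 1e-6
        st = slr_window_scores(
            tracks_from(S1, grid, "a"), tracks_from(S2, grid, "b"),
            [LockBase("chr1", 0, 100)], epsilon=eps,
        )
        for w in range(100):
            acc = 0.0
            for i in range(5):
                for j in range(5):
                    acc += -math.log(max(S1[i, w], eps) / max(S2[j, w], eps))
            assert st.slr[w] == pytest.approx(acc / 25, abs=1e-12)

    def test_undefined_outside_bases(self):
        c1 = tracks_from([[1.0, 1, 1]])
        c2 = tracks_from([[1.0, 1, 1]], grid=c1[0].grid)
        st = slr_window_scores(c1, c2, [LockBase("chr1", 0, 1)])
        assert np.isnan(st.slr[1]) and np.isnan(st.slr[2])

    def test_same_sex_pairs_only_on_xy(self):
        genome = Genome((("chr1", 20_000), ("chrX", 10_000)))
        grid = WindowGrid(genome, 10_000)
        # chrX scores differ by sex: male pair ratio e, female pair ratio e^3
        c1 = tracks_from([[1, 1, 1.0], [1, 1, 1.0]], grid, "a")
        c2 = tracks_from([[1, 1, math.e], [1, 1, math.e**3]], grid, "b")
        bases = [LockBase("chr1", 0, 2), LockBase("chrX", 2, 3)]
        st = slr_window_scores(
            c1, c2, bases, c1_sexes=["M", "F"], c2_sexes=["M", "F"]
        )
        assert st.slr[2] == pytest.approx((1 + 3) / 2)  # male + female pairs only
        assert st.n_pairs[2] == 2
        # autosome uses all four pairs
        assert st.n_pairs[0] == 4

    def test_no_same_sex_pair_warns_and_nans(self):
        genome = Genome((("chrX", 10_000),))
        grid = WindowGrid(genome, 10_000)
        c1 = tracks_from([[1.0]], grid, "a")
        c2 = tracks_from([[1.0]], grid, "b")
        with pytest.warns(UserWarning, match="same-sex"):
            st = slr_window_scores(
                c1, c2, [LockBase("chrX", 0, 1)], c1_sexes=["M"], c2_sexes=["F"]
            )
        assert np.isnan(st.slr[0])


def score_track_from(slr_values, bases=None):
    grid = make_grid(len(slr_values))
    from lockscape.dlocks import DLockScoreTrack

    slr = np.asarray(slr_values, dtype=float)
    bases = bases or [LockBase("chr1", 0, len(slr))]
    full = np.full(grid.n_total, np.nan)
    for b in bases:
        full[b.start_win : b.end_win] = slr[b.start_win : b.end_win]
    return DLockScoreTrack(("c1", "c2"), grid, bases, full, np.ones(grid.n_total, int))


class TestSegmentation:
    def test_sign_runs_split(self):
        dl = segment_dlocks(score_track_from([1.0, 2, -1, -3]))
        assert [(d.n_windows, d.total_score) for d in dl] == [(2, 3.0), (2, -4.0)]
        assert dl[0].sign == 1 and dl[1].sign == -1

    def test_all_positive_single_block(self):
        dl = segment_dlocks(score_track_from([0.5, 0.5, 0.5]))
        assert len(dl) == 1 and dl[0].interval == Interval("chr1", 0, 30_000)

    def test_zero_terminates_runs(self):
        dl = segment_dlocks(score_track_from([1.0, 0.0, 1.0]))
        assert [(d.start_win, d.end_win) for d in dl] == [(0, 1), (2, 3)]

    def test_blocks_confined_to_bases(self):
        bases = [LockBase("chr1", 0, 2), LockBase("chr1", 3, 5)]
        dl = segment_dlocks(score_track_from([1.0, 1, 1, 1, 1], bases))
        assert [(d.start_win, d.end_win) for d in dl] == [(0, 2), (3, 5)]


def mk_dlocks(scores, chrom="chr1"):
    out = []
    for k, s in enumerate(scores):
        out.append(
            DLock(Interval(chrom, k * 10_000, (k + 1) * 10_000), k, k + 1, float(s), 1, ("c1", "c2"))
        )
    return out


class TestRanking:
    def test_type7_quantile_of_1_to_10(self):
        dl = rank_dlocks(mk_dlocks(range(1, 11)), (0.90,))
        # Q(0.9) of {1..10} = 9.1 under linear interpolation: only 10 passes
        flagged = [d.total_score for d in dl if d.flags[0.90]]
        assert flagged == [10.0]
        assert float(np.quantile(np.arange(1, 11), 0.9)) == pytest.approx(9.1)

    def test_p0_everything_above_min_passes(self):
        dl = rank_dlocks(mk_dlocks(range(1, 6)), (0.0,))
        assert [d.total_score for d in dl if d.flags[0.0]] == [2.0, 3, 4, 5]

    def test_order_invariance(self):
        scores = [3.0, -1, 7, 2, -5, 9, 4]
        a = rank_dlocks(mk_dlocks(scores), (0.90,))
        b = rank_dlocks(mk_dlocks(scores[::-1]), (0.90,))
        fa = {d.total_score: d.flags[0.90] for d in a}
        fb = {d.total_score: d.flags[0.90] for d in b}
        assert fa == fb

    def test_negative_blocks_use_lower_tail(self):
        dl = rank_dlocks(mk_dlocks([-10.0, -1, 1, 2, 3, 4, 5, 6, 7, 8]), (0.90,))
        neg = [d for d in dl if d.sign < 0]
        assert [d.total_score for d in neg if d.flags[0.90]] == [-10.0]

    def test_chry_inherits_autosomal_thresholds(self):
        auto = mk_dlocks(range(1, 11))
        y = mk_dlocks([100.0], chrom="chrY")
        dl = rank_dlocks(auto + y, (0.90,))
        ydl = [d for d in dl if d.chrom == "chrY"][0]
        assert ydl.flags[0.90]  # 100 > 9.1 even though chrY is excluded from Q

    def test_flag_rate_bounded_on_random_scores(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            dl = rank_dlocks(mk_dlocks(rng.normal(size=n)), (0.90,))
            rate = sum(1 for d in dl if d.sign > 0 and d.flags[0.90]) / n
            assert rate <= 0.10 + 1.0 / n

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rank_dlocks([], (0.9,))


class TestSummary:
    def test_toy_arithmetic(self):
        genome = Genome((("chr1", 10_000_000),))
        d = DLock(Interval("chr1", 0, 500_000), 0, 50, 5.0, 50, ("a", "b"))
        genes = FeatureTrack("genes", [], names=[])
        s = summarize_dlocks([d], genes, genome)
        assert s.pct_genome == pytest.approx(5.0)
        assert s.avg_size_bp == pytest.approx(500_000)
        assert s.n_dlocks == 1

    def test_uniform_genes_density_ratio_near_one(self):
        rng = np.random.default_rng(6)
        genome = Genome((("chr1", 10_000_000),))
        starts = rng.integers(0, 9_990_000, size=4000)
        genes = FeatureTrack(
            "genes",
            [Interval("chr1", int(s), int(s) + 1_000) for s in starts],
            names=[f"g{i}" for i in range(4000)],
        )
        dl = [DLock(Interval("chr1", 2_000_000, 4_000_000), 0, 200, 1.0, 200, ("a", "b"))]
        s = summarize_dlocks(dl, genes, genome)
        assert s.gene_density_ratio == pytest.approx(1.0, rel=0.1)

    def test_no_blocks_all_zero(self):
        genome = Genome((("chr1", 1_000_000),))
        s = summarize_dlocks([], FeatureTrack("g", [], names=[]), genome)
        assert (s.pct_genome, s.n_dlocks, s.n_genes) == (0.0, 0, 0)


class TestRunComparisons:
    def _groups(self, grid, rng, names):
        return {
            name: tracks_from(rng.uniform(0, 2, (2, grid.n_total)), grid, name)
            for name in names
        }

    def test_ten_comparisons_when_all_present(self):
        rng = np.random.default_rng(8)
        grid = make_grid(200)
        groups = self._groups(
            grid, rng,
            ["granulocyte", "cd34", "aml_a", "aml_b", "k562_control", "k562_unc0638"],
        )
        res = run_comparisons(groups)
        assert len(res) == 10
        assert list(res) == [f"{a}_gt_{b}" for a, b in COMPARISONS]

    def test_reversed_pair_negates_slr(self):
        rng = np.random.default_rng(8)
        grid = make_grid(100)
        groups = self._groups(grid, rng, ["granulocyte", "cd34", "aml_a", "aml_b",
                                          "k562_control", "k562_unc0638"])
        res = run_comparisons(groups)
        f = res["cd34_gt_granulocyte"].score_track.slr
        r = res["granulocyte_gt_cd34"].score_track.slr
        both = ~np.isnan(f) & ~np.isnan(r)
        assert both.any()
        np.testing.assert_array_equal(f[both], -r[both])

    def test_missing_category_skipped_with_warning(self):
        rng = np.random.default_rng(8)
        grid = make_grid(100)
        groups = self._groups(grid, rng, ["granulocyte", "cd34"])
        with pytest.warns(UserWarning, match="skipping"):
            res = run_comparisons(groups)
        assert list(res) == ["cd34_gt_granulocyte", "granulocyte_gt_cd34"]
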