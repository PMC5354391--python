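import numpy as np
import pytest

from lockscape.correlation_clustering import (
    boundary_metaprofile,
    feature_density_track,
    hcluster_samples,
    linkage_to_newick,
    pearson_pairwise,
)
from lockscape.genomic_io import DomainSet, FeatureTrack, Genome, Interval
from lockscape.windowing import WindowGrid

from conftest import make_grid, make_track


class TestFeatureDensity:
    def test_interval_coverage_per_window(self):
        genome = Genome((("chr1", 40_000),))
        grid = WindowGrid(genome, 10_000)
        ft = FeatureTrack("genes", [Interval("chr1", 5_000, 15_000)])
        t = feature_density_track(ft, grid)
        assert t.scores.tolist() == [5_000, 5_000, 0, 0]

    def test_point_counts(self):
        genome = Genome((("chr1", 20_000),))
        grid = WindowGrid(genome, 10_000)
        ft = FeatureTrack(
            "snv",
            [Interval("chr1", 100, 101), Interval("chr1", 200, 201), Interval("chr1", 300, 301)],
            kind="point",
        )
        t = feature_density_track(ft, grid)
        assert t.scores.tolist() == [3, 0]

    def test_genome_wide_feature_constant(self):
        genome = Genome((("chr1", 30_000),))
        grid = WindowGrid(genome, 10_000)
        ft = FeatureTrack("all", [Interval("chr1", 0, 30_000)])
        t = feature_density_track(ft, grid)
        assert t.scores.tolist() == [10_000] * 3

    def test_overlapping_intervals_count_once(self):
        genome = Genome((("chr1", 10_000),))
        grid = WindowGrid(genome, 10_000)
        ft = FeatureTrack("f", [Interval("chr1", 0, 6_000), Interval("chr1", 4_000, 8_000)])
        assert feature_density_track(ft, grid).scores.tolist() == [8_000]


class TestPearson:
    def test_self_correlation_is_one(self):
        t = make_track([1.0, 2, 3, 4], normalized=False)
        cm = pearson_pairwise([t, t], autosomes_only=False)
        assert cm.r[0, 1] == pytest.approx(1.0)

    def test_affine_invariance(self):
        x = make_track([1.0, 2, 3, 4], normalized=False)
        y = make_track(2 * np.array([1.0, 2, 3, 4]) + 1, normalized=False)
        assert pearson_pairwise([x, y], autosomes_only=False).r[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = make_track([1.0, 2, 3])
        y = make_track([3.0, 2, 1])
        assert pearson_pairwise([x, y], autosomes_only=False).r[0, 1] == pytest.approx(-1.0)

    def test_matches_two_pass_formula(self):
        rng = np.random.default_rng(5)
        tracks = [make_track(rng.uniform(0, 4, 200)) for _ in range(4)]
        cm = pearson_pairwise(tracks, autosomes_only=False)
        for i in range(4):
            for j in range(4):
                x, y = tracks[i].scores, tracks[j].scores
                xm, ym = x - x.mean(), y - y.mean()
                r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
                assert cm.r[i, j] == pytest.approx(r, abs=1e-12)
        assert np.array_equal(cm.r, cm.r.T)
        assert np.diag(cm.r).tolist() == [1.0] * 4

    def test_joint_masking_restricts_windows(self):
        a = make_track([1.0, 2, 3, 4, 5])
        b = make_track([1.0, 2, 3, 4, 0])
        b.mask[4] = True
        cm = pearson_pairwise([a, b], autosomes_only=False)
        assert cm.n_windows[0, 1] == 4
        assert cm.r[0, 1] == pytest.approx(1.0)

    def test_zero_variance_reported_missing(self):
        a = make_track([1.0, 1, 1, 1])
        b = make_track([1.0, 2, 3, 4])
        assert np.isnan(pearson_pairwise([a, b], autosomes_only=False).r[0, 1])

    def test_too_few_joint_windows_errors(self):
        a = make_track([1.0, 2, 3])
        b = make_track([1.0, 2, 3])
        b.mask[:2] = True
        with pytest.raises(ValueError, match="fewer than 3"):
            pearson_pairwise([a, b], autosomes_only=False)


class TestHCluster:
    def test_identical_pair_merges_first_at_zero(self):
        grid = make_grid(6)
        x = [1.0, 2, 3, 1, 2, 3]
        a = make_track(x, "a", grid)
        b = make_track(x, "b", grid)
        c = make_track([3.0, 2, 1, 3, 2, 1], "c", grid)
        Z, order = hcluster_samples([c, a, b], autosomes_only=False)
        # first merge joins leaves 0,1 (a, b after lexical sort) at height 0
        assert sorted(Z[0, :2].astype(int).tolist()) == [0, 1]
        assert Z[0, 2] == pytest.approx(0.0)
        assert Z[1, 2] == pytest.approx(2.0)  # complete linkage: 1 - (-1)

    def test_permutation_invariance_of_heights(self):
        rng = np.random.default_rng(3)
        grid = make_grid(50)
        tracks = [make_track(rng.uniform(0, 2, 50), f"s{i}", grid) for i in range(5)]
        Z1, o1 = hcluster_samples(tracks, autosomes_only=False)
        Z2, o2 = hcluster_samples(tracks[::-1], autosomes_only=False)
        np.testing.assert_allclose(Z1[:, 2], Z2[:, 2], atol=1e-12)
        assert o1 == o2

    def test_all_identical_flat_cluster(self):
        grid = make_grid(4)
        tracks = [make_track([1.0, 2, 3, 4], f"s{i}", grid) for i in range(3)]
        Z, _ = hcluster_samples(tracks, autosomes_only=False)
        assert np.allclose(Z[:, 2], 0.0)

    def test_newick_has_all_leaves(self):
        grid = make_grid(10)
        rng = np.random.default_rng(1)
        tracks = [make_track(rng.uniform(0, 2, 10), f"s{i}", grid) for i in range(4)]
        Z, _ = hcluster_samples(tracks, autosomes_only=False)
        nwk = linkage_to_newick(Z, [t.sample_id for t in sorted(tracks, key=lambda t: t.sample_id)])
        assert nwk.endswith(";") and all(f"s{i}" in nwk for i in range(4))


class TestBoundaryProfile:
    def test_self_profile_is_step_function(self):
        """Using the domains themselves as the feature gives ~0 outside, ~1 inside."""
        genome = Genome((("chr1", 1_000_000),))
        ivs = [Interval("chr1", s, s + 100_000) for s in range(100_000, 900_000, 200_000)]
        domains = DomainSet("d", [(iv, 1.0) for iv in ivs])
        feature = FeatureTrack("self", list(ivs))
        prof = boundary_metaprofile(domains, feature, flank=40_000, bin=10_000, genome=genome)
        outside = prof.density[prof.offsets < 0]
        inside = prof.density[prof.offsets > 0]
        np.testing.assert_allclose(outside, 0.0, atol=1e-9)
        np.testing.assert_allclose(inside, 1.0, atol=1e-9)
        assert prof.n_boundaries == 2 * len(ivs)

    def test_uniform_feature_flat_profile(self):
        genome = Genome((("chr1", 500_000),))
        domains = DomainSet("d", [(Interval("chr1", 200_000, 300_000), 1.0)])
        feature = FeatureTrack("u", [Interval("chr1", 0, 500_000)])
        prof = boundary_metaprofile(domains, feature, flank=50_000, bin=10_000, genome=genome)
        np.testing.assert_allclose(prof.density, 1.0, atol=1e-9)

    def test_feature_inside_domain_only_inside_bins(self):
        genome = Genome((("chr1", 500_000),))
        domains = DomainSet("d", [(Interval("chr1", 200_000, 300_000), 1.0)])
        feature = FeatureTrack("f", [Interval("chr1", 210_000, 290_000)])
        prof = boundary_metaprofile(domains, feature, flank=30_000, bin=10_000, genome=genome)
        assert (prof.density[prof.offsets < 0] == 0).all()
        assert prof.density[prof.offsets > 0].sum() > 0

    def test_no_boundaries_errors(self):
        feature = FeatureTrack("f", [])
        with pytest.raises(ValueError, match="boundaries"):
            boundary_metaprofile(DomainSet("d", []), feature, 10_000, 10_000)
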