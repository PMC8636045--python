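import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cisclust.correlation import pair_distances, pearson_matrix
from cisclust.io_formats import GeneAnnotation
from cisclust.spectral import null_correlation_matrices
from cisclust.stats import (
    benjamini_hochberg,
    compare_phenotypes,
    ks_distance,
    ks_permutation_test,
    nnd,
    piecewise_ks_vs_null,
    shannon_entropy,
)
from cisclust.synthetic import SyntheticSpec, simulate


def brute_force_ks(a, b):
    """Independent oracle: evaluate both step CDFs at every pooled point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


def _genes_at_ranks(ranks):
    return [GeneAnnotation(f"g{r}", "chr1", 1000 * (r + 1), r) for r in ranks]


class TestNND:
    def test_single_cluster_example(self):
        genes = _genes_at_ranks([2, 5, 9])
        d = nnd([0, 0, 0], genes, metric="rank")
        assert sorted(d.per_gene_nnd.tolist()) == [3, 3, 4]

    def test_consecutive_ranks_all_one(self):
        genes = _genes_at_ranks(range(6))
        d = nnd([0] * 6, genes, metric="rank")
        assert (d.per_gene_nnd == 1).all()

    def test_alternating_clusters_all_two(self):
        genes = _genes_at_ranks(range(8))
        labels = [0, 1, 0, 1, 0, 1, 0, 1]
        d = nnd(labels, genes, metric="rank")
        assert (d.per_gene_nnd == 2).all()

    def test_bp_metric(self):
        genes = [
            GeneAnnotation("a", "chr1", 100, 0),
            GeneAnnotation("b", "chr1", 500, 1),
            GeneAnnotation("c", "chr1", 5000, 2),
        ]
        d = nnd([0, 0, 0], genes, metric="bp")
        assert sorted(d.per_gene_nnd.tolist()) == [400, 400, 4500]

    def test_singletons_excluded_and_counted(self):
        genes = _genes_at_ranks(range(5))
        d = nnd([0, 0, 1, 2, 2], genes, metric="rank")
        assert len(d.per_gene_nnd) == 4
        assert d.n_singletons == 1

    def test_all_singletons_rejected(self):
        genes = _genes_at_ranks(range(3))
        with pytest.raises(ValueError, match="NND undefined"):
            nnd([0, 1, 2], genes)


class TestEntropy:
    def test_degenerate_distribution_zero(self):
        assert shannon_entropy(np.array([2.0, 2.0, 2.0])) == 0.0

    def test_uniform_is_log_support(self):
        h = shannon_entropy(np.array([1.0, 2.0, 3.0, 4.0]))
        assert h == pytest.approx(np.log(4))

    def test_half_quarter_quarter_in_bits(self):
        h = shannon_entropy(np.array([1.0, 1.0, 2.0, 3.0]), base="2")
        assert h == pytest.approx(1.5)

    def test_permutation_invariant_and_maximal_iff_uniform(self):
        rng = np.random.default_rng(0)
        vals = np.array([1.0, 1.0, 2.0, 5.0, 5.0, 5.0])
        assert shannon_entropy(vals) == pytest.approx(
            shannon_entropy(rng.permutation(vals))
        )
        assert shannon_entropy(vals) < np.log(3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.array([]))


class TestKS:
    def test_identical_samples_zero(self):
        assert ks_distance([1, 2, 3], [1, 2, 3]).statistic == 0.0

    def test_disjoint_supports_one(self):
        assert ks_distance([1, 2], [3, 4]).statistic == 1.0

    def test_shifted_thirds(self):
        assert ks_distance([1, 2, 3], [2, 3, 4]).statistic == pytest.approx(1 / 3)

    def test_symmetry(self):
        a, b = [1.0, 5.0, 2.2], [0.4, 2.2, 9.0, 3.0]
        assert ks_distance(a, b).statistic == ks_distance(b, a).statistic

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_distance([], [1.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(-5, 5), min_size=1, max_size=20),
        b=st.lists(st.integers(-5, 5), min_size=1, max_size=20),
    )
    def test_matches_brute_force_with_ties(self, a, b):
        assert ks_distance(a, b).statistic == pytest.approx(brute_force_ks(a, b))

    def test_matches_scipy(self):
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.standard_normal(rng.integers(2, 40))
            b = rng.standard_normal(rng.integers(2, 40)) + rng.normal()
            assert ks_distance(a, b).statistic == pytest.approx(
                ks_2samp(a, b).statistic
            )

    def test_permutation_pvalue_add_one_bounds(self):
        rng = np.random.default_rng(6)
        res = ks_permutation_test(
            rng.standard_normal(30), rng.standard_normal(30) + 2.0,
            n_resamples=99, seed=1,
        )
        assert res.p_value == pytest.approx(1 / 100)  # nothing beats a 2-sigma shift
        res2 = ks_permutation_test(
            rng.standard_normal(30), rng.standard_normal(30), n_resamples=99, seed=2
        )
        assert res2.p_value > 0.05


def test_benjamini_hochberg_known_case():
    p = np.array([0.01, 0.04, 0.03, 0.5])
    q = benjamini_hochberg(p)
    # frozen from statsmodels multipletests(method="fdr_bh") on the same vector
    np.testing.assert_allclose(q, [0.04, 0.05333333333333334, 0.05333333333333334, 0.5])
    with_nan = benjamini_hochberg(np.array([0.01, np.nan]))
    assert np.isnan(with_nan[1])


class TestPiecewiseKS:
    def test_decay_data_ks_decreases_with_distance(self):
        from scipy.stats import spearmanr

        spec = SyntheticSpec(
            n_genes=80, n_samples=300, mode="decay", loading=0.9,
            decay_scale_bp=10_000_000, seed=31,
        )
        m, _ = simulate(spec)
        corr = pearson_matrix(m)
        nulls = null_correlation_matrices(m, 5, seed=32)
        pw = piecewise_ks_vs_null(
            corr, nulls, pair_distances(m.genes, "bp"), n_windows=10, n_resamples=0
        )
        rho = spearmanr(np.arange(10), pw.statistics).statistic
        assert rho < 0

    def test_pvalues_present_and_window_bounds_ordered(self, small_matrix):
        corr = pearson_matrix(small_matrix)
        nulls = null_correlation_matrices(small_matrix, 3, seed=1)
        pw = piecewise_ks_vs_null(
            corr, nulls, pair_distances(small_matrix.genes, "bp"),
            n_windows=2, n_resamples=200, seed=3,
        )
        assert len(pw.windows) == 2
        assert all(0 <= w.statistic <= 1 for w in pw.windows)
        assert all(0 < w.p_value <= 1 for w in pw.windows)
        assert pw.mean_p_value == pytest.approx(np.mean([w.p_value for w in pw.windows]))
        assert (pw.d_low <= pw.d_high).all()

    def test_empty_null_rejected(self, small_matrix):
        corr = pearson_matrix(small_matrix)
        with pytest.raises(ValueError):
            piecewise_ks_vs_null(
                corr, [], pair_distances(small_matrix.genes, "bp"), 2
            )


def test_compare_phenotypes_identical_and_symmetry():
    genes = _genes_at_ranks(range(10))
    a = nnd([0] * 5 + [1] * 5, genes, metric="rank")
    ks, delta = compare_phenotypes(a, a)
    assert ks.statistic == 0.0
    assert delta == 0.0
    b = nnd([0, 1] * 5, genes, metric="rank")
    ks_ab, _ = compare_phenotypes(a, b)
    ks_ba, _ = compare_phenotypes(b, a)
    assert ks_ab.statistic == ks_ba.statistic
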