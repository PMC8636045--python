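import numpy as np
import pytest

from cisclust.correlation import pearson_matrix
from cisclust.synthetic import SyntheticSpec, expected_correlation, simulate


def _block_pairs(truth):
    n = len(truth)
    iu, ju = np.triu_indices(n, k=1)
    same = truth[iu] == truth[ju]
    return iu, ju, same


def test_determinism_same_seed_identical():
    spec = SyntheticSpec(n_genes=40, n_samples=50, mode="blocks", seed=9)
    m1, t1 = simulate(spec)
    m2, t2 = simulate(spec)
    np.testing.assert_array_equal(m1.values, m2.values)
    np.testing.assert_array_equal(t1, t2)
    assert [g.start_bp for g in m1.genes] == [g.start_bp for g in m2.genes]


def test_positions_stable_across_sample_sizes():
    a, _ = simulate(SyntheticSpec(n_genes=30, n_samples=10, mode="null", seed=4))
    b, _ = simulate(SyntheticSpec(n_genes=30, n_samples=500, mode="null", seed=4))
    assert [g.start_bp for g in a.genes] == [g.start_bp for g in b.genes]


def test_full_loading_gives_perfect_within_block_correlation():
    spec = SyntheticSpec(
        n_genes=20, n_samples=30, mode="blocks", n_blocks=4, loading=1.0, seed=2
    )
    m, truth = simulate(spec)
    c = pearson_matrix(m).values
    iu, ju, same = _block_pairs(truth)
    np.testing.assert_allclose(c[iu[same], ju[same]], 1.0, atol=1e-10)


def test_zero_loading_mean_absolute_correlation_vanishes():
    spec = SyntheticSpec(
        n_genes=30, n_samples=1000, mode="blocks", n_blocks=3, loading=0.0, seed=5
    )
    m, _ = simulate(spec)
    c = pearson_matrix(m).values
    iu, ju = np.triu_indices(30, k=1)
    assert np.abs(c[iu, ju]).mean() < 3.0 / np.sqrt(1000)


def test_within_block_correlation_matches_loading():
    spec = SyntheticSpec(
        n_genes=60, n_samples=500, mode="blocks", n_blocks=5, loading=0.6, seed=8
    )
    m, truth = simulate(spec)
    c = pearson_matrix(m).values
    iu, ju, same = _block_pairs(truth)
    assert abs(c[iu[same], ju[same]].mean() - 0.6) < 0.05


@pytest.mark.parametrize("n_samples,tol", [(100, 0.35), (900, 0.12)])
def test_entrywise_convergence_rate(n_samples, tol):
    """Empirical correlations approach the population ones at O(1/sqrt(N_s))."""
    spec = SyntheticSpec(
        n_genes=30, n_samples=n_samples, mode="blocks", n_blocks=3,
        loading=0.5, seed=13,
    )
    m, _ = simulate(spec)
    c = pearson_matrix(m).values
    expected = np.array(
        [
            [expected_correlation(spec, i, j) for j in range(30)]
            for i in range(30)
        ]
    )
    err = np.abs(c - expected)
    iu, ju = np.triu_indices(30, k=1)
    assert err[iu, ju].max() < tol  # ~ 3.5 / sqrt(n_samples)


def test_expected_correlation_block_cases():
    spec = SyntheticSpec(n_genes=10, n_samples=5, mode="blocks", n_blocks=2, loading=0.7)
    _, truth = simulate(spec)
    i = 0
    j_other = int(np.flatnonzero(truth != truth[0])[0])
    j_same = int(np.flatnonzero(truth == truth[0])[1])
    assert expected_correlation(spec, i, j_other) == 0.0
    assert expected_correlation(spec, i, j_same) == pytest.approx(0.7)


def test_expected_correlation_decay_at_zero_lag_is_loading():
    spec = SyntheticSpec(n_genes=10, n_samples=5, mode="decay", loading=0.8, seed=1)
    # correlation at lag d is loading * exp(-d/xi): continuous in d, -> loading
    m, _ = simulate(spec)
    d01 = m.genes[1].start_bp - m.genes[0].start_bp
    want = 0.8 * np.exp(-d01 / spec.decay_scale)
    assert expected_correlation(spec, 0, 1) == pytest.approx(want)
    assert expected_correlation(spec, 3, 3) == 1.0


def test_expected_correlation_control_sign_algebra():
    spec = SyntheticSpec(
        n_genes=200, n_samples=5, mode="control", n_blocks=2,
        loading=0.7, neg_fraction=0.5, seed=3,
    )
    _, truth = simulate(spec)
    pos = np.flatnonzero(truth > 0)
    neg = np.flatnonzero(truth < 0)
    # find a (+,-) pair sharing a factor
    fac_pos = truth[pos]
    i = int(pos[np.flatnonzero(fac_pos == 1)[0]])
    j = int(neg[np.flatnonzero(truth[neg] == -1)[0]])
    assert expected_correlation(spec, i, j) == pytest.approx(-0.7)


def test_null_mode_has_no_truth_and_rejects_expected_correlation():
    spec = SyntheticSpec(n_genes=10, n_samples=5, mode="null", seed=0)
    _, truth = simulate(spec)
    assert truth is None
    with pytest.raises(ValueError):
        expected_correlation(spec, 0, 1)


def test_decay_profile_median_non_increasing():
    from cisclust.correlation import distance_profile, pair_distances

    spec = SyntheticSpec(
        n_genes=100, n_samples=400, mode="decay", loading=0.9,
        decay_scale_bp=10_000_000, seed=21,
    )
    m, _ = simulate(spec)
    c = pearson_matrix(m)
    prof = distance_profile(c, pair_distances(m.genes, "bp"), n_windows=8)
    med = prof.sign_frame("positive")["median"].to_numpy()
    # allow tiny sampling wiggle between adjacent windows
    assert np.all(np.diff(med) < 0.03)
    assert med[0] > med[-1] + 0.1


def test_control_profile_is_flat():
    from cisclust.correlation import distance_profile, pair_distances

    spec = SyntheticSpec(
        n_genes=100, n_samples=400, mode="control", n_blocks=5,
        loading=0.7, seed=22,
    )
    m, _ = simulate(spec)
    c = pearson_matrix(m)
    prof = distance_profile(c, pair_distances(m.genes, "bp"), n_windows=8)
    med = prof.sign_frame("positive")["median"].to_numpy()
    assert abs(med[0] - med[-1]) < 0.05


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        SyntheticSpec(n_genes=10, n_samples=5, mode="blocks", n_blocks=11)
    with pytest.raises(ValueError):
        SyntheticSpec(n_genes=10, n_samples=5, loading=1.5)
    with pytest.raises(ValueError):
        SyntheticSpec(n_genes=10, n_samples=5, mode="bogus")
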