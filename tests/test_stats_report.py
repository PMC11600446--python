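import itertools

import numpy as np
import pytest

from virtualckd.stats_report import (
    mann_whitney,
    similarity_report,
    spearman,
    wilcoxon_signed_rank,
)


# --------------------------------------------------------------------- #
# Mann-Whitney


def test_mwu_exhaustive_permutation_oracle():
    # oracle: enumerate all C(6,3)=20 assignments of the pooled sample
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    pooled = x + y
    obs = mann_whitney(x, y)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_stat(x, y)
    mean_u = len(x) * len(y) / 2.0
    count = 0
    combos = list(itertools.combinations(range(6), 3))
    for idx in combos:
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(6) if i not in idx]
        if abs(u_stat(xs, ys) - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    assert obs.p_value == pytest.approx(count / len(combos), rel=1e-12)
    assert obs.p_value == pytest.approx(0.1, rel=1e-12)


def test_mwu_identical_samples_null_center():
    x = [1.0, 2.0, 3.0, 4.0]
    r = mann_whitney(x, x)
    assert r.statistic == pytest.approx(len(x) * len(x) / 2.0)
    assert r.p_value > 0.9


def test_mwu_monotone_transform_invariance():
    rng = np.random.default_rng(0)
    x = rng.normal(size=12)
    y = rng.normal(0.5, size=15)
    p1 = mann_whitney(x, y).p_value
    p2 = mann_whitney(np.exp(x), np.exp(y)).p_value
    assert p1 == pytest.approx(p2, rel=1e-12)


def test_mwu_input_validation():
    with pytest.raises(ValueError):
        mann_whitney([1.0], [2.0, 3.0])


def test_mwu_order_invariance():
    x = [3.0, 1.0, 2.0, 5.0]
    y = [4.0, 6.0, 2.5]
    assert mann_whitney(x, y).p_value == mann_whitney(x[::-1], y[::-1]).p_value


# --------------------------------------------------------------------- #
# Wilcoxon


def test_wilcoxon_sign_flip_oracle():
    # oracle: enumerate all 2^5 sign assignments of ranks 1..5
    pre = np.zeros(5)
    post = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    obs = wilcoxon_signed_rank(pre, post)
    ranks = np.array([1, 2, 3, 4, 5])
    w_obs = 15.0  # all-positive signed-rank sum
    mean_w = ranks.sum() / 2.0
    count = 0
    for signs in itertools.product([0, 1], repeat=5):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    assert obs.p_value == pytest.approx(count / 32.0, rel=1e-12)
    assert obs.p_value == pytest.approx(0.0625, rel=1e-12)


def test_wilcoxon_degenerate_all_zero():
    pre = np.array([1.0, 2.0, 3.0])
    r = wilcoxon_signed_rank(pre, pre)
    assert r.p_value == 1.0
    assert "degenerate" in r.note


def test_wilcoxon_antisymmetry():
    rng = np.random.default_rng(1)
    pre = rng.normal(size=10)
    post = pre + rng.normal(0.3, size=10)
    a = wilcoxon_signed_rank(pre, post)
    b = wilcoxon_signed_rank(post, pre)
    assert a.p_value == pytest.approx(b.p_value, rel=1e-12)


def test_wilcoxon_drops_zero_pairs():
    pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    post = np.array([1.0, 2.5, 3.5, 4.5, 5.5, 6.5])
    r = wilcoxon_signed_rank(pre, post)
    assert r.n == (5,)
    assert "1 zero pair" in r.note


def test_wilcoxon_validation():
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([1.0, 2.0], [1.0])


# --------------------------------------------------------------------- #
# Spearman


def test_spearman_perfect_correlations():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    assert spearman(x, x).statistic == pytest.approx(1.0)
    assert spearman(x, x[::-1]).statistic == pytest.approx(-1.0)
    y = np.exp(x)  # any strictly increasing transform
    assert spearman(x, list(y)).statistic == pytest.approx(1.0)


def test_spearman_hand_computed_example():
    # d^2 sum = 4 -> rho = 1 - 6*4/(5*24) = 0.8
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    y = [1.0, 3.0, 2.0, 5.0, 4.0]
    r = spearman(x, y)
    assert r.statistic == pytest.approx(0.8, rel=1e-12)
    # oracle: exhaustive permutation count
    from scipy.stats import rankdata

    rx = rankdata(x)
    count = 0
    perms = list(itertools.permutations(rankdata(y)))
    for perm in perms:
        rho = np.corrcoef(rx, perm)[0, 1]
        if abs(rho) >= 0.8 - 1e-12:
            count += 1
    assert r.p_value == pytest.approx(count / len(perms), rel=1e-12)


def test_spearman_constant_input_rejected():
    with pytest.raises(ValueError):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_spearman_large_n_t_approx():
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    y = x + rng.normal(size=40)
    r = spearman(x, y)
    assert r.note == "t approximation"
    assert r.p_value < 0.01


# --------------------------------------------------------------------- #
# similarity report


def _dims(shift=0.0, n=30, seed=0):
    rng = np.random.default_rng(seed)
    base = {
        "map_baseline": rng.normal(107, 9, n),
        "gfr_baseline": rng.normal(48, 12, n),
        "map_3yr": rng.normal(97, 8, n),
        "gfr_3yr": rng.normal(46, 20, n),
    }
    if shift:
        base["map_baseline"] = base["map_baseline"] + shift
    return base


def test_similarity_identical_passes():
    d = _dims()
    results, passed = similarity_report(d, d)
    assert passed
    assert all(r.p_value > 0.9 for r in results.values())


def test_similarity_shifted_dimension_fails_only_there():
    cohort = _dims(seed=1)
    virtual = {k: v.copy() for k, v in _dims(seed=1).items()}
    virtual["map_baseline"] = virtual["map_baseline"] + 5 * 9.0
    results, passed = similarity_report(virtual, cohort)
    assert not passed
    assert results["map_baseline"].p_value < 0.05
    for dim in ("gfr_baseline", "map_3yr", "gfr_3yr"):
        assert results[dim].p_value > 0.05


def test_similarity_composition_matches_individual_tests():
    virtual = _dims(seed=2)
    cohort = _dims(seed=3)
    results, passed = similarity_report(virtual, cohort)
    for dim, r in results.items():
        solo = mann_whitney(virtual[dim], cohort[dim])
        assert r.p_value == solo.p_value
    assert passed == all(r.p_value > 0.05 for r in results.values())


def test_similarity_missing_dimension():
    d = _dims()
    partial = {k: d[k] for k in list(d)[:3]}
    with pytest.raises(ValueError):
        similarity_report(partial, d)
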