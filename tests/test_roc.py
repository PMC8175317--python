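"""ROC primitives: AUC, Youden cut-points, bootstrap CIs, DeLong, binormal forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tauroi import (
    auc,
    binormal_auc,
    binormal_youden_cut,
    bootstrap_cis,
    classify_tau_positive,
    delong_ci,
    delong_paired,
    sens_spec_at_cut,
    youden_cutpoint,
)


def brute_force_auc(neg, pos):
    total = 0.0
    for n in neg:
        for p in pos:
            total += (p > n) + 0.5 * (p == n)
    return total / (len(neg) * len(pos))


def brute_force_youden(neg, pos):
    """Exhaustive maximum of J over every candidate threshold."""
    pooled = np.unique(np.concatenate([neg, pos]))
    cands = np.concatenate(([-np.inf], (pooled[:-1] + pooled[1:]) / 2, [np.inf]))
    best = -np.inf
    for t in cands:
        j = np.mean(pos > t) + np.mean(neg <= t) - 1
        best = max(best, j)
    return best


# ----------------------------------------------------------------- AUC


def test_auc_hand_counted_example():
    assert auc([1, 2, 3], [2, 3, 4]) == pytest.approx(7 / 9)


def test_auc_symmetry_and_complement(rng):
    x = rng.normal(size=30)
    assert auc(x, x) == pytest.approx(0.5)
    neg, pos = rng.normal(0, 1, 25), rng.normal(1, 1, 35)
    assert auc(pos, neg) == pytest.approx(1 - auc(neg, pos))


@pytest.mark.parametrize("seed", range(5))
def test_auc_equals_all_pairs_brute_force_with_ties(seed):
    rng = np.random.default_rng(seed)
    n0, n1 = rng.integers(2, 50, size=2)
    # coarse grid forces plenty of ties
    neg = rng.integers(0, 8, size=n0) / 4.0
    pos = rng.integers(1, 9, size=n1) / 4.0
    assert auc(neg, pos) == pytest.approx(brute_force_auc(neg, pos), abs=1e-12)


@settings(deadline=None, max_examples=40)
@given(
    neg=st.lists(st.integers(-12, 12), min_size=2, max_size=20),
    pos=st.lists(st.integers(-12, 12), min_size=2, max_size=20),
)
def test_auc_invariant_under_increasing_transforms(neg, pos):
    # quarter-unit grid: exp/affine maps keep distinct values distinct
    neg = np.asarray(neg) / 4.0
    pos = np.asarray(pos) / 4.0
    base = auc(neg, pos)
    assert auc(np.exp(neg), np.exp(pos)) == pytest.approx(base, abs=1e-12)
    assert auc(3.2 * np.asarray(neg) + 1, 3.2 * np.asarray(pos) + 1) == pytest.approx(
        base, abs=1e-12
    )


# ----------------------------------------------------------------- Youden


def test_youden_perfect_separation_midpoint():
    res = youden_cutpoint([1.0, 1.1, 1.2], [1.5, 1.6])
    assert res.cutpoint == pytest.approx(1.35)
    assert res.youden_j == pytest.approx(1.0)
    assert res.sensitivity == 100.0 and res.specificity == 100.0


def test_youden_identical_groups_zero_j():
    res = youden_cutpoint([1, 2, 3], [1, 2, 3])
    assert res.youden_j == pytest.approx(0.0)


@pytest.mark.parametrize("seed", range(6))
def test_youden_matches_exhaustive_maximum(seed):
    rng = np.random.default_rng(seed)
    neg = rng.integers(0, 12, size=rng.integers(3, 40)) / 5.0
    pos = rng.integers(2, 14, size=rng.integers(3, 40)) / 5.0
    res = youden_cutpoint(neg, pos)
    assert res.youden_j == pytest.approx(brute_force_youden(neg, pos), abs=1e-12)
    # reported sens/spec consistent with the cut and with the J identity
    sens, spec = sens_spec_at_cut(neg, pos, res.cutpoint)
    assert res.youden_j == pytest.approx(sens / 100 + spec / 100 - 1, abs=1e-12)


@settings(deadline=None, max_examples=40)
@given(
    neg=st.lists(st.integers(0, 12), min_size=2, max_size=15),
    pos=st.lists(st.integers(2, 16), min_size=2, max_size=15),
    shift_q=st.integers(-8, 8),
)
def test_youden_shift_equivariance(neg, pos, shift_q):
    # quarter-unit grid keeps threshold arithmetic exact in binary floats
    neg = np.asarray(neg) / 4.0
    pos = np.asarray(pos) / 4.0
    shift = shift_q / 4.0
    base = youden_cutpoint(neg, pos)
    moved = youden_cutpoint(np.asarray(neg) + shift, np.asarray(pos) + shift)
    assert moved.youden_j == pytest.approx(base.youden_j, abs=1e-12)
    if np.isfinite(base.cutpoint):
        assert moved.cutpoint == pytest.approx(base.cutpoint + shift, abs=1e-9)


# ----------------------------------------------------------------- bootstrap


def test_bootstrap_zero_variance_gives_zero_width(rng):
    res = bootstrap_cis(np.full(20, 1.0), np.full(20, 2.0), B=200, seed=1)
    assert res.cut_ci == (1.5, 1.5)
    assert res.sens_ci == (100.0, 100.0) and res.spec_ci == (100.0, 100.0)


def test_bootstrap_seeded_determinism(rng):
    neg, pos = rng.normal(1.2, 0.2, 40), rng.normal(1.8, 0.3, 30)
    r1 = bootstrap_cis(neg, pos, B=300, seed=5)
    r2 = bootstrap_cis(neg, pos, B=300, seed=5)
    assert r1 == r2


def test_bootstrap_rejects_small_B_and_tiny_groups(rng):
    neg, pos = rng.normal(0, 1, 40), rng.normal(1, 1, 40)
    with pytest.raises(ValueError, match="at least 100"):
        bootstrap_cis(neg, pos, B=50)
    with pytest.raises(ValueError, match="at least 10"):
        bootstrap_cis(neg[:5], pos, B=200)


# ----------------------------------------------------------------- DeLong


def test_delong_self_comparison_is_null(rng):
    scores = rng.normal(size=60)
    y = (rng.random(60) > 0.5).astype(int)
    y[:2] = [0, 1]  # both classes present
    res = delong_paired(scores, scores, y)
    assert res.delta == 0.0 and res.p == 1.0 and res.z == 0.0


def test_delong_detects_real_difference(rng):
    n = 300
    y = np.repeat([0, 1], n // 2)
    informative = y + rng.normal(0, 0.7, n)
    noise = rng.normal(0, 1, n)
    res = delong_paired(informative, noise, y)
    assert res.auc_a > 0.75 and abs(res.auc_b - 0.5) < 0.15
    assert res.p < 0.01


def test_delong_ci_brackets_auc(rng):
    neg, pos = rng.normal(0, 1, 80), rng.normal(1, 1, 60)
    res = delong_ci(neg, pos)
    assert 0 <= res.ci_low <= res.auc <= res.ci_high <= 1


def test_delong_validation_errors(rng):
    with pytest.raises(ValueError, match="equal length"):
        delong_paired([1, 2], [1, 2, 3], [0, 1])
    with pytest.raises(ValueError, match="single class"):
        delong_paired([1, 2], [1, 2], [1, 1])


# ----------------------------------------------------------------- binormal


def test_binormal_closed_forms():
    assert binormal_auc(0, 1, 1, 1) == pytest.approx(stats.norm.cdf(1 / np.sqrt(2)))
    assert binormal_youden_cut(0, 1, 1, 1) == pytest.approx(0.5)
    assert binormal_auc(1.3, 0.2, 1.3, 0.4) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        binormal_auc(0, 0, 1, 1)


def test_binormal_unequal_variance_cut_is_density_crossing():
    mu0, s0, mu1, s1 = 1.2, 0.15, 1.9, 0.45
    cut = binormal_youden_cut(mu0, s0, mu1, s1)
    assert mu0 < cut < mu1
    f0 = stats.norm.pdf(cut, mu0, s0)
    f1 = stats.norm.pdf(cut, mu1, s1)
    assert f0 == pytest.approx(f1, rel=1e-9)


def test_binormal_monte_carlo_agreement(rng):
    mu0, s0, mu1, s1 = 1.2, 0.15, 1.9, 0.45
    neg = rng.normal(mu0, s0, 20000)
    pos = rng.normal(mu1, s1, 20000)
    assert auc(neg, pos) == pytest.approx(binormal_auc(mu0, s0, mu1, s1), abs=0.01)


# ----------------------------------------------------------------- positivity


def test_tau_positivity_is_strict_greater():
    assert classify_tau_positive(1.36, 1.35) == "positive"
    assert classify_tau_positive(1.35, 1.35) == "negative"
    assert classify_tau_positive(0.86, 1.35) == "negative"
    with pytest.raises(ValueError):
        classify_tau_positive(np.nan, 1.35)
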