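"""ROC analysis: AUC, Youden-index cut-points, bootstrap CIs, DeLong tests.

Conventions
-----------
* Higher score = more disease-like ("greater" direction); a subject is called
  positive when its score is strictly greater than the threshold.
* Candidate thresholds are midpoints between consecutive distinct pooled
  score values, plus -inf/+inf sentinels, so cut-points are reproducible and
  fall between the group clusters (e.g. a 1.35 cut between CU and AD SUVRs).
* At ties in the Youden index the smallest threshold wins (favours
  sensitivity, the screening-friendly choice).
* AUC uses the Mann-Whitney estimator with ties counted 1/2; AUC confidence
  intervals use the DeLong variance; cut-point/sensitivity/specificity CIs
  use a stratified percentile bootstrap.

The binormal closed forms (`binormal_auc`, `binormal_youden_cut`) are exact
oracles for testing and calibration, not estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


# --------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_neg: int
    n_pos: int


@dataclass(frozen=True)
class CutoffResult:
    cutpoint: float
    sensitivity: float  # percent
    specificity: float  # percent
    youden_j: float
    cut_ci: tuple[float, float] | None = None
    sens_ci: tuple[float, float] | None = None
    spec_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    delta: float
    variance: float
    z: float
    p: float


# --------------------------------------------------------------------------
# validation helpers


def _as_scores(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError(f"{name} group is empty")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} group contains non-finite scores")
    return x


# --------------------------------------------------------------------------
# AUC


def auc(neg_scores, pos_scores) -> float:
    """Empirical AUC: fraction of (neg, pos) pairs with pos > neg, ties 1/2."""
    neg = _as_scores(neg_scores, "negative")
    pos = _as_scores(pos_scores, "positive")
    ranks = stats.rankdata(np.concatenate([neg, pos]))
    r_pos = ranks[neg.size:].sum()
    n0, n1 = neg.size, pos.size
    return (r_pos - n1 * (n1 + 1) / 2.0) / (n0 * n1)


# --------------------------------------------------------------------------
# Youden cut-point


def _candidate_thresholds(pooled: np.ndarray) -> np.ndarray:
    v = np.unique(pooled)
    mids = (v[:-1] + v[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _sens_spec_at(neg_sorted: np.ndarray, pos_sorted: np.ndarray, t: np.ndarray):
    """Sensitivity/specificity (proportions) at thresholds t; call = score > t."""
    n0, n1 = neg_sorted.size, pos_sorted.size
    sens = 1.0 - np.searchsorted(pos_sorted, t, side="right") / n1
    spec = np.searchsorted(neg_sorted, t, side="right") / n0
    return sens, spec


def youden_cutpoint(neg_scores, pos_scores, direction: str = "greater") -> CutoffResult:
    """Youden-optimal threshold (J = sensitivity + specificity - 1).

    Only the "greater" direction (higher score = positive) is supported,
    matching the tau-positivity convention.
    """
    if direction != "greater":
        raise ValueError("only direction='greater' is supported")
    neg = np.sort(_as_scores(neg_scores, "negative"))
    pos = np.sort(_as_scores(pos_scores, "positive"))
    t = _candidate_thresholds(np.concatenate([neg, pos]))
    sens, spec = _sens_spec_at(neg, pos, t)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax returns the first (= smallest threshold) at ties
    return CutoffResult(
        cutpoint=float(t[best]),
        sensitivity=float(100.0 * sens[best]),
        specificity=float(100.0 * spec[best]),
        youden_j=float(j[best]),
    )


def sens_spec_at_cut(neg_scores, pos_scores, cutpoint: float) -> tuple[float, float]:
    """Sensitivity/specificity in percent at a fixed cut (call = score > cut)."""
    neg = np.sort(_as_scores(neg_scores, "negative"))
    pos = np.sort(_as_scores(pos_scores, "positive"))
    sens, spec = _sens_spec_at(neg, pos, np.asarray([cutpoint], dtype=float))
    return float(100.0 * sens[0]), float(100.0 * spec[0])


def bootstrap_cis(
    neg_scores,
    pos_scores,
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CutoffResult:
    """Youden cut-point with stratified percentile-bootstrap CIs.

    Resamples within each group independently, re-derives the Youden
    threshold per replicate, and returns percentile (alpha/2, 1-alpha/2)
    intervals for the cut-point, sensitivity and specificity.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    neg = _as_scores(neg_scores, "negative")
    pos = _as_scores(pos_scores, "positive")
    if neg.size < 10 or pos.size < 10:
        raise ValueError("bootstrap CIs need at least 10 subjects per group")
    point = youden_cutpoint(neg, pos)
    rng = np.random.default_rng(seed)
    cuts = np.empty(B)
    sens = np.empty(B)
    spec = np.empty(B)
    for b in range(B):
        rn = rng.choice(neg, size=neg.size, replace=True)
        rp = rng.choice(pos, size=pos.size, replace=True)
        res = youden_cutpoint(rn, rp)
        cuts[b] = res.cutpoint
        sens[b] = res.sensitivity
        spec[b] = res.specificity
    lo, hi = 100 * alpha / 2.0, 100 * (1 - alpha / 2.0)

    def ci(x: np.ndarray) -> tuple[float, float]:
        return (float(np.percentile(x, lo)), float(np.percentile(x, hi)))

    return CutoffResult(
        cutpoint=point.cutpoint,
        sensitivity=point.sensitivity,
        specificity=point.specificity,
        youden_j=point.youden_j,
        cut_ci=ci(cuts),
        sens_ci=ci(sens),
        spec_ci=ci(spec),
    )


# --------------------------------------------------------------------------
# DeLong


def _placements(neg: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Mid-rank placement values V10 (per positive) and V01 (per negative)."""
    n0, n1 = neg.size, pos.size
    pooled = np.concatenate([neg, pos])
    r_all = stats.rankdata(pooled)
    r_neg = stats.rankdata(neg)
    r_pos = stats.rankdata(pos)
    v01 = 1.0 - (r_all[:n0] - r_neg) / n1  # P(pos > this neg), ties 1/2
    v10 = (r_all[n0:] - r_pos) / n0  # P(this pos > neg), ties 1/2
    a = float(v10.mean())
    return v10, v01, a


def delong_ci(neg_scores, pos_scores, alpha: float = 0.05) -> RocResult:
    """AUC with DeLong (placement-value) standard-error CI, truncated to [0, 1]."""
    neg = _as_scores(neg_scores, "negative")
    pos = _as_scores(pos_scores, "positive")
    v10, v01, a = _placements(neg, pos)
    var = _delong_var_single(v10, v01)
    zq = stats.norm.ppf(1 - alpha / 2.0)
    half = zq * np.sqrt(var)
    return RocResult(
        auc=a,
        ci_low=float(max(0.0, a - half)),
        ci_high=float(min(1.0, a + half)),
        n_neg=neg.size,
        n_pos=pos.size,
    )


def _delong_var_single(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    s01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    return float(s10 / v10.size + s01 / v01.size)


def delong_paired(scores_a, scores_b, labels) -> DeLongResult:
    """Paired DeLong test comparing AUCs of two scores on the same subjects.

    ``labels`` is a boolean/0-1 vector (1 = positive class).  Uses the
    structural-components covariance estimator; two-sided normal p-value.
    """
    a_sc = np.asarray(scores_a, dtype=float).ravel()
    b_sc = np.asarray(scores_b, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if a_sc.size != b_sc.size or a_sc.size != y.size:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    if not (np.all(np.isfinite(a_sc)) and np.all(np.isfinite(b_sc))):
        raise ValueError("scores contain non-finite values")
    y = y.astype(bool) if y.dtype == bool else np.asarray(y, dtype=float) > 0.5
    if y.all() or not y.any():
        raise ValueError("labels contain a single class")
    pos_mask = y
    v10 = np.empty((int(pos_mask.sum()), 2))
    v01 = np.empty((int((~pos_mask).sum()), 2))
    aucs = np.empty(2)
    for i, sc in enumerate((a_sc, b_sc)):
        v10[:, i], v01[:, i], aucs[i] = _placements(sc[~pos_mask], sc[pos_mask])
    n1, n0 = v10.shape[0], v01.shape[0]
    s10 = np.cov(v10, rowvar=False) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(v01, rowvar=False) if n0 > 1 else np.zeros((2, 2))
    cov = s10 / n1 + s01 / n0
    delta = float(aucs[0] - aucs[1])
    var = float(max(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1], 0.0))
    if var <= 1e-16:
        z, p = 0.0, 1.0
    else:
        z = delta / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(
        auc_a=float(aucs[0]),
        auc_b=float(aucs[1]),
        delta=delta,
        variance=var,
        z=float(z),
        p=min(max(p, np.finfo(float).tiny), 1.0),
    )


# --------------------------------------------------------------------------
# binormal closed forms (test/calibration oracles)


def binormal_auc(mu0: float, sigma0: float, mu1: float, sigma1: float) -> float:
    """AUC of two normal score distributions: Phi(d / sqrt(s0^2 + s1^2))."""
    if sigma0 <= 0 or sigma1 <= 0:
        raise ValueError("sigmas must be positive")
    return float(stats.norm.cdf((mu1 - mu0) / np.hypot(sigma0, sigma1)))


def binormal_youden_cut(mu0: float, sigma0: float, mu1: float, sigma1: float) -> float:
    """Youden-optimal threshold for two normals: the density-crossing point.

    With equal variances this is the midpoint (mu0 + mu1) / 2; otherwise the
    quadratic log-density equation is solved and the root between the two
    means returned.
    """
    if sigma0 <= 0 or sigma1 <= 0:
        raise ValueError("sigmas must be positive")
    if np.isclose(sigma0, sigma1):
        return float((mu0 + mu1) / 2.0)
    # equate log densities: quadratic a c^2 + b c + const = 0
    a = 1.0 / sigma1**2 - 1.0 / sigma0**2
    b = 2.0 * (mu0 / sigma0**2 - mu1 / sigma1**2)
    c = mu1**2 / sigma1**2 - mu0**2 / sigma0**2 + 2.0 * np.log(sigma1 / sigma0)
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    lo, hi = sorted((mu0, mu1))
    inside = roots[(roots >= lo) & (roots <= hi)]
    if inside.size:
        return float(inside[0])
    # degenerate overlap (e.g. equal means): closest root to the means
    return float(roots[np.argmin(np.abs(roots - (mu0 + mu1) / 2.0))])


def classify_tau_positive(composite_suvr: float, cutpoint: float) -> str:
    """Tau-positivity call: 'positive' iff composite SUVR > cutpoint (strict)."""
    if not (np.isfinite(composite_suvr) and np.isfinite(cutpoint)):
        raise ValueError("inputs must be finite")
    return "positive" if composite_suvr > cutpoint else "negative"
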