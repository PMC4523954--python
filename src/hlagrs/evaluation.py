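"""ROC/AUC machinery and PPV-based clinical-utility statistics.

AUC is the Mann-Whitney concordance (ties get half credit); 95%
confidence intervals use DeLong's structural-component variance with a
normal approximation, and paired score comparisons use the paired
DeLong test (which replaces Harrell's paired-concordance test for
uncensored binary outcomes).

The clinical-utility statistic is the implications ratio

    r = (1 - PPV) / PPV,
    PPV = sens * prev / (sens * prev + (1 - spec) * (1 - prev)),

the number of unaffected individuals implicated per true case
implicated, equal to the reciprocal of the post-test odds of disease.
At sensitivity 1 and specificity 0 it reduces to the pre-test baseline
(1 - prev) / prev, e.g. 9:1 at 10% prevalence.  Differences in r between
two scores at a target sensitivity are assessed with a stratified
(case/control-preserving) bootstrap and percentile confidence
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCCurve",
    "RatioCurve",
    "BootstrapDiff",
    "auc",
    "auc_with_ci",
    "paired_auc_test",
    "roc_curve",
    "ppv",
    "implication_ratio_curve",
    "ratio_at_sensitivity",
    "bootstrap_ratio_difference",
]


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending; +inf sentinel first
    sens: np.ndarray
    spec: np.ndarray


@dataclass
class RatioCurve:
    sens: np.ndarray
    r: np.ndarray
    prev: float
    thresholds: np.ndarray


@dataclass
class BootstrapDiff:
    mean_diff: float
    ci_low: float
    ci_high: float
    B: int
    seed: int
    n_redrawn: int = 0


def _split(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    return cases, controls


# ---------------------------------------------------------------------------
# AUC and DeLong
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(cases: np.ndarray, controls: np.ndarray):
    """Structural components V10 (per case) and V01 (per control)."""
    m, n = len(cases), len(controls)
    all_scores = np.concatenate([cases, controls])
    r_all = _midrank(all_scores)
    r_cases = _midrank(cases)
    r_controls = _midrank(controls)
    a = float((r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    v10 = (r_all[:m] - r_cases) / n
    v01 = 1.0 - (r_all[m:] - r_controls) / m
    return a, v10, v01


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties."""
    cases, controls = _split(np.asarray(scores), np.asarray(labels))
    a, _, _ = _delong_components(cases, controls)
    return a


def auc_with_ci(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05):
    """(AUC, (low, high)) with a DeLong 95% CI (normal approximation)."""
    cases, controls = _split(np.asarray(scores), np.asarray(labels))
    a, v10, v01 = _delong_components(cases, controls)
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return a, (max(0.0, a - half), min(1.0, a + half))


def paired_auc_test(scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray):
    """Two-sided paired DeLong test for a difference in AUC.

    Both score vectors must be on the same individuals in the same
    order.  Returns (delta_auc, p_value).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors differ in length")
    labels = np.asarray(labels, dtype=int)
    ca, na = _split(scores_a, labels)
    cb, nb = _split(scores_b, labels)
    aa, v10a, v01a = _delong_components(ca, na)
    ab, v10b, v01b = _delong_components(cb, nb)
    m, n = len(ca), len(na)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = aa - ab
    if var <= 0:
        return delta, 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    return delta, float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# ROC and the implications ratio
# ---------------------------------------------------------------------------

def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC with positive calls at score >= threshold.

    Thresholds are the unique observed scores in descending order with a
    +inf sentinel, giving the (sens=0, spec=1) and (sens=1, spec=0)
    endpoints; tied scores share a threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _split(scores, labels)
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    n_case = labels.sum()
    n_ctrl = len(labels) - n_case
    thresholds = np.r_[np.inf, s[distinct]]
    sens = np.r_[0.0, tps / n_case]
    spec = np.r_[1.0, 1.0 - fps / n_ctrl]
    return ROCCurve(thresholds=thresholds, sens=sens, spec=spec)


def ppv(sens: float, spec: float, prev: float) -> float:
    """Positive predictive value at the given prevalence."""
    for name, v in (("sens", sens), ("spec", spec), ("prev", prev)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    denom = sens * prev + (1.0 - spec) * (1.0 - prev)
    if denom == 0.0:
        raise ValueError("PPV undefined: no positive calls (sens=0 and spec=1)")
    return sens * prev / denom


def implication_ratio_curve(scores: np.ndarray, labels: np.ndarray, prev: float) -> RatioCurve:
    """r = (1 - PPV)/PPV at every ROC threshold with at least one positive call."""
    if not 0.0 < prev < 1.0:
        raise ValueError("prev must be in (0, 1)")
    roc = roc_curve(scores, labels)
    keep = ~((roc.sens == 0.0) & (roc.spec == 1.0))
    sens = roc.sens[keep]
    spec = roc.spec[keep]
    thr = roc.thresholds[keep]
    r = np.empty(len(sens))
    for i, (se, sp) in enumerate(zip(sens, spec)):
        p = ppv(se, sp, prev)
        r[i] = (1.0 - p) / p if p > 0 else np.inf
    return RatioCurve(sens=sens, r=r, prev=prev, thresholds=thr)


def _ratio_at_sens_sorted(case_scores: np.ndarray, control_scores: np.ndarray, prev: float, sens_target: float) -> float:
    """r at the largest threshold achieving sens >= target.

    The threshold is the k-th largest case score with k = ceil(target * n_cases);
    ties can push the realized sensitivity above the target.
    """
    m = len(case_scores)
    k = int(np.ceil(sens_target * m))
    if k < 1:
        k = 1
    cs = np.sort(case_scores)[::-1]
    t = cs[k - 1]
    sens = (case_scores >= t).mean()
    spec = (control_scores < t).mean()
    p = ppv(sens, spec, prev)
    if p == 0.0:
        return np.inf
    return (1.0 - p) / p


def ratio_at_sensitivity(scores: np.ndarray, labels: np.ndarray, prev: float, sens_target: float) -> float:
    """Implications ratio at the largest threshold with sens >= sens_target."""
    if not 0.0 < prev < 1.0:
        raise ValueError("prev must be in (0, 1)")
    if not 0.0 < sens_target <= 1.0:
        raise ValueError("sens_target must be in (0, 1]")
    cases, controls = _split(np.asarray(scores), np.asarray(labels))
    return float(_ratio_at_sens_sorted(cases, controls, prev, sens_target))


def bootstrap_ratio_difference(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    prev: float,
    sens_target: float,
    B: int = 10_000,
    seed: int = 0,
) -> BootstrapDiff:
    """Stratified bootstrap of r_a - r_b at a target sensitivity.

    Cases and controls are resampled separately with replacement
    (stratum sizes preserved); per replicate the ratio at the target
    sensitivity is computed for each score and the difference recorded.
    Reports the mean difference and the percentile 95% CI.  Replicates
    where the target is unattainable are redrawn (warned if > 1% of B).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b, labels must be aligned")
    case_ix = np.flatnonzero(labels == 1)
    ctrl_ix = np.flatnonzero(labels == 0)
    if len(case_ix) < 2 or len(ctrl_ix) < 2:
        raise ValueError("need at least two cases and two controls")

    rng = np.random.default_rng(seed)
    diffs = np.empty(B)
    n_redrawn = 0
    b = 0
    while b < B:
        ci = rng.choice(case_ix, size=len(case_ix), replace=True)
        ni = rng.choice(ctrl_ix, size=len(ctrl_ix), replace=True)
        try:
            ra = _ratio_at_sens_sorted(scores_a[ci], scores_a[ni], prev, sens_target)
            rb = _ratio_at_sens_sorted(scores_b[ci], scores_b[ni], prev, sens_target)
        except ValueError:
            n_redrawn += 1
            continue
        if not (np.isfinite(ra) and np.isfinite(rb)):
            n_redrawn += 1
            continue
        diffs[b] = ra - rb
        b += 1
    if n_redrawn > 0.01 * B:
        warnings.warn(f"{n_redrawn} bootstrap replicates redrawn (unattainable target)", stacklevel=2)
    lo, hi = np.quantile(diffs, [0.025, 0.975])
    return BootstrapDiff(
        mean_diff=float(diffs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        B=B,
        seed=seed,
        n_redrawn=n_redrawn,
    )
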