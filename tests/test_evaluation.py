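"""AUC/DeLong machinery and the PPV-based implications ratio."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from hlagrs.evaluation import (
    auc,
    auc_with_ci,
    bootstrap_ratio_difference,
    implication_ratio_curve,
    paired_auc_test,
    ppv,
    ratio_at_sensitivity,
    roc_curve,
)


def brute_force_auc(scores, labels):
    """Exhaustive pairwise concordance with half credit for ties."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for n in controls:
            total += 1.0 if c > n else (0.5 if c == n else 0.0)
    return total / (len(cases) * len(controls))


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_auc_perfect_and_ties():
    labels = np.array([1, 1, 0, 0])
    assert auc(np.array([4.0, 3.0, 2.0, 1.0]), labels) == 1.0
    assert auc(np.ones(4), labels) == 0.5


def test_auc_equals_exhaustive_concordance():
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(5, 31))
        labels = np.zeros(n, dtype=int)
        labels[: max(1, int(rng.integers(1, n)))] = 1
        rng.shuffle(labels)
        if labels.sum() in (0, n):
            continue
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


def test_auc_matches_sklearn():
    rng = np.random.default_rng(1)
    labels = rng.integers(0, 2, 200)
    labels[:2] = [0, 1]
    scores = rng.normal(size=200) + labels
    assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        auc(np.arange(4.0), np.ones(4, dtype=int))


def test_delong_ci_empirical_coverage():
    """DeLong 95% CI covers the true AUC in >=90% of simulated datasets
    (binormal model, true AUC 0.7, n=200)."""
    rng = np.random.default_rng(2)
    delta = np.sqrt(2) * 0.5244  # Phi(delta/sqrt(2)) = 0.70
    true_auc = 0.70
    covered = 0
    n_sim = 500
    for _ in range(n_sim):
        cases = rng.normal(delta, 1, size=100)
        controls = rng.normal(0, 1, size=100)
        scores = np.concatenate([cases, controls])
        labels = np.r_[np.ones(100, dtype=int), np.zeros(100, dtype=int)]
        _, (lo, hi) = auc_with_ci(scores, labels)
        covered += lo <= true_auc <= hi
    assert covered / n_sim >= 0.90


# ---------------------------------------------------------------------------
# Paired DeLong test
# ---------------------------------------------------------------------------

def test_paired_test_identical_scores():
    rng = np.random.default_rng(3)
    labels = rng.integers(0, 2, 100)
    labels[:2] = [0, 1]
    s = rng.normal(size=100)
    d, p = paired_auc_test(s, s, labels)
    assert d == 0.0
    assert p == 1.0


def test_paired_test_symmetry():
    rng = np.random.default_rng(4)
    labels = rng.integers(0, 2, 150)
    labels[:2] = [0, 1]
    a = rng.normal(size=150) + labels
    b = rng.normal(size=150) + 0.3 * labels
    d_ab, p_ab = paired_auc_test(a, b, labels)
    d_ba, p_ba = paired_auc_test(b, a, labels)
    assert d_ab == pytest.approx(-d_ba)
    assert p_ab == pytest.approx(p_ba)


def test_paired_test_power_on_strong_difference():
    """AUC 0.9 vs 0.6 on n=500: significant at 0.01 in >=95% of seeds."""
    hits = 0
    n_seeds = 100
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        labels = np.r_[np.ones(250, dtype=int), np.zeros(250, dtype=int)]
        strong = np.where(labels == 1, rng.normal(1.81, 1, 500), rng.normal(0, 1, 500))
        weak = np.where(labels == 1, rng.normal(0.36, 1, 500), rng.normal(0, 1, 500))
        _, p = paired_auc_test(strong, weak, labels)
        hits += p < 0.01
    assert hits / n_seeds >= 0.95


def test_paired_test_misaligned_inputs():
    with pytest.raises(ValueError, match="differ in length"):
        paired_auc_test(np.zeros(3), np.zeros(4), np.array([0, 1, 0]))


# ---------------------------------------------------------------------------
# ROC curve
# ---------------------------------------------------------------------------

def test_roc_endpoints_and_monotonicity():
    rng = np.random.default_rng(5)
    labels = rng.integers(0, 2, 50)
    labels[:2] = [0, 1]
    scores = np.round(rng.normal(size=50), 1)
    roc = roc_curve(scores, labels)
    assert (roc.sens[0], roc.spec[0]) == (0.0, 1.0)
    assert (roc.sens[-1], roc.spec[-1]) == (1.0, 0.0)
    assert np.all(np.diff(roc.sens) >= 0)
    assert np.all(np.diff(roc.spec) <= 0)
    assert np.all(np.diff(roc.thresholds) < 0)


# ---------------------------------------------------------------------------
# PPV and implications ratio
# ---------------------------------------------------------------------------

def test_ppv_baseline_and_edge_cases():
    p = ppv(1.0, 0.0, 0.1)
    assert p == pytest.approx(0.1)
    assert (1 - p) / p == pytest.approx(9.0)
    assert ppv(0.5, 1.0, 0.2) == 1.0  # no false positives
    assert ppv(0.9, 0.32, 0.1) == pytest.approx(0.128205128, abs=1e-9)
    r = (1 - ppv(0.9, 0.32, 0.1)) / ppv(0.9, 0.32, 0.1)
    assert r == pytest.approx(6.8, abs=0.01)
    with pytest.raises(ValueError, match="undefined"):
        ppv(0.0, 1.0, 0.1)
    with pytest.raises(ValueError, match="in \\[0, 1\\]"):
        ppv(1.2, 0.5, 0.1)


def test_ppv_strictly_increasing_in_prevalence():
    prevs = np.linspace(0.01, 0.99, 50)
    vals = [ppv(0.8, 0.7, p) for p in prevs]
    assert np.all(np.diff(vals) > 0)


def test_ratio_curve_baseline_and_identity():
    rng = np.random.default_rng(6)
    labels = rng.integers(0, 2, 80)
    labels[:2] = [0, 1]
    scores = rng.normal(size=80)
    rc = implication_ratio_curve(scores, labels, prev=0.1)
    # last point: everyone implicated -> r = (1-prev)/prev = 9
    assert rc.sens[-1] == 1.0
    assert rc.r[-1] == pytest.approx(9.0)
    assert np.all(rc.r >= 0)
    # identity: r = 1 / (LR * pretest-odds)
    roc = roc_curve(scores, labels)
    keep = ~((roc.sens == 0) & (roc.spec == 1))
    sens, spec = roc.sens[keep], roc.spec[keep]
    with np.errstate(divide="ignore"):
        lr = sens / (1 - spec)
        expected = 1.0 / (lr * (0.1 / 0.9))
    np.testing.assert_allclose(rc.r, expected, atol=1e-12)


def test_ratio_curve_perfect_classifier():
    scores = np.array([5.0, 4.0, 1.0, 0.0])
    labels = np.array([1, 1, 0, 0])
    rc = implication_ratio_curve(scores, labels, prev=0.1)
    at_sep = rc.r[(rc.sens == 1.0) & (rc.thresholds == 4.0)]
    assert at_sep[0] == pytest.approx(0.0)


def test_ratio_curve_monotone_transform_invariance():
    rng = np.random.default_rng(7)
    labels = rng.integers(0, 2, 60)
    labels[:2] = [0, 1]
    scores = rng.normal(size=60)
    rc1 = implication_ratio_curve(scores, labels, prev=0.1)
    rc2 = implication_ratio_curve(np.exp(2 * scores) + 3, labels, prev=0.1)
    np.testing.assert_allclose(rc1.sens, rc2.sens)
    np.testing.assert_allclose(rc1.r, rc2.r)


def test_ratio_at_sensitivity_manual_walk():
    scores = np.array([9.0, 8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
    labels = np.array([1, 1, 0, 1, 0, 1, 0, 0, 0, 0])

    def manual(target, prev):
        best = None
        for t in sorted(np.unique(scores))[::-1]:
            sens = np.mean(scores[labels == 1] >= t)
            spec = np.mean(scores[labels == 0] < t)
            if sens >= target:
                best = (sens, spec)
                break  # largest threshold reaching the target
        p = ppv(best[0], best[1], prev)
        return (1 - p) / p

    for target in (0.5, 0.75, 0.9, 1.0):
        assert ratio_at_sensitivity(scores, labels, 0.1, target) == pytest.approx(
            manual(target, 0.1)
        )


def test_ratio_at_full_sensitivity_is_baseline():
    scores = np.array([3.0, 2.0, 1.0, 0.5, 0.2])
    labels = np.array([1, 0, 1, 0, 0])
    # at sens=1 the threshold is the lowest case score; all controls below
    # it are still excluded, so use scores where spec hits 0
    scores2 = np.array([1.0, 2.0, 0.5, 3.0, 2.5])
    assert ratio_at_sensitivity(scores2, labels, 0.1, 1.0) == pytest.approx(
        (1 - ppv(1.0, np.mean(scores2[labels == 0] < 1.0), 0.1))
        / ppv(1.0, np.mean(scores2[labels == 0] < 1.0), 0.1)
    )
    # perfect classifier at sens 0.9 -> no false positives -> r = 0
    perfect = np.array([5.0, 4.0, 3.0, 1.0, 0.0])
    labels2 = np.array([1, 1, 1, 0, 0])
    assert ratio_at_sensitivity(perfect, labels2, 0.1, 0.9) == 0.0


# ---------------------------------------------------------------------------
# Stratified bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_identical_scores():
    rng = np.random.default_rng(8)
    labels = np.r_[np.ones(40, dtype=int), np.zeros(160, dtype=int)]
    s = rng.normal(size=200) + labels
    bd = bootstrap_ratio_difference(s, s, labels, prev=0.1, sens_target=0.9, B=500, seed=0)
    assert bd.mean_diff == 0.0
    assert bd.ci_low <= 0.0 <= bd.ci_high


def test_bootstrap_determinism():
    rng = np.random.default_rng(9)
    labels = np.r_[np.ones(50, dtype=int), np.zeros(150, dtype=int)]
    a = rng.normal(size=200) + 1.5 * labels
    b = rng.normal(size=200) + 0.3 * labels
    r1 = bootstrap_ratio_difference(a, b, labels, 0.1, 0.9, B=300, seed=42)
    r2 = bootstrap_ratio_difference(a, b, labels, 0.1, 0.9, B=300, seed=42)
    assert (r1.mean_diff, r1.ci_low, r1.ci_high) == (r2.mean_diff, r2.ci_low, r2.ci_high)


def test_bootstrap_separates_better_from_worse_score():
    """A clearly better score yields a CI excluding zero in most seeds
    (scaled-down replication count)."""
    hits = 0
    n_seeds = 10
    for seed in range(n_seeds):
        rng = np.random.default_rng(500 + seed)
        n_case, n_ctrl = 120, 1080
        labels = np.r_[np.ones(n_case, dtype=int), np.zeros(n_ctrl, dtype=int)]
        better = np.where(labels == 1, rng.normal(1.8, 1, len(labels)), rng.normal(0, 1, len(labels)))
        worse = np.where(labels == 1, rng.normal(0.3, 1, len(labels)), rng.normal(0, 1, len(labels)))
        bd = bootstrap_ratio_difference(worse, better, labels, 0.1, 0.9, B=500, seed=seed)
        hits += bd.ci_low > 0.0  # worse minus better: positive difference
    assert hits >= 9


def test_bootstrap_input_validation():
    labels = np.array([1, 0, 0, 0])
    with pytest.raises(ValueError, match="at least two"):
        bootstrap_ratio_difference(
            np.arange(4.0), np.arange(4.0), labels, 0.1, 0.9, B=10, seed=0
        )
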