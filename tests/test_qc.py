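"""Variant/sample QC: exact tests, relatedness, PCA outliers, Fst."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from hlagrs.genotypes import GenotypeMatrix
from hlagrs.qc import (
    QCThresholds,
    differential_missingness_test,
    flag_related,
    hwe_exact_test,
    ibd_pihat,
    ld_thin,
    pca_outliers,
    run_qc,
    variant_qc,
    weir_cockerham_fst,
)
from hlagrs.simdata import SimParams, simulate_cohort


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_het, n_hom_minor, n_hom_major):
    """Direct enumeration of the conditional distribution of het counts."""
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    probs = {}
    for h in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        if hom_maj < 0:
            continue
        # P(h | allele counts) ∝ n! / (hom_min! h! hom_maj!) * 2^h
        logp = (
            special.gammaln(n + 1)
            - special.gammaln(hom_min + 1)
            - special.gammaln(h + 1)
            - special.gammaln(hom_maj + 1)
            + h * np.log(2.0)
        )
        probs[h] = logp
    mx = max(probs.values())
    dist = {h: np.exp(lp - mx) for h, lp in probs.items()}
    z = sum(dist.values())
    dist = {h: v / z for h, v in dist.items()}
    p_obs = dist[n_het]
    return sum(v for v in dist.values() if v <= p_obs * (1 + 1e-12)), dist


def test_hwe_monomorphic_site():
    assert hwe_exact_test(0, 0, 100) == 1.0


def test_hwe_allele_label_symmetry():
    assert hwe_exact_test(10, 3, 7) == pytest.approx(hwe_exact_test(10, 7, 3), abs=1e-15)


@pytest.mark.parametrize(
    "het, hom_min, hom_maj",
    [(10, 10, 80), (0, 10, 90), (5, 0, 95), (57, 14, 50), (2, 9, 2)],
)
def test_hwe_matches_enumeration_oracle(het, hom_min, hom_maj):
    expected, dist = hwe_enumeration_oracle(het, hom_min, hom_maj)
    assert hwe_exact_test(het, hom_min, hom_maj) == pytest.approx(expected, abs=1e-12)
    # conditional distribution is a proper distribution
    assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)


def test_hwe_extreme_deviation_is_significant():
    # all heterozygotes at a common allele: strong HWE violation
    assert hwe_exact_test(100, 0, 0) < 1e-10


def test_hwe_invalid_input():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)


# ---------------------------------------------------------------------------
# Differential missingness
# ---------------------------------------------------------------------------

def test_diff_missingness_no_association():
    assert differential_missingness_test(5, 95, 5, 95) == pytest.approx(1.0)
    assert differential_missingness_test(0, 100, 0, 100) == pytest.approx(1.0)


def test_diff_missingness_matches_hypergeometric_oracle():
    cm, cc, nm, nc = 20, 80, 2, 98
    # two-sided Fisher: sum hypergeometric probabilities <= P(observed)
    total_missing = cm + nm
    n_case, n_ctrl = cm + cc, nm + nc
    N = n_case + n_ctrl
    rv = stats.hypergeom(N, total_missing, n_case)
    p_obs = rv.pmf(cm)
    expected = sum(
        rv.pmf(k)
        for k in range(max(0, total_missing - n_ctrl), min(total_missing, n_case) + 1)
        if rv.pmf(k) <= p_obs * (1 + 1e-7)
    )
    assert differential_missingness_test(cm, cc, nm, nc) == pytest.approx(expected, abs=1e-12)


def test_diff_missingness_invalid():
    with pytest.raises(ValueError):
        differential_missingness_test(-1, 5, 5, 5)


# ---------------------------------------------------------------------------
# Variant-level filters
# ---------------------------------------------------------------------------

def _matrix(dosages, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else [1] * m,
            "pos": np.arange(1, m + 1) * 10,
            "a1": "A",
            "a2": "G",
        }
    )
    individuals = pd.DataFrame(
        {"iid": [f"i{k}" for k in range(n)], "sex": 1, "phenotype": [1, 0] * (n // 2)}
    )
    return GenotypeMatrix(dosages, variants, individuals)


def test_variant_qc_removes_low_maf():
    rng = np.random.default_rng(0)
    d = rng.binomial(2, 0.3, size=(200, 2)).astype(float)
    d[:, 1] = 0.0
    d[0, 1] = 1.0  # MAF 1/400 = 0.0025 < 1%
    g = _matrix(d)
    rep = variant_qc(g, g.phenotype_array(), QCThresholds())
    assert "v1" not in rep.kept_variants
    assert "v0" in rep.kept_variants


def test_variant_qc_removes_high_missingness():
    rng = np.random.default_rng(1)
    d = rng.binomial(2, 0.4, size=(100, 2)).astype(float)
    d[:15, 1] = np.nan  # 15% missing
    g = _matrix(d)
    rep = variant_qc(g, g.phenotype_array(), QCThresholds())
    assert "v1" not in rep.kept_variants


def test_variant_qc_removes_non_autosomal():
    rng = np.random.default_rng(2)
    d = rng.binomial(2, 0.4, size=(100, 3)).astype(float)
    g = _matrix(d, chrom=[1, 23, "X"])
    rep = variant_qc(g, g.phenotype_array(), QCThresholds())
    assert rep.kept_variants == ["v0"]
    assert rep.removal_counts["non_autosomal"] == 2


def test_variant_qc_all_pass_identity():
    rng = np.random.default_rng(3)
    d = rng.binomial(2, 0.4, size=(200, 5)).astype(float)
    g = _matrix(d)
    rep = variant_qc(g, g.phenotype_array(), QCThresholds())
    assert rep.kept_variants == list(g.variant_ids)
    assert rep.removal_counts["removed_total"] == 0


def test_variant_qc_no_controls_warns(caplog):
    rng = np.random.default_rng(4)
    d = rng.binomial(2, 0.4, size=(50, 3)).astype(float)
    g = _matrix(d)
    labels = np.ones(50, dtype=int)
    import logging

    with caplog.at_level(logging.WARNING, logger="hlagrs.qc"):
        rep = variant_qc(g, labels, QCThresholds())
    assert "HWE filter skipped" in caplog.text
    assert rep.removal_counts["hwe"] == 0


def test_variant_filters_are_conjunctive_and_order_free():
    """The kept set equals the intersection of the individual filters."""
    rng = np.random.default_rng(5)
    d = rng.binomial(2, rng.uniform(0.005, 0.5, size=30), size=(300, 30)).astype(float)
    miss = rng.random(d.shape) < 0.08
    d[miss] = np.nan
    g = _matrix(d)
    thr = QCThresholds()
    rep = variant_qc(g, g.phenotype_array(), thr)
    vs = rep.variant_stats.set_index("id")
    manual = [
        v
        for v in g.variant_ids
        if vs.loc[v, "maf"] >= thr.maf_min
        and vs.loc[v, "missingness"] <= thr.var_missing_max
        and vs.loc[v, "hwe_p"] >= thr.hwe_p_min
        and vs.loc[v, "diff_missing_p"] >= thr.diff_missing_p_min
    ]
    assert rep.kept_variants == manual


# ---------------------------------------------------------------------------
# IBD pi-hat
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def related_cohort():
    params = SimParams(
        n_individuals=60,
        n_snps=5000,
        n_causal=5,
        missing_rate=0.0,
        n_duplicate_pairs=1,
        n_parent_offspring_pairs=1,
    )
    return simulate_cohort(params, seed=9)


def test_pihat_duplicate_pair(related_cohort):
    pt = ibd_pihat(related_cohort.genotypes).set_index(["iid1", "iid2"])
    dup = related_cohort.contaminants.query("kind == 'duplicate'").iloc[0]
    key = (dup.source_iid, dup.iid)
    pihat = pt.loc[key, "pihat"] if key in pt.index else pt.loc[(dup.iid, dup.source_iid), "pihat"]
    assert pihat >= 0.95


def test_pihat_parent_offspring(related_cohort):
    pt = ibd_pihat(related_cohort.genotypes).set_index(["iid1", "iid2"])
    po = related_cohort.contaminants.query("kind == 'parent_offspring'").iloc[0]
    key = (po.source_iid, po.iid)
    pihat = pt.loc[key, "pihat"] if key in pt.index else pt.loc[(po.iid, po.source_iid), "pihat"]
    assert 0.4 <= pihat <= 0.6


def test_pihat_unrelated_pairs(related_cohort):
    pt = ibd_pihat(related_cohort.genotypes)
    contam = set(related_cohort.contaminants.iid)
    clean = pt[~pt.iid1.isin(contam) & ~pt.iid2.isin(contam)]
    assert clean.pihat.between(0.0, 0.05).mean() > 0.95
    assert clean.pihat.mean() < 0.02


def test_flag_related_removes_one_member(related_cohort):
    kept, flagged = flag_related(related_cohort.genotypes, QCThresholds())
    dup = related_cohort.contaminants.query("kind == 'duplicate'").iloc[0]
    assert len(flagged) >= 2  # duplicate + parent-offspring pairs
    removed = set(related_cohort.genotypes.iids) - set(kept)
    assert len({dup.iid, dup.source_iid} & removed) == 1


def test_pihat_requires_two_individuals(toy_genotypes):
    with pytest.raises(ValueError):
        ibd_pihat(toy_genotypes.subset(individual_mask=np.array([0])))


# ---------------------------------------------------------------------------
# PCA outliers
# ---------------------------------------------------------------------------

def test_pca_outliers_removes_planted_group():
    params = SimParams(n_individuals=200, n_snps=1500, n_causal=5, n_ancestry_outliers=8)
    c = simulate_cohort(params, seed=1)
    kept = set(pca_outliers(c.genotypes, QCThresholds(pca_k=2)))
    planted = set(c.contaminants.iid)
    assert len(planted - kept) >= 0.9 * len(planted)


def test_pca_no_removals_with_unreachable_threshold(small_cohort):
    thr = QCThresholds(pca_k=5, pca_sd=10.0)
    kept = pca_outliers(small_cohort.genotypes, thr)
    assert len(kept) == small_cohort.genotypes.n_individuals


def test_pca_two_single_passes_equal_two_iterations(small_cohort):
    g = small_cohort.genotypes
    thr1 = QCThresholds(pca_k=5, pca_sd=2.0, pca_iters=1)
    thr2 = QCThresholds(pca_k=5, pca_sd=2.0, pca_iters=2)
    pass1 = pca_outliers(g, thr1)
    g1 = g.select_individuals(pass1)
    pass2 = pca_outliers(g1, thr1)
    assert pass2 == pca_outliers(g, thr2)


def test_pca_k_truncated_with_warning(toy_genotypes):
    with pytest.warns(UserWarning, match="truncated"):
        pca_outliers(toy_genotypes, QCThresholds(pca_k=50, pca_iters=1))


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------

def test_fst_no_differentiation():
    rng = np.random.default_rng(0)
    freqs = rng.uniform(0.1, 0.5, 300)
    d = rng.binomial(2, freqs, size=(400, 300)).astype(float)
    g = _matrix(d)
    cluster = np.repeat(["a", "b"], 200)
    _, mean_fst = weir_cockerham_fst(g, cluster)
    assert abs(mean_fst) <= 0.01


def test_fst_fixed_difference():
    d = np.vstack([np.full((20, 1), 2.0), np.full((20, 1), 0.0)])
    g = _matrix(d)
    cluster = np.repeat(["a", "b"], 20)
    per_variant, mean_fst = weir_cockerham_fst(g, cluster)
    assert per_variant[0] == pytest.approx(1.0)
    assert mean_fst == pytest.approx(1.0)


def test_fst_matches_hand_computed_components():
    """Two clusters, one variant; components transcribed independently
    from the Weir-Cockerham definitions."""
    c1 = [0.0, 0.0, 1.0, 1.0, 2.0]  # n=5, p=0.4, het=0.4
    c2 = [2.0, 2.0, 2.0, 1.0, 1.0]  # n=5, p=0.8, het=0.4
    d = np.array(c1 + c2)[:, None]
    g = _matrix(d)
    cluster = np.repeat(["x", "y"], 5)

    ni = np.array([5.0, 5.0])
    pi = np.array([0.4, 0.8])
    hi = np.array([0.4, 0.4])
    r = 2
    nbar = ni.mean()
    nc = (ni.sum() - (ni**2).sum() / ni.sum()) / (r - 1)
    pbar = (ni * pi).sum() / ni.sum()
    s2 = (ni * (pi - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (ni * hi).sum() / ni.sum()
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    expected = a / (a + b + c)

    per_variant, mean_fst = weir_cockerham_fst(g, cluster)
    assert per_variant[0] == pytest.approx(expected, abs=1e-12)
    assert mean_fst == pytest.approx(expected, abs=1e-12)


def test_fst_monomorphic_excluded():
    d = np.hstack(
        [
            np.ones((40, 1)),  # monomorphic everywhere -> undefined
            np.vstack([np.full((20, 1), 2.0), np.full((20, 1), 0.0)]),
        ]
    )
    d[:, 0] = 0.0
    g = _matrix(d)
    cluster = np.repeat(["a", "b"], 20)
    per_variant, mean_fst = weir_cockerham_fst(g, cluster)
    assert np.isnan(per_variant[0])
    assert mean_fst == pytest.approx(1.0)


def test_fst_cluster_validation(toy_genotypes):
    with pytest.raises(ValueError):
        weir_cockerham_fst(toy_genotypes, np.array(["a"] * 6))


# ---------------------------------------------------------------------------
# Full chain recall on synthetic truth
# ---------------------------------------------------------------------------

def test_qc_recall_on_planted_contaminants():
    """Across seeds: >=95% of planted duplicate pairs resolved and
    ancestry outliers removed; <=5% of clean individuals removed."""
    resolved = 0
    planted_total = 0
    clean_removed = 0
    clean_total = 0
    thr = QCThresholds(pca_k=2)
    for seed in range(5):
        params = SimParams(
            n_individuals=150,
            n_snps=2000,
            n_causal=10,
            missing_rate=0.01,
            n_duplicate_pairs=4,
            n_ancestry_outliers=6,
        )
        c = simulate_cohort(params, seed=seed)
        _, rep = run_qc(c.genotypes, c.phenotype, thr)
        removed = set(c.genotypes.iids) - set(rep.kept_individuals)
        dup_sources = set()
        for rec in c.contaminants.itertuples():
            planted_total += 1
            if rec.kind == "duplicate":
                dup_sources.add(rec.source_iid)
                if rec.iid in removed or rec.source_iid in removed:
                    resolved += 1
            else:
                if rec.iid in removed:
                    resolved += 1
        clean = set(c.genotypes.iids[: params.n_individuals]) - dup_sources
        clean_total += len(clean)
        clean_removed += len(removed & clean)
    assert resolved / planted_total >= 0.95
    assert clean_removed / clean_total <= 0.05


def test_ld_thin_removes_correlated_duplicated_column():
    rng = np.random.default_rng(0)
    d = rng.binomial(2, 0.3, size=(200, 10)).astype(float)
    d[:, 5] = d[:, 4]  # perfect LD pair
    g = _matrix(d)
    kept = ld_thin(g, r2_max=0.2, window=10, step=5)
    assert ("v4" in kept) and ("v5" not in kept)
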