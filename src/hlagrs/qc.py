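"""GWAS quality control: variant filters, relatedness, PCA outliers, Fst.

The variant-level chain removes non-autosomal variants and variants with
MAF < 1%, missingness > 10%, Hardy-Weinberg deviation in controls at
P < 5e-6 (exact test), or case/control differential missingness at
P < 1e-3 (Fisher exact).  Individuals with > 10% missingness are removed.
Relatedness is screened by method-of-moments identity-by-descent pi-hat
(flag pairs above 0.1, drop the member with higher missingness), and
ancestry outliers by iterated PCA (drop individuals > 3 SD from the
per-PC median on any of the top PCs, two passes).  The filters are
conjunctive, so applying them in any order keeps the same variant set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .genotypes import GenotypeMatrix

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_exact_test",
    "differential_missingness_test",
    "variant_qc",
    "individual_qc",
    "ibd_pihat",
    "flag_related",
    "pca_outliers",
    "weir_cockerham_fst",
    "ld_thin",
    "run_qc",
]

logger = logging.getLogger(__name__)

AUTOSOMES = set(range(1, 23))


@dataclass(frozen=True)
class QCThresholds:
    maf_min: float = 0.01
    var_missing_max: float = 0.10
    hwe_p_min: float = 5e-6
    diff_missing_p_min: float = 1e-3
    indiv_missing_max: float = 0.10
    ibd_pihat_max: float = 0.10
    pca_k: int = 50
    pca_sd: float = 3.0
    pca_iters: int = 2
    ld_r2: float = 0.2
    ld_window: int = 50
    ld_step: int = 5

    def __post_init__(self) -> None:
        if self.pca_k < 1:
            raise ValueError("pca_k must be >= 1")
        for name in ("maf_min", "var_missing_max", "indiv_missing_max", "ibd_pihat_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QCReport:
    kept_variants: list
    kept_individuals: list
    removal_counts: dict
    variant_stats: pd.DataFrame
    pihat_flagged: pd.DataFrame = field(default_factory=pd.DataFrame)
    fst_summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------

def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Two-sided Hardy-Weinberg exact test (plink-style, no mid-p).

    Sums, over all heterozygote counts with the same parity compatible
    with the observed allele counts, the conditional probabilities no
    larger than that of the observed configuration.
    """
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        raise ValueError("no genotypes observed")

    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    rare = min(n_minor, n_major)
    if rare == 0:
        return 1.0

    # Conditional distribution of the het count given allele counts.
    # Recurrences (Wigginton et al.): upward in het count,
    #   P(h+2)/P(h) = 4 * hom_minor(h) * hom_major(h) / ((h+2)(h+1))
    # where hom_minor(h) = (rare - h)/2, hom_major(h) = n - h - hom_minor(h).
    h_min = rare % 2
    hets = np.arange(h_min, rare + 1, 2)
    logp = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i - 1]
        hom_r = (rare - h) / 2.0
        hom_c = n - h - hom_r
        ratio = 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        logp[i] = logp[i - 1] + np.log(ratio)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()

    if n_het not in set(hets.tolist()):
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = probs[np.searchsorted(hets, n_het)]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def differential_missingness_test(
    case_missing: int, case_called: int, control_missing: int, control_called: int
) -> float:
    """Two-sided Fisher exact p for case/control missingness."""
    for v in (case_missing, case_called, control_missing, control_called):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    if case_missing + case_called < 1 or control_missing + control_called < 1:
        raise ValueError("each group needs at least one genotype attempt")
    table = [[case_missing, case_called], [control_missing, control_called]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Variant- and sample-level filters
# ---------------------------------------------------------------------------

def _genotype_counts(dosages_col: np.ndarray) -> tuple[int, int, int]:
    called = dosages_col[~np.isnan(dosages_col)]
    return (
        int((called == 1).sum()),
        int((called == 2).sum()),
        int((called == 0).sum()),
    )


def variant_qc(g: GenotypeMatrix, labels: np.ndarray, thr: QCThresholds) -> QCReport:
    """Apply all variant-level filters; HWE on controls only.

    ``labels``: 1 = case, 0 = control, aligned with ``g`` individuals.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != g.n_individuals:
        raise ValueError("labels not aligned with genotype matrix")
    is_control = labels == 0
    is_case = labels == 1
    has_controls = bool(is_control.any())
    if not has_controls:
        logger.warning("no controls present: HWE filter skipped")

    maf = g.maf()
    miss = g.variant_missingness()
    chrom = pd.to_numeric(g.variants["chrom"], errors="coerce")
    autosomal = chrom.isin(list(AUTOSOMES)).to_numpy()

    m = g.n_variants
    hwe_p = np.ones(m)
    diff_p = np.ones(m)
    case_d = g.dosages[is_case, :]
    ctrl_d = g.dosages[is_control, :]
    n_case = int(is_case.sum())
    n_ctrl = int(is_control.sum())
    case_missing = np.isnan(case_d).sum(axis=0)
    ctrl_missing = np.isnan(ctrl_d).sum(axis=0)
    for j in range(m):
        if has_controls:
            het, hom_min, hom_maj = _genotype_counts(ctrl_d[:, j])
            if het + hom_min + hom_maj > 0:
                hwe_p[j] = hwe_exact_test(het, hom_min, hom_maj)
        if n_case > 0 and n_ctrl > 0:
            diff_p[j] = differential_missingness_test(
                int(case_missing[j]),
                n_case - int(case_missing[j]),
                int(ctrl_missing[j]),
                n_ctrl - int(ctrl_missing[j]),
            )

    fails = {
        "non_autosomal": ~autosomal,
        "maf": maf < thr.maf_min,
        "missingness": miss > thr.var_missing_max,
        "hwe": hwe_p < thr.hwe_p_min,
        "diff_missingness": diff_p < thr.diff_missing_p_min,
    }
    fail_any = np.zeros(m, dtype=bool)
    for mask in fails.values():
        fail_any |= mask

    stats_table = pd.DataFrame(
        {
            "id": g.variant_ids,
            "maf": maf,
            "missingness": miss,
            "hwe_p": hwe_p,
            "diff_missing_p": diff_p,
            "kept": ~fail_any,
        }
    )
    kept = [v for v, ok in zip(g.variant_ids, ~fail_any) if ok]
    counts = {k: int(v.sum()) for k, v in fails.items()}
    counts["removed_total"] = int(fail_any.sum())
    return QCReport(
        kept_variants=kept,
        kept_individuals=list(g.iids),
        removal_counts=counts,
        variant_stats=stats_table,
    )


def individual_qc(g: GenotypeMatrix, thr: QCThresholds) -> list:
    """IDs of individuals passing the per-individual missingness filter."""
    miss = g.individual_missingness()
    return [i for i, m in zip(g.iids, miss) if m <= thr.indiv_missing_max]


# ---------------------------------------------------------------------------
# Relatedness (method-of-moments IBD)
# ---------------------------------------------------------------------------

def ibd_pihat(g: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise pi-hat = P(IBD=2) + 0.5 P(IBD=1), method of moments.

    Observed IBS sharing per pair is compared with its expectation under
    IBD states 0/1/2 given sample allele frequencies; the IBD state
    probabilities are solved sequentially and clamped to [0, 1].
    Variants should be LD-thinned by the caller.
    """
    n = g.n_individuals
    if n < 2:
        raise ValueError("need at least two individuals")
    d = g.dosages
    p = g.allele1_freq()
    ok = (p > 0) & (p < 1)
    d = d[:, ok]
    p = p[ok]
    q = 1 - p

    # Expected per-variant IBS probabilities conditional on IBD state.
    e_ibs0_z0 = 2 * p**2 * q**2
    e_ibs1_z0 = 4 * p**3 * q + 4 * p * q**3
    e_ibs1_z1 = 2 * p**2 * q + 2 * p * q**2
    e_ibs2_z0 = 1 - e_ibs0_z0 - e_ibs1_z0
    e_ibs2_z1 = 1 - e_ibs1_z1

    # One-hot genotype indicators (missing rows contribute zero) let all
    # pairwise IBS counts and expectations be computed as matmuls.
    called = ~np.isnan(d)
    g0 = (d == 0) & called
    g1 = (d == 1) & called
    g2 = (d == 2) & called
    G0 = g0.astype(float)
    G1 = g1.astype(float)
    G2 = g2.astype(float)
    M = called.astype(float)

    ibs0 = G0 @ G2.T + G2 @ G0.T
    ibs1 = G1 @ (G0 + G2).T + (G0 + G2) @ G1.T
    ibs2 = G0 @ G0.T + G1 @ G1.T + G2 @ G2.T
    n_shared = M @ M.T
    E0_z0 = (M * e_ibs0_z0) @ M.T
    E1_z0 = (M * e_ibs1_z0) @ M.T
    E2_z0 = (M * e_ibs2_z0) @ M.T
    E1_z1 = (M * e_ibs1_z1) @ M.T
    E2_z1 = (M * e_ibs2_z1) @ M.T

    # The state estimates are left unclipped before combining: clipping
    # each at zero would bias pi-hat upward for unrelated pairs.
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(E0_z0 > 0, ibs0 / E0_z0, 0.0)
        p1 = np.where(E1_z1 > 0, (ibs1 - p0 * E1_z0) / E1_z1, 0.0)
        p2 = np.where(n_shared > 0, (ibs2 - p0 * E2_z0 - p1 * E2_z1) / n_shared, 0.0)
    pihat = np.clip(p2 + 0.5 * p1, 0.0, 1.0)

    iu = np.triu_indices(n, k=1)
    valid = n_shared[iu] > 0
    iids = g.iids
    return pd.DataFrame(
        {
            "iid1": iids[iu[0][valid]],
            "iid2": iids[iu[1][valid]],
            "pihat": pihat[iu][valid],
        }
    )


def flag_related(g: GenotypeMatrix, thr: QCThresholds, pihat: pd.DataFrame | None = None):
    """Remove one member of each pair with pi-hat above the threshold.

    The member with higher genotype missingness is dropped; ties break
    lexicographically by ID.  Returns (kept IDs, flagged-pairs table).
    """
    if pihat is None:
        pihat = ibd_pihat(g)
    miss = dict(zip(g.iids, g.individual_missingness()))
    flagged = pihat[pihat["pihat"] > thr.ibd_pihat_max].copy()
    removed: set = set()
    for rec in flagged.sort_values("pihat", ascending=False).itertuples():
        if rec.iid1 in removed or rec.iid2 in removed:
            continue
        m1, m2 = miss[rec.iid1], miss[rec.iid2]
        if m1 > m2:
            removed.add(rec.iid1)
        elif m2 > m1:
            removed.add(rec.iid2)
        else:
            removed.add(max(rec.iid1, rec.iid2))
    kept = [i for i in g.iids if i not in removed]
    return kept, flagged


# ---------------------------------------------------------------------------
# PCA outliers
# ---------------------------------------------------------------------------

def _standardized(g: GenotypeMatrix) -> np.ndarray:
    d = g.dosages.copy()
    mean = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = np.take(mean, idx[1])
    d -= mean
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    return d / sd


def pca_outliers(g: GenotypeMatrix, thr: QCThresholds) -> list:
    """Iteratively drop individuals far from the per-PC median.

    Each pass computes the top-k PCs of the standardized (mean-imputed)
    dosage matrix and removes individuals more than ``pca_sd`` standard
    deviations from the median on any of PCs 1..k; ``pca_iters`` passes.
    Returns surviving IDs.
    """
    current = g
    for _ in range(thr.pca_iters):
        n, m = current.n_individuals, current.n_variants
        k = min(thr.pca_k, n - 1, m)
        if k < thr.pca_k:
            warnings.warn(f"pca_k truncated to {k} (n={n}, m={m})", stacklevel=2)
        if k < 1:
            break
        x = _standardized(current)
        pcs = PCA(n_components=k, svd_solver="full" if min(n, m) < 500 else "randomized",
                  random_state=0).fit_transform(x)
        med = np.median(pcs, axis=0)
        sd = pcs.std(axis=0)
        sd[sd == 0] = 1.0
        outlier = (np.abs(pcs - med) > thr.pca_sd * sd).any(axis=1)
        if not outlier.any():
            break
        current = current.subset(individual_mask=~outlier)
    return list(current.iids)


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------

def weir_cockerham_fst(g: GenotypeMatrix, cluster: np.ndarray):
    """Weir-Cockerham Fst per variant and ratio-of-sums mean.

    ``cluster``: per-individual labels; at least two clusters with >= 2
    individuals each.  Variants monomorphic in every cluster have
    undefined Fst (NaN) and are excluded from the mean.
    Returns (per-variant array, mean).
    """
    cluster = np.asarray(cluster)
    labels = np.unique(cluster)
    if len(labels) < 2:
        raise ValueError("need at least two clusters")
    groups = [np.flatnonzero(cluster == lab) for lab in labels]
    if any(len(ix) < 2 for ix in groups):
        raise ValueError("each cluster needs at least two individuals")
    r = len(groups)

    m = g.n_variants
    a_comp = np.full(m, np.nan)
    b_comp = np.full(m, np.nan)
    c_comp = np.full(m, np.nan)
    for j in range(m):
        ni, pi, hi = [], [], []
        for ix in groups:
            col = g.dosages[ix, j]
            col = col[~np.isnan(col)]
            if len(col) < 2:
                continue
            ni.append(len(col))
            pi.append(col.mean() / 2.0)
            hi.append((col == 1).mean())
        if len(ni) < 2:
            continue
        ni = np.asarray(ni, dtype=float)
        pi = np.asarray(pi)
        hi = np.asarray(hi)
        ri = len(ni)
        nbar = ni.mean()
        nc = (ni.sum() - (ni**2).sum() / ni.sum()) / (ri - 1)
        pbar = (ni * pi).sum() / (ni.sum())
        s2 = (ni * (pi - pbar) ** 2).sum() / ((ri - 1) * nbar)
        hbar = (ni * hi).sum() / ni.sum()
        if pbar in (0.0, 1.0):
            continue  # monomorphic everywhere
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((ri - 1) / ri) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((ri - 1) / ri) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        a_comp[j], b_comp[j], c_comp[j] = a, b, c

    with np.errstate(invalid="ignore", divide="ignore"):
        per_variant = a_comp / (a_comp + b_comp + c_comp)
    defined = ~np.isnan(a_comp)
    denom = (a_comp[defined] + b_comp[defined] + c_comp[defined]).sum()
    mean_fst = float(a_comp[defined].sum() / denom) if defined.any() and denom != 0 else float("nan")
    return per_variant, mean_fst


# ---------------------------------------------------------------------------
# LD thinning (plink indep-pairwise style)
# ---------------------------------------------------------------------------

def ld_thin(g: GenotypeMatrix, r2_max: float = 0.2, window: int = 50, step: int = 5) -> list:
    """Greedy pairwise r^2 pruning in sliding windows; returns kept IDs."""
    x = _standardized(g)
    m = g.n_variants
    keep = np.ones(m, dtype=bool)
    n = x.shape[0]
    start = 0
    while start < m:
        idx = np.array([j for j in range(start, min(start + window, m)) if keep[j]])
        if len(idx) >= 2:
            r2 = (x[:, idx].T @ x[:, idx] / n) ** 2
            for ii in range(len(idx)):
                if not keep[idx[ii]]:
                    continue
                hits = np.flatnonzero(r2[ii, ii + 1 :] > r2_max) + ii + 1
                keep[idx[hits]] = False
        start += step
    return [v for v, k in zip(g.variant_ids, keep) if k]


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def run_qc(g: GenotypeMatrix, labels: np.ndarray, thr: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Variant filters, then sample missingness, relatedness, PCA outliers.

    Returns the filtered matrix and a consolidated report.
    """
    thr = thr or QCThresholds()
    report = variant_qc(g, labels, thr)
    g2 = g.select_variants(report.kept_variants)

    kept_miss = set(individual_qc(g2, thr))
    g3 = g2.subset(individual_mask=np.array([i in kept_miss for i in g2.iids]))

    thinned = ld_thin(g3, thr.ld_r2, thr.ld_window, thr.ld_step)
    g_thin = g3.select_variants(thinned)
    kept_rel, flagged = flag_related(g_thin, thr)
    g4 = g3.subset(individual_mask=np.array([i in set(kept_rel) for i in g3.iids]))

    g4_thin = g4.select_variants([v for v in thinned if v in set(g4.variant_ids)])
    kept_pca = set(pca_outliers(g4_thin, thr))
    g5 = g4.subset(individual_mask=np.array([i in kept_pca for i in g4.iids]))

    report.kept_individuals = list(g5.iids)
    report.pihat_flagged = flagged
    report.removal_counts["indiv_missingness"] = g2.n_individuals - g3.n_individuals
    report.removal_counts["related"] = g3.n_individuals - g4.n_individuals
    report.removal_counts["pca_outliers"] = g4.n_individuals - g5.n_individuals
    return g5, report
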