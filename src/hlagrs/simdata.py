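"""Seeded synthetic case-control cohorts with HLA-DQ architecture.

The generator emulates the genetic architecture of celiac disease (CD)
with a liability-threshold model:

* each individual carries two HLA haplotypes drawn from a four-label pool
  (DQ2.5-carrying, DQ2.2-carrying, DQ8-carrying, neutral), which determine
  DQA1/DQB1 alleles and hence the risk heterodimer state;
* liability = heterodimer-state shift + sum of causal SNP effects on the
  standardized dosage scale + standard normal noise;
* an individual is a case when liability exceeds a threshold calibrated so
  that prevalence within the heterodimer-carrier stratum matches
  ``prevalence_target`` (default 10%, the at-risk-stratum prevalence).

The default liability shifts make the risk heterodimers close to
necessary-but-not-sufficient: ~99.6% of cases carry one, split roughly
88% DQ2.5 / 4% DQ2.2 / 6% DQ8, with a DQ2.5 homozygote > heterozygote
risk gradient.  Non-carriers receive a strongly negative shift so that
non-carrier cases are rare (<1% of cases).

QC contaminants (exact duplicates, parent-offspring pairs, ancestry
outliers with Fst-style allele-frequency drift) and random missingness
can be injected, with a truth table recorded for QC recall tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix, write_dosage_tsv, write_plink

__all__ = [
    "SimParams",
    "Cohort",
    "simulate_cohort",
    "disease_probability",
    "calibrate_threshold",
    "heterodimer_state_probs",
    "write_cohort",
]

# Alleles contributed by each haplotype label (DQA1, DQB1).
_HAP_ALLELES = {
    "DQ2.5": ("05:01", "02:01"),
    "DQ2.2": ("02:01", "02:02"),
    "DQ8": ("03:01", "03:02"),
    "neutral": ("01:01", "05:01"),
}

_STATES = ("dq25_hom", "dq25_het_dq22", "dq25_het", "dq22", "dq8", "none")


def _default_hap_freqs() -> dict[str, float]:
    return {"DQ2.5": 0.11, "DQ2.2": 0.05, "DQ8": 0.08, "neutral": 0.76}


def _default_shifts() -> dict[str, float]:
    # Solved once against the case-composition targets in the module
    # docstring (10% carrier-stratum prevalence, ~88/4/6 heterodimer split
    # among cases, hom:het risk ratio ~2.5) and frozen.
    return {
        "dq25_hom": 2.74,
        "dq25_het_dq22": 2.50,
        "dq25_het": 1.83,
        "dq22": 0.66,
        "dq8": 0.66,
        "none": -2.50,
    }


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic cohort generator."""

    n_individuals: int = 2000
    n_snps: int = 1000
    n_causal: int = 20
    causal_effect_sd: float = 0.15
    hla_haplotype_freqs: dict[str, float] = field(default_factory=_default_hap_freqs)
    hla_liability_shifts: dict[str, float] = field(default_factory=_default_shifts)
    prevalence_target: float = 0.10
    missing_rate: float = 0.01
    n_hla_markers: int = 0
    hla_marker_flip_rate: float = 0.05
    n_duplicate_pairs: int = 0
    n_parent_offspring_pairs: int = 0
    n_ancestry_outliers: int = 0
    ancestry_fst: float = 0.05
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = self.hla_haplotype_freqs
        if set(freqs) != set(_HAP_ALLELES):
            raise ValueError(f"haplotype frequencies must have keys {sorted(_HAP_ALLELES)}")
        if abs(sum(freqs.values()) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        for name, v in freqs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"frequency of {name} outside [0, 1]")
        for name in ("prevalence_target", "missing_rate", "hla_marker_flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.prevalence_target < 1.0:
            raise ValueError("prevalence_target must be in (0, 1)")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if set(self.hla_liability_shifts) != set(_STATES):
            raise ValueError(f"liability shifts must have keys {sorted(_STATES)}")

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=seed)


@dataclass
class Cohort:
    """A simulated case-control cohort.

    ``true_liability``, ``heterodimer_state`` and ``causal_effects`` are
    generator diagnostics; ``contaminants`` is the QC truth table with
    columns ``iid, kind, source_iid``.
    """

    genotypes: GenotypeMatrix
    dq_alleles: pd.DataFrame
    true_liability: np.ndarray
    heterodimer_state: np.ndarray
    causal_effects: pd.DataFrame
    contaminants: pd.DataFrame
    params: SimParams

    @property
    def phenotype(self) -> np.ndarray:
        return self.genotypes.phenotype_array()

    @property
    def iids(self) -> np.ndarray:
        return self.genotypes.iids


# ---------------------------------------------------------------------------
# Liability model
# ---------------------------------------------------------------------------

def heterodimer_state_probs(params: SimParams) -> dict[str, float]:
    """Population probability of each heterodimer state under random
    pairing of haplotypes."""
    f = params.hla_haplotype_freqs
    f25, f22, f8, f0 = f["DQ2.5"], f["DQ2.2"], f["DQ8"], f["neutral"]
    return {
        "dq25_hom": f25**2,
        "dq25_het_dq22": 2 * f25 * f22,
        "dq25_het": 2 * f25 * (1 - f25 - f22),
        "dq22": (1 - f25) ** 2 - (1 - f25 - f22) ** 2,
        "dq8": (f8 + f0) ** 2 - f0**2,
        "none": f0**2,
    }


def _polygenic_sd(params: SimParams) -> float:
    """SD of heterodimer-independent liability (polygenic + noise)."""
    return math.sqrt(1.0 + params.n_causal * params.causal_effect_sd**2)


def calibrate_threshold(params: SimParams) -> float:
    """Liability threshold giving carrier-stratum prevalence equal to
    ``prevalence_target`` (analytic, under the model's own assumptions)."""
    probs = heterodimer_state_probs(params)
    shifts = params.hla_liability_shifts
    sigma = _polygenic_sd(params)
    p_carrier = 1.0 - probs["none"]

    def carrier_prev(t: float) -> float:
        acc = sum(
            probs[s] * stats.norm.sf((t - shifts[s]) / sigma)
            for s in _STATES
            if s != "none"
        )
        return acc / p_carrier

    lo, hi = -20.0, 40.0
    return optimize.brentq(lambda t: carrier_prev(t) - params.prevalence_target, lo, hi, xtol=1e-10)


def disease_probability(heterodimer_state: str, polygenic_liability: float, params: SimParams) -> float:
    """P(case) for a given heterodimer state and polygenic liability.

    The survival function of the standard normal noise at the calibrated
    threshold minus the state shift minus the polygenic contribution;
    monotone nondecreasing in the polygenic liability.
    """
    if heterodimer_state not in _STATES:
        raise ValueError(f"unknown heterodimer state {heterodimer_state!r}; expected one of {_STATES}")
    t = calibrate_threshold(params)
    shift = params.hla_liability_shifts[heterodimer_state]
    return float(stats.norm.sf(t - shift - polygenic_liability))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _state_from_haps(h1: str, h2: str) -> str:
    haps = (h1, h2)
    n25 = haps.count("DQ2.5")
    if n25 == 2:
        return "dq25_hom"
    if n25 == 1:
        return "dq25_het_dq22" if "DQ2.2" in haps else "dq25_het"
    if "DQ2.2" in haps:
        return "dq22"
    if "DQ8" in haps:
        return "dq8"
    return "none"


def _draw_haplotypes(rng: np.random.Generator, n: int, params: SimParams) -> np.ndarray:
    labels = list(_HAP_ALLELES)
    probs = [params.hla_haplotype_freqs[l] for l in labels]
    idx = rng.choice(len(labels), size=(n, 2), p=probs)
    return np.array(labels, dtype=object)[idx]


def _dq_table(iids: np.ndarray, haps: np.ndarray) -> pd.DataFrame:
    a = np.array([[_HAP_ALLELES[h][0] for h in row] for row in haps])
    b = np.array([[_HAP_ALLELES[h][1] for h in row] for row in haps])
    return pd.DataFrame(
        {"IID": iids, "DQA1_1": a[:, 0], "DQA1_2": a[:, 1], "DQB1_1": b[:, 0], "DQB1_2": b[:, 1]}
    )


def draw_architecture(params: SimParams, seed: int) -> dict:
    """Draw the shared genetic architecture (allele frequencies, causal
    SNP indices and effects) so that several cohorts can be generated
    from one architecture (e.g. a training and a drifted validation
    cohort)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    freqs = rng.uniform(*params.maf_range, size=params.n_snps)
    causal_idx = np.sort(rng.choice(params.n_snps, size=params.n_causal, replace=False))
    betas = rng.normal(0.0, params.causal_effect_sd, size=params.n_causal)
    return {"freqs": freqs, "causal_idx": causal_idx, "betas": betas}


def simulate_cohort(
    params: SimParams,
    seed: int | None = None,
    architecture: dict | None = None,
    iid_prefix: str = "S",
) -> Cohort:
    """Generate a cohort under the liability-threshold model.

    Deterministic given ``(params, seed)``; ``seed`` defaults to
    ``params.seed``.  Raises if thresholding leaves zero cases or zero
    controls.
    """
    if seed is None:
        seed = params.seed
    ss = np.random.SeedSequence(seed)
    (s_hla, s_geno, s_eff, s_noise, s_miss, s_contam, s_marker) = ss.spawn(7)
    rng_hla = np.random.default_rng(s_hla)
    rng_geno = np.random.default_rng(s_geno)
    rng_eff = np.random.default_rng(s_eff)
    rng_noise = np.random.default_rng(s_noise)
    rng_miss = np.random.default_rng(s_miss)
    rng_contam = np.random.default_rng(s_contam)
    rng_marker = np.random.default_rng(s_marker)

    n, m = params.n_individuals, params.n_snps

    # --- SNP genotypes ---
    if architecture is None:
        freqs = rng_geno.uniform(*params.maf_range, size=m)
        causal_idx = np.sort(rng_eff.choice(m, size=params.n_causal, replace=False))
        betas = rng_eff.normal(0.0, params.causal_effect_sd, size=params.n_causal)
    else:
        freqs = np.asarray(architecture["freqs"], dtype=float)
        causal_idx = np.asarray(architecture["causal_idx"], dtype=int)
        betas = np.asarray(architecture["betas"], dtype=float)
        if freqs.shape[0] != m or causal_idx.shape[0] != params.n_causal:
            raise ValueError("architecture inconsistent with params")
    dosages = rng_geno.binomial(2, freqs, size=(n, m)).astype(float)

    # standardized dosages at the causal SNPs, using the true frequencies
    p = freqs[causal_idx]
    z = (dosages[:, causal_idx] - 2 * p) / np.sqrt(2 * p * (1 - p))
    polygenic = z @ betas

    # --- HLA haplotypes and heterodimer states ---
    haps = _draw_haplotypes(rng_hla, n, params)
    states = np.array([_state_from_haps(h1, h2) for h1, h2 in haps], dtype=object)
    shifts = np.array([params.hla_liability_shifts[s] for s in states])

    # --- liability and phenotype ---
    noise = rng_noise.normal(size=n)
    liability = shifts + polygenic + noise
    threshold = calibrate_threshold(params)
    phenotype = (liability > threshold).astype(int)
    if phenotype.sum() == 0:
        raise ValueError(
            "simulated cohort has zero cases; increase n_individuals, "
            "prevalence_target, or the liability shifts"
        )
    if phenotype.sum() == n:
        raise ValueError(
            "simulated cohort has zero controls; decrease prevalence_target "
            "or the liability shifts"
        )

    iids = np.array([f"{iid_prefix}{i:06d}" for i in range(n)], dtype=object)

    variants = pd.DataFrame(
        {
            "id": [f"rs{j + 1:06d}" for j in range(m)],
            "chrom": 1 + (np.arange(m) % 22),
            "pos": 10_000 + 100 * np.arange(m),
            "a1": "A",
            "a2": "G",
        }
    )

    # --- optional HLA-region binary "imputed marker" channel ---
    if params.n_hla_markers > 0:
        risk_labels = ["DQ2.5", "DQ2.2", "DQ8"]
        marker_cols = []
        marker_meta = []
        for k in range(params.n_hla_markers):
            label = risk_labels[k % len(risk_labels)]
            present = (haps == label).any(axis=1).astype(float)
            flip = rng_marker.random(n + 0) < params.hla_marker_flip_rate
            present[flip] = 1.0 - present[flip]
            marker_cols.append(present)
            marker_meta.append(
                {
                    "id": f"HLA_{label.replace('.', '')}_{k + 1}",
                    "chrom": 6,
                    "pos": 32_500_000 + 10 * k,
                    "a1": "P",
                    "a2": "A",
                }
            )
        dosages = np.column_stack([dosages] + marker_cols)
        variants = pd.concat([variants, pd.DataFrame(marker_meta)], ignore_index=True)

    sex = rng_hla.integers(1, 3, size=n)
    individuals = pd.DataFrame({"iid": iids, "sex": sex, "phenotype": phenotype})
    dq = _dq_table(iids, haps)

    # --- contaminants, appended after the base cohort ---
    contam_rows = []
    extra_dos, extra_ind, extra_dq = [], [], []
    extra_liab, extra_state = [], []
    m_total = dosages.shape[1]

    def _append(iid, row, state, liab, pheno, dq_row, kind, source):
        extra_dos.append(row)
        extra_ind.append({"iid": iid, "sex": int(rng_contam.integers(1, 3)), "phenotype": pheno})
        extra_dq.append(dq_row)
        extra_liab.append(liab)
        extra_state.append(state)
        contam_rows.append({"iid": iid, "kind": kind, "source_iid": source})

    for k in range(params.n_duplicate_pairs):
        src = int(rng_contam.integers(0, n))
        iid = f"DUP{k:03d}"
        dq_row = dq.iloc[src].to_dict() | {"IID": iid}
        _append(iid, dosages[src].copy(), states[src], liability[src], int(phenotype[src]), dq_row, "duplicate", iids[src])

    for k in range(params.n_parent_offspring_pairs):
        src = int(rng_contam.integers(0, n))
        iid = f"PO{k:03d}"
        parent = dosages[src, :m]
        mate = rng_contam.binomial(2, freqs).astype(float)
        child = rng_contam.binomial(1, parent / 2.0) + rng_contam.binomial(1, mate / 2.0)
        row = child.astype(float)
        if m_total > m:  # carry a fresh marker channel for the child
            row = np.concatenate([row, np.zeros(m_total - m)])
        ch_haps = _draw_haplotypes(rng_contam, 1, params)[0]
        state = _state_from_haps(*ch_haps)
        zc = (row[causal_idx] - 2 * p) / np.sqrt(2 * p * (1 - p))
        liab = params.hla_liability_shifts[state] + zc @ betas + rng_contam.normal()
        dq_row = _dq_table(np.array([iid], dtype=object), ch_haps[None, :]).iloc[0].to_dict()
        _append(iid, row, state, liab, int(liab > threshold), dq_row, "parent_offspring", iids[src])

    if params.n_ancestry_outliers > 0:
        fst = params.ancestry_fst
        a = freqs * (1 - fst) / fst
        b = (1 - freqs) * (1 - fst) / fst
        drifted = rng_contam.beta(a, b)
        for k in range(params.n_ancestry_outliers):
            iid = f"ANC{k:03d}"
            row = rng_contam.binomial(2, drifted).astype(float)
            if m_total > m:
                row = np.concatenate([row, np.zeros(m_total - m)])
            oh = _draw_haplotypes(rng_contam, 1, params)[0]
            state = _state_from_haps(*oh)
            zo = (row[causal_idx] - 2 * p) / np.sqrt(2 * p * (1 - p))
            liab = params.hla_liability_shifts[state] + zo @ betas + rng_contam.normal()
            dq_row = _dq_table(np.array([iid], dtype=object), oh[None, :]).iloc[0].to_dict()
            _append(iid, row, state, liab, int(liab > threshold), dq_row, "ancestry_outlier", None)

    if extra_dos:
        dosages = np.vstack([dosages, np.array(extra_dos)])
        individuals = pd.concat([individuals, pd.DataFrame(extra_ind)], ignore_index=True)
        dq = pd.concat([dq, pd.DataFrame(extra_dq)[dq.columns]], ignore_index=True)
        liability = np.concatenate([liability, extra_liab])
        states = np.concatenate([states, np.array(extra_state, dtype=object)])

    # --- missingness last, over the whole final matrix ---
    if params.missing_rate > 0:
        mask = rng_miss.random(dosages.shape) < params.missing_rate
        dosages = dosages.copy()
        dosages[mask] = np.nan

    genotypes = GenotypeMatrix(dosages, variants, individuals)
    causal = pd.DataFrame(
        {"variant_id": variants["id"].to_numpy()[causal_idx], "beta": betas, "freq": p}
    )
    contaminants = pd.DataFrame(contam_rows, columns=["iid", "kind", "source_iid"])
    return Cohort(
        genotypes=genotypes,
        dq_alleles=dq,
        true_liability=liability,
        heterodimer_state=states,
        causal_effects=causal,
        contaminants=contaminants,
        params=params,
    )


def simulate_cohort_pair(
    params: SimParams,
    n_validation: int | None = None,
    seed: int | None = None,
    drift_fst: float = 0.01,
) -> tuple[Cohort, Cohort]:
    """A training cohort and an external-validation cohort sharing the
    same causal architecture, with a small Fst-style allele-frequency
    drift between them (emulating training in one population and
    validating in another)."""
    if seed is None:
        seed = params.seed
    ss = np.random.SeedSequence(seed)
    s_arch, s_train, s_valid, s_drift = ss.spawn(4)

    arch_seed = int(s_arch.generate_state(1)[0] % (2**31 - 1))
    arch = draw_architecture(params, arch_seed)

    train_seed = int(s_train.generate_state(1)[0] % (2**31 - 1))
    train = simulate_cohort(params, seed=train_seed, architecture=arch, iid_prefix="TR")

    if drift_fst > 0:
        rng = np.random.default_rng(s_drift)
        p = arch["freqs"]
        a = p * (1 - drift_fst) / drift_fst
        b = (1 - p) * (1 - drift_fst) / drift_fst
        drifted = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
        arch_valid = dict(arch, freqs=drifted)
    else:
        arch_valid = arch
    vparams = replace(params, n_individuals=n_validation or params.n_individuals)
    valid_seed = int(s_valid.generate_state(1)[0] % (2**31 - 1))
    valid = simulate_cohort(vparams, seed=valid_seed, architecture=arch_valid, iid_prefix="VA")
    return train, valid


def write_cohort(cohort: Cohort, prefix, format: str = "plink-bed") -> None:
    """Write genotypes (PLINK triple or dosage TSV) plus the DQ-allele TSV."""
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "plink-bed":
        write_plink(cohort.genotypes, prefix)
    elif format == "dosage-tsv":
        write_dosage_tsv(cohort.genotypes, prefix)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'plink-bed' or 'dosage-tsv'")
    cohort.dq_alleles.to_csv(f"{prefix}.dq.tsv", sep="\t", index=False)
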