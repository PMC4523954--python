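"""Celiac-disease risk heterodimer typing from unphased HLA-DQ alleles.

The HLA-DQ heterodimers conferring celiac risk are encoded by specific
DQA1/DQB1 allele pairs:

* DQ2.5 — DQA1*05 with DQB1*02 (the dominant risk heterodimer),
* DQ2.2 — DQA1*02 with DQB1*02,
* DQ8   — DQA1*03 with DQB1*03:02.

Calling is presence-based on unphased genotypes: cis/trans phase is not
resolved, so a trans-encoded DQ2.5 (DQA1*05 and DQB1*02 on opposite
haplotypes) counts as DQ2.5-positive.  The DQ2.5 copy number is the
minimum of the per-gene risk-allele counts, matching the convention that
homozygosity means two copies of both DQA1*05 and DQB1*02.

Two scalar risk scores are derived per individual:

* ``dq25_zygosity`` — the DQ2.5 copy number (0, 1, or 2);
* ``haplotype_risk_code`` — a 3-level code: 0 (low) for no risk
  heterodimer, 2 (high) for DQ2.5-homozygous or DQ2.5-heterozygous
  together with DQ2.2, and 1 (medium) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "DQGenotype",
    "HeterodimerProfile",
    "infer_heterodimer_profile",
    "haplotype_risk_code",
    "dq25_zygosity",
    "type_cohort",
    "read_dq_alleles",
]


def _family(allele: str) -> str:
    """Two-digit allele family: '05:01' -> '05', '05' -> '05'."""
    allele = str(allele).strip()
    fam = allele.split(":")[0]
    if not fam or not fam.isdigit():
        raise ValueError(f"malformed HLA allele label: {allele!r}")
    return fam.zfill(2)


def _protein(allele: str) -> str:
    """Two-field label when available ('03:02'), else the family."""
    allele = str(allele).strip()
    parts = allele.split(":")
    if len(parts) >= 2:
        return f"{_family(allele)}:{parts[1]}"
    return _family(allele)


@dataclass(frozen=True)
class DQGenotype:
    """Unphased pair of DQA1 and pair of DQB1 allele labels."""

    dqa1: tuple[str, str]
    dqb1: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.dqa1) != 2 or len(self.dqb1) != 2:
            raise ValueError("exactly two alleles required per gene")


@dataclass(frozen=True)
class HeterodimerProfile:
    dq25_copies: int
    has_dq22: bool
    has_dq8: bool

    @property
    def states(self) -> frozenset[str]:
        s = set()
        if self.dq25_copies == 2:
            s.add("DQ2.5-hom")
        elif self.dq25_copies == 1:
            s.add("DQ2.5-het")
        if self.has_dq22:
            s.add("DQ2.2")
        if self.has_dq8:
            s.add("DQ8")
        return frozenset(s)


def infer_heterodimer_profile(dq: DQGenotype) -> HeterodimerProfile:
    """Call DQ2.5 / DQ2.2 / DQ8 status from an unphased DQ genotype."""
    a_fams = [_family(a) for a in dq.dqa1]
    b_fams = [_family(b) for b in dq.dqb1]
    b_prot = [_protein(b) for b in dq.dqb1]

    n_a05 = a_fams.count("05")
    n_b02 = b_fams.count("02")
    dq25_copies = min(n_a05, n_b02)
    has_dq22 = "02" in a_fams and n_b02 >= 1
    has_dq8 = "03" in a_fams and "03:02" in b_prot
    return HeterodimerProfile(dq25_copies=dq25_copies, has_dq22=has_dq22, has_dq8=has_dq8)


def haplotype_risk_code(p: HeterodimerProfile) -> int:
    """3-level HLA risk code: 0 low, 1 medium, 2 high.

    High risk: DQ2.5-homozygous, or DQ2.5-heterozygous together with
    DQ2.2.  Low risk: no risk heterodimer at all.  Medium: the rest.
    """
    if not p.states:
        return 0
    if p.dq25_copies == 2 or (p.dq25_copies == 1 and p.has_dq22):
        return 2
    return 1


def dq25_zygosity(p: HeterodimerProfile) -> int:
    """Number of DQ2.5 copies carried (het = 1, hom = 2)."""
    return p.dq25_copies


# ---------------------------------------------------------------------------
# Cohort-level typing
# ---------------------------------------------------------------------------

def read_dq_alleles(path: str | Path) -> pd.DataFrame:
    """Read a DQ-allele TSV: ``IID DQA1_1 DQA1_2 DQB1_1 DQB1_2``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["IID", "DQA1_1", "DQA1_2", "DQB1_1", "DQB1_2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"DQ allele table missing columns: {missing}")
    return df[required]


def type_cohort(dq_alleles: pd.DataFrame) -> pd.DataFrame:
    """Per-individual heterodimer profile plus both HLA risk scores.

    Returns a DataFrame indexed like the input with columns
    ``iid, dq25_copies, has_dq22, has_dq8, risk_code, zygosity``.
    """
    rows = []
    for rec in dq_alleles.itertuples(index=False):
        dq = DQGenotype(dqa1=(rec.DQA1_1, rec.DQA1_2), dqb1=(rec.DQB1_1, rec.DQB1_2))
        p = infer_heterodimer_profile(dq)
        rows.append(
            {
                "iid": rec.IID,
                "dq25_copies": p.dq25_copies,
                "has_dq22": p.has_dq22,
                "has_dq8": p.has_dq8,
                "risk_code": haplotype_risk_code(p),
                "zygosity": dq25_zygosity(p),
            }
        )
    return pd.DataFrame(rows)
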