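"""Apply portable risk-score files to genotype matrices.

Follows plink ``--score`` semantics with summation (not averaging):
per variant, if the score file's effect allele matches the genotype
matrix's counted allele the dosage is used as-is; if it matches the
other allele the dosage is flipped to 2 - d; otherwise the variant is
dropped with a warning.  Variants absent from the genotype data are
dropped and tallied in a coverage report.  Missing dosages are replaced
by twice the effect-allele frequency observed in the data (the expected
dosage), keeping scores comparable across individuals with different
call rates.  The final score is sum(weight x aligned dosage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["RiskScoreFile", "CoverageReport", "load_risk_score", "apply_risk_score"]

logger = logging.getLogger(__name__)

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class RiskScoreFile:
    """Ordered (variant ID, effect allele, weight) records."""

    entries: pd.DataFrame  # columns: variant_id, effect_allele, weight
    name: str = "risk-score"

    def __post_init__(self) -> None:
        required = ["variant_id", "effect_allele", "weight"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise ValueError(f"risk score table missing columns: {missing}")
        if self.entries["variant_id"].duplicated().any():
            dups = self.entries.loc[self.entries["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicated variant IDs in score file: {list(dups[:5])}")
        if not np.isfinite(self.entries["weight"].to_numpy(dtype=float)).all():
            raise ValueError("score weights must be finite")
        self.entries = self.entries.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.entries)

    def save(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False, header=False)


@dataclass
class CoverageReport:
    n_entries: int
    n_used: int
    absent: list = field(default_factory=list)
    allele_mismatch: list = field(default_factory=list)
    ambiguous: list = field(default_factory=list)


def load_risk_score(path: str | Path, name: str | None = None) -> RiskScoreFile:
    """Parse a whitespace-delimited 3-column (ID, effect allele, weight) file."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            vid, allele, weight = parts
            try:
                w = float(weight)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric weight {weight!r}") from exc
            rows.append({"variant_id": vid, "effect_allele": allele, "weight": w})
    if not rows:
        raise ValueError(f"{path}: empty score file")
    entries = pd.DataFrame(rows)
    return RiskScoreFile(entries=entries, name=name or path.stem)


def apply_risk_score(rsf: RiskScoreFile, g: GenotypeMatrix) -> tuple[pd.DataFrame, CoverageReport]:
    """Score each individual; returns (scores table, coverage report).

    Scores table columns: ``iid, score, n_variants_used``.
    """
    var_index = pd.Index(g.variants["id"])
    pos = var_index.get_indexer(rsf.entries["variant_id"])
    report = CoverageReport(n_entries=len(rsf), n_used=0)

    total = np.zeros(g.n_individuals)
    n_used = 0
    for entry, j in zip(rsf.entries.itertuples(index=False), pos):
        if j < 0:
            report.absent.append(entry.variant_id)
            continue
        a1 = str(g.variants["a1"].iloc[j])
        a2 = str(g.variants["a2"].iloc[j])
        if frozenset((a1.upper(), a2.upper())) in _AMBIGUOUS:
            report.ambiguous.append(entry.variant_id)
            logger.warning("ambiguous (palindromic) alleles at %s; matching as-is", entry.variant_id)
        allele = str(entry.effect_allele)
        col = g.dosages[:, j]
        if allele == a1:
            aligned = col
        elif allele == a2:
            aligned = 2.0 - col
        else:
            report.allele_mismatch.append(entry.variant_id)
            logger.warning(
                "effect allele %s at %s matches neither %s nor %s; variant dropped",
                allele, entry.variant_id, a1, a2,
            )
            continue
        called = ~np.isnan(aligned)
        eaf = aligned[called].mean() / 2.0 if called.any() else 0.0
        filled = np.where(called, aligned, 2.0 * eaf)
        total += entry.weight * filled
        n_used += 1

    if n_used == 0:
        raise ValueError(f"no variants of score {rsf.name!r} overlap the genotype data")
    report.n_used = n_used
    scores = pd.DataFrame({"iid": g.iids, "score": total, "n_variants_used": n_used})
    return scores, report
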