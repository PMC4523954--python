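"""Genotype container and PLINK / dosage-TSV input-output.

The central in-memory object is :class:`GenotypeMatrix`: an individuals x
variants matrix of minor-allele dosages in {0, 1, 2} with NaN for missing
calls, plus variant metadata (ID, chromosome, 1-based position, counted
allele ``a1`` and other allele ``a2``) and per-individual metadata
(ID, sex, phenotype).

Files are read and written in two dialects:

* PLINK bed/bim/fam (bed v1.0 magic ``6c 1b 01``, SNP-major 2-bit codes);
  the fam phenotype column uses the PLINK convention 1=control, 2=case,
  0/-9 = missing.
* a plain dosage TSV with header ``IID <variantID...>`` and values
  0/1/2/NA, plus a sidecar ``<prefix>.variants.tsv`` carrying alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "write_plink",
    "read_plink",
    "write_dosage_tsv",
    "read_dosage_tsv",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit bed codes (per pair of bits, little-endian within a byte), keyed by
# dosage of allele1 (the counted/minor allele):
#   00 -> hom a1 (dosage 2), 10 -> het (1), 11 -> hom a2 (0), 01 -> missing
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass
class GenotypeMatrix:
    """Individuals x variants minor-allele dosage matrix with metadata.

    Parameters
    ----------
    dosages
        Float array of shape (n_individuals, n_variants); entries in
        {0, 1, 2} or NaN for a missing call.
    variants
        DataFrame with columns ``id, chrom, pos, a1, a2`` (a1 is the
        counted allele); variant IDs must be unique.
    individuals
        DataFrame with columns ``iid, sex, phenotype`` (phenotype 1 =
        case, 0 = control, -1 unknown); IIDs must be unique.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        n, m = self.dosages.shape
        if len(self.individuals) != n:
            raise ValueError("individuals table does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variants table does not match dosage columns")
        if self.variants["id"].duplicated().any():
            raise ValueError("variant IDs must be unique")
        if self.individuals["iid"].duplicated().any():
            raise ValueError("individual IDs must be unique")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")
        self.variants = self.variants.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def iids(self) -> np.ndarray:
        return self.individuals["iid"].to_numpy()

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def phenotype_array(self) -> np.ndarray:
        return self.individuals["phenotype"].to_numpy(dtype=int)

    # -- per-variant summary statistics ------------------------------------
    def allele1_freq(self) -> np.ndarray:
        """Frequency of the counted allele among called genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele1_freq()
        return np.minimum(f, 1.0 - f)

    def variant_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def individual_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    # -- subsetting --------------------------------------------------------
    def subset(
        self,
        individual_mask: np.ndarray | None = None,
        variant_mask: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        d = self.dosages
        ind = self.individuals
        var = self.variants
        if individual_mask is not None:
            individual_mask = np.asarray(individual_mask)
            d = d[individual_mask, :]
            ind = ind.iloc[np.flatnonzero(individual_mask)] if individual_mask.dtype == bool else ind.iloc[individual_mask]
        if variant_mask is not None:
            variant_mask = np.asarray(variant_mask)
            d = d[:, variant_mask]
            var = var.iloc[np.flatnonzero(variant_mask)] if variant_mask.dtype == bool else var.iloc[variant_mask]
        return GenotypeMatrix(d.copy(), var.copy(), ind.copy())

    def select_individuals(self, iids) -> "GenotypeMatrix":
        pos = pd.Index(self.individuals["iid"]).get_indexer(list(iids))
        if (pos < 0).any():
            missing = [i for i, p in zip(iids, pos) if p < 0]
            raise KeyError(f"unknown individual IDs: {missing[:5]}")
        return self.subset(individual_mask=pos)

    def select_variants(self, ids) -> "GenotypeMatrix":
        pos = pd.Index(self.variants["id"]).get_indexer(list(ids))
        if (pos < 0).any():
            missing = [i for i, p in zip(ids, pos) if p < 0]
            raise KeyError(f"unknown variant IDs: {missing[:5]}")
        return self.subset(variant_mask=pos)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def _phenotype_to_fam(pheno: int) -> int:
    # internal 0/1 -> fam 1=control, 2=case; anything else -> -9 (missing)
    if pheno == 1:
        return 2
    if pheno == 0:
        return 1
    return -9


def _fam_to_phenotype(code: float) -> int:
    if code == 2:
        return 1
    if code == 1:
        return 0
    return -1


def write_plink(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a bed/bim/fam triple (bed v1.0, SNP-major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = g.n_individuals

    fam = pd.DataFrame(
        {
            "fid": g.individuals["iid"],
            "iid": g.individuals["iid"],
            "father": 0,
            "mother": 0,
            "sex": g.individuals.get("sex", pd.Series([0] * n)),
            "phenotype": [_phenotype_to_fam(p) for p in g.individuals["phenotype"]],
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": g.variants["chrom"],
            "id": g.variants["id"],
            "cm": 0,
            "pos": g.variants["pos"],
            "a1": g.variants["a1"],
            "a2": g.variants["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    # SNP-major: one row of ceil(n/4) bytes per variant, 2 bits per sample,
    # sample index increasing from the least significant bit pair.
    codes = np.full(g.dosages.shape, 0b01, dtype=np.uint8)  # missing
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[g.dosages == dosage] = code
    n_bytes = (n + 3) // 4
    padded = np.zeros((g.n_variants, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(g.n_variants, n_bytes, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a bed/bim/fam triple written in SNP-major bed v1.0 layout."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major bed v1.0 file")
    body = raw[3:]
    n_bytes = (n + 3) // 4
    if body.size != m * n_bytes:
        raise ValueError("bed payload size inconsistent with fam/bim")
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T

    individuals = pd.DataFrame(
        {
            "iid": fam["iid"].astype(str),
            "sex": fam["sex"],
            "phenotype": [_fam_to_phenotype(p) for p in fam["phenotype"]],
        }
    )
    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(dosages, variants, individuals)


# ---------------------------------------------------------------------------
# Dosage TSV dialect
# ---------------------------------------------------------------------------

def write_dosage_tsv(g: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.dosage.tsv`` (IID + one column per variant) and a
    ``<prefix>.variants.tsv`` sidecar with alleles and phenotype-free
    variant metadata; phenotypes go to ``<prefix>.pheno.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(g.dosages, columns=g.variant_ids)
    df.insert(0, "IID", g.iids)
    df.to_csv(f"{prefix}.dosage.tsv", sep="\t", index=False, na_rep="NA", float_format="%g")
    g.variants.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)
    g.individuals.to_csv(f"{prefix}.pheno.tsv", sep="\t", index=False)


def read_dosage_tsv(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    df = pd.read_csv(f"{prefix}.dosage.tsv", sep="\t", dtype={"IID": str})
    variants = pd.read_csv(f"{prefix}.variants.tsv", sep="\t", dtype={"id": str, "a1": str, "a2": str})
    individuals = pd.read_csv(f"{prefix}.pheno.tsv", sep="\t", dtype={"iid": str})
    dosages = df.drop(columns="IID").to_numpy(dtype=float)
    if not (df["IID"].to_numpy() == individuals["iid"].to_numpy()).all():
        raise ValueError("dosage and phenotype files disagree on individual order")
    if list(df.columns[1:]) != list(variants["id"]):
        raise ValueError("dosage and variant files disagree on variant order")
    return GenotypeMatrix(dosages, variants, individuals)
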