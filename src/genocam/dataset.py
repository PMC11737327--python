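"""Core genotype containers.

Genotypes are coded by minor-allele dosage: 0 = AA (major homozygote),
1 = Aa (heterozygote), 2 = aa (minor homozygote), -1 = missing. A dataset
is a samples x SNPs matrix of these codes plus case/control labels and
per-SNP metadata; the SNP column order is canonical and shared by every
downstream image layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CONTROL = 0
CASE = 1

_LABEL_NAMES = {CONTROL: "control", CASE: "case"}
_LABEL_CODES = {v: k for k, v in _LABEL_NAMES.items()}

VALID_CODES = frozenset({-1, 0, 1, 2})


class ValidationError(ValueError):
    """Raised when a spec/dataset violates its invariants; names the field."""


@dataclass
class SnpSpec:
    """Per-SNP metadata: identity, position, allele frequency and planted effect.

    ``rr_het``/``rr_hom`` are relative risks of the heterozygote and minor
    homozygote versus the major homozygote; non-risk SNPs have both equal to 1.
    """

    snp_id: str
    chromosome: str = "1"
    position: int = 0
    maf: float = 0.25
    is_risk: bool = False
    rr_het: float = 1.0
    rr_hom: float = 1.0
    major_allele: str = "A"
    minor_allele: str = "C"

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.rr_het < 0 or self.rr_hom < 0:
            raise ValidationError("relative risks must be >= 0")
        if not self.is_risk and (self.rr_het != 1.0 or self.rr_hom != 1.0):
            raise ValidationError(
                f"non-risk SNP {self.snp_id} must have rr_het = rr_hom = 1"
            )


@dataclass
class GenotypeDataset:
    """Samples x SNPs genotype matrix with labels and SNP metadata."""

    sample_ids: list[str]
    labels: np.ndarray  # int8, CONTROL/CASE per sample
    snps: list[SnpSpec]
    genotypes: np.ndarray  # int8 (n_samples, n_snps), values in {-1,0,1,2}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"sample_ids length {len(self.sample_ids)} != {n} matrix rows"
            )
        if self.labels.shape != (n,):
            raise ValidationError("labels length does not match matrix rows")
        if len(self.snps) != m:
            raise ValidationError(f"snps length {len(self.snps)} != {m} matrix columns")
        if not np.isin(self.labels, [CONTROL, CASE]).all():
            raise ValidationError("labels must be 0 (control) or 1 (case)")
        if not np.isin(self.genotypes, [-1, 0, 1, 2]).all():
            raise ValidationError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def case_mask(self) -> np.ndarray:
        return self.labels == CASE

    @property
    def control_mask(self) -> np.ndarray:
        return self.labels == CONTROL

    def label_names(self) -> list[str]:
        return [_LABEL_NAMES[int(v)] for v in self.labels]

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeDataset":
        """Return a new dataset restricted to the given sample/SNP indices."""
        sample_idx = (
            np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        )
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            sample_ids=[self.sample_ids[i] for i in sample_idx],
            labels=self.labels[sample_idx],
            snps=[replace(self.snps[j]) for j in snp_idx],
            genotypes=self.genotypes[np.ix_(sample_idx, snp_idx)],
        )

    # ---- internal TSV dialect -------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the dataset as TSV: sample_id, label, then one column per SNP."""
        df = pd.DataFrame(self.genotypes, columns=self.snp_ids)
        df.insert(0, "label", self.label_names())
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, snps: Sequence[SnpSpec] | None = None):
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        snp_ids = list(df.columns[2:])
        labels = np.array([_LABEL_CODES[v] for v in df["label"]], dtype=np.int8)
        if snps is None:
            snps = [SnpSpec(snp_id=sid) for sid in snp_ids]
        else:
            snps = list(snps)
            if [s.snp_id for s in snps] != snp_ids:
                raise ValidationError("snps metadata does not match TSV columns")
        return cls(
            sample_ids=list(df["sample_id"]),
            labels=labels,
            snps=snps,
            genotypes=df[snp_ids].to_numpy(dtype=np.int8),
        )


def label_name(code: int) -> str:
    return _LABEL_NAMES[int(code)]


def label_code(name: str) -> int:
    return _LABEL_CODES[name]
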