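"""Quality control and allelic association pre-screen.

Implements the standard GWAS QC battery (per-individual and per-SNP
missingness, minor-allele frequency, Hardy-Weinberg equilibrium) and the
1-df allelic chi-square test on the 2x2 minor/major x case/control allele
table, without continuity correction (the classic PLINK ``--assoc`` form).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .dataset import GenotypeDataset, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    snp_id: str
    chi2_stat: float
    df: int
    p_value: float
    monomorphic: bool = False


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """1-df chi-square goodness of fit of genotype counts to Hardy-Weinberg.

    The expectation uses the sample allele frequency q = (2*n_aa + n_Aa) / 2n.
    Returns ``(chi2, p)``; exact HWE proportions give chi2 = 0, p = 1.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValidationError("genotype counts must be >= 0")
    n = counts.sum()
    if n == 0:
        raise ValidationError("all genotype counts are zero")
    q = (2 * counts[2] + counts[1]) / (2 * n)
    p = 1.0 - q
    expected = n * np.array([p * p, 2 * p * q, q * q])
    # monomorphic SNP: expectation puts all mass on one cell, fit is exact
    nz = expected > 0
    stat = float(((counts[nz] - expected[nz]) ** 2 / expected[nz]).sum())
    return stat, float(chi2_dist.sf(stat, df=1))


def _chi2_2x2(table: np.ndarray) -> float:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / n
    if (expected == 0).any():
        return 0.0
    return float(((table - expected) ** 2 / expected).sum())


def allelic_assoc_test(d: GenotypeDataset, snp_index: int) -> AssociationResult:
    """Allelic 1-df chi-square for one SNP.

    Genotype code g contributes g minor and 2-g major alleles; missing
    genotypes are dropped. A SNP monomorphic after dropping missing has an
    undefined statistic and is reported as chi2 = 0, p = 1 with a flag.
    """
    snp = d.snps[snp_index]
    g = d.genotypes[:, snp_index]
    table = np.zeros((2, 2), dtype=float)  # rows case/control, cols minor/major
    for row, mask in ((0, d.case_mask), (1, d.control_mask)):
        gv = g[mask]
        gv = gv[gv >= 0].astype(float)
        table[row, 0] = gv.sum()
        table[row, 1] = (2 - gv).sum()
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise ValidationError(f"SNP {snp.snp_id}: a label group has no called genotypes")
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        logger.warning("SNP %s is monomorphic; association undefined", snp.snp_id)
        return AssociationResult(snp.snp_id, 0.0, 1, 1.0, monomorphic=True)
    stat = _chi2_2x2(table)
    return AssociationResult(snp.snp_id, stat, 1, float(chi2_dist.sf(stat, df=1)))


def assoc_scan(d: GenotypeDataset) -> list[AssociationResult]:
    """Allelic association test for every SNP, in dataset order."""
    if not d.case_mask.any() or not d.control_mask.any():
        raise ValidationError("association scan needs both cases and controls")
    return [allelic_assoc_test(d, j) for j in range(d.n_snps)]


def prescreen(results: list[AssociationResult], p_threshold: float) -> np.ndarray:
    """Indices of SNPs with p <= threshold, original order preserved."""
    if not (0.0 < p_threshold <= 1.0):
        raise ValidationError(f"p_threshold must be in (0, 1], got {p_threshold}")
    return np.array(
        [j for j, r in enumerate(results) if r.p_value <= p_threshold], dtype=int
    )


@dataclass
class QcLog:
    """Counts removed by each filter, in application order."""

    individuals_missing: int = 0
    snps_missing: int = 0
    snps_maf: int = 0
    snps_hwe: int = 0
    steps: list[str] = field(default_factory=list)


def _snp_stats(genotypes: np.ndarray):
    """Per-SNP call counts and minor allele frequency over called genotypes."""
    called = genotypes >= 0
    n_called = called.sum(axis=0)
    minor = np.where(called, genotypes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n_called > 0, minor / (2.0 * n_called), 0.0)
    return n_called, maf


def qc_filter(
    d: GenotypeDataset,
    snp_miss_max: float = 0.05,
    ind_miss_max: float = 0.05,
    maf_min: float = 0.05,
    hwe_p_min: float = 0.01,
) -> tuple[GenotypeDataset, QcLog]:
    """Apply the standard QC battery and return the filtered dataset plus a log.

    Filter order: (1) individuals by missing fraction, then per SNP:
    (2) missingness, (3) MAF computed on all remaining samples,
    (4) HWE computed on controls only (cases may deviate through association).
    """
    log = QcLog()

    ind_miss = (d.genotypes < 0).mean(axis=1)
    keep_ind = ind_miss <= ind_miss_max
    log.individuals_missing = int((~keep_ind).sum())
    log.steps.append(f"individual missingness > {ind_miss_max}: removed {log.individuals_missing}")
    if not keep_ind.any():
        raise ValidationError("QC removed every individual")
    d = d.subset(sample_idx=np.flatnonzero(keep_ind))

    g = d.genotypes
    snp_miss = (g < 0).mean(axis=0)
    keep = snp_miss <= snp_miss_max
    log.snps_missing = int((~keep).sum())

    _, maf = _snp_stats(g)
    maf_fail = maf < maf_min
    log.snps_maf = int((maf_fail & keep).sum())
    keep &= ~maf_fail

    controls = g[d.control_mask]
    hwe_fail = np.zeros(d.n_snps, dtype=bool)
    for j in np.flatnonzero(keep):
        gj = controls[:, j]
        gj = gj[gj >= 0]
        if gj.size == 0:
            continue
        counts = np.bincount(gj, minlength=3)
        _, p = hwe_test(*counts[:3])
        hwe_fail[j] = p < hwe_p_min
    log.snps_hwe = int((hwe_fail & keep).sum())
    keep &= ~hwe_fail

    log.steps.append(f"SNP missingness > {snp_miss_max}: removed {log.snps_missing}")
    log.steps.append(f"MAF < {maf_min}: removed {log.snps_maf}")
    log.steps.append(f"HWE p < {hwe_p_min} (controls): removed {log.snps_hwe}")
    for step in log.steps:
        logger.info("qc_filter: %s", step)

    if not keep.any():
        raise ValidationError("QC removed every SNP")
    return d.subset(snp_idx=np.flatnonzero(keep)), log
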