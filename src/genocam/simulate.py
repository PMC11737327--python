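"""Case/control genotype simulator with planted risk SNPs.

Controls are drawn from Hardy-Weinberg genotype frequencies at each SNP's
minor-allele frequency q: P(AA, Aa, aa) = ((1-q)^2, 2q(1-q), q^2). Cases use
the retrospective distribution P(g | case) proportional to P(g) * RR(g) with
RR(AA) = 1, the standard rare-disease approximation for case/control designs.
Risk effects default to a multiplicative model (rr_hom = rr_het^2), the model
family used by PLINK-style simulators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import CASE, CONTROL, GenotypeDataset, SnpSpec, ValidationError


@dataclass
class SimulationSpec:
    """Parameters of one simulated case/control set.

    Defaults reproduce the reference simulation design: 4,000 cases + 4,000
    controls over 2,000 biallelic SNPs of which 200 carry disease risk.
    """

    n_cases: int = 4000
    n_controls: int = 4000
    n_null_snps: int = 1800
    n_risk_snps: int = 200
    maf_low: float = 0.05
    maf_high: float = 0.5
    rr_het: float = 1.5
    rr_hom: float | None = None  # None -> multiplicative: rr_het ** 2
    missing_rate: float = 0.0
    risk_positions: str = "scattered"  # or "block": one contiguous gene-like locus
    seed: int = 0

    def __post_init__(self) -> None:
        if self.risk_positions not in ("scattered", "block"):
            raise ValidationError(
                f"risk_positions must be 'scattered' or 'block', got {self.risk_positions!r}"
            )
        for name in ("n_cases", "n_controls", "n_null_snps", "n_risk_snps"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValidationError(
                f"need 0 < maf_low <= maf_high <= 0.5, got "
                f"maf_low={self.maf_low}, maf_high={self.maf_high}"
            )
        if self.rr_het < 0:
            raise ValidationError(f"rr_het must be >= 0, got {self.rr_het}")
        if self.rr_hom is not None and self.rr_hom < 0:
            raise ValidationError(f"rr_hom must be >= 0, got {self.rr_hom}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError(
                f"missing_rate must be in [0, 1), got {self.missing_rate}"
            )

    @property
    def effective_rr_hom(self) -> float:
        return self.rr_het**2 if self.rr_hom is None else self.rr_hom

    @property
    def n_snps(self) -> int:
        return self.n_null_snps + self.n_risk_snps

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


def hwe_genotype_probs(maf: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities, shape (..., 3) for codes 0/1/2."""
    q = np.asarray(maf, dtype=float)
    p = 1.0 - q
    return np.stack([p * p, 2.0 * p * q, q * q], axis=-1)


def case_genotype_probs(maf: np.ndarray, rr_het: np.ndarray, rr_hom: np.ndarray):
    """Retrospective case genotype distribution: P(g) * RR(g), normalized."""
    probs = hwe_genotype_probs(maf)
    rr = np.stack([np.ones_like(np.asarray(rr_het, dtype=float)), rr_het, rr_hom], axis=-1)
    w = probs * rr
    return w / w.sum(axis=-1, keepdims=True)


def _draw_categorical(probs: np.ndarray, n_rows: int, rng: np.random.Generator):
    """Draw n_rows samples per SNP from per-SNP 3-way distributions.

    probs: (n_snps, 3). Returns int8 matrix (n_rows, n_snps).
    """
    cum = np.cumsum(probs, axis=-1)  # (n_snps, 3)
    u = rng.random((n_rows, probs.shape[0]))
    geno = (u[..., None] > cum[None, :, :-1]).sum(axis=-1)
    return geno.astype(np.int8)


def simulate_dataset(spec: SimulationSpec) -> GenotypeDataset:
    """Generate one case/control genotype set per the simulation spec.

    Deterministic for a fixed ``spec.seed``: the same spec always yields a
    bit-identical dataset. By default risk SNPs are scattered uniformly over
    the SNP order (independent loci); ``risk_positions="block"`` instead
    places them in one contiguous run, emulating a localized risk gene.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_snps
    if m == 0 or spec.n_samples == 0:
        raise ValidationError("cannot simulate an empty dataset (no SNPs or samples)")

    mafs = rng.uniform(spec.maf_low, spec.maf_high, size=m)
    if spec.risk_positions == "block":
        # one contiguous run of risk loci, emulating a risk gene region
        start = int(rng.integers(0, m - spec.n_risk_snps + 1)) if m > spec.n_risk_snps else 0
        risk_idx = np.arange(start, start + spec.n_risk_snps)
    else:
        risk_idx = rng.choice(m, size=spec.n_risk_snps, replace=False)
    is_risk = np.zeros(m, dtype=bool)
    is_risk[risk_idx] = True
    rr_het = np.where(is_risk, spec.rr_het, 1.0)
    rr_hom = np.where(is_risk, spec.effective_rr_hom, 1.0)

    control_probs = hwe_genotype_probs(mafs)
    case_probs = case_genotype_probs(mafs, rr_het, rr_hom)

    g_cases = _draw_categorical(case_probs, spec.n_cases, rng)
    g_controls = _draw_categorical(control_probs, spec.n_controls, rng)
    genotypes = np.vstack([g_cases, g_controls])

    if spec.missing_rate > 0:
        miss = rng.random(genotypes.shape) < spec.missing_rate
        genotypes[miss] = -1

    width = max(4, len(str(m)))
    snps = [
        SnpSpec(
            snp_id=f"snp{j + 1:0{width}d}",
            chromosome="1",
            position=(j + 1) * 10_000,
            maf=float(mafs[j]),
            is_risk=bool(is_risk[j]),
            rr_het=float(rr_het[j]),
            rr_hom=float(rr_hom[j]),
        )
        for j in range(m)
    ]
    labels = np.concatenate(
        [np.full(spec.n_cases, CASE, dtype=np.int8),
         np.full(spec.n_controls, CONTROL, dtype=np.int8)]
    )
    sample_ids = [f"case{i + 1:05d}" for i in range(spec.n_cases)] + [
        f"ctrl{i + 1:05d}" for i in range(spec.n_controls)
    ]
    return GenotypeDataset(
        sample_ids=sample_ids, labels=labels, snps=snps, genotypes=genotypes
    )
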