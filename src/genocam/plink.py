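"""PLINK text-format (.ped/.map) reader and writer.

Only the whitespace-delimited text dialect is supported: a .map row is
``chrom snp_id cm position`` and a .ped row is the six leading columns
(FID IID PAT MAT SEX PHENO, phenotype 1 = control / 2 = case) followed by
two allele letters per SNP. Missing genotypes are "0 0" on disk and code -1
in memory. Allele letters map to dosage codes by the majority allele per
SNP (ties broken lexicographically, so round trips are stable). Note that a
SNP whose in-sample minor-allele count exceeds half the called alleles
re-anchors to the observed majority on read; write-read round trips are
exact whenever the sample majority matches the generating major allele.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import numpy as np

from .dataset import CASE, CONTROL, GenotypeDataset, SnpSpec, ValidationError


class PlinkParseError(ValidationError):
    pass


def write_plink_text(d: GenotypeDataset, ped_path: str | Path, map_path: str | Path) -> None:
    ped_path, map_path = Path(ped_path), Path(map_path)
    with open(map_path, "w") as fh:
        for s in d.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")

    majors = np.array([s.major_allele for s in d.snps])
    minors = np.array([s.minor_allele for s in d.snps])
    pheno = {CONTROL: "1", CASE: "2"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(d.sample_ids):
            g = d.genotypes[i]
            a1 = np.where(g >= 1, minors, majors)
            a2 = np.where(g == 2, minors, majors)
            a1 = np.where(g < 0, "0", a1)
            a2 = np.where(g < 0, "0", a2)
            pairs = " ".join(f"{x} {y}" for x, y in zip(a1, a2))
            fh.write(f"{sid} {sid} 0 0 0 {pheno[int(d.labels[i])]} {pairs}\n")


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    snps: list[SnpSpec] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PlinkParseError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, snp_id, _cm, pos = parts
            snps.append(SnpSpec(snp_id=snp_id, chromosome=chrom, position=int(pos)))
    m = len(snps)

    sample_ids: list[str] = []
    labels: list[int] = []
    rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PlinkParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields for {m} SNPs, "
                    f"got {len(parts)}"
                )
            sample_ids.append(parts[1])
            pheno = parts[5]
            if pheno not in ("1", "2"):
                raise PlinkParseError(f"{ped_path}:{lineno}: phenotype must be 1 or 2, got {pheno}")
            labels.append(CONTROL if pheno == "1" else CASE)
            alleles = parts[6:]
            rows.append([(alleles[2 * j], alleles[2 * j + 1]) for j in range(m)])

    n = len(rows)
    genotypes = np.full((n, m), -1, dtype=np.int8)
    for j in range(m):
        counts: Counter[str] = Counter()
        for i in range(n):
            for a in rows[i][j]:
                if a != "0":
                    counts[a] += 1
        observed = sorted(counts)
        if len(observed) > 2:
            raise PlinkParseError(
                f"{map_path}: SNP {snps[j].snp_id} has {len(observed)} alleles "
                f"({', '.join(observed)}); only biallelic SNPs are supported"
            )
        if not observed:
            continue  # entirely missing column stays -1
        # majority allele is "major"; lexicographic tie-break keeps round trips stable
        major = max(observed, key=lambda a: (counts[a], a == min(observed)))
        minor = next((a for a in observed if a != major), "C" if major != "C" else "G")
        snps[j].major_allele = major
        snps[j].minor_allele = minor
        for i in range(n):
            a, b = rows[i][j]
            if a == "0" or b == "0":
                continue
            genotypes[i, j] = (a != major) + (b != major)

    return GenotypeDataset(
        sample_ids=sample_ids,
        labels=np.array(labels, dtype=np.int8),
        snps=snps,
        genotypes=genotypes,
    )
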