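"""Genotype-to-image conversion.

Three encoders are provided:

* ``cc`` — color-image conversion: AA -> (0, 0, 255) blue, Aa -> (0, 170, 0)
  green, aa -> (85, 0, 0) dark red; the three numbers are the R, G, B
  channels. Padding (grid cells not backed by a SNP) is black (0, 0, 0), so
  every cell state has a distinct color and the encoding is lossless.
* ``chen`` — grayscale: AA -> 0, Aa -> 154, aa -> 254. Note that AA collides
  with the padding value 0 by construction; this information loss is a
  documented property of the scheme and is preserved faithfully.
* ``yue`` — grayscale over the 10 unordered base-pair genotypes (AA, AC, ...,
  TT), coded 1..10 and scaled by 25 so values span 25..250; padding is 0.
  Laid out with one chromosome per row block.

Layouts map SNP order onto a square pixel grid invertibly; ``side_length``
gives the minimal square side for a SNP count (2,000 SNPs -> 45).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .dataset import GenotypeDataset, ValidationError, label_code, label_name

# ---- encoder tables -----------------------------------------------------

CC_PALETTE: dict[int, tuple[int, int, int]] = {
    0: (0, 0, 255),   # AA: blue
    1: (0, 170, 0),   # Aa: green
    2: (85, 0, 0),    # aa: dark red
}
CC_PADDING: tuple[int, int, int] = (0, 0, 0)

CHEN_PALETTE: dict[int, int] = {0: 0, 1: 154, 2: 254}
CHEN_PADDING: int = 0  # collides with AA; see module docstring

# the 10 unordered base pairs in lexicographic order, coded 1..10, gray = 25*code
YUE_CLASSES: dict[frozenset[str] | str, int] = {}
_PAIRS = ["".join(p) for p in combinations_with_replacement("ACGT", 2)]
YUE_CODES: dict[str, int] = {pair: i + 1 for i, pair in enumerate(_PAIRS)}
YUE_SCALE = 25
YUE_PADDING = 0

ENCODER_CHANNELS = {"cc": 3, "chen": 1, "yue": 1}


def side_length(n_pixels_needed: int) -> int:
    """Smallest integer s with s*s >= n (minimal square image side)."""
    if n_pixels_needed < 1:
        raise ValidationError(f"need at least 1 pixel, got {n_pixels_needed}")
    s = math.isqrt(n_pixels_needed)
    return s if s * s == n_pixels_needed else s + 1


# ---- layouts ------------------------------------------------------------


@dataclass
class LayoutMap:
    """Invertible SNP index -> (row, col) assignment on a side x side grid."""

    side: int
    entries: np.ndarray  # (n_snps, 2) int rows/cols
    padding_mask: np.ndarray  # (side, side) bool, True where no SNP

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=int)
        self.padding_mask = np.asarray(self.padding_mask, dtype=bool)
        n = len(self.entries)
        cells = {tuple(rc) for rc in self.entries}
        if len(cells) != n:
            raise ValidationError("layout entries must be distinct cells")
        if n + int(self.padding_mask.sum()) != self.side**2:
            raise ValidationError("entries + padding cells must tile the grid")

    @property
    def n_snps(self) -> int:
        return len(self.entries)

    def flat_indices(self) -> np.ndarray:
        """Row-major flat position of each SNP's cell."""
        return self.entries[:, 0] * self.side + self.entries[:, 1]

    def snp_grid(self) -> np.ndarray:
        """(side, side) grid of SNP indices, -1 on padding cells."""
        grid = np.full((self.side, self.side), -1, dtype=int)
        grid[self.entries[:, 0], self.entries[:, 1]] = np.arange(self.n_snps)
        return grid

    def to_tsv(self, path: str | Path, snp_ids: Sequence[str]) -> None:
        pd.DataFrame(
            {
                "snp_id": list(snp_ids),
                "row": self.entries[:, 0],
                "col": self.entries[:, 1],
                "side": self.side,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> tuple["LayoutMap", list[str]]:
        df = pd.read_csv(path, sep="\t")
        entries = df[["row", "col"]].to_numpy()
        side = int(df["side"].iloc[0])
        mask = np.ones((side, side), dtype=bool)
        mask[entries[:, 0], entries[:, 1]] = False
        return cls(side=side, entries=entries, padding_mask=mask), list(df["snp_id"])


def layout_end_to_end(n_snps: int, side: int | None = None) -> LayoutMap:
    """Row-major fill: SNP i -> (i // side, i % side); tail cells are padding."""
    if side is None:
        side = side_length(n_snps)
    if side * side < n_snps:
        raise ValidationError(f"side {side} too small for {n_snps} SNPs (need {side_length(n_snps)})")
    idx = np.arange(n_snps)
    entries = np.stack([idx // side, idx % side], axis=1)
    mask = np.ones((side, side), dtype=bool)
    mask[entries[:, 0], entries[:, 1]] = False
    return LayoutMap(side=side, entries=entries, padding_mask=mask)


def min_side_chromosome_rows(chrom_lengths: Sequence[int]) -> int:
    """Smallest s with sum_c ceil(len_c / s) <= s."""
    total = int(sum(chrom_lengths))
    s = side_length(max(total, 1))
    while sum(-(-c // s) for c in chrom_lengths) > s:
        s += 1
    return s


def layout_chromosome_rows(chrom_lengths: Sequence[int], side: int | None = None) -> LayoutMap:
    """Each chromosome starts at column 0 of a fresh row and wraps across rows.

    The remainder of a chromosome's last row is padding, so chromosomes never
    share a row. Raises if the requested side cannot hold all chromosomes,
    naming the minimal feasible side.
    """
    chrom_lengths = [int(c) for c in chrom_lengths]
    if any(c < 0 for c in chrom_lengths):
        raise ValidationError("chromosome lengths must be >= 0")
    minimal = min_side_chromosome_rows(chrom_lengths)
    if side is None:
        side = minimal
    rows_needed = sum(-(-c // side) for c in chrom_lengths)
    if rows_needed > side or side < minimal:
        raise ValidationError(
            f"side {side} infeasible for chromosome lengths {chrom_lengths}; "
            f"minimal feasible side is {minimal}"
        )
    entries = []
    row = 0
    for c in chrom_lengths:
        for i in range(c):
            entries.append((row + i // side, i % side))
        row += -(-c // side) if c else 0
    entries = np.asarray(entries, dtype=int).reshape(-1, 2)
    mask = np.ones((side, side), dtype=bool)
    if len(entries):
        mask[entries[:, 0], entries[:, 1]] = False
    return LayoutMap(side=side, entries=entries, padding_mask=mask)


# ---- images -------------------------------------------------------------


@dataclass
class GenotypeImage:
    """A square pixel grid for one sample: (side, side) or (side, side, 3) uint8."""

    pixels: np.ndarray
    encoder_id: str
    sample_id: str
    label: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.encoder_id not in ENCODER_CHANNELS:
            raise ValidationError(f"unknown encoder_id {self.encoder_id!r}")
        side = self.pixels.shape[0]
        want_channels = ENCODER_CHANNELS[self.encoder_id]
        shape = (side, side, 3) if want_channels == 3 else (side, side)
        if self.pixels.shape != shape:
            raise ValidationError(
                f"{self.encoder_id} image must have shape {shape}, got {self.pixels.shape}"
            )

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @property
    def channels(self) -> int:
        return ENCODER_CHANNELS[self.encoder_id]


def _check_codes(codes: np.ndarray) -> np.ndarray:
    codes = np.asarray(codes)
    if not np.isin(codes, [-1, 0, 1, 2]).all():
        bad = codes[~np.isin(codes, [-1, 0, 1, 2])][0]
        raise ValidationError(f"genotype code {bad} out of range {{-1,0,1,2}}")
    return codes.astype(int)


def encode_cc(genotypes: np.ndarray, layout: LayoutMap, sample_id: str = "", label: int = 0) -> GenotypeImage:
    """Color encoding; missing genotypes render as the padding color (0,0,0)."""
    codes = _check_codes(genotypes)
    if len(codes) != layout.n_snps:
        raise ValidationError(f"{len(codes)} genotypes vs layout of {layout.n_snps} SNPs")
    lut = np.zeros((4, 3), dtype=np.uint8)
    for code, rgb in CC_PALETTE.items():
        lut[code] = rgb
    lut[3] = CC_PADDING  # missing (-1) indexed as 3
    grid = np.zeros((layout.side, layout.side, 3), dtype=np.uint8)
    grid[layout.entries[:, 0], layout.entries[:, 1]] = lut[codes]
    return GenotypeImage(grid, "cc", sample_id, label)


def encode_chen(genotypes: np.ndarray, layout: LayoutMap, sample_id: str = "", label: int = 0) -> GenotypeImage:
    """Chen grayscale encoding; AA (0) is indistinguishable from padding."""
    codes = _check_codes(genotypes)
    if len(codes) != layout.n_snps:
        raise ValidationError(f"{len(codes)} genotypes vs layout of {layout.n_snps} SNPs")
    lut = np.array([CHEN_PALETTE[0], CHEN_PALETTE[1], CHEN_PALETTE[2], CHEN_PADDING], dtype=np.uint8)
    grid = np.zeros((layout.side, layout.side), dtype=np.uint8)
    grid[layout.entries[:, 0], layout.entries[:, 1]] = lut[codes]
    return GenotypeImage(grid, "chen", sample_id, label)


def _yue_class(pair) -> int:
    if pair is None:
        return 0
    a, b = pair
    a, b = a.upper(), b.upper()
    for base in (a, b):
        if base not in "ACGT":
            raise ValidationError(f"invalid base {base!r} in genotype pair")
    return YUE_CODES["".join(sorted((a, b)))]


def encode_yue(pairs: Sequence, layout: LayoutMap, sample_id: str = "", label: int = 0) -> GenotypeImage:
    """Yue grayscale encoding of unordered base pairs; (a,A) == (A,a)."""
    if len(pairs) != layout.n_snps:
        raise ValidationError(f"{len(pairs)} genotypes vs layout of {layout.n_snps} SNPs")
    values = np.array([_yue_class(p) * YUE_SCALE for p in pairs], dtype=np.uint8)
    grid = np.full((layout.side, layout.side), YUE_PADDING, dtype=np.uint8)
    grid[layout.entries[:, 0], layout.entries[:, 1]] = values
    return GenotypeImage(grid, "yue", sample_id, label)


def genotype_pairs(d: GenotypeDataset, sample_index: int) -> list[tuple[str, str] | None]:
    """Base-pair representation of one sample using each SNP's allele letters."""
    out: list[tuple[str, str] | None] = []
    for j, s in enumerate(d.snps):
        g = int(d.genotypes[sample_index, j])
        if g < 0:
            out.append(None)
        elif g == 0:
            out.append((s.major_allele, s.major_allele))
        elif g == 1:
            out.append((s.major_allele, s.minor_allele))
        else:
            out.append((s.minor_allele, s.minor_allele))
    return out


_CC_DECODE = {rgb: code for code, rgb in CC_PALETTE.items()}
_CC_DECODE[CC_PADDING] = -1  # missing on an entry cell
_CHEN_DECODE = {v: code for code, v in CHEN_PALETTE.items()}
_YUE_DECODE = {code * YUE_SCALE: tuple(pair) for pair, code in YUE_CODES.items()}


def decode(image: GenotypeImage, layout: LayoutMap):
    """Invert an encoder on the layout's entry cells.

    cc: exact, missing decodes to -1. chen: exact on non-missing codes
    (value 0 decodes to AA; missing is unrecoverable by construction).
    yue: returns base pairs, None where the cell holds the padding value.
    """
    r, c = layout.entries[:, 0], layout.entries[:, 1]
    if image.encoder_id == "cc":
        out = np.empty(layout.n_snps, dtype=np.int8)
        for i, rgb in enumerate(map(tuple, image.pixels[r, c])):
            if rgb not in _CC_DECODE:
                raise ValidationError(f"pixel {rgb} is not in the cc palette")
            out[i] = _CC_DECODE[rgb]
        return out
    if image.encoder_id == "chen":
        out = np.empty(layout.n_snps, dtype=np.int8)
        for i, v in enumerate(image.pixels[r, c]):
            v = int(v)
            if v not in _CHEN_DECODE:
                raise ValidationError(f"gray value {v} is not in the chen palette")
            out[i] = _CHEN_DECODE[v]
        return out
    if image.encoder_id == "yue":
        pairs = []
        for v in image.pixels[r, c]:
            v = int(v)
            if v == YUE_PADDING:
                pairs.append(None)
            elif v in _YUE_DECODE:
                pairs.append(_YUE_DECODE[v])
            else:
                raise ValidationError(f"gray value {v} is not in the yue palette")
        return pairs
    raise ValidationError(f"unknown encoder_id {image.encoder_id!r}")


def encode_dataset(d: GenotypeDataset, encoder_id: str, layout: LayoutMap | None = None):
    """Encode every sample of a dataset; returns (images, layout).

    cc/chen use the end-to-end layout; yue uses the chromosome-rows layout
    (they coincide for single-chromosome data).
    """
    if layout is None:
        if encoder_id == "yue":
            lengths: list[int] = []
            for s in d.snps:
                if lengths and s.chromosome == last:
                    lengths[-1] += 1
                else:
                    lengths.append(1)
                last = s.chromosome
            layout = layout_chromosome_rows(lengths)
        else:
            layout = layout_end_to_end(d.n_snps)
    images = []
    for i, sid in enumerate(d.sample_ids):
        lab = int(d.labels[i])
        if encoder_id == "cc":
            img = encode_cc(d.genotypes[i], layout, sid, lab)
        elif encoder_id == "chen":
            img = encode_chen(d.genotypes[i], layout, sid, lab)
        elif encoder_id == "yue":
            img = encode_yue(genotype_pairs(d, i), layout, sid, lab)
        else:
            raise ValidationError(f"unknown encoder_id {encoder_id!r}")
        images.append(img)
    return images, layout


# ---- lossless image and manifest I/O ------------------------------------

_LOSSLESS_SUFFIXES = {".png", ".bmp"}


def write_image(img: GenotypeImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _LOSSLESS_SUFFIXES:
        raise ValidationError(
            f"refusing lossy/unknown format {path.suffix!r}; use .png or .bmp"
        )
    mode = "RGB" if img.channels == 3 else "L"
    Image.fromarray(img.pixels, mode=mode).save(path)


def read_image(path: str | Path, encoder_id: str, sample_id: str = "", label: int = 0) -> GenotypeImage:
    arr = np.asarray(Image.open(path))
    return GenotypeImage(arr, encoder_id, sample_id, label)


def write_manifest(images: Sequence[GenotypeImage], paths: Sequence[str | Path], manifest_path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [im.sample_id for im in images],
            "label": [label_name(im.label) for im in images],
            "path": [str(p) for p in paths],
            "encoder_id": [im.encoder_id for im in images],
            "side": [im.side for im in images],
        }
    ).to_csv(manifest_path, sep="\t", index=False)


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path, sep="\t", dtype={"sample_id": str})
    df["label_code"] = [label_code(v) for v in df["label"]]
    return df


def load_manifest_images(manifest_path: str | Path, root: str | Path | None = None) -> list[GenotypeImage]:
    df = read_manifest(manifest_path)
    root = Path(root) if root is not None else Path(manifest_path).parent
    images = []
    for rec in df.itertuples():
        p = Path(rec.path)
        if not p.is_absolute():
            p = root / p
        images.append(read_image(p, rec.encoder_id, rec.sample_id, rec.label_code))
    return images
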