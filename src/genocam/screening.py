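"""Grad-CAM based risk-SNP screening.

For each test sample the classifier predicts as a case, a Grad-CAM map is
computed at the last convolutional layer: channel weights are the spatial
means of the class-score gradient, the map is the ReLU of the weighted
channel sum, bilinearly upsampled to input resolution. The per-sample maps
are accumulated (over predicted cases only), min-max normalized into a
weight matrix in [0, 1], read off at each SNP's layout cell, and the top 5%
of SNPs by weight are screened as risk SNPs. Gene-level enrichment against
an offline annotation (snp_id -> gene TSV) and a reference risk-gene list
yields the risk-gene ratio |screened genes ∩ reference| / |screened genes|.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from .dataset import CASE, ValidationError
from .encoding import LayoutMap
from .nn import ConvNet

logger = logging.getLogger(__name__)


@dataclass
class CamMap:
    """Nonnegative importance grid at input resolution for one sample."""

    grid: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValidationError("CamMap grid must be square")
        if (self.grid < 0).any():
            raise ValidationError("CamMap entries must be >= 0")


def _cam_from_activations(a3: np.ndarray, d_a3: np.ndarray, out_side: int) -> np.ndarray:
    """alpha_k = spatial mean of gradient; map = ReLU(sum_k alpha_k A^k)."""
    alpha = d_a3.mean(axis=(0, 1))  # (F,)
    cam = np.maximum((a3 * alpha).sum(axis=-1), 0.0)
    if cam.shape != (out_side, out_side):
        cam = resize(cam, (out_side, out_side), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.maximum(cam, 0.0)


def gradcam(model: ConvNet, x: np.ndarray, target_class: int = CASE, sample_id: str = "") -> CamMap:
    """Grad-CAM map of one input (side, side, C) at input resolution."""
    if x.ndim == 3:
        x = x[None]
    a3, d_a3 = model.class_score_grad_last_conv(x, target_class)
    grid = _cam_from_activations(a3[0], d_a3[0], model.config.input_side)
    return CamMap(grid=grid, sample_id=sample_id)


def accumulate_cams(model: ConvNet, x_test: np.ndarray, target_class: int = CASE,
                    batch_size: int = 128) -> np.ndarray:
    """Elementwise sum of Grad-CAM maps over test samples PREDICTED as cases.

    The true labels play no role; screening follows the classifier's output.
    Raises if the model predicts no sample as a case.
    """
    if len(x_test) == 0:
        raise ValidationError("test set must be non-empty")
    preds = model.predict(x_test)
    case_idx = np.flatnonzero(preds == target_class)
    if case_idx.size == 0:
        raise ValidationError("no test sample was predicted as a case; nothing to screen")
    side = model.config.input_side
    acc = np.zeros((side, side))
    for s in range(0, case_idx.size, batch_size):
        chunk = x_test[case_idx[s : s + batch_size]]
        a3, d_a3 = model.class_score_grad_last_conv(chunk, target_class)
        for i in range(len(chunk)):
            acc += _cam_from_activations(a3[i], d_a3[i], side)
    return acc


def normalize_weights(accumulated: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min-max normalize to [0, 1]; a constant grid maps to all ones (flagged)."""
    grid = np.asarray(accumulated, dtype=float)
    if (grid < 0).any():
        raise ValidationError("accumulated grid must be nonnegative")
    lo, hi = grid.min(), grid.max()
    if hi == lo:
        logger.warning("accumulated Grad-CAM grid is constant; all weights set to 1")
        return np.ones_like(grid), True
    return (grid - lo) / (hi - lo), False


def pixel_weights_to_snps(grid: np.ndarray, layout: LayoutMap) -> np.ndarray:
    """Per-SNP weights read at each SNP's layout cell; padding cells dropped."""
    grid = np.asarray(grid)
    if grid.shape != (layout.side, layout.side):
        raise ValidationError(
            f"grid shape {grid.shape} does not match layout side {layout.side}"
        )
    return grid[layout.entries[:, 0], layout.entries[:, 1]].astype(float)


def select_top(weights: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Indices of the top ``ceil(fraction * n)`` SNPs by weight.

    Sorted by weight descending; ties broken by ascending SNP index, so the
    selection is reproducible.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    weights = np.asarray(weights, dtype=float)
    n = len(weights)
    k = math.ceil(fraction * n)
    order = np.lexsort((np.arange(n), -weights))
    return order[:k]


@dataclass
class ScreenReport:
    """Ranked SNP weights, the screened subset and gene-level enrichment."""

    snp_ids: list[str]
    weights: np.ndarray
    selected: np.ndarray  # indices, ranked
    snp_genes: dict[str, list[str]] = field(default_factory=dict)  # selected snp -> genes
    genes: list[str] = field(default_factory=list)  # deduplicated, selected+annotated
    risk_genes: list[str] = field(default_factory=list)  # genes found in the reference
    risk_gene_ratio: float | None = None  # None when no selected SNP is annotated
    degenerate_weights: bool = False

    def to_frame(self) -> pd.DataFrame:
        n = len(self.snp_ids)
        rank = np.full(n, -1)
        rank[self.selected] = np.arange(1, len(self.selected) + 1)
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "weight": self.weights,
                "rank": rank,
                "selected": rank > 0,
                "genes": [";".join(self.snp_genes.get(s, [])) for s in self.snp_ids],
            }
        )

    def write(self, report_path: str | Path, summary_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(report_path, sep="\t", index=False)
        if summary_path is not None:
            with open(summary_path, "w") as fh:
                json.dump(
                    {
                        "n_snps": len(self.snp_ids),
                        "n_selected": int(len(self.selected)),
                        "n_genes": len(self.genes),
                        "n_risk_genes": len(self.risk_genes),
                        "risk_gene_ratio": self.risk_gene_ratio,
                        "degenerate_weights": self.degenerate_weights,
                    },
                    fh,
                    indent=2,
                )


def read_annotation(path: str | Path) -> pd.DataFrame:
    """snp_id -> gene_symbol TSV, one row per pair."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"snp_id", "gene_symbol"}
    if not need.issubset(df.columns):
        raise ValidationError(f"annotation TSV must have columns {sorted(need)}")
    return df


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def annotate_and_score(
    snp_ids: list[str],
    weights: np.ndarray,
    selected: np.ndarray,
    annotation: pd.DataFrame | None = None,
    reference_genes: set[str] | None = None,
    degenerate: bool = False,
) -> ScreenReport:
    """Attach gene annotation to the screened SNPs and compute the ratio.

    Selected SNPs without a matching gene stay in the SNP report but are
    dropped from gene-level scoring. The risk-gene ratio is the fraction of
    screened genes present in the reference list; None when no screened SNP
    has an annotation (reported as not applicable).
    """
    report = ScreenReport(
        snp_ids=list(snp_ids),
        weights=np.asarray(weights, dtype=float),
        selected=np.asarray(selected, dtype=int),
        degenerate_weights=degenerate,
    )
    if annotation is None or annotation.empty:
        if annotation is not None:
            logger.warning("empty annotation; gene-level report is empty")
        return report
    gene_map: dict[str, list[str]] = {}
    for rec in annotation.itertuples():
        gene_map.setdefault(rec.snp_id, []).append(rec.gene_symbol)
    genes: list[str] = []
    for i in report.selected:
        sid = report.snp_ids[i]
        gs = gene_map.get(sid, [])
        if gs:
            report.snp_genes[sid] = gs
            for g in gs:
                if g not in genes:
                    genes.append(g)
    report.genes = genes
    if not genes:
        logger.warning("no screened SNP has a gene annotation; ratio not applicable")
        return report
    if reference_genes is not None:
        report.risk_genes = [g for g in genes if g in reference_genes]
        report.risk_gene_ratio = len(report.risk_genes) / len(genes)
    return report


def screen(
    model: ConvNet,
    x_test: np.ndarray,
    layout: LayoutMap,
    snp_ids: list[str],
    fraction: float = 0.05,
    annotation: pd.DataFrame | None = None,
    reference_genes: set[str] | None = None,
) -> ScreenReport:
    """Full screening stage: Grad-CAM accumulation -> weights -> top-5% -> genes."""
    acc = accumulate_cams(model, x_test)
    grid, degenerate = normalize_weights(acc)
    weights = pixel_weights_to_snps(grid, layout)
    selected = select_top(weights, fraction)
    return annotate_and_score(snp_ids, weights, selected, annotation, reference_genes, degenerate)
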