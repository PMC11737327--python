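"""End-to-end scaled-down benchmark: simulate -> encode -> train -> screen.

This module pins the package's reference study conditions at desk scale:
one simulated set of 2,000 samples (1,000 cases / 1,000 controls) over 400
SNPs of which 40 carry risk (rr_het = 2, multiplicative), images of side 20,
and fixed hyperparameters (filter 5, learning rate 0.01, momentum 0.9,
L2 1e-6) trained for at most 40 epochs. Inputs are centered by the training
set's per-channel mean after the 1/255 scaling; this is part of the model
boundary, chosen because all-positive channel inputs slow SGD convergence
noticeably at these learning rates.

``run_benchmark`` executes the whole pipeline for one (seed, encoder) pair
and reports test metrics plus risk-SNP recovery of the top-5% Grad-CAM
screen, so classifier quality and screening quality can be compared across
encoders under identical conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import GenotypeDataset
from .encoding import encode_dataset
from .nn import HyperParams, ModelConfig, build_model
from .screening import normalize_weights, pixel_weights_to_snps, select_top, accumulate_cams
from .simulate import SimulationSpec, simulate_dataset
from .training import EvalMetrics, SplitSpec, evaluate, split_dataset, stack_images, train

BENCHMARK_HP = HyperParams(filter_size=5, learning_rate=0.01, momentum=0.9, l2=1e-6)


@dataclass
class BenchmarkResult:
    encoder: str
    seed: int
    metrics: EvalMetrics
    best_val_accuracy: float
    best_epoch: int
    snp_weights: np.ndarray
    selected: np.ndarray
    risk_mask: np.ndarray
    history: list[dict] = field(default_factory=list)

    @property
    def risk_recovery(self) -> float:
        """Fraction of planted risk SNPs inside the top-5% selection."""
        return float(self.risk_mask[self.selected].sum() / self.risk_mask.sum())

    @property
    def recovery_enrichment(self) -> float:
        """Recovery relative to the random baseline |selected| / n_snps."""
        baseline = len(self.selected) / len(self.risk_mask)
        return self.risk_recovery / baseline


def benchmark_spec(seed: int) -> SimulationSpec:
    return SimulationSpec(
        n_cases=1000, n_controls=1000, n_null_snps=360, n_risk_snps=40,
        rr_het=2.0, seed=seed,
    )


def center_inputs(x: np.ndarray, means: np.ndarray | None = None):
    """Subtract per-channel means (computed on ``x`` when not given)."""
    if means is None:
        means = x.mean(axis=(0, 1, 2), keepdims=True)
    return x - means, means


def run_benchmark(
    seed: int,
    encoder: str = "cc",
    dataset: GenotypeDataset | None = None,
    conv_filters: tuple[int, int, int] = (8, 16, 32),
    batch_size: int = 64,
    max_epochs: int = 40,
    hp: HyperParams = BENCHMARK_HP,
    top_fraction: float = 0.05,
) -> BenchmarkResult:
    """One full pipeline run under the reference desk-scale conditions."""
    if dataset is None:
        dataset = simulate_dataset(benchmark_spec(seed))
    images, layout = encode_dataset(dataset, encoder)
    x, y = stack_images(images)
    idx_tr, idx_val, idx_te = split_dataset(y, SplitSpec(seed=seed))
    _, means = center_inputs(x[idx_tr])
    x, _ = center_inputs(x, means)

    cfg = ModelConfig(
        input_side=layout.side, input_channels=x.shape[3],
        conv_filters=conv_filters, batch_size=batch_size,
        max_epochs=max_epochs, seed=seed,
    )
    model = build_model(cfg, hp)
    result = train(model, x[idx_tr], y[idx_tr], x[idx_val], y[idx_val])
    metrics = evaluate(result.model, x[idx_te], y[idx_te])

    acc = accumulate_cams(result.model, x[idx_te])
    grid, _ = normalize_weights(acc)
    weights = pixel_weights_to_snps(grid, layout)
    selected = select_top(weights, top_fraction)
    risk_mask = np.array([s.is_risk for s in dataset.snps])

    return BenchmarkResult(
        encoder=encoder, seed=seed, metrics=metrics,
        best_val_accuracy=result.best_val_accuracy, best_epoch=result.best_epoch,
        snp_weights=weights, selected=selected, risk_mask=risk_mask,
        history=result.history,
    )
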