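"""Bayesian hyperparameter optimization over the 4-d search box.

Sequential model-based optimization: a Gaussian-process surrogate (Matern
5/2 plus white noise) is fitted to the (hyperparameters, objective) pairs
observed so far, and each next trial maximizes expected improvement over a
random candidate cloud. Learning rate and L2 live on log10 scale; the
categorical filter size is relaxed to a continuous coordinate and rounded
to the nearest allowed value. The objective is maximized (validation
accuracy, typically). Fully seeded and deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .dataset import ValidationError
from .nn import FILTER_SIZES, L2_BOUNDS, LR_BOUNDS, MOMENTUM_BOUNDS, HyperParams

logger = logging.getLogger(__name__)

_LOG_LR = tuple(np.log10(LR_BOUNDS))
_LOG_L2 = tuple(np.log10(L2_BOUNDS))


def _to_unit(hp: HyperParams) -> np.ndarray:
    """Map hyperparameters into the unit cube used by the surrogate."""
    f = FILTER_SIZES.index(hp.filter_size) / (len(FILTER_SIZES) - 1)
    lr = (np.log10(hp.learning_rate) - _LOG_LR[0]) / (_LOG_LR[1] - _LOG_LR[0])
    mom = (hp.momentum - MOMENTUM_BOUNDS[0]) / (MOMENTUM_BOUNDS[1] - MOMENTUM_BOUNDS[0])
    l2 = (np.log10(hp.l2) - _LOG_L2[0]) / (_LOG_L2[1] - _LOG_L2[0])
    return np.array([f, lr, mom, l2])


def _from_unit(u: np.ndarray) -> HyperParams:
    u = np.clip(u, 0.0, 1.0)
    f_idx = int(round(u[0] * (len(FILTER_SIZES) - 1)))
    return HyperParams(
        filter_size=FILTER_SIZES[f_idx],
        learning_rate=float(10 ** (_LOG_LR[0] + u[1] * (_LOG_LR[1] - _LOG_LR[0]))),
        momentum=float(MOMENTUM_BOUNDS[0] + u[2] * (MOMENTUM_BOUNDS[1] - MOMENTUM_BOUNDS[0])),
        l2=float(10 ** (_LOG_L2[0] + u[3] * (_LOG_L2[1] - _LOG_L2[0]))),
    )


@dataclass
class Trial:
    hp: HyperParams
    value: float | None  # None when the trial failed (e.g. diverged)
    failed: bool = False


@dataclass
class BayesOptResult:
    best_hp: HyperParams
    best_value: float
    trials: list[Trial] = field(default_factory=list)


class TrialFailed(RuntimeError):
    """An objective evaluation failed; the optimizer records it and moves on."""


def bayes_optimize(
    objective: Callable[[HyperParams], float],
    n_trials: int = 20,
    seed: int = 0,
    n_initial: int = 5,
    n_candidates: int = 2048,
) -> BayesOptResult:
    """Maximize ``objective`` over the hyperparameter box.

    The first ``min(n_initial, n_trials)`` trials are quasi-random; the rest
    are chosen by expected improvement under a GP surrogate. Returns the
    argmax over all evaluated trials plus the full trial log. Raises if every
    trial failed.
    """
    if n_trials < 1:
        raise ValidationError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    xs: list[np.ndarray] = []
    ys: list[float] = []

    def _evaluate(u: np.ndarray) -> None:
        hp = _from_unit(u)
        try:
            val = float(objective(hp))
        except (TrialFailed, FloatingPointError, ArithmeticError) as exc:
            logger.warning("trial %d failed: %s", len(trials) + 1, exc)
            trials.append(Trial(hp=hp, value=None, failed=True))
            return
        trials.append(Trial(hp=hp, value=val))
        xs.append(_to_unit(hp))  # store the rounded point the trial actually used
        ys.append(val)

    for _ in range(min(n_initial, n_trials)):
        _evaluate(rng.random(4))

    while len(trials) < n_trials:
        if len(ys) < 2:
            _evaluate(rng.random(4))
            continue
        x_arr, y_arr = np.array(xs), np.array(ys)
        kernel = ConstantKernel(1.0) * Matern(length_scale=np.full(4, 0.3), nu=2.5) + WhiteKernel(1e-4)
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(x_arr, y_arr)
        cand = rng.random((n_candidates, 4))
        # include perturbations of the incumbent for local refinement
        inc = x_arr[np.argmax(y_arr)]
        local = np.clip(inc + rng.normal(0, 0.05, size=(64, 4)), 0, 1)
        cand = np.vstack([cand, local])
        mu, sigma = gp.predict(cand, return_std=True)
        best = y_arr.max()
        sigma = np.maximum(sigma, 1e-12)
        z = (mu - best) / sigma
        ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
        _evaluate(cand[int(np.argmax(ei))])

    if not ys:
        raise ValidationError(
            f"all {n_trials} trials failed; trial log: {[t.hp for t in trials]}"
        )
    ibest = int(np.argmax(ys))
    ok = [t for t in trials if not t.failed]
    return BayesOptResult(best_hp=ok[ibest].hp, best_value=ys[ibest], trials=trials)
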