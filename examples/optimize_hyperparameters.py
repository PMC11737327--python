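"""Bayesian optimization over the hyperparameter box on a closed-form objective.

Uses a known concave function of log learning rate (optimum at lr = 10^-1.5)
so the run finishes in seconds and the result is checkable by eye; swapping
the objective for a training run (validation accuracy) is one line.
"""

import numpy as np

import genocam as gc


def objective(hp: gc.HyperParams) -> float:
    return -((np.log10(hp.learning_rate) + 1.5) ** 2)


res = gc.bayes_optimize(objective, n_trials=20, seed=0)
print(f"{len(res.trials)} trials, best value {res.best_value:.4f}")
print(f"best hyperparameters: filter {res.best_hp.filter_size}, "
      f"lr {res.best_hp.learning_rate:.4g} (true optimum 0.0316), "
      f"momentum {res.best_hp.momentum:.3f}, l2 {res.best_hp.l2:.3g}")
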