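"""Reference experiments on synthetic data.

These are the package's standard study procedures, kept in one place so the
test suite, the examples and the reproduction script all run exactly the same
protocol:

* :func:`recovery_experiment` — train a desk-scale CNN on planted-rule
  windows and measure held-out correlations on the planted task;
* :func:`mutagenesis_peak` — average saturated-mutagenesis importance over
  accurately predicted held-out windows and locate the most important column;
* :func:`nas_experiment` — run the controller search on a reduced layer
  space and compare the final-step mean reward with a random cohort of equal
  total size.

Problem sizes default to what runs in minutes on one CPU core.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .model import ArchitectureTokens, ModelConfig, build_model, predict, train
from .mutagenesis import (average_importance, positional_importance,
                          saturated_mutagenesis, select_accurate_sequences)
from .nas import SearchConfig, compute_reward, run_search, sample_random_cohort
from .outcomes import TASK_NAMES
from .simulate import PlantedRule, planted_dataset
from .sequences import split_dataset

#: Desk-scale recovery architecture: two dilated kernel-8 convolutions reach
#: the window boundary (receptive span 29 each), which a model needs to read
#: *absolute* position through global average pooling; remaining layers are
#: identity.
RECOVERY_TOKENS = ArchitectureTokens(
    ops=(4, 4, 7, 7, 7, 7, 7, 7),
    residuals=tuple((0,) * t for t in range(8)))

RECOVERY_CONFIG = ModelConfig(width_scale=1, dropout=0.0, learning_rate=5e-3,
                              batch_size=64, max_epochs=32,
                              early_stop_patience=12)


def recovery_experiment(seed: int, n: int = 5000,
                        rule: PlantedRule = PlantedRule(),
                        tokens: ArchitectureTokens = RECOVERY_TOKENS,
                        config: ModelConfig = RECOVERY_CONFIG):
    """Train on planted-rule data; return the model and held-out metrics.

    Returns a dict with the trained model, the test split (sites, X, Y), and
    the per-task held-out Pearson correlations (``pearson`` indexed like
    TASK_NAMES; the planted task is ins1, index 0).
    """
    sites, X, Y = planted_dataset(n, rule, seed=seed)
    Y = np.asarray(Y)
    idx_tr, idx_va, idx_te = split_dataset(range(n), seed=seed + 1)
    cfg = replace(config, seed=seed + 2)
    net = build_model(tokens, cfg)
    trained = train(net, (X[idx_tr], Y[idx_tr]), (X[idx_va], Y[idx_va]), cfg)
    preds = predict(trained, X[idx_te])
    pearson = [float(stats.pearsonr(preds[:, j], Y[idx_te, j]).statistic)
               for j in range(len(TASK_NAMES))]
    return {
        "model": trained,
        "pearson": dict(zip(TASK_NAMES, pearson)),
        "test_sites": [sites[i] for i in idx_te],
        "test_X": X[idx_te],
        "test_Y": Y[idx_te],
        "n_epochs": len(trained.training_log),
    }


def mutagenesis_peak(trained, test_sites, test_Y, task: str = "ins1",
                     tolerance: float = 0.05, max_windows: int = 50):
    """Averaged-importance peak column (1-based) for one task.

    Windows predicted within ``tolerance`` of truth on every task are used
    (falling back to all windows if none qualify), capped at ``max_windows``.
    Returns (peak_position_1based, averaged ImportanceMatrix, n_used).
    """
    kept = select_accurate_sequences(trained, test_sites, test_Y,
                                     tolerance=tolerance)
    use = (kept if kept else list(test_sites))[:max_windows]
    mats = [saturated_mutagenesis(trained, s)[task] for s in use]
    avg = average_importance(mats)
    peak = int(np.argmax(positional_importance(avg))) + 1
    return peak, avg, len(use)


NAS_CHILD_CONFIG = ModelConfig(width_scale=1, dropout=0.0, learning_rate=5e-3,
                               batch_size=64, early_stop_patience=10 ** 6)


def nas_experiment(seed: int, n: int = 1300, n_layers: int = 3,
                   controller_steps: int = 12, m: int = 4,
                   child_epochs: int = 5, residual_density: float = 0.5):
    """Controller search vs a random cohort on interaction-rule data.

    The planted rule includes its pairwise interaction term so architectures
    with nonlinear convolution layers genuinely outperform pooling/identity
    stacks.  The random cohort has the same total number of architectures as
    the search samples, with uniform operations and Bernoulli(0.5) residual
    bits — the untrained controller's own sampling distribution.
    """
    rule = PlantedRule().with_interaction()
    _, X, Y = planted_dataset(n, rule, seed=seed)
    Y = np.asarray(Y)
    idx_tr, idx_va, _ = split_dataset(range(n), (0.76, 0.23, 0.01),
                                      seed=seed + 1)
    train_set = (X[idx_tr], Y[idx_tr])
    val_set = (X[idx_va], Y[idx_va])
    cfg = SearchConfig(n_layers=n_layers, batch_architectures=m,
                       controller_steps=controller_steps,
                       child_train_epochs=child_epochs, seed=seed + 2,
                       child_config=NAS_CHILD_CONFIG)
    best_tokens, log = run_search(cfg, train_set, val_set)
    final = [r.reward for r in log if r.step == controller_steps]
    first = [r.reward for r in log if r.step == 1]

    cohort = sample_random_cohort(len(log), residual_density, seed=seed + 3,
                                  n_layers=n_layers)
    cohort_rewards = []
    for k, tokens in enumerate(cohort):
        child_seed = (seed * 104729 + k) % (2 ** 31)
        rec = compute_reward(tokens, train_set, val_set, cfg,
                             child_seed=child_seed)
        cohort_rewards.append(rec.reward)
    return {
        "best_tokens": best_tokens,
        "log": log,
        "final_step_mean_reward": float(np.mean(final)),
        "first_step_mean_reward": float(np.mean(first)),
        "cohort_mean_reward": float(np.mean(cohort_rewards)),
        "cohort_rewards": cohort_rewards,
    }
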