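"""Neural architecture search with a REINFORCE-trained recurrent controller.

The controller is an LSTM policy over architecture tokens.  One LSTM step is
taken per searched layer t: the embedded previous operation token is the
input, and the hidden state h_t parameterises

* the operation choice, sampled from softmax(W_o . h_t) over the 7 candidate
  operations, and
* one residual bit per preceding layer r < t, sampled from
  sigmoid(v^T tanh(W_r1 . h_t + W_r2 . h_r)) — an additive attention score
  between the deciding layer and the candidate source layer.

The controller parameters theta = {LSTM weights, W_o, W_r1, W_r2, v,
embeddings} are updated by the score-function policy gradient

    (1/m) sum_k  grad_theta log pi(a_k; theta) * (R_k - b),

where the reward R_k of a sampled architecture is the mean validation
Spearman correlation over the six tasks of a child model trained from
scratch for a small fixed budget, and b is an exponential moving average of
rewards.  W_o and v start at zero, so the untrained controller samples
operations exactly uniformly and residual bits at probability 1/2.

Children share no weights (no supernet): each sample is trained from scratch,
which keeps rewards unbiased and runs comfortably at desk scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import autodiff as ad
from .exceptions import ConfigError, StalenessError
from .model import (ArchitectureTokens, ModelConfig, N_OP_CHOICES,
                    N_SEARCHED_LAYERS, SequenceCNN, predict, train)
from .outcomes import TASK_NAMES

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """Search-loop hyperparameters.

    ``batch_architectures`` (m) architectures are sampled and rewarded per
    controller step; each child trains from scratch for
    ``child_train_epochs`` epochs.  The controller's own optimiser is Adam
    with ``controller_lr`` — at desk-scale step budgets a learning rate of
    this magnitude is needed for the policy to move at all within the run.
    """

    n_layers: int = N_SEARCHED_LAYERS
    batch_architectures: int = 4
    controller_steps: int = 10
    child_train_epochs: int = 8
    controller_lr: float = 0.1
    ema_decay: float = 0.9
    hidden_size: int = 32
    reward_tasks: tuple = TASK_NAMES
    seed: int = 0
    child_config: ModelConfig = field(default_factory=lambda: ModelConfig(
        dropout=0.0, early_stop_patience=10**6))

    def __post_init__(self) -> None:
        if self.batch_architectures < 1 or self.controller_steps < 1:
            raise ConfigError("batch_architectures and controller_steps must be >= 1")
        if not 0 < self.ema_decay < 1:
            raise ConfigError("ema_decay must lie in (0, 1)")


@dataclass
class RewardRecord:
    tokens: ArchitectureTokens
    reward: float
    log_likelihood: float
    step: int
    per_task: tuple = ()

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.reward <= 1.0 + 1e-9:
            raise ConfigError(f"reward {self.reward} outside [-1, 1]")


class ControllerState:
    """Trainable controller parameters, optimiser moments and EMA baseline."""

    def __init__(self, n_layers: int = N_SEARCHED_LAYERS, hidden_size: int = 32,
                 lr: float = 0.1, ema_decay: float = 0.9, seed: int = 0):
        self.n_layers = n_layers
        self.hidden = hidden_size
        rng = np.random.default_rng(seed)
        H = hidden_size
        self.params: dict[str, ad.Tensor] = {
            # row N_OP_CHOICES is the start-of-sequence embedding
            "embed": ad.parameter(rng, N_OP_CHOICES + 1, H, scale=0.1),
            "W_ih": ad.parameter(rng, H, 4 * H),
            "W_hh": ad.parameter(rng, H, 4 * H),
            "b_lstm": ad.Tensor(np.zeros(4 * H), requires_grad=True),
            # zero init => exactly uniform op marginals / 0.5 residual probs
            "W_o": ad.Tensor(np.zeros((H, N_OP_CHOICES)), requires_grad=True),
            "W_r1": ad.parameter(rng, H, H),
            "W_r2": ad.parameter(rng, H, H),
            "v": ad.Tensor(np.zeros((H, 1)), requires_grad=True),
        }
        self.baseline: float | None = None  # set to the first batch mean
        self.decay = ema_decay
        self.optimizer = ad.Adam(self.params.values(), lr=lr)

    # -- policy rollout ------------------------------------------------------

    def _lstm_step(self, x: ad.Tensor, h: ad.Tensor, c: ad.Tensor):
        H = self.hidden
        gates = x @ self.params["W_ih"] + h @ self.params["W_hh"] + self.params["b_lstm"]
        i = gates[:, 0 * H: 1 * H].sigmoid()
        f = gates[:, 1 * H: 2 * H].sigmoid()
        g = gates[:, 2 * H: 3 * H].tanh()
        o = gates[:, 3 * H: 4 * H].sigmoid()
        c_new = f * c + i * g
        return o * c_new.tanh(), c_new

    def _rollout(self, rng: np.random.Generator | None = None,
                 tokens: ArchitectureTokens | None = None):
        """Sample (rng given) or replay (tokens given) one architecture.

        Returns (ArchitectureTokens, log-likelihood Tensor): the summed log
        probability of every sampled token under the current parameters.
        """
        if (rng is None) == (tokens is None):
            raise ConfigError("provide exactly one of rng (sample) or tokens (replay)")
        embed = self.params["embed"]
        H = self.hidden
        h = ad.Tensor(np.zeros((1, H)))
        c = ad.Tensor(np.zeros((1, H)))
        x = embed[N_OP_CHOICES].reshape(1, H)
        hs: list[ad.Tensor] = []
        ll_terms: list[ad.Tensor] = []
        ops: list[int] = []
        residuals: list[tuple[int, ...]] = []
        for t in range(self.n_layers):
            h, c = self._lstm_step(x, h, c)
            logp = ad.log_softmax(h @ self.params["W_o"])  # (1, 7)
            if tokens is None:
                op = int(rng.choice(N_OP_CHOICES, p=np.exp(logp.data[0]))) + 1
            else:
                op = tokens.ops[t]
            ops.append(op)
            ll_terms.append(logp[0, op - 1])
            bits = []
            for r in range(t):  # preceding layers 1..t-1 (hs[r] is layer r+1)
                score = (self.params["W_r1"].transpose(1, 0) @ h.reshape(H, 1)
                         + self.params["W_r2"].transpose(1, 0) @ hs[r].reshape(H, 1))
                p_res = (self.params["v"].transpose(1, 0) @ score.tanh()).sigmoid()
                if tokens is None:
                    bit = int(rng.random() < p_res.data[0, 0])
                else:
                    bit = tokens.residuals[t][r]
                bits.append(bit)
                prob = p_res if bit else 1.0 - p_res
                ll_terms.append(prob.clip(1e-12, 1.0).log()[0, 0])
            residuals.append(tuple(bits))
            hs.append(h)
            x = embed[op - 1].reshape(1, H)
        total = ll_terms[0]
        for term in ll_terms[1:]:
            total = total + term
        return ArchitectureTokens(ops=tuple(ops), residuals=tuple(residuals)), total

    def log_prob(self, tokens: ArchitectureTokens) -> ad.Tensor:
        """Replayed log pi(a; theta) for a given token set (differentiable)."""
        return self._rollout(tokens=tokens)[1]


def sample_architecture(state: ControllerState, seed_or_rng):
    """Draw one architecture; returns (tokens, float log-likelihood)."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    tokens, ll = state._rollout(rng=rng)
    return tokens, float(ll.data)


def compute_reward(tokens: ArchitectureTokens, train_set, validation_set,
                   config: SearchConfig, step: int = 0, child_seed: int = 0,
                   log_likelihood: float = math.nan) -> RewardRecord:
    """Train a child from scratch and score it by mean validation Spearman.

    A task on which the child (or the labels) is constant has an undefined
    rank correlation; it contributes 0 to the reward and is logged.
    """
    child_cfg = replace(config.child_config, seed=child_seed,
                        max_epochs=config.child_train_epochs)
    net = SequenceCNN(tokens, child_cfg)
    trained = train(net, train_set, validation_set, child_cfg)
    preds = predict(trained, validation_set[0])
    obs = np.asarray(validation_set[1], dtype=float)
    per_task = []
    for j, task in enumerate(config.reward_tasks):
        if np.ptp(preds[:, j]) == 0 or np.ptp(obs[:, j]) == 0:
            logger.info("constant predictions/labels on %s: reward term 0", task)
            per_task.append(0.0)
        else:
            per_task.append(float(stats.spearmanr(preds[:, j], obs[:, j]).statistic))
    return RewardRecord(tokens=tokens, reward=float(np.mean(per_task)),
                        log_likelihood=log_likelihood, step=step,
                        per_task=tuple(per_task))


def reinforce_update(state: ControllerState, records) -> ControllerState:
    """One policy-gradient ascent step from a batch of reward records.

    Maximises (1/m) sum_k log pi(a_k)(R_k - b); afterwards the EMA baseline
    is updated with the batch mean reward.  On the very first update the
    baseline is initialised to the batch mean (variance reduction from step
    one).  Records must have been sampled under the *current* parameters:
    each log-likelihood is re-derived by replay and compared against the
    recorded value.
    """
    records = list(records)
    if not records:
        raise ConfigError("need at least one reward record")
    m = len(records)
    if state.baseline is None:
        state.baseline = float(np.mean([r.reward for r in records]))
    state.optimizer.zero_grad()
    objective = None
    for rec in records:
        ll = state.log_prob(rec.tokens)
        if np.isfinite(rec.log_likelihood) and \
                abs(float(ll.data) - rec.log_likelihood) > 1e-6:
            raise StalenessError(
                f"recorded log-likelihood {rec.log_likelihood:.6f} does not match "
                f"replay {float(ll.data):.6f}: parameters have moved")
        term = ll * ((rec.reward - state.baseline) / m)
        objective = term if objective is None else objective + term
    loss = -objective
    loss.backward()
    state.optimizer.step()
    mean_r = float(np.mean([r.reward for r in records]))
    state.baseline = state.decay * state.baseline + (1 - state.decay) * mean_r
    return state


def run_search(config: SearchConfig, train_set, validation_set):
    """Full controller loop; returns (best final-step tokens, search log).

    "Best" is the argmax-reward architecture among those sampled in the final
    controller step; the globally best record is available from the log.
    """
    state = ControllerState(n_layers=config.n_layers,
                            hidden_size=config.hidden_size,
                            lr=config.controller_lr,
                            ema_decay=config.ema_decay, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    log: list[RewardRecord] = []
    for step in range(1, config.controller_steps + 1):
        batch = []
        for k in range(config.batch_architectures):
            tokens, ll = sample_architecture(state, rng)
            child_seed = (config.seed * 7919 + step * 131 + k) % (2 ** 31)
            rec = compute_reward(tokens, train_set, validation_set, config,
                                 step=step, child_seed=child_seed,
                                 log_likelihood=ll)
            batch.append(rec)
        reinforce_update(state, batch)
        log.extend(batch)
        logger.info("controller step %d/%d: mean reward %.4f baseline %.4f",
                    step, config.controller_steps,
                    float(np.mean([r.reward for r in batch])), state.baseline)
    final = [r for r in log if r.step == config.controller_steps]
    best = max(final, key=lambda r: r.reward)
    return best.tokens, log


def sample_random_cohort(n: int, residual_density: float, seed: int = 0,
                         n_layers: int = N_SEARCHED_LAYERS) -> list[ArchitectureTokens]:
    """Uniform-operation cohort with Bernoulli(residual_density) skip bits."""
    if not 0.0 <= residual_density <= 1.0:
        raise ConfigError("residual_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n):
        ops = tuple(int(o) + 1 for o in rng.integers(0, N_OP_CHOICES, size=n_layers))
        residuals = tuple(
            tuple(int(b) for b in rng.random(t) < residual_density)
            for t in range(n_layers))
        cohort.append(ArchitectureTokens(ops=ops, residuals=residuals))
    return cohort


def count_model_space(layers: int, op_choices: int = N_OP_CHOICES) -> int:
    """Exact number of distinct token assignments: ops^T * 2^(T(T-1)/2)."""
    if layers < 1 or op_choices < 1:
        raise ConfigError("layers and op_choices must be >= 1")
    return op_choices ** layers * 2 ** (layers * (layers - 1) // 2)


def grid_refine(best_tokens: ArchitectureTokens, train_set, validation_set,
                width_grid, dropout_grid, config: SearchConfig) -> ModelConfig:
    """Retrain the chosen architecture over a (width_scale, dropout) grid.

    Returns the config with the best mean validation Spearman; ties break
    toward smaller width, then smaller dropout (the grid is scanned in that
    order and only strict improvements replace the incumbent).
    """
    if not width_grid or not dropout_grid:
        raise ConfigError("grids must be non-empty")
    best_cfg, best_reward = None, -np.inf
    for w in sorted(width_grid):
        for d in sorted(dropout_grid):
            cfg = replace(config.child_config, width_scale=int(w), dropout=float(d),
                          max_epochs=config.child_train_epochs)
            rec = compute_reward(best_tokens, train_set, validation_set,
                                 replace(config, child_config=cfg),
                                 child_seed=config.seed)
            logger.info("grid (width=%s, dropout=%s): reward %.4f", w, d, rec.reward)
            if rec.reward > best_reward:
                best_cfg, best_reward = cfg, rec.reward
    return best_cfg


def search_log_frame(log):
    import pandas as pd

    return pd.DataFrame([
        {"step": r.step, "reward": r.reward, "log_likelihood": r.log_likelihood,
         "architecture": r.tokens.describe()} for r in log])
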