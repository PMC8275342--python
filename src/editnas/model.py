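"""Multi-task convolutional sequence model over architecture tokens.

A model is a fixed *input stem* (linear kernel-8 convolution expanding the
4-channel one-hot sequence to ``base_filters * width_scale`` channels),
followed by 8 *searched* layers, each chosen from seven candidate operations

    1 conv4   convolution, kernel 4, dilation 1, ReLU
    2 conv8   convolution, kernel 8, dilation 1, ReLU
    3 dconv4  convolution, kernel 4, dilation 4, ReLU
    4 dconv8  convolution, kernel 8, dilation 4, ReLU
    5 maxpool4   max pooling, size 4, stride 1
    6 avgpool4   average pooling, size 4, stride 1
    7 identity

plus, for layer t, one binary residual token per preceding layer r < t; a set
token adds layer r's output into layer t's input.  Same-padding and stride 1
everywhere keep the sequence length at 60, so residual sums are always
shape-compatible.  The output stem is global average pooling, a ReLU dense
layer, and 6 sigmoid heads — one per editing-outcome statistic.  Dropout (at
the configured rate) follows each searched layer during training only.

Targets are probabilities in [0,1], and training minimises binary
cross-entropy with those *soft* targets, summed over the six tasks and
averaged over examples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .exceptions import ArchitectureError, DimensionError, TrainingError
from .sequences import WINDOW_LENGTH

N_TASKS = 6
N_SEARCHED_LAYERS = 8
N_OP_CHOICES = 7
OP_NAMES = {1: "conv4", 2: "conv8", 3: "dconv4", 4: "dconv8",
            5: "maxpool4", 6: "avgpool4", 7: "identity"}
_CONV_SPECS = {1: (4, 1), 2: (8, 1), 3: (4, 4), 4: (8, 4)}  # op -> (kernel, dilation)

BCE_EPS = 1e-7  # probability clipping before logs


@dataclass(frozen=True)
class ArchitectureTokens:
    """Operation choices and residual-connection bits for the searched layers.

    ``ops[t]`` in [1, 7] selects the operation of layer t+1; ``residuals[t]``
    has exactly t binary entries, one per preceding layer (layer 1 has none).
    """

    ops: tuple
    residuals: tuple

    def __post_init__(self) -> None:
        ops = tuple(int(o) for o in self.ops)
        res = tuple(tuple(int(b) for b in row) for row in self.residuals)
        object.__setattr__(self, "ops", ops)
        object.__setattr__(self, "residuals", res)
        if len(res) != len(ops):
            raise ArchitectureError(
                f"{len(ops)} ops but {len(res)} residual rows")
        for o in ops:
            if not 1 <= o <= N_OP_CHOICES:
                raise ArchitectureError(f"op token {o} outside [1, {N_OP_CHOICES}]")
        for t, row in enumerate(res):
            if len(row) != t:
                raise ArchitectureError(
                    f"layer {t + 1} has {len(row)} residual tokens, expected {t}")
            if any(b not in (0, 1) for b in row):
                raise ArchitectureError("residual tokens must be 0/1")

    @property
    def n_layers(self) -> int:
        return len(self.ops)

    def describe(self) -> str:
        return "-".join(OP_NAMES[o] for o in self.ops)

    def to_json(self) -> str:
        return json.dumps({"ops": list(self.ops),
                           "residuals": [list(r) for r in self.residuals]})

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureTokens":
        d = json.loads(text)
        return cls(ops=tuple(d["ops"]),
                   residuals=tuple(tuple(r) for r in d["residuals"]))

    @classmethod
    def all_identity(cls, n_layers: int = N_SEARCHED_LAYERS) -> "ArchitectureTokens":
        return cls(ops=(7,) * n_layers,
                   residuals=tuple((0,) * t for t in range(n_layers)))


@dataclass
class ModelConfig:
    """Hyperparameters of the child model and its optimisation.

    ``width_scale`` multiplies ``base_filters`` in the stem and every searched
    convolution (the published large-scale setting is width_scale=6 with
    dropout=0.4; the desk-scale default here is 1 with light dropout).
    Optimiser specifics are not part of the architecture contract and are
    deliberately exposed: Adam, lr 1e-3, batch 128 by default.
    """

    base_filters: int = 32
    width_scale: int = 1
    dropout: float = 0.1
    stem_kernel: int = 8
    dense_units: int = 32
    early_stop_patience: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 100
    seed: int = 0

    @property
    def filters(self) -> int:
        return self.base_filters * self.width_scale


class SequenceCNN:
    """Materialised network for a given set of architecture tokens."""

    def __init__(self, tokens: ArchitectureTokens, config: ModelConfig):
        self.tokens = tokens
        self.config = config
        rng = np.random.default_rng(config.seed)
        F = config.filters
        self.params: dict[str, ad.Tensor] = {}
        self.params["stem_w"] = ad.parameter(rng, F, 4, config.stem_kernel)
        self.params["stem_b"] = ad.Tensor(np.zeros(F), requires_grad=True)
        for t, op in enumerate(tokens.ops):
            if op in _CONV_SPECS:
                k, _ = _CONV_SPECS[op]
                self.params[f"conv{t}_w"] = ad.parameter(rng, F, F, k)
                self.params[f"conv{t}_b"] = ad.Tensor(np.zeros(F), requires_grad=True)
        self.params["dense_w"] = ad.parameter(rng, F, config.dense_units, fan_in=F)
        self.params["dense_b"] = ad.Tensor(np.zeros(config.dense_units),
                                           requires_grad=True)
        self.params["head_w"] = ad.parameter(rng, config.dense_units, N_TASKS,
                                             fan_in=config.dense_units)
        self.params["head_b"] = ad.Tensor(np.zeros(N_TASKS), requires_grad=True)

    def parameters(self) -> list[ad.Tensor]:
        return list(self.params.values())

    def forward(self, x, training: bool = False,
                rng: np.random.Generator | None = None) -> ad.Tensor:
        """Forward pass on a (B, 4, 60) batch; returns (B, 6) sigmoid outputs."""
        arr = x.data if isinstance(x, ad.Tensor) else np.asarray(x, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[1] != 4 or arr.shape[2] != WINDOW_LENGTH:
            raise DimensionError(f"expected (B, 4, {WINDOW_LENGTH}), got {arr.shape}")
        h = x if isinstance(x, ad.Tensor) else ad.Tensor(arr)
        h = ad.conv1d(h, self.params["stem_w"], self.params["stem_b"])  # linear stem
        outputs = [h]  # outputs[0] = stem, outputs[t] = searched layer t
        drop = self.config.dropout
        for t, op in enumerate(self.tokens.ops):
            inp = outputs[-1]
            for r, bit in enumerate(self.tokens.residuals[t], start=1):
                if bit:
                    inp = inp + outputs[r]
            if op in _CONV_SPECS:
                _, dil = _CONV_SPECS[op]
                out = ad.conv1d(inp, self.params[f"conv{t}_w"],
                                self.params[f"conv{t}_b"], dilation=dil).relu()
            elif op == 5:
                out = ad.pool1d(inp, size=4, mode="max")
            elif op == 6:
                out = ad.pool1d(inp, size=4, mode="avg")
            else:  # identity
                out = inp
            if training and drop > 0:
                if rng is None:
                    raise TrainingError("dropout requires an rng during training")
                mask = (rng.random(out.data.shape) >= drop) / (1.0 - drop)
                out = out * ad.Tensor(mask)
            outputs.append(out)
        pooled = outputs[-1].mean(axis=2)          # global average pooling
        hidden = (pooled @ self.params["dense_w"] + self.params["dense_b"]).relu()
        logits = hidden @ self.params["head_w"] + self.params["head_b"]
        return logits.sigmoid()

    # -- weights I/O --------------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()


def build_model(tokens: ArchitectureTokens, config: ModelConfig | None = None) -> SequenceCNN:
    """Materialise an untrained network from architecture tokens."""
    return SequenceCNN(tokens, config or ModelConfig())


def multitask_bce(pred, target):
    """Binary cross-entropy with soft targets, summed over the six tasks.

    Predictions are clipped to [eps, 1-eps] (eps = 1e-7) before logs.  Accepts
    numpy arrays (returns a float) or autodiff Tensors (returns a Tensor for
    backprop); the mean is over examples.
    """
    is_tensor = isinstance(pred, ad.Tensor)
    p = pred if is_tensor else ad.Tensor(np.atleast_2d(pred))
    y = target if isinstance(target, ad.Tensor) else ad.Tensor(np.atleast_2d(target))
    if p.data.shape != y.data.shape:
        raise DimensionError(f"pred {p.data.shape} vs target {y.data.shape}")
    pc = p.clip(BCE_EPS, 1.0 - BCE_EPS)
    ll = y * pc.log() + (1.0 - y) * (1.0 - pc).log()
    loss = -(ll.sum(axis=1).mean())
    return loss if is_tensor else float(loss.data)


@dataclass
class TrainedModel:
    """A trained network plus its tokens, config and per-epoch loss log."""

    model: SequenceCNN
    training_log: list = field(default_factory=list)

    @property
    def tokens(self) -> ArchitectureTokens:
        return self.model.tokens

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


def train(model: SequenceCNN, train_set, validation_set,
          config: ModelConfig | None = None) -> TrainedModel:
    """Mini-batch Adam with early stopping on validation loss.

    ``train_set``/``validation_set`` are (X, Y) pairs with X of shape
    (n, 4, 60) and Y of shape (n, 6).  Training stops when the validation
    loss has not improved for ``early_stop_patience`` epochs or at
    ``max_epochs``; the returned weights are from the best-validation epoch.
    """
    cfg = config or model.config
    Xtr, Ytr = (np.asarray(a, dtype=np.float64) for a in train_set)
    Xva, Yva = (np.asarray(a, dtype=np.float64) for a in validation_set)
    if len(Xtr) == 0 or len(Xva) == 0:
        raise TrainingError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = ad.Adam(model.parameters(), lr=cfg.learning_rate)
    best_loss, best_weights, since_best = np.inf, model.get_weights(), 0
    log: list[dict] = []
    n = len(Xtr)
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start: start + cfg.batch_size]
            opt.zero_grad()
            pred = model.forward(Xtr[idx], training=True, rng=rng)
            loss = multitask_bce(pred, ad.Tensor(Ytr[idx]))
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_pred = model.forward(Xva).data
        val_loss = multitask_bce(val_pred, Yva)
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        log.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                    "val_loss": val_loss})
        if val_loss < best_loss - 1e-12:
            best_loss, best_weights, since_best = val_loss, model.get_weights(), 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    model.set_weights(best_weights)
    return TrainedModel(model=model, training_log=log)


def predict(model, X) -> np.ndarray:
    """Deterministic inference (dropout off) on a (k, 4, 60) batch -> (k, 6)."""
    net = model.model if isinstance(model, TrainedModel) else model
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 2
    if single:
        X = X[None]
    out = net.forward(X, training=False).data
    return out[0] if single else out


# -- checkpointing (JSON: weights + tokens + config together) -------------------

def save_checkpoint(trained: TrainedModel, path) -> None:
    net = trained.model
    payload = {
        "format_version": 1,
        "tokens": json.loads(net.tokens.to_json()),
        "config": asdict(net.config),
        "weights": {k: v.tolist() for k, v in net.get_weights().items()},
        "training_log": trained.training_log,
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    tokens = ArchitectureTokens(
        ops=tuple(payload["tokens"]["ops"]),
        residuals=tuple(tuple(r) for r in payload["tokens"]["residuals"]))
    config = ModelConfig(**payload["config"])
    net = SequenceCNN(tokens, config)
    net.set_weights({k: np.array(v) for k, v in payload["weights"].items()})
    return TrainedModel(model=net, training_log=payload.get("training_log", []))


def write_training_log_tsv(trained: TrainedModel, path) -> None:
    import pandas as pd

    pd.DataFrame(trained.training_log).to_csv(path, sep="\t", index=False)
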