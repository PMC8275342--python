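"""In-silico saturated mutagenesis: perturbation-based base importance.

For a 60 bp window, every possible single-base substitution (3 alternatives x
60 positions = 180 perturbed sequences) is pushed through the model in one
batch together with the reference.  The importance of base b at position p
for a task is

    prediction(reference) - prediction(window with b at p),

so a *positive* entry means the reference base elevates the predicted
statistic relative to the alternative.  Entries at the reference base are
exactly zero; positions holding 'N' are skipped (perturbing an unknown base
is undefined) and logged.

Only windows the model predicts accurately are worth interpreting: the
standard filter keeps windows where every task's prediction is within a
tolerance (default 0.05) of the measured truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DimensionError, InputError
from .outcomes import TASK_NAMES
from .sequences import ALPHABET, WINDOW_LENGTH, TargetSite, one_hot
from .model import predict

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImportanceMatrix:
    """4x60 per-task base-importance scores for one reference window."""

    values: np.ndarray
    task: str
    reference_window: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (4, WINDOW_LENGTH):
            raise DimensionError(f"importance matrix must be 4x{WINDOW_LENGTH}")
        object.__setattr__(self, "values", v)


def saturated_mutagenesis(model, site) -> dict[str, ImportanceMatrix]:
    """One 4x60 importance matrix per task from a single batched forward pass."""
    window = site.window if isinstance(site, TargetSite) else str(site).upper()
    seqs = [window]
    entries: list[tuple[int, int]] = []  # (base row, position) per perturbed seq
    for p, ref_base in enumerate(window):
        if ref_base == "N":
            logger.info("skipping position %d: reference base is N", p + 1)
            continue
        for b, base in enumerate(ALPHABET):
            if base == ref_base:
                continue
            seqs.append(window[:p] + base + window[p + 1:])
            entries.append((b, p))
    X = np.stack([one_hot(s) for s in seqs])
    preds = predict(model, X)  # (1 + 3*positions, 6)
    ref_pred = preds[0]
    diffs = ref_pred[None, :] - preds[1:]  # reference minus alternative
    out = {}
    for j, task in enumerate(TASK_NAMES):
        mat = np.zeros((4, WINDOW_LENGTH))
        for (b, p), d in zip(entries, diffs[:, j]):
            mat[b, p] = d
        out[task] = ImportanceMatrix(values=mat, task=task,
                                     reference_window=window)
    return out


def select_accurate_sequences(model, sites, truths, tolerance: float = 0.05,
                              per_task: bool = False):
    """Keep sites the model predicts within ``tolerance`` of the truth.

    Default mode requires *every* task within tolerance simultaneously; with
    ``per_task=True`` a dict of per-task site subsets is returned instead.
    """
    sites = list(sites)
    truths = np.asarray(truths, dtype=float)
    if len(sites) != len(truths):
        raise InputError("sites and truths must align")
    X = np.stack([one_hot(s) for s in sites])
    preds = predict(model, X)
    err = np.abs(preds - truths)
    if per_task:
        return {task: [s for s, keep in zip(sites, err[:, j] <= tolerance) if keep]
                for j, task in enumerate(TASK_NAMES)}
    keep = (err <= tolerance).all(axis=1)
    return [s for s, k in zip(sites, keep) if k]


def average_importance(matrices, mask_mean: bool = False) -> ImportanceMatrix:
    """Entrywise mean of importance matrices for one task.

    By default skipped entries (reference base, 'N' positions) contribute
    their structural zeros; with ``mask_mean=True`` each entry is averaged
    only over the sequences in which it was actually computed.
    """
    matrices = list(matrices)
    if not matrices:
        raise InputError("need at least one matrix")
    tasks = {m.task for m in matrices}
    if len(tasks) > 1:
        raise InputError(f"cannot aggregate mixed tasks {sorted(tasks)}")
    stack = np.stack([m.values for m in matrices])
    if mask_mean:
        counts = np.zeros((4, WINDOW_LENGTH))
        for m in matrices:
            for p, ref_base in enumerate(m.reference_window):
                if ref_base == "N":
                    continue
                for b, base in enumerate(ALPHABET):
                    if base != ref_base:
                        counts[b, p] += 1
        mean = np.divide(stack.sum(axis=0), counts, out=np.zeros_like(counts),
                         where=counts > 0)
    else:
        mean = stack.mean(axis=0)
    return ImportanceMatrix(values=mean, task=matrices[0].task,
                            reference_window="N" * WINDOW_LENGTH)


def positional_importance(matrix: ImportanceMatrix) -> np.ndarray:
    """Column summary: mean |importance| over the three alternative bases."""
    return np.abs(matrix.values).sum(axis=0) / 3.0


def write_importance_tsv(matrix: ImportanceMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=list(ALPHABET),
                      columns=[str(i + 1) for i in range(WINDOW_LENGTH)])
    df.index.name = f"base/{matrix.task}"
    df.to_csv(path, sep="\t")


def plot_importance(matrix: ImportanceMatrix, path) -> None:
    """Heatmap of per-base importance (4 x 60) for one task."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(12, 2.5))
    vmax = np.abs(matrix.values).max() or 1.0
    im = ax.imshow(matrix.values, aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(4), list(ALPHABET))
    ax.set_xlabel("window position (1-based)")
    ax.set_title(f"saturated mutagenesis importance: {matrix.task}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
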