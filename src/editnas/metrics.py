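"""Evaluation protocols: rank/linear correlations and median-binarized AUC.

Models are scored per task with Pearson's r, Spearman's rho and Kendall's
tau between predicted and observed statistics, plus an AUC-ROC obtained by
binarizing observations at their median ("high" = strictly greater than the
median) and treating predictions as classification scores.  Values equal to
the median fall in the "low" class; this matters on tied data and is the
literal strict reading of a greater-than split.

All metrics are kept as fractions in [-1, 1] / [0, 1]; percentage formatting
is presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .exceptions import DimensionError, UndefinedMetricError
from .outcomes import TASK_NAMES


@dataclass(frozen=True)
class CorrelationResult:
    pearson: float
    spearman: float
    kendall_tau: float
    undefined: bool = False


def correlations(pred, obs) -> CorrelationResult:
    """Pearson, Spearman and Kendall's tau between two equal-length vectors.

    A constant input leaves all three undefined: the result carries NaNs and
    an explicit ``undefined`` flag rather than a silent zero.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise DimensionError(f"shape mismatch: {pred.shape} vs {obs.shape}")
    if len(pred) < 2:
        raise DimensionError("need at least 2 observations")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, undefined=True)
    rp = stats.pearsonr(pred, obs).statistic
    rs = stats.spearmanr(pred, obs).statistic
    kt = stats.kendalltau(pred, obs).statistic
    return CorrelationResult(float(rp), float(rs), float(kt))


def median_binarized_auc(pred, obs) -> float:
    """AUC-ROC of ``pred`` against obs binarized at its median.

    Labels are 1 where obs > median(obs), else 0; ties among predictions use
    the midrank convention (equivalently, the normalized Mann-Whitney U).
    Raises when binarization leaves a single class.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or len(pred) < 2:
        raise DimensionError("pred and obs must be equal-length, n >= 2")
    labels = obs > np.median(obs)
    if labels.all() or not labels.any():
        raise UndefinedMetricError("median binarization produced one class")
    return float(roc_auc_score(labels.astype(int), pred))


def evaluation_report(pred: np.ndarray, obs: np.ndarray,
                      tasks=TASK_NAMES) -> pd.DataFrame:
    """Per-task metric table for (n, T) prediction/observation matrices."""
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    if pred.shape != obs.shape or pred.shape[1] != len(tasks):
        raise DimensionError(f"expected matching (n, {len(tasks)}) matrices")
    rows = []
    for j, task in enumerate(tasks):
        cor = correlations(pred[:, j], obs[:, j])
        try:
            auc = median_binarized_auc(pred[:, j], obs[:, j])
        except UndefinedMetricError:
            auc = np.nan
        rows.append({"task": task, "pearson": cor.pearson,
                     "spearman": cor.spearman, "kendall_tau": cor.kendall_tau,
                     "auc_median": auc, "n": pred.shape[0],
                     "undefined": cor.undefined or np.isnan(auc)})
    return pd.DataFrame(rows)
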