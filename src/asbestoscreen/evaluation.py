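"""Model evaluation: ROC/threshold metrics, paired tests, saliency maps.

AUCs come with percentile-bootstrap confidence intervals (2000 seeded
resamples by default); confusion-matrix metrics are reported at a stated
threshold with undefined ratios returned as NaN rather than zero; model
pairs are compared with McNemar's test on paired correctness (exact binomial
form for few discordant pairs, chi-square with continuity correction
otherwise); prediction distributions can be stratified by the panel's
agreement level; and input-gradient saliency maps localise what drives a
volumetric prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .nn import sigmoid
from .volumes import Volume

__all__ = [
    "roc_auc",
    "threshold_metrics",
    "mcnemar_test",
    "agreement_stratified_report",
    "saliency_map",
]

_EXACT_MCNEMAR_MAX = 25  # below this many discordant pairs, use the exact binomial form


def _bootstrap_ci(stat_fn, n_cases: int, n_boot: int, seed: int, level: float = 0.95):
    rng = np.random.default_rng(seed)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_cases, size=n_cases)
        s = stat_fn(idx)
        if s is not None:
            stats.append(s)
    if not stats:
        return float("nan"), float("nan")
    lo, hi = np.quantile(stats, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def roc_auc(scores, labels, n_boot: int = 2000, seed: int = 0, ci_level: float = 0.95) -> dict:
    """Rank-based ROC-AUC (ties count 1/2) with a percentile bootstrap CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    point = float(roc_auc_score(labels, scores))

    def stat(idx):
        lab = labels[idx]
        if lab.min() == lab.max():
            return None  # single-class resample carries no ranking information
        return roc_auc_score(lab, scores[idx])

    lo, hi = _bootstrap_ci(stat, len(scores), n_boot, seed, ci_level)
    return {"auc": point, "ci": (lo, hi)}


def _confusion(scores, labels, threshold):
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, tn, fp, fn


def _ratio(num, den):
    return num / den if den > 0 else float("nan")


def threshold_metrics(
    scores, labels, threshold: float = 0.5, n_boot: int = 2000, seed: int = 0
) -> dict:
    """Accuracy/sensitivity/specificity/PPV/NPV at a threshold, with CIs.

    Ratios with a zero denominator (e.g. PPV with no predicted positives)
    are reported as NaN, never as zero.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("threshold metrics need both classes present")

    def metrics_at(idx):
        tp, tn, fp, fn = _confusion(scores[idx], labels[idx], threshold)
        return {
            "accuracy": _ratio(tp + tn, tp + tn + fp + fn),
            "sensitivity": _ratio(tp, tp + fn),
            "specificity": _ratio(tn, tn + fp),
            "ppv": _ratio(tp, tp + fp),
            "npv": _ratio(tn, tn + fn),
        }

    all_idx = np.arange(len(scores))
    point = metrics_at(all_idx)
    out = {"threshold": threshold}
    rng = np.random.default_rng(seed)
    boot = {k: [] for k in point}
    for _ in range(n_boot):
        idx = rng.integers(0, len(scores), size=len(scores))
        m = metrics_at(idx)
        for k, v in m.items():
            if np.isfinite(v):
                boot[k].append(v)
    for k, v in point.items():
        ci = (
            tuple(float(q) for q in np.quantile(boot[k], [0.025, 0.975]))
            if boot[k]
            else (float("nan"), float("nan"))
        )
        out[k] = v
        out[f"{k}_ci"] = ci
    return out


def mcnemar_test(correct_a, correct_b) -> float:
    """Two-sided McNemar p-value from paired per-case correctness indicators.

    Uses the exact binomial form when the discordant count ``b + c`` is below
    25, otherwise the chi-square statistic with continuity correction.  With
    no discordant pairs the models are indistinguishable and p = 1.
    """
    a = np.asarray(correct_a).astype(bool)
    b = np.asarray(correct_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("paired correctness vectors must have equal length")
    n01 = int(np.sum(a & ~b))
    n10 = int(np.sum(~a & b))
    if n01 + n10 == 0:
        return 1.0
    table = [[int(np.sum(a & b)), n01], [n10, int(np.sum(~a & ~b))]]
    exact = (n01 + n10) < _EXACT_MCNEMAR_MAX
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(min(res.pvalue, 1.0))


def agreement_stratified_report(scores, n_positive_votes) -> pd.DataFrame:
    """Prediction distribution per panel-agreement stratum (k = 0..3).

    Returns mean, standard deviation, and quartiles of the predicted
    probabilities within each stratum; empty strata appear as NaN rows.
    A ``monotone`` attribute-style column is not added — compare
    ``mean[3] > mean[0]`` directly.
    """
    scores = np.asarray(scores, dtype=float)
    k = np.asarray(n_positive_votes).astype(int)
    if scores.shape != k.shape:
        raise ValueError("scores and vote counts must align")
    if ((k < 0) | (k > 3)).any():
        raise ValueError("positive-vote counts must be in 0..3")
    rows = []
    for stratum in range(4):
        s = scores[k == stratum]
        if s.size == 0:
            rows.append({"k": stratum, "n": 0, "mean": np.nan, "sd": np.nan,
                         "q25": np.nan, "median": np.nan, "q75": np.nan})
        else:
            q25, med, q75 = np.quantile(s, [0.25, 0.5, 0.75])
            rows.append({"k": stratum, "n": int(s.size), "mean": float(s.mean()),
                         "sd": float(s.std(ddof=1)) if s.size > 1 else np.nan,
                         "q25": float(q25), "median": float(med), "q75": float(q75)})
    return pd.DataFrame(rows).set_index("k")


def saliency_map(model, volume, heatmap=None, dlco_pct: float | None = None) -> np.ndarray:
    """Input-gradient saliency: |d p / d voxel|, max-normalised to [0, 1].

    Backpropagates the predicted probability to the input voxels and sums
    the absolute gradient over input channels, yielding a nonnegative grid
    aligned with the input volume.
    """
    if not hasattr(model, "backward"):
        raise TypeError("model does not expose gradients; saliency needs a backprop-capable classifier")
    values = volume.values if isinstance(volume, Volume) else np.asarray(volume)
    channels = [values]
    if model.config.input_channels == 2:
        if heatmap is None:
            raise ValueError("this model takes the anomaly heatmap as a second channel")
        channels.append(np.asarray(heatmap))
    x = np.stack(channels)[None].astype(np.float64)
    dlco = None
    if model.config.use_dlco_input:
        if dlco_pct is None:
            raise ValueError("this model takes DLCO as additional input")
        dlco = np.array([dlco_pct / 100.0])

    logit = model.forward(x, dlco)
    p = sigmoid(logit)
    # d p / d logit = p (1 - p); propagate that scalar back to the voxels
    gx = model.backward(np.asarray(p * (1.0 - p)), need_input_grad=True)
    sal = np.abs(gx[0]).sum(axis=0)
    peak = sal.max()
    return sal / peak if peak > 0 else sal
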