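"""Model evaluation: ROC/AUC with DeLong confidence intervals, one-vs-rest
multiclass AUCs, confusion matrices and operating rates, the DeLong paired
test, decision-curve analysis, tile-level heatmaps, and t-SNE embeddings.

AUC follows the Mann-Whitney convention (ties count half).  Confidence
intervals and the paired comparison both use the DeLong structural-component
covariance estimator, keeping a single estimator family throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "auc_ci",
    "ovr_aucs",
    "micro_macro_auc",
    "confusion_and_rates",
    "delong_test",
    "decision_curve",
    "probability_heatmap",
    "plot_probability_heatmap",
    "tsne_embed",
    "EvalReport",
    "evaluate_binary",
]


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based, ties averaged)."""
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out

def _delong_components(preds: np.ndarray, y: np.ndarray):
    """AUCs and structural-component covariance for k paired predictors.

    preds: (k, n) scores; y: binary 0/1 labels. Returns (aucs, S) where S is
    the k x k covariance of the AUC estimates.
    """
    pos = preds[:, y == 1]
    neg = preds[:, y == 0]
    m, n = pos.shape[1], neg.shape[1]
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    k = preds.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    sx = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    sy = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    s = np.atleast_2d(sx) / m + np.atleast_2d(sy) / n
    return aucs, s


def _as_binary(labels, positive=None) -> np.ndarray:
    y = np.asarray(labels)
    vals = sorted(pd.unique(y))
    if set(vals) <= {0, 1}:
        return y.astype(int)
    if len(vals) != 2:
        raise ValueError(f"expected binary labels, got {vals}")
    pos = positive if positive is not None else vals[1]
    return (y == pos).astype(int)


def auc_ci(scores, labels, level: float = 0.95,
           positive=None) -> tuple[float, float, float]:
    """AUC with a DeLong-variance Wald CI, clipped to [0, 1]."""
    y = _as_binary(labels, positive)
    if y.min() == y.max():
        raise ValueError("only one class present; AUC undefined")
    aucs, s = _delong_components(np.asarray(scores, dtype=float)[None, :], y)
    se = float(np.sqrt(max(s[0, 0], 0.0)))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return (float(aucs[0]),
            float(max(aucs[0] - zq * se, 0.0)),
            float(min(aucs[0] + zq * se, 1.0)))


def delong_test(scores_a, scores_b, labels,
                positive=None) -> tuple[float, float, float, float]:
    """Two-sided DeLong test for two correlated AUCs on paired documents.

    Returns (auc_a, auc_b, z, p).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("scores must be paired (same documents, same length)")
    y = _as_binary(labels, positive)
    if len(y) != len(a):
        raise ValueError("labels length does not match scores")
    aucs, s = _delong_components(np.vstack([a, b]), y)
    var = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    diff = aucs[0] - aucs[1]
    if var <= 0:
        z = 0.0 if abs(diff) < 1e-12 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), float(z), p


# ---------------------------------------------------------------------------
# Multiclass AUC
# ---------------------------------------------------------------------------

def ovr_aucs(probabilities: pd.DataFrame, labels) -> dict[str, float | None]:
    """One-vs-others AUC per class; absent classes map to None."""
    y = np.asarray(labels).astype(str)
    out: dict[str, float | None] = {}
    for cls in probabilities.columns:
        mask = (y == str(cls)).astype(int)
        if mask.min() == mask.max():
            out[str(cls)] = None
            continue
        auc, *_ = auc_ci(probabilities[cls].to_numpy(), mask)
        out[str(cls)] = auc
    return out


def micro_macro_auc(probabilities: pd.DataFrame, labels) -> tuple[float, float]:
    """Micro (pooled decisions) and macro (unweighted mean) one-vs-rest AUC."""
    per_class = ovr_aucs(probabilities, labels)
    defined = [v for v in per_class.values() if v is not None]
    if not defined:
        raise ValueError("no class with both positive and negative documents")
    macro = float(np.mean(defined))
    y = np.asarray(labels).astype(str)
    onehot = np.column_stack([(y == str(c)).astype(int)
                              for c in probabilities.columns])
    micro, *_ = auc_ci(probabilities.to_numpy().ravel(), onehot.ravel())
    return float(micro), macro


# ---------------------------------------------------------------------------
# Confusion matrix and operating rates
# ---------------------------------------------------------------------------

def confusion_and_rates(predicted, truth, positive_class) -> dict:
    """Confusion matrix plus accuracy/sensitivity/specificity.

    Rates come from the 2x2 table with ``positive_class`` as positive
    (other labels pooled as negative).
    """
    pred = np.asarray(predicted)
    y = np.asarray(truth)
    if len(pred) != len(y):
        raise ValueError("length mismatch")
    labels = sorted(set(map(str, y)) | set(map(str, pred)))
    if str(positive_class) not in labels:
        raise ValueError(f"unknown positive_class {positive_class!r}")
    mat = pd.DataFrame(0, index=labels, columns=labels)
    for t, p in zip(y.astype(str), pred.astype(str)):
        mat.loc[t, p] += 1
    tp = int(((y.astype(str) == str(positive_class))
              & (pred.astype(str) == str(positive_class))).sum())
    fn = int((y.astype(str) == str(positive_class)).sum()) - tp
    fp = int((pred.astype(str) == str(positive_class)).sum()) - tp
    tn = len(y) - tp - fn - fp
    return {
        "confusion": mat,
        "accuracy": float((pred.astype(str) == y.astype(str)).mean()),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
    }


# ---------------------------------------------------------------------------
# Decision curve analysis
# ---------------------------------------------------------------------------

def decision_curve(probabilities, labels, thresholds) -> pd.DataFrame:
    """Net benefit of acting on the model at each threshold pt.

    net_benefit = TP/n - FP/n * pt/(1-pt); treat-all and treat-none
    references included as columns.
    """
    pt = np.asarray(thresholds, dtype=float)
    if pt.size == 0:
        raise ValueError("empty threshold grid")
    if ((pt <= 0) | (pt >= 1)).any():
        raise ValueError("thresholds must lie strictly in (0, 1)")
    p = np.asarray(probabilities, dtype=float)
    y = _as_binary(labels)
    n = len(y)
    prev = y.mean()
    rows = []
    for t in pt:
        act = p >= t
        tp = int((act & (y == 1)).sum())
        fp = int((act & (y == 0)).sum())
        odds = t / (1 - t)
        rows.append({
            "threshold": t,
            "net_benefit": tp / n - fp / n * odds,
            "treat_all": prev - (1 - prev) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Heatmaps and embeddings
# ---------------------------------------------------------------------------

def probability_heatmap(table: pd.DataFrame,
                        prob_column: str) -> tuple[np.ma.MaskedArray, np.ndarray]:
    """Per-tile probability and prediction maps for one slide.

    Returns ``(prob_map, pred_map)`` of shape ``(max_row+1, max_col+1)``;
    grid cells without a tile are masked in the probability map and hold
    ``None`` in the (object-dtype) prediction map.
    """
    if table["slide_id"].nunique() > 1:
        raise ValueError("heatmap expects the table of exactly one slide")
    cells = list(zip(table["col"].astype(int), table["row"].astype(int)))
    if len(cells) != len(set(cells)):
        raise ValueError("duplicate grid cells in slide table")
    nrow = int(table["row"].max()) + 1
    ncol = int(table["col"].max()) + 1
    prob = np.ma.masked_all((nrow, ncol))
    pred = np.full((nrow, ncol), None, dtype=object)
    for _, r in table.iterrows():
        prob[int(r["row"]), int(r["col"])] = float(r[prob_column])
        pred[int(r["row"]), int(r["col"])] = r["label"]
    return prob, pred


def plot_probability_heatmap(table: pd.DataFrame, prob_column: str, path) -> None:
    """Render probability (continuous colormap + colorbar) and prediction maps."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prob, pred = probability_heatmap(table, prob_column)
    labels = sorted({v for v in pred.ravel() if v is not None})
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    im = ax1.imshow(prob, vmin=0, vmax=1, cmap="viridis")
    ax1.set_title(prob_column)
    fig.colorbar(im, ax=ax1)
    idx = np.full(prob.shape, np.nan)
    for i, l in enumerate(labels):
        idx[pred == l] = i
    im2 = ax2.imshow(np.ma.masked_invalid(idx), cmap="tab10",
                     vmin=0, vmax=max(len(labels) - 1, 1))
    ax2.set_title("predicted label")
    fig.colorbar(im2, ax=ax2, ticks=range(len(labels)))
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def tsne_embed(features: pd.DataFrame | np.ndarray, seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding (standard sklearn implementation, seeded)."""
    x = np.asarray(features, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature values")
    if len(x) < 3:
        raise ValueError("need at least 3 documents to embed")
    from sklearn.manifold import TSNE

    perplexity = min(30.0, (len(x) - 1) / 3.0)
    return TSNE(n_components=2, random_state=seed, init="pca",
                perplexity=perplexity).fit_transform(x)


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """One fitted model's evaluation bundle (JSON-serializable)."""

    level: str
    document_unit: str | None
    auc: float
    ci: tuple[float, float]
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: dict
    decision_curve: list[dict] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = {k: getattr(self, k) for k in
             ("level", "document_unit", "auc", "ci", "accuracy",
              "sensitivity", "specificity", "confusion", "decision_curve",
              "extras")}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=float)


def evaluate_binary(scores, labels, positive_class,
                    threshold: float = 0.5,
                    level: str = "wsi",
                    document_unit: str | None = None,
                    dca_thresholds=None) -> EvalReport:
    """Binary evaluation at an operating threshold (default 0.5)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    auc, lo, hi = auc_ci(s, _as_binary(y, positive_class))
    neg_name = "other"
    pred = np.where(s >= threshold, str(positive_class), neg_name)
    truth = np.where(np.asarray(_as_binary(y, positive_class)) == 1,
                     str(positive_class), neg_name)
    rates = confusion_and_rates(pred, truth, str(positive_class))
    dca = (decision_curve(s, _as_binary(y, positive_class), dca_thresholds)
           .to_dict("records") if dca_thresholds is not None else [])
    return EvalReport(
        level=level, document_unit=document_unit, auc=auc, ci=(lo, hi),
        accuracy=rates["accuracy"], sensitivity=rates["sensitivity"],
        specificity=rates["specificity"],
        confusion=rates["confusion"].to_dict(), decision_curve=dca)
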