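"""Association screen between fusion features and binary pathological findings.

Each feature is compared between finding-positive and finding-negative cases
with a two-sided Welch t-test (equivalent, up to monotone transformation, to
a point-biserial association).  Raw p-values are reported to match the usual
P < 0.05 screening convention; a Benjamini-Hochberg adjusted column is
emitted alongside for honest reuse.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["associate", "summarize", "screen_findings"]


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def associate(features: pd.DataFrame, finding: pd.Series | np.ndarray,
              ) -> pd.DataFrame:
    """Welch t-test of every feature between finding groups.

    Returns a frame ``feature, statistic, p, p_adjusted`` (BH), excluding
    constant features (dropped with a warning).  Requires both finding
    levels with at least 2 cases each.
    """
    y = np.asarray(finding).astype(int)
    if len(y) != len(features):
        raise ValueError("finding length does not match feature rows")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("finding must be binary 0/1")
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("finding is constant; association undefined")
    if n1 < 2 or n0 < 2:
        raise ValueError("each finding level needs >= 2 cases")

    constant = [c for c in features.columns
                if features[c].nunique(dropna=False) <= 1]
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant feature(s): {constant[:5]}",
            stacklevel=2)
    cols = [c for c in features.columns if c not in constant]
    x = features[cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(x[y == 1], x[y == 0], equal_var=False, axis=0)
    out = pd.DataFrame({"feature": cols, "statistic": t, "p": p})
    dropped = out["p"].isna()
    if dropped.any():
        warnings.warn(f"dropping {int(dropped.sum())} untestable feature(s)",
                      stacklevel=2)
        out = out[~dropped].reset_index(drop=True)
    out["p_adjusted"] = _bh_adjust(out["p"].to_numpy())
    return out


def summarize(assoc: pd.DataFrame, alpha: float = 0.05,
              top_k: int = 10) -> tuple[int, list[str]]:
    """Count of significant features and the top-k names ranked by p.

    Ranking is ascending by p with ties broken by feature name.
    """
    count = int((assoc["p"] < alpha).sum())
    ranked = assoc.sort_values(["p", "feature"], kind="mergesort")
    return count, ranked["feature"].head(top_k).tolist()


def screen_findings(features: pd.DataFrame, findings: pd.DataFrame,
                    alpha: float = 0.05, top_k: int = 10) -> pd.DataFrame:
    """Run the screen for every finding column; long-format result table."""
    frames = []
    for col in findings.columns:
        if col == "case_id":
            continue
        a = associate(features, findings[col])
        a.insert(1, "finding", col)
        frames.append(a)
    if not frames:
        raise ValueError("no finding columns")
    return pd.concat(frames, ignore_index=True)
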