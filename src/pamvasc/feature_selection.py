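"""Welch screening and correlation pruning of the per-image feature table.

Features are screened for group differences (normal/benign vs EC/EIN) with
Welch's unequal-variance t-test, then pruned for redundancy: ranked by
ascending p, a feature is accepted only if its absolute Pearson correlation
with every already-accepted feature stays below a threshold, stopping at k
features.  No multiple-testing correction is applied; raw two-sided p-values
drive both the screen and the ranking.  Missing values (e.g. an undefined
branching interval) are handled with pairwise-complete observations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rf_preprocessing import ValidationError

__all__ = ["WelchResult", "SelectionResult", "welch_t", "select_features"]

LABEL_COLUMN = "label"
DEFAULT_K = 5
DEFAULT_CORR_THRESHOLD = 0.5
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class SelectionResult:
    """Per-feature Welch statistics, correlation matrix, and the chosen set."""

    stats: pd.DataFrame  # index=feature, columns: t, df, p, n_a, n_b
    correlation: pd.DataFrame
    selected: list[str]

    def to_json_dict(self) -> dict:
        return {
            "selected": self.selected,
            "stats": self.stats.reset_index().to_dict(orient="records"),
            "correlation": {
                "features": list(self.correlation.index),
                "matrix": self.correlation.to_numpy().tolist(),
            },
        }


def welch_t(group_a: np.ndarray, group_b: np.ndarray) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch–Satterthwaite degrees of freedom; p from the Student-t survival
    function.  Two groups with zero variance and equal means give t = 0,
    p = 1 rather than 0/0.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 finite observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        delta = a.mean() - b.mean()
        if delta == 0.0:
            return WelchResult(t=0.0, df=float(na + nb - 2), p=1.0)
        return WelchResult(t=math.copysign(math.inf, delta), df=float(na + nb - 2), p=0.0)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def _pairwise_pearson(x: pd.Series, y: pd.Series) -> float:
    """|r| over pairwise-complete observations; 0 if degenerate."""
    ok = x.notna() & y.notna()
    if ok.sum() < 3:
        return 0.0
    xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    return float(abs(np.corrcoef(xv, yv)[0, 1]))


def select_features(
    table: pd.DataFrame,
    k: int = DEFAULT_K,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    label_column: str = LABEL_COLUMN,
) -> SelectionResult:
    """Greedy p-ordered selection of significant, mutually uncorrelated features.

    Only features with Welch p < ``alpha`` are eligible.  Ties in p are broken
    by feature name, so the selection is deterministic.  If fewer than ``k``
    features are acceptable the shorter list is returned with a warning.
    """
    if label_column not in table.columns:
        raise ValidationError(f"table has no {label_column!r} column")
    labels = table[label_column]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 label values, got {groups}")
    features = [c for c in table.columns if c != label_column]

    rows = []
    for name in features:
        col = pd.to_numeric(table[name], errors="coerce")
        a = col[labels == groups[0]].dropna().to_numpy()
        b = col[labels == groups[1]].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append((name, np.nan, np.nan, np.nan, len(a), len(b)))
            continue
        res = welch_t(a, b)
        rows.append((name, res.t, res.df, res.p, len(a), len(b)))
    stats_df = pd.DataFrame(
        rows, columns=["feature", "t", "df", "p", "n_a", "n_b"]
    ).set_index("feature")

    corr = pd.DataFrame(np.eye(len(features)), index=features, columns=features)
    for i, fi in enumerate(features):
        for fj in features[i + 1 :]:
            r = _pairwise_pearson(
                pd.to_numeric(table[fi], errors="coerce"),
                pd.to_numeric(table[fj], errors="coerce"),
            )
            corr.loc[fi, fj] = corr.loc[fj, fi] = r

    eligible = stats_df[stats_df["p"] < alpha].reset_index()
    eligible = eligible.sort_values(["p", "feature"], kind="mergesort")
    selected: list[str] = []
    for name in eligible["feature"]:
        if len(selected) >= k:
            break
        if all(corr.loc[name, s] < corr_threshold for s in selected):
            selected.append(name)
    if len(selected) < k:
        warnings.warn(
            f"only {len(selected)} of the requested {k} features are "
            f"significant at p<{alpha} and mutually uncorrelated "
            f"(|r|<{corr_threshold})",
            stacklevel=2,
        )
    return SelectionResult(stats=stats_df, correlation=corr, selected=selected)
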