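"""Group statistics over cluster labelings.

One-way MANOVA (Wilks' lambda with Rao's F approximation), Tukey-Kramer HSD
post-hoc tests, unadjusted LSD pairwise t-tests for questionnaire scores,
partial eta squared effect sizes, and descriptive cluster profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ManovaResult",
    "one_way_manova",
    "tukey_hsd",
    "lsd_pairwise",
    "partial_eta_squared",
    "cluster_profile",
]


@dataclass
class ManovaResult:
    wilks_lambda: float
    f_stat: float
    df1: float
    df2: float  # exact (fractional) denominator df
    df2_display: int  # truncated for reporting
    p_value: float


def _sscp(X: np.ndarray) -> np.ndarray:
    centered = X - X.mean(axis=0)
    return centered.T @ centered


def one_way_manova(X, labels) -> ManovaResult:
    """Wilks' lambda MANOVA with Rao's F approximation.

    df1 = p(k-1); df2 = s[(N-k) - (p-(k-1)+1)/2] - (p(k-1)-2)/2 with
    s = sqrt((p^2 (k-1)^2 - 4) / (p^2 + (k-1)^2 - 5)).  The denominator df is
    reported both exactly and truncated to an integer for display.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    N, p = X.shape
    groups = np.unique(labels)
    k = groups.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if np.sum(labels == g) < p + 1:
            raise ValueError(f"group {g!r} smaller than p+1 = {p + 1}")
    W = np.zeros((p, p))
    for g in groups:
        W += _sscp(X[labels == g])
    T = _sscp(X)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("singular SSCP matrix")
    lam = float(np.exp(logdet_w - logdet_t))
    h = k - 1
    denom = p * p + h * h - 5
    s = math.sqrt((p * p * h * h - 4) / denom) if denom > 0 else 1.0
    df1 = p * h
    df2 = s * ((N - k) - (p - h + 1) / 2.0) - (df1 - 2) / 2.0
    lam_s = lam ** (1.0 / s)
    f_stat = (1.0 - lam_s) / lam_s * (df2 / df1)
    p_value = float(sps.f.sf(f_stat, df1, df2))
    return ManovaResult(
        wilks_lambda=lam,
        f_stat=float(f_stat),
        df1=float(df1),
        df2=float(df2),
        df2_display=int(df2),
        p_value=p_value,
    )


def _pooled_within(values: np.ndarray, labels: np.ndarray):
    groups = np.unique(labels)
    n = values.size
    k = groups.size
    ssw = 0.0
    means = {}
    counts = {}
    for g in groups:
        vals = values[labels == g]
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        means[g] = float(vals.mean())
        counts[g] = int(vals.size)
        ssw += float(((vals - vals.mean()) ** 2).sum())
    df = n - k
    msw = ssw / df
    return groups, means, counts, msw, df


def tukey_hsd(values, labels) -> pd.DataFrame:
    """All pairwise comparisons with studentized-range statistics (Tukey-Kramer).

    Unequal group sizes are handled by the Kramer form
    ``se = sqrt(MSW/2 * (1/n_i + 1/n_j))``; adjusted p-values come from the
    studentized-range distribution with k groups and N-k error df.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups, means, counts, msw, df = _pooled_within(values, labels)
    k = groups.size
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            diff = means[a] - means[b]
            se = math.sqrt(msw / 2.0 * (1.0 / counts[a] + 1.0 / counts[b]))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df))
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_diff": diff,
                    "se": se,
                    "q": q,
                    "p_adj": min(max(p_adj, 0.0), 1.0),
                }
            )
    return pd.DataFrame(rows)


def lsd_pairwise(values, labels) -> pd.DataFrame:
    """Unadjusted pairwise t-tests using the pooled within-group variance."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups, means, counts, msw, df = _pooled_within(values, labels)
    rows = []
    for i in range(groups.size):
        for j in range(i + 1, groups.size):
            a, b = groups[i], groups[j]
            diff = means[a] - means[b]
            se = math.sqrt(msw * (1.0 / counts[a] + 1.0 / counts[b]))
            t = diff / se
            p = float(2.0 * sps.t.sf(abs(t), df))
            rows.append(
                {"group_a": a, "group_b": b, "mean_diff": diff, "se": se, "t": t, "p": p}
            )
    return pd.DataFrame(rows)


def partial_eta_squared(values, labels) -> float:
    """Effect size SS_between / (SS_between + SS_within) for one feature."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for g in groups:
        vals = values[labels == g]
        ssb += vals.size * (vals.mean() - grand) ** 2
        ssw += float(((vals - vals.mean()) ** 2).sum())
    total = ssb + ssw
    if total == 0:
        raise ValueError("zero total sum of squares")
    return float(ssb / total)


def cluster_profile(features: pd.DataFrame, scores: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-cluster mean (SD) of ROM features and scores plus prevalence percentages.

    ``features`` must carry trunk_rom/hip_rom/knee_rom columns, ``scores``
    pseq/pain columns, aligned row-wise with ``labels``.  SDs of singleton
    clusters are reported as NaN.
    """
    labels = np.asarray(labels)
    df = features[["trunk_rom", "hip_rom", "knee_rom"]].copy().reset_index(drop=True)
    df["pseq"] = np.asarray(scores["pseq"])
    df["pain"] = np.asarray(scores["pain"])
    df["cluster"] = labels
    grouped = df.groupby("cluster")
    out = grouped.agg(["mean", "std"])
    out.columns = [f"{col}_{stat}" for col, stat in out.columns]
    out["n_trials"] = grouped.size()
    out["prevalence_pct"] = 100.0 * out["n_trials"] / labels.size
    return out.reset_index()
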