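"""Nonparametric group statistics and infiltration correlation.

Every spectral feature is compared across the four cortical compartments with
a Kruskal-Wallis omnibus test followed by Dunn's post hoc pairwise test
(mean-rank z statistics with tie-corrected variance, Holm-adjusted p values by
default).  Two-group contrasts (e.g. glioma subtypes) use Mann-Whitney;
monotone associations (distance from the tumor border, biopsy tumor-cell
counts) use two-sided Spearman correlation.

Biopsy infiltration counts (tumor cells / 250 um^2) are stratified into
healthy (count 0), low infiltration (0 < count < 50) and high infiltration
(count >= 50); feature-count correlations are computed within each stratum.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Significance threshold used throughout.
ALPHA = 0.05

#: Infiltration stratum boundary (tumor cells per 250 um^2).
HIGH_INFILTRATION_MIN = 50


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p value.

    Degenerate input (all observations identical) is defined as H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    groups = [values[labels == g] for g in pd.unique(labels)]
    groups = [g[np.isfinite(g)] for g in groups]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(values, labels, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's post hoc test for all group pairs after a Kruskal-Wallis omnibus.

    z_ab = (Rbar_a - Rbar_b) / sqrt(A (1/n_a + 1/n_b)) with the tie-corrected
    variance factor A = N(N+1)/12 - sum(t^3 - t) / (12 (N - 1)).  Two-sided
    normal p values are adjusted by the chosen method (``holm`` default,
    ``bonferroni`` available, ``none`` to disable).  Group pairs are ordered
    by sorted group name so the result is independent of input ordering.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    group_names = sorted(set(labels.tolist()))
    ranks = sps.rankdata(values)
    n_total = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_factor -= tie_term / (12.0 * (n_total - 1))

    mean_rank = {g: ranks[labels == g].mean() for g in group_names}
    n = {g: int((labels == g).sum()) for g in group_names}

    rows = []
    for a, b in itertools.combinations(group_names, 2):
        if n[a] == 0 or n[b] == 0:
            continue
        se = np.sqrt(var_factor * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    if adjust == "none" or out.empty:
        out["p_adj"] = out.get("p_raw", pd.Series(dtype=float))
    else:
        out["p_adj"] = multipletests(out["p_raw"].to_numpy(), method=adjust)[1]
    return out


def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration for small tie-free samples, tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_corr(x, y) -> tuple[float, float]:
    """Two-sided Spearman rank correlation (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("need n >= 4 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("zero rank variance; correlation undefined")
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def infiltration_stratum(count: int) -> str:
    """Stratum label from a biopsy tumor-cell count: ``healthy`` at 0, ``low``
    below 50 cells / 250 um^2, ``high`` at or above 50."""
    if count < 0:
        raise ValueError("counts must be >= 0")
    if count == 0:
        return "healthy"
    return "low" if count < HIGH_INFILTRATION_MIN else "high"


@dataclass
class CorrelationResult:
    stratum: str
    feature: str
    rho: float
    p: float
    n: int


def stratify_and_correlate(biopsy_table: pd.DataFrame, feature_table: pd.DataFrame,
                           features: list[str] | None = None,
                           min_n: int = 4) -> pd.DataFrame:
    """Spearman correlation of each feature with the infiltration count,
    within each infiltration stratum.

    ``biopsy_table`` needs ``channel_id`` and ``count`` columns; biopsies are
    joined to the feature table by channel.  Strata with fewer than ``min_n``
    biopsies report missing (NaN) correlations.
    """
    if features is None:
        features = [c for c in feature_table.columns
                    if c not in ("channel_id", "patient_id", "label")
                    and pd.api.types.is_numeric_dtype(feature_table[c])]
    merged = biopsy_table.merge(feature_table, on="channel_id", how="left",
                                validate="many_to_one")
    unmatched = merged[features[0]].isna() if features else pd.Series(dtype=bool)
    if len(features) and unmatched.any():
        logger.warning("%d biopsies without matching channel features",
                       int(unmatched.sum()))
    merged["stratum"] = merged["count"].map(infiltration_stratum)
    rows = []
    for stratum, block in merged.groupby("stratum"):
        for feat in features:
            sub = block[[feat, "count"]].dropna()
            if len(sub) < min_n or sub["count"].nunique() < 2 or sub[feat].nunique() < 2:
                rows.append(CorrelationResult(stratum, feat, np.nan, np.nan, len(sub)))
                continue
            rho, p = spearman_corr(sub[feat], sub["count"])
            rows.append(CorrelationResult(stratum, feat, rho, p, len(sub)))
    return pd.DataFrame([r.__dict__ for r in rows])


def compartment_summary(feature_table: pd.DataFrame, feature_cols: list[str],
                        label_col: str = "label",
                        group_order: tuple[str, ...] = (
                            "tumoral", "close_peritumoral",
                            "far_peritumoral", "healthy"),
                        adjust: str = "holm") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature compartment means +/- SD with omnibus and pairwise tests.

    Returns ``(summary, pairwise)``: the summary has one row per feature with
    mean and SD per compartment plus Kruskal-Wallis H and p; the pairwise
    frame stacks Dunn results (z, raw and adjusted p) for all label pairs and
    features.
    """
    labeled = feature_table.dropna(subset=[label_col])
    present = [g for g in group_order if g in set(labeled[label_col])]
    summary_rows = []
    pairwise_frames = []
    for feat in feature_cols:
        sub = labeled[[feat, label_col]].dropna()
        row: dict[str, object] = {"feature": feat}
        for g in present:
            vals = sub.loc[sub[label_col] == g, feat]
            row[f"mean_{g}"] = vals.mean()
            row[f"sd_{g}"] = vals.std(ddof=1)
        try:
            h, p = kruskal_wallis(sub[feat], sub[label_col])
        except ValueError:
            h, p = np.nan, np.nan
        row["H"], row["p_omnibus"] = h, p
        summary_rows.append(row)
        if np.isfinite(h):
            pw = dunn_posthoc(sub[feat], sub[label_col], adjust=adjust)
            pw.insert(0, "feature", feat)
            pairwise_frames.append(pw)
    pairwise = (pd.concat(pairwise_frames, ignore_index=True)
                if pairwise_frames else pd.DataFrame())
    return pd.DataFrame(summary_rows), pairwise
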