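"""Landscape typology and nonparametric group comparisons.

Landscape units are classified by forest share into three Hladnik-style
types (forest > 85%, forested 40-85%, agricultural/urban < 40%).  Ecosystem-
service values, ES-group means and LULC compositions are compared across
landscape types and efficiency categories with the tie-corrected
Kruskal-Wallis H test, and associations are measured with Spearman's rank
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import LULC_CLASSES
from .indicators import ES_GROUPS

LANDSCAPE_TYPES = ("forest", "forested", "agricultural_urban")


@dataclass
class KWResult:
    H: float
    df: int
    p_value: float
    group_sizes: dict[str, int]


@dataclass
class SpearmanResult:
    rho: float
    p_value: float


def classify_landscape_type(forest_share: float) -> str:
    """Forest if share > 0.85, forested if 0.40 <= share <= 0.85, else
    agricultural_urban.  The 0.85 boundary belongs to the middle band."""
    if not 0.0 <= forest_share <= 1.0:
        raise ValueError(f"forest share {forest_share} outside [0, 1]")
    if forest_share > 0.85:
        return "forest"
    if forest_share >= 0.40:
        return "forested"
    return "agricultural_urban"


#: below this total sample size the "auto" p-value switches to permutation
SMALL_SAMPLE_N = 50


def _permutation_p(values: np.ndarray, sizes: np.ndarray, H_obs: float,
                   n_perm: int, seed: int) -> float:
    """Monte-Carlo permutation p for the tie-corrected H statistic."""
    n = len(values)
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(ranks, (n_perm, 1)), axis=1)
    tot = np.zeros(n_perm)
    start = 0
    for sz in sizes:
        tot += perm[:, start : start + sz].sum(axis=1) ** 2 / sz
        start += sz
    H_perm = (12.0 / (n * (n + 1)) * tot - 3.0 * (n + 1)) / tie
    return float(np.mean(H_perm >= H_obs - 1e-12))


def kruskal_wallis(
    values,
    group_labels,
    p_method: str = "auto",
    n_perm: int = 20_000,
    seed: int = 0,
) -> KWResult:
    """Tie-corrected Kruskal-Wallis H test.

    The p-value uses the chi-square approximation on (g - 1) df
    (``p_method="chi2"``) or a seeded ``n_perm``-draw permutation reference
    (``"permutation"``); the default ``"auto"`` picks permutation for small
    samples (n <= 50), where the chi-square approximation can be off by far
    more than Monte-Carlo error, and chi-square otherwise.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = pd.unique(labels)
    groups = [values[labels == g] for g in uniq]
    groups = [g for g in groups if len(g) > 0]
    sizes_d = {str(g): int((labels == g).sum()) for g in uniq}
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two non-empty groups")
    if p_method not in ("auto", "chi2", "permutation"):
        raise ValueError(f"unknown p_method {p_method!r}")
    df = len(groups) - 1
    if all(np.all(g == values[0]) for g in groups):
        # all observations identical: no rank variation
        return KWResult(H=0.0, df=df, p_value=1.0, group_sizes=sizes_d)
    H, p_chi2 = sps.kruskal(*groups)
    if p_method == "chi2" or (p_method == "auto" and len(values) > SMALL_SAMPLE_N):
        p = float(p_chi2)
    else:
        # canonical order (sorted values, label-sorted group sizes) so the
        # seeded Monte-Carlo p is invariant to observation ordering
        order = np.argsort([str(g) for g in uniq])
        sizes = np.array([len(groups[i]) for i in order])
        p = _permutation_p(np.sort(values), sizes, float(H), n_perm, seed)
    return KWResult(H=float(H), df=df, p_value=p, group_sizes=sizes_d)


def spearman(x, y) -> SpearmanResult:
    """Tie-handled Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("Spearman correlation needs at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p_value=float(p))


def _group_mean_sd(df: pd.DataFrame, labels: pd.Series, order) -> pd.DataFrame:
    out = {}
    for g in order:
        sub = df.loc[labels == g]
        out[g] = {
            c: f"{sub[c].mean():.3f} ({sub[c].std(ddof=1):.3f})" if len(sub) else ""
            for c in df.columns
        }
    return pd.DataFrame(out)


def es_group_means(es_norm: pd.DataFrame) -> pd.DataFrame:
    """Per-LU mean of normalized ES values within each of the three ES groups
    (plus the overall mean over all 17)."""
    cols = {}
    for grp in ("regulating", "cultural", "provisioning"):
        members = [c for c in es_norm.columns if ES_GROUPS.get(c) == grp]
        cols[grp] = es_norm[members].mean(axis=1)
    cols["all"] = es_norm.mean(axis=1)
    return pd.DataFrame(cols, index=es_norm.index)


def _kw_or_nan(values, labels) -> tuple[float, float]:
    try:
        r = kruskal_wallis(values, labels)
        return r.H, r.p_value
    except ValueError:
        warnings.warn("only one group present; Kruskal-Wallis omitted", stacklevel=2)
        return np.nan, np.nan


def group_tables(
    es_norm: pd.DataFrame,
    scores: pd.Series,
    categories: pd.Series,
    landscape_types: pd.Series,
    lulc_shares: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Build the four standard report tables.

    - ``es_vs_landscape``: Spearman rho of each ES against binary
      landscape-type membership indicators, with a Kruskal-Wallis H across
      types per ES.
    - ``es_groups_by_landscape``: ES-group means (SD) by landscape type + KW.
    - ``lulc_by_category``: mean LULC shares (%) by efficiency category + KW.
    - ``es_groups_by_category``: ES-group means (SD) by efficiency category + KW.
    """
    idx = es_norm.index
    for other in (scores, categories, landscape_types, lulc_shares):
        if not idx.equals(other.index):
            raise ValueError("lu_id indices are not aligned across tables")

    # (i) per-ES Spearman vs type membership, KW across types
    rows = {}
    for c in es_norm.columns:
        row = {"es_group": ES_GROUPS.get(c, "")}
        for t in LANDSCAPE_TYPES:
            ind = (landscape_types == t).astype(float)
            try:
                row[f"rho_{t}"] = spearman(es_norm[c], ind).rho
            except ValueError:
                row[f"rho_{t}"] = np.nan
        H, p = _kw_or_nan(es_norm[c].to_numpy(), landscape_types.to_numpy())
        row["kw_H"], row["kw_p"] = H, p
        rows[c] = row
    es_vs_landscape = pd.DataFrame(rows).T

    # (ii) ES-group means by landscape type
    grp = es_group_means(es_norm)
    table = _group_mean_sd(grp, landscape_types, LANDSCAPE_TYPES)
    table["kw_H"], table["kw_p"] = zip(
        *[_kw_or_nan(grp[g].to_numpy(), landscape_types.to_numpy()) for g in grp.columns]
    )
    es_groups_by_landscape = table

    # (iii) LULC shares (%) by efficiency category
    cat_order = ("efficient", "less_inefficient", "more_inefficient")
    lulc_pct = lulc_shares[list(LULC_CLASSES)] * 100.0
    lt = {}
    for cat in cat_order:
        sub = lulc_pct.loc[categories == cat]
        lt[cat] = sub.mean() if len(sub) else pd.Series(np.nan, index=lulc_pct.columns)
    lulc_by_category = pd.DataFrame(lt)
    lulc_by_category["kw_H"], lulc_by_category["kw_p"] = zip(
        *[_kw_or_nan(lulc_pct[c].to_numpy(), categories.to_numpy()) for c in lulc_pct.columns]
    )

    # (iv) ES-group means by efficiency category
    table4 = _group_mean_sd(grp, categories, cat_order)
    table4["kw_H"], table4["kw_p"] = zip(
        *[_kw_or_nan(grp[g].to_numpy(), categories.to_numpy()) for g in grp.columns]
    )
    es_groups_by_category = table4

    return {
        "es_vs_landscape": es_vs_landscape,
        "es_groups_by_landscape": es_groups_by_landscape,
        "lulc_by_category": lulc_by_category,
        "es_groups_by_category": es_groups_by_category,
    }
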