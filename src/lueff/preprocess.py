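"""Normalization and DEA-problem assembly.

ES columns are min-max rescaled to [0, 100] per column; exact zeros in inputs
and outputs are then replaced by 0.001 (solver-stability convention for
frontier software that cannot handle zero data).  The single DEA input is the
area-weighted mean management cost of the LULC classes in the LU, with urban
and artificial areas excluded from both the numerator and the area total.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import LULC_CLASSES, URBAN, ScenarioConfig
from .dea import DEAProblem
from .landscape import SyntheticLandscape

ZERO_REPLACEMENT = 0.001


def minmax_rescale(column: np.ndarray | pd.Series) -> np.ndarray:
    """Min-max rescale a column to [0, 100].

    A constant column carries no contrast; it is mapped to 100 everywhere
    (preserving the fixed output structure) with a loud warning.
    """
    col = np.asarray(column, dtype=float)
    if col.size < 2:
        raise ValueError("min-max normalization needs at least 2 values")
    lo, hi = col.min(), col.max()
    if hi == lo:
        warnings.warn(
            "constant column in min-max normalization; mapping all values to 100",
            stacklevel=2,
        )
        return np.full_like(col, 100.0)
    out = np.clip(100.0 * (col - lo) / (hi - lo), 0.0, 100.0)
    # pin the extremes exactly despite float rounding
    out[col == lo] = 0.0
    out[col == hi] = 100.0
    return out


def replace_zeros(values: np.ndarray | pd.DataFrame, eps: float = ZERO_REPLACEMENT):
    """Replace exact zeros by ``eps``; all other entries untouched."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    arr = values.values if isinstance(values, pd.DataFrame) else np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative entries are not allowed (indicators are non-negative)")
    out = np.where(arr == 0.0, eps, arr)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def normalize_es(es_raw: pd.DataFrame, eps: float = ZERO_REPLACEMENT) -> pd.DataFrame:
    """Per-column min-max to [0, 100], then zero replacement."""
    normed = pd.DataFrame(
        {c: minmax_rescale(es_raw[c]) for c in es_raw.columns}, index=es_raw.index
    )
    return replace_zeros(normed, eps)


def management_cost_input(
    lulc_shares: np.ndarray, cost_table: dict[str, float], urban_class: str = URBAN
) -> float:
    """Area-weighted mean management cost over the LU's non-urban classes.

    Urban/artificial area is excluded from both the cost and the effective
    area, i.e. shares are renormalized over the remaining classes.  A fully
    urban LU has cost 0 (replaced by 0.001 during assembly).
    """
    shares = np.asarray(lulc_shares, dtype=float)
    total = 0.0
    weight = 0.0
    for i, cls in enumerate(LULC_CLASSES):
        if cls == urban_class or shares[i] <= 0:
            continue
        if cls not in cost_table:
            raise ValueError(f"no management cost for present class {cls!r}")
        total += shares[i] * cost_table[cls]
        weight += shares[i]
    if weight == 0.0:
        return 0.0
    return total / weight


def cost_inputs(
    landscape: SyntheticLandscape, config: ScenarioConfig | None = None
) -> pd.Series:
    """Per-LU management-cost input (EUR ha^-1 yr^-1), before zero replacement."""
    cfg = config or landscape.config
    vals = [
        management_cost_input(u.lulc_shares, cfg.cost_table) for u in landscape.units
    ]
    return pd.Series(vals, index=landscape.lu_ids, name="avg_cost").rename_axis("lu_id")


def assemble_dea_problem(
    es_norm: pd.DataFrame, cost: pd.Series, eps: float = ZERO_REPLACEMENT
) -> DEAProblem:
    """Bundle normalized ES outputs and the cost input into a DEA problem."""
    if not es_norm.index.equals(cost.index):
        raise ValueError("lu_id indices of ES matrix and cost input do not align")
    x = replace_zeros(cost.to_numpy(dtype=float)[:, None], eps)
    y = replace_zeros(es_norm.to_numpy(dtype=float), eps)
    assert np.all(x > 0) and np.all(y > 0), "DEA matrices must be strictly positive"
    return DEAProblem(
        x=x,
        y=y,
        dmu_names=[str(i) for i in es_norm.index],
        input_names=["avg_cost"],
        output_names=list(es_norm.columns),
    )
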