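"""End-to-end analysis pipeline.

simulate -> map ES indicators -> normalize + cost input -> DEA efficiency ->
landscape/efficiency group tables -> Tobit driver regression -> report.

Every stage writes plain-text artifacts (CSV / GeoJSON / markdown) into the
output directory, and a run manifest records the seed, a config hash and a
SHA-256 digest per file so deterministic stages can be verified byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from . import __version__
from .config import ScenarioConfig
from .dea import DEAResult, efficiency_all
from .indicators import ES_COLUMNS, compute_es_matrix
from .landscape import SyntheticLandscape, generate_scenario
from .preprocess import assemble_dea_problem, cost_inputs, normalize_es
from .stats import classify_landscape_type, group_tables
from .tobit import driver_table, fit_two_limit_tobit

TOBIT_COVARIATES = (
    "pop_density",
    "natura_share",
    "road_density",
    "slope_pct",
    "elev_m",
    "n_lulc",
    "dist_heritage_m",
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_efficiency_map(
    landscape: SyntheticLandscape, result: DEAResult, path
) -> None:
    """Write a GeoJSON FeatureCollection: one feature per LU with its score,
    category, landscape type and forest share."""
    if len(landscape.units) != len(result.scores):
        raise ValueError("landscape and DEA result sizes do not match")
    features = []
    for i, u in enumerate(landscape.units):
        props = {
            "lu_id": int(u.lu_id),
            "theta": float(result.scores[i]),
            "category": str(result.categories[i]),
            "landscape_type": classify_landscape_type(u.forest_share),
            "forest_share": float(u.forest_share),
            "area_km2": float(u.area_km2),
        }
        features.append(
            {"type": "Feature", "geometry": mapping(u.polygon), "properties": props}
        )
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc, indent=1))


def validate_inputs(es_csv, cost_csv, drivers_csv) -> list[str]:
    """Schema check for externally supplied stage inputs.

    Returns a (possibly empty) list of machine-readable error strings; it
    never raises on content problems.
    """
    errors: list[str] = []
    try:
        es = pd.read_csv(es_csv, index_col="lu_id")
        cost = pd.read_csv(cost_csv, index_col="lu_id")
        drv = pd.read_csv(drivers_csv, index_col="lu_id")
    except Exception as exc:  # unreadable file is still a report entry
        return [f"read-error: {exc}"]
    if list(es.columns) != list(ES_COLUMNS):
        errors.append(
            f"es-schema: expected the 17 ES columns {list(ES_COLUMNS)}, got {list(es.columns)}"
        )
    if "avg_cost" not in cost.columns:
        errors.append("cost-schema: missing column avg_cost")
    else:
        bad = cost.index[cost["avg_cost"] < 0].tolist()
        if bad:
            errors.append(f"cost-negative: rows {bad}")
    neg = es.lt(0).any()
    for c in es.columns[neg]:
        errors.append(f"es-negative: column {c}")
    if not es.index.equals(cost.index):
        errors.append("alignment: es and cost lu_id indices differ")
    if not es.index.equals(drv.index):
        errors.append("alignment: es and drivers lu_id indices differ")
    missing = [c for c in TOBIT_COVARIATES if c not in drv.columns]
    if missing:
        errors.append(f"drivers-schema: missing columns {missing}")
    return errors


def run_all(config, out_dir, seed: int | None = None) -> dict:
    """Run the full pipeline and return the run manifest (also written as
    ``manifest.json`` in ``out_dir``).

    ``config`` may be a :class:`ScenarioConfig` or a YAML path; ``seed``
    overrides the config seed when given.
    """
    if not isinstance(config, ScenarioConfig):
        config = ScenarioConfig.from_yaml(config)
    if seed is not None:
        config = ScenarioConfig.from_dict({**config.to_dict(), "seed": int(seed)})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    landscape = generate_scenario(config)
    shares = landscape.shares_frame()
    drivers = landscape.drivers_frame()
    es_raw = compute_es_matrix(landscape)
    es_norm = normalize_es(es_raw)
    cost = cost_inputs(landscape)
    problem = assemble_dea_problem(es_norm, cost)
    result = efficiency_all(problem)

    scores = pd.Series(result.scores, index=es_norm.index, name="theta")
    categories = pd.Series(result.categories, index=es_norm.index, name="category")
    ltypes = pd.Series(
        [classify_landscape_type(u.forest_share) for u in landscape.units],
        index=es_norm.index,
        name="landscape_type",
    )
    tables = group_tables(es_norm, scores, categories, ltypes, shares)

    X = np.column_stack(
        [np.ones(len(drivers))] + [drivers[c].to_numpy(float) for c in TOBIT_COVARIATES]
    )
    fit = fit_two_limit_tobit(
        scores.to_numpy(), X, names=["const", *TOBIT_COVARIATES]
    )
    tobit_tbl = driver_table(fit)

    # ---- write artifacts
    files: dict[str, Path] = {}

    def save(name: str, writer) -> None:
        path = out / name
        writer(path)
        files[name] = path

    save("lulc_shares.csv", lambda p: shares.to_csv(p))
    save("drivers.csv", lambda p: drivers.to_csv(p))
    save("es_raw.csv", lambda p: es_raw.to_csv(p))
    save("es_norm.csv", lambda p: es_norm.to_csv(p))
    save("cost.csv", lambda p: cost.to_frame().to_csv(p))
    scores_df = pd.concat([scores, categories, ltypes], axis=1)
    scores_df["peers"] = [
        ";".join(result.dmu_names[j] for j in pk) for pk in result.peers
    ]
    save("scores.csv", lambda p: scores_df.to_csv(p))
    for key, tbl in tables.items():
        save(f"table_{key}.csv", lambda p, t=tbl: t.to_csv(p))
    save("tobit.csv", lambda p: tobit_tbl.to_csv(p))
    save("landscape.geojson", lambda p: write_efficiency_map(landscape, result, p))
    save("report.md", lambda p: p.write_text(_report_md(result, fit, tables, ltypes)))

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_landscape_units": len(landscape),
        "files": {name: _sha256(path) for name, path in sorted(files.items())},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _report_md(result: DEAResult, fit, tables: dict, ltypes: pd.Series) -> str:
    s = result.summary()
    ineff = result.scores[result.categories != "efficient"]
    less = float(np.mean(ineff >= result.scores.mean())) * 100 if len(ineff) else 0.0
    lines = [
        "# Landscape-unit efficiency report",
        "",
        f"- landscape units: {s['n']}",
        f"- mean efficiency: {s['mean']:.3f} (sd {s['sd']:.3f})",
        f"- efficient units (theta = 1): {s['n_efficient']}",
        f"- inefficient units above average efficiency (less inefficient): {less:.1f}%",
        f"- landscape types: "
        + ", ".join(f"{t}: {int((ltypes == t).sum())}" for t in ltypes.unique()),
        "",
        "## Tobit driver regression",
        "",
        f"- pseudo-R2: {fit.pseudo_r2:.3f}; sigma: {fit.sigma:.4f}; "
        f"log-likelihood: {fit.loglik:.2f}",
        f"- censored observations: {fit.n_lower} at 0, {fit.n_upper} at 1 "
        f"of {fit.n_obs}",
        "",
        driver_table(fit).to_markdown(),
        "",
    ]
    for key, tbl in tables.items():
        lines += [f"## {key}", "", tbl.to_markdown(), ""]
    return "\n".join(lines)
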