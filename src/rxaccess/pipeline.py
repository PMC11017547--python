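"""Stage functions behind the command-line pipeline.

Each stage reads and writes the documented CSV schemas, so any stage can be
replaced by real data prepared elsewhere (e.g. block distances from a GIS
tool, or a tract table with a pre-computed PWMSD column).  In-memory variants
are provided for library use; the CLI wraps the file-based ones.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import access, disparity, io
from .network import FacilityPoint, RoadNetwork
from .synthetic import ScenarioConfig, SyntheticScenario, generate_scenario

log = logging.getLogger("rxaccess")

__all__ = [
    "compute_block_distances",
    "compute_tract_access",
    "analyze_tract_records",
    "run_scenario_analysis",
    "stage_simulate",
    "stage_distances",
    "stage_pwmsd",
    "stage_analyze",
    "run_all",
]


# ---------------------------------------------------------------------------
# in-memory stages


def compute_block_distances(
    network: RoadNetwork, facilities: list[FacilityPoint], blocks: pd.DataFrame
) -> pd.DataFrame:
    """Per-block nearest-facility distance: ``block_id, distance_km, …``."""
    res = network.nearest_facility_distances(
        facilities,
        list(zip(blocks["x_km"], blocks["y_km"])),
        blocks["block_id"].astype(str),
    )
    return res.rename(columns={"point_id": "block_id"})


def compute_tract_access(
    tracts: pd.DataFrame,
    blocks: pd.DataFrame,
    distances: pd.DataFrame,
    threshold_km: float = 1.0,
) -> tuple[pd.DataFrame, dict, dict]:
    """Exclusion cascade + PWMSD + descriptive summary.

    Returns (tract_access, exclusion_log, summary).  Zero PWMSD values are
    floored so the downstream log transform is defined.
    """
    merged = blocks.merge(distances[["block_id", "distance_km"]], on="block_id")
    tract_access, xlog = access.apply_exclusions(tracts, merged)
    tract_access = access.floor_zero_distances(tract_access)
    summary = access.descriptive_stats(tract_access, threshold_km=threshold_km)
    return tract_access, xlog, summary


def analyze_tract_records(
    records: pd.DataFrame,
    covariates: tuple[str, ...] = disparity.DEFAULT_COVARIATES,
    adjust_for: str | None = None,
    hc_type: str = "HC3",
    bin_specs: tuple[tuple[str, float], ...] = (
        ("median_income", 1000.0),
        ("pct_higher_ed", 1.0),
    ),
) -> dict:
    """Quartile GLMs, Table-1-style descriptives, and binned trends."""
    model = disparity.QuartileDisparityModel(
        records, covariates=covariates, adjust_for=adjust_for, hc_type=hc_type
    )
    results = model.fit()
    trends = []
    for var, width in bin_specs:
        if var not in records.columns:
            continue
        strata = ("all", "urban", "rural") if "pop_density" in records.columns else ("all",)
        for s in strata:
            t = disparity.binned_trends(records, var, width, strata=s)
            t.insert(0, "bin_variable", var)
            trends.append(t)
    return {
        "results": results,
        "model_results": results.to_frame(),
        "quartile_table": results.quartile_table(),
        "trends": pd.concat(trends, ignore_index=True) if trends else pd.DataFrame(),
    }


def run_scenario_analysis(
    scenario: SyntheticScenario,
    threshold_km: float = 1.0,
    adjust_for: str | None = None,
    hc_type: str = "HC3",
) -> dict:
    """Full in-memory pipeline on a synthetic scenario.

    Returns the block distances, tract access table, exclusion log, the
    descriptive summary, the tract-records table and the fitted disparity
    results.
    """
    distances = compute_block_distances(
        scenario.network, scenario.facility_points(), scenario.blocks
    )
    tract_access, xlog, summary = compute_tract_access(
        scenario.tracts, scenario.blocks, distances, threshold_km
    )
    records = tract_access[~tract_access["excluded"]].merge(
        scenario.tracts.drop(columns=["water_only"]), on="tract_id"
    )
    analysis = analyze_tract_records(records, adjust_for=adjust_for, hc_type=hc_type)
    return {
        "distances": distances,
        "tract_access": tract_access,
        "exclusion_log": xlog,
        "summary": summary,
        "records": records,
        **analysis,
    }


# ---------------------------------------------------------------------------
# file-based stages (CLI)


def _prov(config_like: dict, seed=None) -> dict:
    p = {"config_hash": io.config_hash(config_like)}
    if seed is not None:
        p["seed"] = seed
    return p


def stage_simulate(scenario_cfg: dict, outdir: str | Path, seed: int | None = None) -> dict:
    t0 = time.perf_counter()
    cfg = ScenarioConfig(**{**scenario_cfg, **({"seed": seed} if seed is not None else {})})
    scenario = generate_scenario(cfg)
    paths = scenario.write(outdir)
    log.info(
        "simulate: seed=%d tracts=%d blocks=%d facilities=%d (%.2fs)",
        cfg.seed, len(scenario.tracts), len(scenario.blocks),
        len(scenario.facilities), time.perf_counter() - t0,
    )
    return {str(k): str(v) for k, v in paths.items()}


def stage_distances(indir: str | Path, outdir: str | Path, seed: int | None = None) -> Path:
    t0 = time.perf_counter()
    indir, outdir = Path(indir), Path(outdir)
    nodes = io.read_csv(indir / "network_nodes.csv")
    edges = io.read_csv(indir / "network_edges.csv")
    blocks = io.read_csv(indir / "blocks.csv")
    fac = io.read_csv(indir / "facilities.csv")
    network = RoadNetwork.from_tables(nodes, edges)
    facilities = [
        FacilityPoint(str(r.facility_id), float(r.x_km), float(r.y_km), bool(r.in_scope))
        for r in fac.itertuples(index=False)
    ]
    dist = compute_block_distances(network, facilities, blocks)
    n_unreach = int((~dist["reachable"]).sum())
    if n_unreach:
        log.warning("distances: %d unreachable block(s)", n_unreach)
    out = io.write_csv(
        dist, outdir / "block_distances.csv",
        {**_prov({"stage": "distances"}, seed), "n_blocks": len(dist)},
    )
    log.info("distances: %d blocks (%.2fs)", len(dist), time.perf_counter() - t0)
    return out


def stage_pwmsd(
    indir: str | Path, outdir: str | Path, threshold_km: float = 1.0, seed: int | None = None
) -> tuple[Path, Path]:
    t0 = time.perf_counter()
    indir, outdir = Path(indir), Path(outdir)
    tracts = io.read_csv(indir / "tracts.csv")
    blocks = io.read_csv(indir / "blocks.csv")
    dist = io.read_csv(Path(outdir) / "block_distances.csv")
    tract_access, xlog, summary = compute_tract_access(tracts, blocks, dist, threshold_km)
    if not (~tract_access["excluded"]).any():
        raise ValueError("all tracts excluded: nothing to analyse")
    prov = _prov({"stage": "pwmsd", "threshold_km": threshold_km}, seed)
    p1 = io.write_csv(tract_access, outdir / "tract_access.csv", prov)
    p2 = Path(outdir) / "pwmsd_summary.json"
    import json

    p2.write_text(json.dumps({"exclusions": {k: v for k, v in xlog.items()},
                              "summary": summary}, indent=2) + "\n")
    log.info(
        "pwmsd: retained %d/%d tracts (%.2fs)",
        xlog["n_retained"], xlog["n_input"], time.perf_counter() - t0,
    )
    return p1, p2


def stage_analyze(
    indir: str | Path,
    outdir: str | Path,
    covariates: tuple[str, ...] = disparity.DEFAULT_COVARIATES,
    adjust_for: str | None = None,
    hc_type: str = "HC3",
    seed: int | None = None,
    records: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Fit the disparity models from tract_access + tracts (or given records).

    When ``records`` is supplied directly (e.g. a deposited dataset with a
    pre-computed PWMSD column) the distance stages are skipped entirely.
    """
    t0 = time.perf_counter()
    indir, outdir = Path(indir), Path(outdir)
    if records is None:
        tract_access = io.read_csv(outdir / "tract_access.csv")
        tracts = io.read_csv(indir / "tracts.csv")
        drop = [c for c in ("water_only",) if c in tracts.columns]
        records = tract_access[~tract_access["excluded"]].merge(
            tracts.drop(columns=drop), on="tract_id"
        )
    for c in covariates:
        if c not in records.columns:
            raise ValueError(f"analysis covariate {c!r} absent from tract records")
    out = analyze_tract_records(
        records, covariates=covariates, adjust_for=adjust_for, hc_type=hc_type
    )
    for cov in covariates:
        log.info("analyze: %s fitted on n=%d", cov, out["results"].results[cov].n)
    prov = _prov({"stage": "analyze", "hc": hc_type, "adjust": adjust_for}, seed)
    paths = {
        "model_results": io.write_csv(out["model_results"], outdir / "model_results.csv", prov),
        "quartile_table": io.write_csv(out["quartile_table"], outdir / "quartile_table.csv", prov),
        "trends": io.write_csv(out["trends"], outdir / "trends.csv", prov),
    }
    log.info("analyze: done (%.2fs)", time.perf_counter() - t0)
    return paths


def run_all(
    scenario_cfg: dict,
    outdir: str | Path,
    seed: int | None = None,
    threshold_km: float = 1.0,
    adjust_for: str | None = None,
    hc_type: str = "HC3",
) -> dict:
    """simulate → distances → pwmsd → analyze, all under one output dir."""
    outdir = Path(outdir)
    stage_simulate(scenario_cfg, outdir, seed)
    stage_distances(outdir, outdir, seed)
    stage_pwmsd(outdir, outdir, threshold_km, seed)
    return stage_analyze(outdir, outdir, seed=seed, adjust_for=adjust_for, hc_type=hc_type)
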