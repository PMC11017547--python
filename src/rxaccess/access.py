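"""Tract-level population-weighted mean shortest distance (PWMSD).

A tract's PWMSD is the mean of its census blocks' network distances to the
nearest pharmacy, weighted by block population:

    PWMSD_t = sum_b pop_b * d_b / sum_b pop_b   over blocks b in tract t.

Tracts pass through an exclusion cascade before analysis: water-only tracts
(no land area) are removed first, then tracts with fewer than 10 residents,
then tracts containing an unreachable populated block (network component with
no facility).  Zero distances — a pharmacy sitting exactly at a populated
block centroid's snap location — are floored to a small positive value before
any downstream log transform, with a QC warning.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "compute_pwmsd",
    "aggregate_tracts",
    "apply_exclusions",
    "floor_zero_distances",
    "descriptive_stats",
    "EXCLUSION_REASONS",
]

EXCLUSION_REASONS = ("none", "no_land", "low_population", "unreachable", "unmatched")

#: floor applied to zero PWMSD so ln(PWMSD) is defined
ZERO_DISTANCE_FLOOR_KM = 0.001


def compute_pwmsd(populations, distances) -> float:
    """Population-weighted mean distance over the blocks of one tract.

    Zero-population blocks contribute nothing.  Raises if the total
    population is zero (the tract must be excluded upstream) or if a populated
    block has an infinite distance (the tract is unreachable).
    """
    pop = np.asarray(populations, dtype=float)
    d = np.asarray(distances, dtype=float)
    if pop.shape != d.shape:
        raise ValueError("populations and distances must align")
    if (pop < 0).any():
        raise ValueError("negative block population")
    total = pop.sum()
    if total <= 0:
        raise ValueError("total tract population is zero: PWMSD undefined")
    if np.isinf(d[pop > 0]).any():
        raise ValueError("populated block unreachable: tract must be flagged")
    return float((pop * d).sum() / total)


def aggregate_tracts(block_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-block distances to per-tract PWMSD.

    ``block_table`` needs columns ``block_id, tract_id, population,
    distance_km``.  Returns one row per tract: ``tract_id, pwmsd_km,
    population, n_blocks, unreachable``.  ``pwmsd_km`` is NaN for tracts with
    zero population or an unreachable populated block; such tracts are flagged
    for the exclusion cascade rather than dropped here.
    """
    rows = []
    for tract_id, grp in block_table.groupby("tract_id", sort=True):
        pop = grp["population"].to_numpy(dtype=float)
        d = grp["distance_km"].to_numpy(dtype=float)
        total = pop.sum()
        unreachable = bool(np.isinf(d[pop > 0]).any()) if total > 0 else False
        if total > 0 and not unreachable:
            pwmsd = compute_pwmsd(pop, d)
        else:
            pwmsd = math.nan
        rows.append(
            {
                "tract_id": str(tract_id),
                "pwmsd_km": pwmsd,
                "population": int(total),
                "n_blocks": int(len(grp)),
                "unreachable": unreachable,
            }
        )
    return pd.DataFrame(rows)


def apply_exclusions(
    tract_table: pd.DataFrame,
    block_table: pd.DataFrame,
    min_population: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Apply the exclusion cascade and report a log of what happened.

    ``tract_table`` must carry ``tract_id`` and a ``water_only`` land-area
    flag; ``block_table`` carries ``tract_id, population, distance_km``.
    Water-only tracts are removed first, then tracts with total population
    below ``min_population``, then tracts with an unreachable populated block.
    Tracts present in ``tract_table`` but absent from the block table are
    logged as unmatched and excluded.

    Returns ``(tract_access, log)`` where ``tract_access`` has one row per
    input tract with ``excluded`` and ``exclusion_reason`` columns, and
    ``log`` records counts at each step in application order.
    """
    if "water_only" not in tract_table.columns:
        raise ValueError("tract table missing 'water_only' land-area flag")
    agg = aggregate_tracts(block_table).set_index("tract_id")

    tracts = tract_table.copy()
    tracts["tract_id"] = tracts["tract_id"].astype(str)
    unmatched = sorted(set(tracts["tract_id"]) - set(agg.index))

    records = []
    for row in tracts.itertuples(index=False):
        tid = str(row.tract_id)
        if tid in agg.index:
            a = agg.loc[tid]
            pwmsd, pop, nb, unreach = (
                a["pwmsd_km"],
                int(a["population"]),
                int(a["n_blocks"]),
                bool(a["unreachable"]),
            )
        else:
            pwmsd, pop, nb, unreach = math.nan, 0, 0, False
        if bool(row.water_only):
            reason = "no_land"
        elif tid in unmatched or pop < min_population:
            reason = "low_population" if tid not in unmatched else "unmatched"
        elif unreach:
            reason = "unreachable"
        else:
            reason = "none"
        records.append(
            {
                "tract_id": tid,
                "pwmsd_km": pwmsd,
                "population": pop,
                "n_blocks": nb,
                "excluded": reason != "none",
                "exclusion_reason": reason,
            }
        )
    out = pd.DataFrame(records)

    n_input = len(out)
    n_water = int((out["exclusion_reason"] == "no_land").sum())
    n_low = int((out["exclusion_reason"] == "low_population").sum())
    n_unmatched = int((out["exclusion_reason"] == "unmatched").sum())
    n_unreach = int((out["exclusion_reason"] == "unreachable").sum())
    log = {
        "order": ["no_land", "low_population", "unreachable"],
        "n_input": n_input,
        "n_water_excluded": n_water,
        "n_after_water": n_input - n_water,
        "n_low_population_excluded": n_low,
        "n_unmatched_excluded": n_unmatched,
        "n_unreachable_excluded": n_unreach,
        "n_retained": int((~out["excluded"]).sum()),
        "unmatched_tracts": unmatched,
        "unreachable_tracts": out.loc[
            out["exclusion_reason"] == "unreachable", "tract_id"
        ].tolist(),
    }
    if n_unreach:
        warnings.warn(
            f"{n_unreach} tract(s) excluded because a populated block cannot "
            "reach any facility on the network",
            stacklevel=2,
        )
    return out, log


def floor_zero_distances(
    tract_access: pd.DataFrame, floor_km: float = ZERO_DISTANCE_FLOOR_KM
) -> pd.DataFrame:
    """Floor zero PWMSD values to ``floor_km`` so ln(PWMSD) is defined.

    Emits a QC warning naming the affected tracts.
    """
    out = tract_access.copy()
    zero = out["pwmsd_km"] == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} tract(s) with zero PWMSD floored to {floor_km} km: "
            f"{out.loc[zero, 'tract_id'].tolist()}",
            stacklevel=2,
        )
        out.loc[zero, "pwmsd_km"] = floor_km
    return out


def descriptive_stats(tract_access: pd.DataFrame, threshold_km: float = 1.0) -> dict:
    """Descriptive summary of PWMSD over non-excluded tracts.

    Reports the unweighted mean, sample SD (n−1 denominator), median and max
    of ``pwmsd_km``; the count and percentage of tracts strictly below
    ``threshold_km`` together with the population living in them; and
    mean/SD/median within the top and bottom 10% of tracts by population
    (floor(n/10) tracts from each end of the population ranking, ties broken
    by tract_id).
    """
    df = tract_access
    if "excluded" in df.columns:
        df = df[~df["excluded"]]
    if df.empty:
        raise ValueError("no tracts to summarise")
    d = df["pwmsd_km"].to_numpy(dtype=float)
    pop = df["population"].to_numpy(dtype=float)

    below = d < threshold_km
    n = len(df)
    k = n // 10
    ranked = df.sort_values(["population", "tract_id"], kind="mergesort")

    def _block(sub: pd.DataFrame) -> dict:
        v = sub["pwmsd_km"].to_numpy(dtype=float)
        return {
            "n": int(len(v)),
            "mean_km": float(v.mean()),
            "sd_km": float(v.std(ddof=1)) if len(v) > 1 else math.nan,
            "median_km": float(np.median(v)),
        }

    return {
        "n_tracts": n,
        "mean_km": float(d.mean()),
        "sd_km": float(d.std(ddof=1)) if n > 1 else math.nan,
        "median_km": float(np.median(d)),
        "max_km": float(d.max()),
        "threshold_km": float(threshold_km),
        "n_below_threshold": int(below.sum()),
        "pct_tracts_below_threshold": float(100.0 * below.sum() / n),
        "population_total": int(pop.sum()),
        "population_below_threshold": int(pop[below].sum()),
        "pct_population_below_threshold": float(
            100.0 * pop[below].sum() / pop.sum()
        ) if pop.sum() > 0 else math.nan,
        "top_decile_by_population": _block(ranked.tail(k)) if k else None,
        "bottom_decile_by_population": _block(ranked.head(k)) if k else None,
    }
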