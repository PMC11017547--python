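"""Synthetic study regions with known ground truth.

Generates everything the pipeline consumes — a planar road network, census
blocks nested in contiguous tracts, pharmacy locations, and tract-level
sociodemographic covariates — from a single seed, so every stage can be
tested end to end without external data.

The region emulates the broad structure of a state with one urban core: node
and facility density, population density, % poverty, % Black/AA and
% Hispanic all rise toward the centre, while median income and % white fall;
% higher education follows a U-shaped (non-monotone) relation to urbanicity.
Facilities can be sited uniformly, proportionally to population (the default,
which reproduces the stylised fact that dense, poorer tracts sit closer to
pharmacies), or by urban score.  A band of in-scope "border" facilities sits
just outside the region's east edge and a set of out-of-scope "foreign"
facilities beyond the north edge, exercising the in-scope predicate.

A separate direct-effect generator bypasses geometry entirely and draws
ln(PWMSD) = beta0 + beta_k·I(Qk) + Normal(0, sigma), for parameter-recovery
tests of the disparity GLM.

Reproducibility: each component (network, populations, covariates,
facilities) draws from its own RNG stream spawned from the master seed, so
e.g. changing the facility count never perturbs block populations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .network import RoadNetwork, FacilityPoint

__all__ = [
    "ScenarioConfig",
    "SyntheticScenario",
    "grid_network",
    "generate_network",
    "generate_blocks_and_tracts",
    "generate_covariates_and_facilities",
    "generate_direct_effect_dataset",
    "generate_scenario",
]

FACILITY_RULES = ("uniform", "population-proportional", "urban-core")


@dataclass
class ScenarioConfig:
    """Knobs for one synthetic region.

    Defaults describe a 10×10-tract region (2 km square tracts, 1 km road
    grid) with ~6 blocks per tract, log-normal block populations around a few
    hundred residents, and roughly one pharmacy per 1.25 tracts sited
    proportionally to population — a deliberately urban-core-heavy region.
    """

    seed: int = 0
    # geometry
    tract_rows: int = 10
    tract_cols: int = 10
    tract_size_km: float = 2.0
    road_spacing_km: float = 1.0
    edge_dropout: float = 0.10
    length_jitter: float = 0.10        # ±10% multiplicative jitter on lengths
    min_largest_component: float = 0.95
    max_network_retries: int = 20
    # blocks & populations
    blocks_per_tract: tuple[int, int] = (4, 8)
    block_pop_mu: float = math.log(400.0)  # log-normal parameters
    block_pop_sigma: float = 0.8
    block_pop_urban_gain: float = 2.0      # added to mu, scaled by urban score
    n_water_tracts: int = 1
    n_low_pop_tracts: int = 2
    # facilities
    n_facilities: int = 80
    facility_rule: str = "population-proportional"
    n_border_facilities: int = 6
    n_foreign_facilities: int = 4
    facility_jitter_km: float = 0.3
    # covariate model: value = base + slope * urban_score + Normal(0, sd)
    urban_scale: float = 0.25          # decay scale as a fraction of region size
    poverty_base: float = 5.0
    poverty_slope: float = 35.0
    poverty_sd: float = 3.0
    black_base: float = 2.0
    black_slope: float = 50.0
    black_sd: float = 4.0
    hispanic_base: float = 2.0
    hispanic_slope: float = 45.0
    hispanic_sd: float = 4.0
    income_base: float = 85_000.0
    income_slope: float = -55_000.0
    income_sd: float = 5_000.0
    white_base: float = 92.0
    white_slope: float = -60.0
    white_sd: float = 5.0
    # U-shape: he = base + curve*(2u-1)^2 + noise
    higher_ed_base: float = 25.0
    higher_ed_curve: float = 30.0
    higher_ed_sd: float = 4.0
    # optional direct-effect mode
    direct_n: int = 1000
    direct_beta: tuple[float, float, float, float] = (0.7, 0.0, 0.0, 0.0)
    direct_sigma: float = 0.5

    def __post_init__(self):
        if self.facility_rule not in FACILITY_RULES:
            raise ValueError(f"facility_rule must be one of {FACILITY_RULES}")
        for name in ("tract_rows", "tract_cols", "n_facilities"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.edge_dropout < 1:
            raise ValueError("edge_dropout must be in [0, 1)")
        if self.direct_sigma < 0:
            raise ValueError("direct_sigma must be non-negative")

    @property
    def width_km(self) -> float:
        return self.tract_cols * self.tract_size_km

    @property
    def height_km(self) -> float:
        return self.tract_rows * self.tract_size_km

    def streams(self) -> dict[str, np.random.Generator]:
        """One independent RNG stream per generated component."""
        children = np.random.SeedSequence(self.seed).spawn(5)
        names = ("network", "populations", "covariates", "facilities", "direct")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class SyntheticScenario:
    """A generated region plus the ground truth used to generate it."""

    config: ScenarioConfig
    network: RoadNetwork
    nodes: pd.DataFrame       # node_id,x_km,y_km
    edges: pd.DataFrame       # node_a,node_b,length_km
    blocks: pd.DataFrame      # block_id,tract_id,x_km,y_km,population
    tracts: pd.DataFrame      # tract_id,water_only,<covariates>,pop_density
    facilities: pd.DataFrame  # facility_id,x_km,y_km,in_scope
    ground_truth: dict = field(default_factory=dict)

    def facility_points(self) -> list[FacilityPoint]:
        return [
            FacilityPoint(str(r.facility_id), float(r.x_km), float(r.y_km),
                          bool(r.in_scope))
            for r in self.facilities.itertuples(index=False)
        ]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the CSV schemas consumed by the pipeline plus manifest.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("network_nodes", self.nodes),
            ("network_edges", self.edges),
            ("blocks", self.blocks),
            ("tracts", self.tracts),
            ("facilities", self.facilities),
        ):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g")
            paths[name] = p
        manifest = {
            "seed": self.config.seed,
            "config": asdict(self.config),
            "ground_truth": self.ground_truth,
        }
        p = outdir / "manifest.json"
        p.write_text(json.dumps(manifest, indent=2, default=list) + "\n")
        paths["manifest"] = p
        return paths


# ---------------------------------------------------------------------------
# network


def grid_network(
    n_cols: int,
    n_rows: int,
    spacing_km: float,
    dropout: float,
    jitter: float,
    rng: np.random.Generator,
    min_largest_component: float = 0.95,
    max_retries: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lattice of n_cols × n_rows nodes with jittered lengths and edge dropout.

    Dropout never shrinks the largest connected component below
    ``min_largest_component`` of all nodes; the draw is retried up to
    ``max_retries`` times, after which an error is raised.
    """
    if n_cols < 2 or n_rows < 2:
        raise ValueError("grid must be at least 2×2 nodes")
    node_rows = []
    for j in range(n_rows):
        for i in range(n_cols):
            node_rows.append(
                {"node_id": f"n{i}_{j}", "x_km": i * spacing_km, "y_km": j * spacing_km}
            )
    nodes = pd.DataFrame(node_rows)

    all_edges = []
    for j in range(n_rows):
        for i in range(n_cols):
            if i + 1 < n_cols:
                all_edges.append((f"n{i}_{j}", f"n{i+1}_{j}"))
            if j + 1 < n_rows:
                all_edges.append((f"n{i}_{j}", f"n{i}_{j+1}"))
    n_total = len(nodes)
    n_drop = int(round(dropout * len(all_edges)))
    need = math.ceil(min_largest_component * n_total)

    import networkx as nx

    for _ in range(max_retries):
        keep_idx = rng.permutation(len(all_edges))[: len(all_edges) - n_drop]
        kept = [all_edges[i] for i in sorted(keep_idx)]
        g = nx.Graph(kept)
        g.add_nodes_from(nodes["node_id"])
        largest = max((len(c) for c in nx.connected_components(g)), default=0)
        if largest >= need:
            break
    else:
        raise RuntimeError(
            f"edge dropout {dropout} could not keep the largest component "
            f"above {min_largest_component:.0%} of nodes in {max_retries} tries"
        )
    lengths = spacing_km * (1.0 + jitter * rng.uniform(-1.0, 1.0, size=len(kept)))
    edges = pd.DataFrame(
        {
            "node_a": [a for a, _ in kept],
            "node_b": [b for _, b in kept],
            "length_km": lengths,
        }
    )
    return nodes, edges


def generate_network(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[RoadNetwork, pd.DataFrame, pd.DataFrame]:
    rng = rng if rng is not None else config.streams()["network"]
    n_cols = int(round(config.width_km / config.road_spacing_km)) + 1
    n_rows = int(round(config.height_km / config.road_spacing_km)) + 1
    nodes, edges = grid_network(
        n_cols, n_rows, config.road_spacing_km, config.edge_dropout,
        config.length_jitter, rng,
        config.min_largest_component, config.max_network_retries,
    )
    return RoadNetwork.from_tables(nodes, edges), nodes, edges


# ---------------------------------------------------------------------------
# blocks and tracts


def _tract_ids(config: ScenarioConfig) -> list[str]:
    return [
        f"t{r:02d}_{c:02d}"
        for r in range(config.tract_rows)
        for c in range(config.tract_cols)
    ]


def _tract_center(config: ScenarioConfig, tract_id: str) -> tuple[float, float]:
    r, c = (int(s) for s in tract_id[1:].split("_"))
    return (
        (c + 0.5) * config.tract_size_km,
        (r + 0.5) * config.tract_size_km,
    )


def generate_blocks_and_tracts(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blocks jittered inside square tract cells; log-normal populations.

    A configurable handful of tracts is forced below 10 residents and one (or
    more) flagged water-only so the exclusion cascade always has work to do.
    """
    rng = rng if rng is not None else config.streams()["populations"]
    tract_ids = _tract_ids(config)
    lo, hi = config.blocks_per_tract
    margin = 0.05 * config.tract_size_km

    special = rng.choice(
        len(tract_ids),
        size=config.n_water_tracts + config.n_low_pop_tracts,
        replace=False,
    )
    water = {tract_ids[i] for i in special[: config.n_water_tracts]}
    low_pop = {tract_ids[i] for i in special[config.n_water_tracts :]}

    block_rows = []
    for tid in tract_ids:
        cx, cy = _tract_center(config, tid)
        half = config.tract_size_km / 2 - margin
        k = int(rng.integers(lo, hi + 1))
        xs = cx + rng.uniform(-half, half, size=k)
        ys = cy + rng.uniform(-half, half, size=k)
        # population density rises toward the urban core: the log-normal
        # location parameter is shifted by the block's urban score
        mu = config.block_pop_mu + config.block_pop_urban_gain * urban_score(config, xs, ys)
        pops = np.round(
            rng.lognormal(mu, config.block_pop_sigma)
        ).astype(int)
        if tid in water:
            pops[:] = 0
        elif tid in low_pop:
            pops[:] = 0
            pops[: min(k, 9)] = 1  # total ≤ 9 < the exclusion threshold
        for i in range(k):
            block_rows.append(
                {
                    "block_id": f"{tid}_b{i}",
                    "tract_id": tid,
                    "x_km": float(xs[i]),
                    "y_km": float(ys[i]),
                    "population": int(pops[i]),
                }
            )
    blocks = pd.DataFrame(block_rows)
    tracts = pd.DataFrame(
        {
            "tract_id": tract_ids,
            "water_only": [int(t in water) for t in tract_ids],
        }
    )
    return blocks, tracts


# ---------------------------------------------------------------------------
# covariates and facilities


def urban_score(config: ScenarioConfig, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exponential-decay urbanicity in (0, 1], 1 at the region centre."""
    cx, cy = config.width_km / 2, config.height_km / 2
    d = np.hypot(np.asarray(x) - cx, np.asarray(y) - cy)
    scale = config.urban_scale * max(config.width_km, config.height_km)
    return np.exp(-d / scale)


def generate_covariates_and_facilities(
    config: ScenarioConfig,
    blocks: pd.DataFrame,
    tracts: pd.DataFrame,
    rng_cov: np.random.Generator | None = None,
    rng_fac: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Urban-gradient covariates and facility placement.

    Percent covariates are linear in the tract's urban score plus Gaussian
    noise, clipped to [0, 100]; % higher education is U-shaped in urbanicity.
    Facility density follows the configured rule; in-scope border facilities
    sit just beyond the east edge and out-of-scope foreign facilities beyond
    the north edge.
    """
    streams = config.streams()
    rng_cov = rng_cov if rng_cov is not None else streams["covariates"]
    rng_fac = rng_fac if rng_fac is not None else streams["facilities"]

    out = tracts.copy()
    centers = np.array([_tract_center(config, t) for t in out["tract_id"]])
    u = urban_score(config, centers[:, 0], centers[:, 1])
    n = len(out)

    def lin(base, slope, sd, lo=0.0, hi=100.0):
        raw = base + slope * u + rng_cov.normal(0.0, sd, size=n)
        clipped = np.clip(raw, lo, hi)
        frac = float(np.mean(raw != clipped))
        if frac > 0.5:
            import warnings

            warnings.warn(
                f"covariate slope clips {frac:.0%} of values; gradient is distorted",
                stacklevel=3,
            )
        return clipped

    out["pct_poverty"] = lin(config.poverty_base, config.poverty_slope, config.poverty_sd)
    out["pct_black_aa"] = lin(config.black_base, config.black_slope, config.black_sd)
    out["pct_hispanic"] = lin(config.hispanic_base, config.hispanic_slope, config.hispanic_sd)
    out["pct_white"] = lin(config.white_base, config.white_slope, config.white_sd)
    out["median_income"] = lin(
        config.income_base, config.income_slope, config.income_sd, lo=10_000.0, hi=250_000.0
    )
    out["pct_higher_ed"] = np.clip(
        config.higher_ed_base
        + config.higher_ed_curve * (2 * u - 1) ** 2
        + rng_cov.normal(0.0, config.higher_ed_sd, size=n),
        0.0,
        100.0,
    )
    tract_pop = blocks.groupby("tract_id")["population"].sum()
    out["pop_density"] = (
        out["tract_id"].map(tract_pop).fillna(0).astype(float)
        / config.tract_size_km**2
    )
    out["urban_score"] = u

    # facilities -----------------------------------------------------------
    fac_rows = []
    populated = blocks[blocks["population"] > 0]
    if config.facility_rule == "uniform":
        xs = rng_fac.uniform(0, config.width_km, size=config.n_facilities)
        ys = rng_fac.uniform(0, config.height_km, size=config.n_facilities)
    elif config.facility_rule == "population-proportional":
        w = populated["population"].to_numpy(dtype=float)
        pick = rng_fac.choice(len(populated), size=config.n_facilities, p=w / w.sum())
        xs = populated["x_km"].to_numpy()[pick] + rng_fac.uniform(
            -config.facility_jitter_km, config.facility_jitter_km, size=config.n_facilities
        )
        ys = populated["y_km"].to_numpy()[pick] + rng_fac.uniform(
            -config.facility_jitter_km, config.facility_jitter_km, size=config.n_facilities
        )
    else:  # urban-core
        w = out["urban_score"].to_numpy(dtype=float)
        pick = rng_fac.choice(len(out), size=config.n_facilities, p=w / w.sum())
        half = config.tract_size_km / 2
        xs = centers[pick, 0] + rng_fac.uniform(-half, half, size=config.n_facilities)
        ys = centers[pick, 1] + rng_fac.uniform(-half, half, size=config.n_facilities)
    for i in range(config.n_facilities):
        fac_rows.append(
            {"facility_id": f"f{i:03d}", "x_km": float(xs[i]), "y_km": float(ys[i]),
             "in_scope": 1}
        )
    # neighbouring-state band: in scope, just past the east edge
    for i in range(config.n_border_facilities):
        fac_rows.append(
            {
                "facility_id": f"border{i:02d}",
                "x_km": float(config.width_km + rng_fac.uniform(0.2, 1.5)),
                "y_km": float(rng_fac.uniform(0, config.height_km)),
                "in_scope": 1,
            }
        )
    # international band: out of scope, past the north edge
    for i in range(config.n_foreign_facilities):
        fac_rows.append(
            {
                "facility_id": f"foreign{i:02d}",
                "x_km": float(rng_fac.uniform(0, config.width_km)),
                "y_km": float(config.height_km + rng_fac.uniform(0.2, 1.5)),
                "in_scope": 0,
            }
        )
    facilities = pd.DataFrame(fac_rows)
    return out, facilities


# ---------------------------------------------------------------------------
# direct-effect generator (parameter-recovery harness)


def generate_direct_effect_dataset(
    n: int = 1000,
    beta: tuple[float, float, float, float] = (0.7, 0.0, 0.0, 0.0),
    sigma: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw tract records with a known quartile effect on ln(PWMSD).

    ``beta`` is (beta0, beta2, beta3, beta4): intercept and the Q2–Q4
    contrasts versus Q1.  Quartile labels are assigned evenly (Q1 first), and
    a synthetic covariate value is drawn inside the band [25·(q−1), 25·q) so
    that rank-based quartiling of the covariate reproduces the labels exactly
    when n is divisible by 4.  Returns the records plus a ground-truth dict.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    b0, b2, b3, b4 = (float(b) for b in beta)
    contrasts = {1: 0.0, 2: b2, 3: b3, 4: b4}

    base, rem = divmod(n, 4)
    sizes = [base + (1 if q < rem else 0) for q in range(4)]
    q_idx = np.concatenate([np.full(s, q + 1) for q, s in enumerate(sizes)])
    cov = np.concatenate(
        [rng.uniform(25.0 * q, 25.0 * (q + 1) - 1.0, size=s) for q, s in enumerate(sizes)]
    )
    ln_d = b0 + np.array([contrasts[q] for q in q_idx]) + rng.normal(0.0, sigma, size=n)
    df = pd.DataFrame(
        {
            "tract_id": [f"s{i:05d}" for i in range(n)],
            "pwmsd_km": np.exp(ln_d),
            "population": 1000,
            "covariate": cov,
            "quartile_true": [f"Q{q}" for q in q_idx],
        }
    )
    truth = {"beta0": b0, "beta2": b2, "beta3": b3, "beta4": b4, "sigma": sigma, "n": n}
    return df, truth


# ---------------------------------------------------------------------------
# orchestration


def generate_scenario(config: ScenarioConfig | None = None, seed: int | None = None) -> SyntheticScenario:
    """Generate a full region from a config (or just a seed with defaults)."""
    if config is None:
        config = ScenarioConfig(seed=seed if seed is not None else 0)
    elif seed is not None:
        raise ValueError("pass either a config or a seed, not both")
    streams = config.streams()
    net, nodes, edges = generate_network(config, streams["network"])
    blocks, tracts = generate_blocks_and_tracts(config, streams["populations"])
    tracts, facilities = generate_covariates_and_facilities(
        config, blocks, tracts, streams["covariates"], streams["facilities"]
    )
    truth = {
        "facility_rule": config.facility_rule,
        "covariate_slopes": {
            "pct_poverty": config.poverty_slope,
            "pct_black_aa": config.black_slope,
            "pct_hispanic": config.hispanic_slope,
            "pct_white": config.white_slope,
            "median_income": config.income_slope,
            "higher_ed_curve": config.higher_ed_curve,
        },
        "urban_score": "exp(-dist_to_center / (urban_scale * max(W, H)))",
        "direct_beta": list(config.direct_beta),
        "direct_sigma": config.direct_sigma,
    }
    return SyntheticScenario(
        config=config, network=net, nodes=nodes, edges=edges,
        blocks=blocks, tracts=tracts, facilities=facilities, ground_truth=truth,
    )
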