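"""Synthetic community generator with known assembly processes.

Emulates a coastal-bay amplicon survey: stations sampled in several months
with replicates, a pure-birth phylogeny whose tips carry Brownian-motion
environmental optima (so selection leaves a phylogenetic footprint),
Gaussian environmental filtering of a lognormal regional species pool,
station-local pool perturbation as a dispersal-limitation mechanism, and
multinomial read sampling as drift. Every generator is deterministic under
its seed, and the generating process per month stratum is recorded as truth
for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .data_model import ENV_VARIABLES, OtuTable

#: Month-level (mean, SD) of each environmental variable used as simulation
#: defaults; keys are (variable, month). Values mirror a three-season coastal
#: bay survey (May/Aug/Oct surface seawater).
DEFAULT_ENV_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("Temp", "May"): (17.48, 2.36), ("Temp", "Aug"): (28.09, 0.53),
    ("Temp", "Oct"): (19.55, 1.26),
    ("Salinity", "May"): (33.19, 0.33), ("Salinity", "Aug"): (29.69, 2.71),
    ("Salinity", "Oct"): (30.15, 1.63),
    ("Conductivity", "May"): (47.04, 0.92),
    ("Conductivity", "Aug"): (45.92, 2.44),
    ("Conductivity", "Oct"): (46.49, 1.13),
    ("DO", "May"): (8.21, 0.51), ("DO", "Aug"): (7.58, 1.51),
    ("DO", "Oct"): (7.93, 0.39),
    ("pH", "May"): (8.04, 0.07), ("pH", "Aug"): (8.39, 0.09),
    ("pH", "Oct"): (8.38, 0.07),
    ("SRP", "May"): (0.003, 0.002), ("SRP", "Aug"): (0.01, 0.004),
    ("SRP", "Oct"): (0.02, 0.01),
    ("COD", "May"): (0.3, 0.14), ("COD", "Aug"): (1.23, 0.82),
    ("COD", "Oct"): (2.45, 0.49),
    ("Nitrite", "May"): (0.02, 0.01), ("Nitrite", "Aug"): (0.05, 0.04),
    ("Nitrite", "Oct"): (0.04, 0.02),
    ("Nitrate", "May"): (0.24, 0.08), ("Nitrate", "Aug"): (0.21, 0.09),
    ("Nitrate", "Oct"): (0.16, 0.07),
    ("AN", "May"): (0.13, 0.02), ("AN", "Aug"): (0.1, 0.02),
    ("AN", "Oct"): (0.02, 0.02),
    ("DIN", "May"): (0.39, 0.08), ("DIN", "Aug"): (0.36, 0.1),
    ("DIN", "Oct"): (0.23, 0.07),
    ("un_ionN", "May"): (0.004, 0.001), ("un_ionN", "Aug"): (0.01, 0.003),
    ("un_ionN", "Oct"): (0.001, 0.001),
    ("Depth", "May"): (8.31, 6.25), ("Depth", "Aug"): (7.71, 6.01),
    ("Depth", "Oct"): (6.98, 5.39),
    ("Trans", "May"): (0.79, 0.5), ("Trans", "Aug"): (1.4, 0.65),
    ("Trans", "Oct"): (1.2, 0.58),
    ("Chl_a", "May"): (4.84, 2.76), ("Chl_a", "Aug"): (2.37, 1.77),
    ("Chl_a", "Oct"): (2.24, 1.74),
}

#: Sampling-box corners (decimal degrees) for simulated station coordinates.
LON_RANGE = (117.7, 118.8)
LAT_RANGE = (38.5, 39.3)


@dataclass
class SyntheticConfig:
    """Study-design and mechanism parameters for the community simulator.

    Defaults describe a small three-month bay survey: 200 taxa, 12 stations,
    2 replicates per station per month, ~26,000 reads per sample. Mechanisms:

    - ``sigma_sel``: Gaussian environmental-filter width in trait units;
      ``inf`` disables selection.
    - ``month_env``: selective environment position per month, in the same
      trait units as the Brownian-motion optima (unit-depth tree, variance
      ``bm_variance`` per unit branch length, so tip optima have SD ~1).
    - ``dispersal_scale``: Dirichlet concentration scale for station-local
      pools; small values give strongly perturbed local pools (dispersal
      limitation), ``inf`` means a single well-mixed pool.
    - ``drift_rounds``: extra multinomial resampling rounds of local pool
      frequencies before read sampling.
    """

    n_taxa: int = 200
    n_stations: int = 12
    n_replicates: int = 2
    months: tuple[str, ...] = ("May", "Aug", "Oct")
    reads_mean: float = 26000.0
    reads_dispersion: float = 0.003  # NB dispersion; CV ~ 5-6% at defaults
    bm_variance: float = 1.0
    sigma_sel: float = math.inf
    month_env: dict = field(default_factory=dict)
    dispersal_scale: float = math.inf
    drift_rounds: int = 1
    pool_lognormal_sd: float = 1.2
    env_params: dict = field(
        default_factory=lambda: dict(DEFAULT_ENV_PARAMS))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if len(self.months) < 2:
            raise ValueError("need at least 2 months for between-month tests")
        for name in ("reads_mean", "bm_variance", "sigma_sel",
                     "dispersal_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def scenario(cls, name: str, seed: int | None = None,
                 **overrides) -> "SyntheticConfig":
        """Preset scenarios: 'selection', 'dispersal', 'neutral', 'mixed'.

        'selection' separates month environments by 4 sigma_sel on the trait
        axis; 'dispersal' uses a shared flat fitness surface but strongly
        perturbed station-local pools; 'neutral' is one well-mixed pool with
        read-sampling drift only; 'mixed' combines moderate selection with
        local-pool perturbation.
        """
        months = overrides.pop("months", ("May", "Aug", "Oct"))
        base = dict(months=months, seed=seed)
        if name == "selection":
            sigma = 0.5
            envs = {m: 4.0 * sigma * k for k, m in enumerate(months)}
            base.update(sigma_sel=sigma, month_env=envs)
        elif name == "dispersal":
            base.update(dispersal_scale=30.0)
        elif name == "neutral":
            pass
        elif name == "mixed":
            sigma = 1.0
            envs = {m: 2.0 * sigma * k for k, m in enumerate(months)}
            base.update(sigma_sel=sigma, month_env=envs,
                        dispersal_scale=200.0)
        else:
            raise ValueError(f"unknown scenario {name!r}")
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticDataset:
    """Bundled table + tree + metadata + generating-process truth."""

    table: OtuTable
    tree: TreeNode
    metadata: pd.DataFrame
    optima: pd.Series
    truth: dict
    planted_ssotus: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Tree and trait simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed=None) -> TreeNode:
    """Pure-birth (Yule) tree with ``n_taxa`` tips, rescaled to unit depth.

    Grown forward in time, so the tree is ultrametric: every root-to-tip
    path has length exactly 1. Tips are named OTU0001..OTUnnnn in a
    seed-determined arrangement.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None, length=None)
    first = [TreeNode(length=None), TreeNode(length=None)]
    root.extend(first)
    active: list[tuple[TreeNode, float]] = [(first[0], 0.0), (first[1], 0.0)]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = rng.integers(len(active))
        node, birth = active.pop(k)
        node.length = t - birth
        kids = [TreeNode(length=None), TreeNode(length=None)]
        node.extend(kids)
        active.append((kids[0], t))
        active.append((kids[1], t))
    depth = t + rng.exponential(1.0 / n_taxa)
    names = [f"OTU{i+1:04d}" for i in range(n_taxa)]
    rng.shuffle(names)
    for (node, birth), name in zip(active, names):
        node.length = depth - birth
        node.name = name
    for node in root.traverse(include_self=False):
        node.length = node.length / depth
    return root


def evolve_env_optima(tree: TreeNode, bm_variance: float,
                      seed=None) -> pd.Series:
    """Brownian-motion environmental optima along the tree from root value 0.

    Each branch adds a Normal(0, bm_variance * branch length) increment, so
    tip optima covary according to shared ancestry (the phylogenetic signal
    the betaNTI null model exploits).
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        parent_val = values[id(node.parent)]
        step_sd = math.sqrt(max(bm_variance * (node.length or 0.0), 0.0))
        values[id(node)] = parent_val + (rng.normal(0.0, step_sd)
                                         if step_sd > 0 else 0.0)
    tips = list(tree.tips())
    return pd.Series({t.name: values[id(t)] for t in tips}).sort_index()


# ---------------------------------------------------------------------------
# Community simulation
# ---------------------------------------------------------------------------

def _station_coordinates(n_stations: int, rng) -> pd.DataFrame:
    lon = rng.uniform(*LON_RANGE, size=n_stations)
    lat = rng.uniform(*LAT_RANGE, size=n_stations)
    ids = [f"ST{i+1:02d}" for i in range(n_stations)]
    return pd.DataFrame({"longitude": lon, "latitude": lat}, index=ids)


def _truth_labels(config: SyntheticConfig) -> dict:
    """Dominant generating mechanism per month stratum."""
    months = list(config.months)
    envs = {m: config.month_env.get(m, 0.0) for m in months}
    truth: dict[str, str] = {}
    selective = math.isfinite(config.sigma_sel)
    limited = math.isfinite(config.dispersal_scale)
    for m in months:
        truth[m] = ("dispersal limitation" if limited else "undominated")
    for i, a in enumerate(months):
        for j in range(i + 1, len(months)):
            b = months[j]
            key = "-".join(sorted([a, b]))
            if selective and abs(envs[a] - envs[b]) > config.sigma_sel:
                truth[key] = "heterogeneous selection"
            elif limited:
                truth[key] = "dispersal limitation"
            else:
                truth[key] = "undominated"
    return truth


def simulate_communities(config: SyntheticConfig,
                         tree: TreeNode | None = None,
                         optima: pd.Series | None = None) -> SyntheticDataset:
    """Simulate the full survey: table, tree, metadata and truth labels.

    Per month the regional pool is filtered by Gaussian fitness
    ``exp(-(optimum - E_month)^2 / (2 sigma_sel^2))``; per station the pool
    is Dirichlet-perturbed with concentration ``dispersal_scale * n_taxa``
    scaled down with station isolation (distance to nearest neighbour);
    reads are drawn multinomially at a negative-binomial library size.
    """
    rng = np.random.default_rng(config.seed)
    if tree is None:
        tree = simulate_tree(config.n_taxa, seed=rng.integers(2 ** 31))
    taxa = sorted(t.name for t in tree.tips())
    if optima is None:
        optima = evolve_env_optima(tree, config.bm_variance,
                                   seed=rng.integers(2 ** 31))
    opt = optima.loc[taxa].to_numpy()

    log_pool = rng.normal(0.0, config.pool_lognormal_sd, size=len(taxa))
    regional = np.exp(log_pool)
    regional /= regional.sum()

    stations = _station_coordinates(config.n_stations, rng)
    # isolation = distance to nearest neighbouring station, normalized
    coords = stations[["longitude", "latitude"]].to_numpy()
    dists = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
    np.fill_diagonal(dists, np.inf)
    isolation = dists.min(axis=1)
    isolation = isolation / isolation.mean()

    sample_ids, columns, meta_rows = [], [], []
    for month in config.months:
        e_m = config.month_env.get(month, 0.0)
        if math.isfinite(config.sigma_sel):
            fitness = np.exp(-(opt - e_m) ** 2 / (2 * config.sigma_sel ** 2))
        else:
            fitness = np.ones(len(taxa))
        month_pool = regional * fitness
        if month_pool.sum() <= 0:
            raise ValueError(
                f"selection too strong: empty pool in month {month}")
        month_pool /= month_pool.sum()
        env_month = {var: config.env_params[(var, month)]
                     for var in ENV_VARIABLES
                     if (var, month) in config.env_params}
        for s_idx, station in enumerate(stations.index):
            if math.isfinite(config.dispersal_scale):
                conc = config.dispersal_scale * month_pool \
                    / max(isolation[s_idx], 0.25)
                local = rng.dirichlet(np.clip(conc, 1e-9, None))
            else:
                local = month_pool.copy()
            # station-level environmental values, shared by replicates
            env_vals = {var: rng.normal(mu, sd)
                        for var, (mu, sd) in env_month.items()}
            for rep in range(1, config.n_replicates + 1):
                p = local
                for _ in range(config.drift_rounds):
                    draw = rng.multinomial(int(config.reads_mean * 10), p)
                    p = draw / draw.sum()
                n_reads = _nb_library(rng, config.reads_mean,
                                      config.reads_dispersion)
                counts = rng.multinomial(n_reads, p)
                sid = f"{station}_{month}_R{rep}"
                sample_ids.append(sid)
                columns.append(counts)
                meta_rows.append({
                    "sample_id": sid, "station": station, "month": month,
                    "replicate": rep,
                    "longitude": stations.loc[station, "longitude"],
                    "latitude": stations.loc[station, "latitude"],
                    **env_vals,
                })

    table = OtuTable(taxa, sample_ids,
                     np.column_stack(columns).astype(np.int64))
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    return SyntheticDataset(table, tree, metadata, optima,
                            _truth_labels(config))


def _nb_library(rng, mean: float, dispersion: float) -> int:
    """Negative-binomial library size (gamma-Poisson mixture)."""
    if dispersion <= 0:
        return int(round(mean))
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return max(int(rng.poisson(lam)), 1)


# ---------------------------------------------------------------------------
# Planted seasonal OTUs
# ---------------------------------------------------------------------------

def plant_season_otus(dataset: SyntheticDataset, n_per_month: int,
                      fold: float, seed=None) -> SyntheticDataset:
    """Multiply ``n_per_month`` random OTUs by ``fold`` in one month each.

    Columns are re-normalized to their original read depth by a multinomial
    redraw of the scaled composition. ``fold=1`` returns the dataset
    unchanged. The planted OTU -> month map is recorded as truth.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    table = dataset.table
    months = list(dict.fromkeys(dataset.metadata["month"]))
    if n_per_month * len(months) > table.n_taxa:
        raise ValueError("more planted OTUs than taxa")
    if fold == 1:
        return SyntheticDataset(table, dataset.tree, dataset.metadata,
                                dataset.optima, dict(dataset.truth), {})
    rng = np.random.default_rng(seed)
    chosen = rng.choice(table.n_taxa, size=n_per_month * len(months),
                        replace=False)
    planted = {table.taxon_ids[k]: months[i // n_per_month]
               for i, k in enumerate(chosen)}
    counts = table.counts.astype(float).copy()
    month_of = dataset.metadata.loc[table.sample_ids, "month"].to_numpy()
    for i, k in enumerate(chosen):
        month = months[i // n_per_month]
        counts[k, month_of == month] *= fold
    totals = table.sample_totals()
    new = np.empty_like(table.counts)
    for j in range(table.n_samples):
        p = counts[:, j] / counts[:, j].sum()
        new[:, j] = rng.multinomial(int(totals[j]), p)
    new_table = OtuTable(list(table.taxon_ids), list(table.sample_ids), new)
    return SyntheticDataset(new_table, dataset.tree, dataset.metadata,
                            dataset.optima, dict(dataset.truth), planted)
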