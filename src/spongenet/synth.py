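"""Synthetic sponge/seawater community generator.

Emulates the statistical structure the analysis assumes so that every
stage of the workflow runs without downloads:

* HMA-like communities — high richness and evenness, low temporal
  turnover, strong coordinated response to the environmental driver
  (hence strong internal correlation), small ASV overlap with seawater;
* LMA-like communities — low richness, strong dominance, high temporal
  turnover, larger ASV overlap with seawater;
* seawater — highest richness, intermediate turnover.

Communities are sampled as Dirichlet base compositions perturbed per
time point by lognormal jitter (turnover) plus a shared temperature
response on the dominant ASVs, then counted by multinomial draws per
replicate.  A Gaussian-copula generator plants a ground-truth
association network for co-occurrence recovery tests.  Everything is
bitwise reproducible under a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .table import ENV_VARIABLES, AsvTable, SampleMetadata

__all__ = [
    "CommunityConfig",
    "PRESETS",
    "GroundTruthNetwork",
    "generate_env_series",
    "generate_community",
    "random_ground_truth",
    "generate_correlated_counts",
    "generate_experiment",
]

#: Sampling months of the five time points (January .. October).
DEFAULT_MONTHS = (1, 4, 6, 8, 10)

#: Size of the common seawater ASV id pool that host communities draw
#: their shared fraction from.
SHARED_POOL_SIZE = 5000


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of one synthetic community (one sample group).

    richness: number of ASVs; evenness: Dirichlet concentration of the
    base composition (higher = more even); temporal_turnover: sd of the
    per-time-point log-abundance jitter; env_response: slope of the
    dominant (top-decile) ASVs on the standardized temperature driver;
    seawater_share: fraction of the ASV id pool drawn from the common
    seawater pool; depth: reads per sample.
    """

    phenotype: str  # HMA | LMA | seawater
    richness: int
    evenness: float
    temporal_turnover: float
    env_response: float
    seawater_share: float
    depth: int = 20_000
    n_timepoints: int = 5
    n_replicates: int = 3
    name: str = ""

    def __post_init__(self) -> None:
        if self.richness < 1:
            raise ValueError("richness must be >= 1")
        if not 0.0 <= self.seawater_share <= 1.0:
            raise ValueError("seawater_share must lie in [0, 1]")
        if self.depth < 1_000:
            raise ValueError("depth must be >= 1000")
        if not self.name:
            object.__setattr__(self, "name", self.phenotype)


#: Phenotype presets.  Richness/evenness contrasts give the diversity
#: ordering seawater > HMA > LMA.  Environmental susceptibility rises
#: from HMA (buffered mesohyl) through LMA to free-living seawater
#: communities, while temporal turnover (idiosyncratic jitter) is
#: lowest in HMA: the combination makes HMA dynamics tightly mutually
#: correlated (dense network) and LMA dynamics driver-coupled but
#: noisy (looser network).  Seawater-share contrasts give LMA its
#: larger ASV overlap with ambient seawater.
PRESETS: dict[str, CommunityConfig] = {
    "HMA": CommunityConfig(
        phenotype="HMA", richness=800, evenness=2.0, temporal_turnover=0.25,
        env_response=0.8, seawater_share=0.10,
    ),
    "LMA": CommunityConfig(
        phenotype="LMA", richness=150, evenness=0.15, temporal_turnover=1.2,
        env_response=1.5, seawater_share=0.45,
    ),
    "seawater": CommunityConfig(
        phenotype="seawater", richness=3000, evenness=1.0, temporal_turnover=0.8,
        env_response=2.0, seawater_share=1.0,
    ),
}


def generate_env_series(
    seed: int | np.random.Generator = 0,
    months: tuple[int, ...] = DEFAULT_MONTHS,
) -> pd.DataFrame:
    """Environmental variables over the sampling time points.

    Temperature follows a seasonal arc from ~14 degC (January) peaking
    ~30 degC at the mid-series time point; dissolved oxygen is
    anti-correlated with temperature; the remaining variables are iid
    lognormal around fixed means.
    """
    rng = np.random.default_rng(seed)
    n = len(months)
    m = np.asarray(months, dtype=float)
    # annual sinusoid peaking just before mid-series (June); note the
    # arc is asymmetric over the sampled months: October stays warm
    # while January is the coldest point
    temperature = 22.0 + 8.0 * np.sin(2 * np.pi * (m - 3.8) / 12.0)
    temperature = temperature + rng.normal(0, 0.2, n)
    do = 9.0 - 3.0 * (temperature - 14.0) / 16.0 + rng.normal(0, 0.2, n)
    means = {
        "salinity": 33.0, "pH": 8.1, "NO3": 2.0, "NO2": 0.3, "NH4": 1.0,
        "DIP": 0.5, "DOP": 0.3, "TDP": 0.8, "TP": 1.2, "SiO3": 10.0,
    }
    data = {"temperature": temperature, "DO": do}
    for var, mu in means.items():
        sigma = 0.02 if var in ("salinity", "pH") else 0.3
        data[var] = mu * np.exp(rng.normal(-sigma**2 / 2, sigma, n))
    df = pd.DataFrame(data, index=pd.Index(months, name="month"))
    return df[list(ENV_VARIABLES)]


def _asv_ids(cfg: CommunityConfig, rng: np.random.Generator) -> list[str]:
    n_shared = int(round(cfg.seawater_share * cfg.richness))
    pool = rng.choice(SHARED_POOL_SIZE, size=n_shared, replace=False)
    shared = [f"SW{i:05d}" for i in sorted(pool)]
    own = [f"{cfg.name}_{i:04d}" for i in range(cfg.richness - n_shared)]
    return shared + own


def generate_community(
    cfg: CommunityConfig,
    env: pd.DataFrame | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[AsvTable, SampleMetadata]:
    """One community over n_timepoints x n_replicates samples.

    Expected composition at time t: Dirichlet base weights times
    exp(jitter_{i,t} + beta * z_t [top-decile ASVs only]) renormalized,
    with z the standardized temperature driver; replicate counts are
    independent multinomial draws at the configured depth.  Jitter is
    shared across replicates of a time point (replicates differ only by
    sampling noise, as field replicates do).
    """
    rng = np.random.default_rng(seed)
    if env is None:
        env = generate_env_series(rng)
    months = list(env.index)[: cfg.n_timepoints]
    ids = _asv_ids(cfg, rng)
    base = rng.dirichlet(np.full(cfg.richness, cfg.evenness))
    base = np.maximum(base, 1e-12)
    n_top = max(1, cfg.richness // 10)
    responders = np.argsort(base)[-n_top:]
    temp = env["temperature"].to_numpy(dtype=float)[: cfg.n_timepoints]
    z = (temp - temp.mean()) / temp.std(ddof=0)
    jitter = rng.normal(0.0, cfg.temporal_turnover, (cfg.richness, cfg.n_timepoints))

    counts = {}
    meta_rows = []
    for t in range(cfg.n_timepoints):
        logw = np.log(base) + jitter[:, t]
        logw[responders] += cfg.env_response * z[t]
        w = np.exp(logw - logw.max())
        comp = w / w.sum()
        for rep in range(cfg.n_replicates):
            sid = f"{cfg.name}_T{t + 1}R{rep + 1}"
            counts[sid] = rng.multinomial(cfg.depth, comp)
            row = {
                "sample_id": sid,
                "host": cfg.name,
                "phenotype": cfg.phenotype if cfg.phenotype != "seawater" else "NA",
                "habitat": "seawater" if cfg.phenotype == "seawater" else "sponge",
                "month": months[t],
                "replicate": rep + 1,
            }
            row.update(env.iloc[t].to_dict())
            meta_rows.append(row)

    table = AsvTable(pd.DataFrame(counts, index=ids))
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    meta.validate_against(table)
    return table, meta


# ---------------------------------------------------------------------------
# Ground-truth association networks


@dataclass
class GroundTruthNetwork:
    """Planted association network for co-occurrence recovery tests."""

    node_ids: list[str]
    edges: list[tuple[str, str, int]]  # (a, b, sign)
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1)")
        seen = set()
        for a, b, sign in self.edges:
            if a == b:
                raise ValueError("self-edges not allowed")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError("duplicate edge")
            seen.add(key)
            if sign not in (-1, 1):
                raise ValueError("edge sign must be -1 or +1")

    def edge_set(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b, _ in self.edges}

    def correlation_matrix(self) -> np.ndarray:
        idx = {a: i for i, a in enumerate(self.node_ids)}
        sigma = np.eye(len(self.node_ids))
        for a, b, sign in self.edges:
            sigma[idx[a], idx[b]] = sigma[idx[b], idx[a]] = sign * self.rho
        return sigma


def random_ground_truth(
    n_nodes: int,
    n_edges: int,
    rho: float = 0.8,
    frac_negative: float = 0.0,
    mode: str = "matching",
    seed: int | np.random.Generator = 0,
) -> GroundTruthNetwork:
    """Random planted network.

    ``matching`` mode places edges on disjoint node pairs, which keeps
    the implied correlation matrix positive definite for any rho < 1;
    ``er`` mode draws edges uniformly among all pairs (may require
    thinning to reach positive definiteness downstream).
    """
    rng = np.random.default_rng(seed)
    ids = [f"ASV{i:04d}" for i in range(n_nodes)]
    if mode == "matching":
        if 2 * n_edges > n_nodes:
            raise ValueError("matching mode needs n_nodes >= 2 * n_edges")
        order = rng.permutation(n_nodes)
        pairs = [(order[2 * k], order[2 * k + 1]) for k in range(n_edges)]
    elif mode == "er":
        all_pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
        sel = rng.choice(len(all_pairs), size=n_edges, replace=False)
        pairs = [all_pairs[k] for k in sel]
    else:
        raise ValueError("mode must be 'matching' or 'er'")
    edges = []
    for i, j in pairs:
        sign = -1 if rng.random() < frac_negative else 1
        a, b = sorted((ids[i], ids[j]))
        edges.append((a, b, sign))
    return GroundTruthNetwork(node_ids=ids, edges=edges, rho=rho)


def generate_correlated_counts(
    gt: GroundTruthNetwork,
    n_samples: int,
    depth: int = 20_000,
    seed: int | np.random.Generator = 0,
    abundance_spread: float = 0.8,
) -> AsvTable:
    """Counts with planted pairwise associations via a Gaussian copula.

    Latent Gaussians with correlation rho on planted edges (sign
    respected, identity elsewhere) are mapped to lognormal expected
    abundances (per-ASV means spread by ``abundance_spread`` on the log
    scale) and counted by per-sample multinomial draws.  A requested
    correlation matrix that is not positive definite is thinned edge by
    edge with a warning.
    """
    rng = np.random.default_rng(seed)
    sigma = gt.correlation_matrix()
    edges = list(gt.edges)
    while np.linalg.eigvalsh(sigma)[0] <= 1e-9:
        if not edges:
            raise ValueError("correlation matrix not positive definite")
        drop = edges.pop(int(rng.integers(len(edges))))
        warnings.warn(
            f"planted correlation matrix not positive definite; dropping "
            f"edge {drop[:2]}",
            stacklevel=2,
        )
        sigma = replace(gt, edges=edges).correlation_matrix()
    chol = np.linalg.cholesky(sigma)
    p = len(gt.node_ids)
    mu = rng.normal(0.0, abundance_spread, p)
    z = chol @ rng.standard_normal((p, n_samples))
    abund = np.exp(mu[:, None] + z)
    comp = abund / abund.sum(axis=0, keepdims=True)
    counts = np.column_stack(
        [rng.multinomial(depth, comp[:, j]) for j in range(n_samples)]
    )
    sample_ids = [f"S{j + 1:03d}" for j in range(n_samples)]
    return AsvTable(pd.DataFrame(counts, index=gt.node_ids, columns=sample_ids))


# ---------------------------------------------------------------------------
# Whole-experiment presets


@dataclass
class SyntheticExperiment:
    """A full multi-group dataset: per-group tables plus pooled metadata."""

    tables: dict[str, AsvTable]
    metadata: SampleMetadata
    env: pd.DataFrame
    configs: dict[str, CommunityConfig] = field(default_factory=dict)
    seed: int | None = None

    def merged_table(self) -> AsvTable:
        merged = pd.concat(
            [t.data for t in self.tables.values()], axis=1
        ).fillna(0).astype(np.int64)
        merged = merged.groupby(level=0).sum()  # shared ASV ids align
        return AsvTable(merged)


def _experiment_groups(preset: str) -> list[tuple[str, str]]:
    if preset == "coastal":
        # one HMA host, two LMA hosts, ambient seawater — the main
        # one-year survey design (5 months x 3 replicates per group)
        return [
            ("Tedania-like", "LMA"),
            ("Haliclona-like", "LMA"),
            ("Spongia-like", "HMA"),
            ("seawater", "seawater"),
        ]
    if preset == "smp":
        # meta-analysis scale: 15 sponge groups (5 HMA, 10 LMA) and 5
        # seawater groups
        groups = [(f"HMA-host-{i + 1}", "HMA") for i in range(5)]
        groups += [(f"LMA-host-{i + 1}", "LMA") for i in range(10)]
        groups += [(f"seawater-{i + 1}", "seawater") for i in range(5)]
        return groups
    raise ValueError(f"unknown preset {preset!r}; choose 'coastal' or 'smp'")


def generate_experiment(
    preset: str = "coastal",
    seed: int = 0,
    depth: int | None = None,
) -> SyntheticExperiment:
    """Generate a named multi-group dataset from phenotype presets."""
    rng = np.random.default_rng(seed)
    env = generate_env_series(rng)
    tables: dict[str, AsvTable] = {}
    metas = []
    configs = {}
    for name, phenotype in _experiment_groups(preset):
        cfg = replace(PRESETS[phenotype], name=name)
        if depth is not None:
            cfg = replace(cfg, depth=depth)
        table, meta = generate_community(cfg, env, seed=int(rng.integers(2**31)))
        tables[name] = table
        metas.append(meta.table)
        configs[name] = cfg
    metadata = SampleMetadata(pd.concat(metas))
    return SyntheticExperiment(
        tables=tables, metadata=metadata, env=env, configs=configs, seed=seed
    )
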