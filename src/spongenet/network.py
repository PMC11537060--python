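"""Correlation-based molecular ecological networks (MENs).

Pipeline: Spearman correlation matrix of prevalence-filtered,
non-log-transformed ASV counts -> random-matrix-theory (RMT) selection
of the correlation cutoff -> thresholded co-occurrence graph ->
topology metrics -> Maslov-Sneppen degree-preserving null ensemble ->
keystone ranking by combined degree / betweenness rank.

RMT threshold selection scans candidate cutoffs; at each cutoff the
thresholded matrix's eigenvalue spectrum is unfolded and the
nearest-neighbor spacing distribution (NNSD) is tested against the
Poisson law P(d) = exp(-d).  Dense correlated matrices show
Wigner-Dyson (GOE) spacing statistics; once the cutoff removes the
noise correlations the spectrum decorrelates and the NNSD becomes
Poisson.  The chosen threshold is the smallest cutoff whose NNSD is
Poisson-consistent and remains so for the next two scan steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .table import AsvTable

__all__ = [
    "CorrelationNetwork",
    "NetworkTopology",
    "NullEnsembleSummary",
    "RmtThresholdError",
    "spearman_matrix",
    "rmt_threshold",
    "build_network",
    "topology",
    "maslov_sneppen_rewire",
    "null_ensemble",
    "keystone_species",
]


class RmtThresholdError(RuntimeError):
    """No scanned cutoff produced a Poisson-consistent NNSD."""

    def __init__(self, message: str, diagnostics: pd.DataFrame | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics


# ---------------------------------------------------------------------------
# Correlation matrix


def spearman_matrix(t: AsvTable) -> tuple[pd.DataFrame, list[str]]:
    """Spearman correlation matrix across ASVs (average ranks for ties).

    Zero-variance ASVs cannot be rank-correlated; they are removed and
    returned as the second element.
    """
    if t.n_samples < 4:
        raise ValueError("need at least 4 samples for rank correlations")
    counts = t.counts.astype(float)
    variances = counts.var(axis=1)
    dropped = [a for a, v in zip(t.asv_ids, variances) if v == 0]
    keep_ids = [a for a, v in zip(t.asv_ids, variances) if v > 0]
    if len(keep_ids) < 2:
        raise ValueError("fewer than 2 ASVs with nonzero variance")
    sub = t.data.loc[keep_ids].to_numpy(dtype=float)
    # rank within each ASV across samples, then Pearson of ranks
    ranks = scipy.stats.rankdata(sub, axis=1)
    corr = np.corrcoef(ranks)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=keep_ids, columns=keep_ids), dropped


# ---------------------------------------------------------------------------
# RMT threshold


def _unfolded_spacings(eigs: np.ndarray, decimals: int = 8) -> np.ndarray | None:
    """Unfold a spectrum and return mean-1 nearest-neighbor spacings.

    Exact-duplicate eigenvalues (ubiquitous in sparse thresholded
    matrices) are collapsed before unfolding.  Unfolding fits a cubic
    polynomial to the empirical cumulative spectral function; spacings
    are differences of the fitted staircase at consecutive eigenvalues.
    """
    vals = np.unique(np.round(np.sort(eigs), decimals))
    if len(vals) < 20:
        return None
    idx = np.arange(1, len(vals) + 1, dtype=float)
    coef = np.polyfit(vals, idx, 3)
    unfolded = np.polyval(coef, vals)
    s = np.diff(unfolded)
    s = s[s > 0]
    if len(s) < 10 or s.mean() <= 0:
        return None
    return s / s.mean()


def _poisson_gof_pvalue(
    spacings: np.ndarray, n_bins: int = 20, s_max: float = 3.0
) -> float:
    """Chi-square goodness of fit of spacings against P(d) = exp(-d).

    The NNSD histogram is formed over [0, s_max]; expected counts come
    from the truncated-renormalized exponential.  Trailing bins are
    merged until every expected count is >= 5 (chi-square validity).
    """
    s = spacings[spacings <= s_max]
    if len(s) < 10:
        return np.nan
    observed, edges = np.histogram(s, bins=n_bins, range=(0.0, s_max))
    cdf = 1.0 - np.exp(-edges)
    probs = np.diff(cdf) / (1.0 - np.exp(-s_max))
    expected = probs * observed.sum()
    # merge sparse tail/head bins until all expected >= 5
    obs, exp = list(observed), list(expected)
    while len(obs) > 2 and exp[-1] < 5:
        last_e, last_o = exp.pop(), obs.pop()
        exp[-1] += last_e
        obs[-1] += last_o
    while len(obs) > 2 and exp[0] < 5:
        first_e, first_o = exp.pop(0), obs.pop(0)
        exp[0] += first_e
        obs[0] += first_o
    if len(obs) < 3:
        return np.nan
    stat, p = scipy.stats.chisquare(obs, exp)
    return float(p)


def _threshold_eigenvalues(c: np.ndarray, s: float) -> np.ndarray | None:
    """Eigenvalues of the thresholded matrix, restricted to active rows.

    Rows with no surviving off-diagonal entry contribute only copies of
    the unit eigenvalue, which duplicate-dropping would discard anyway;
    they are excluded up front for speed.
    """
    m = np.where(np.abs(c) >= s, c, 0.0)
    np.fill_diagonal(m, 1.0)
    active = np.flatnonzero((np.abs(m) > 0).sum(axis=1) > 1)
    if len(active) < 2:
        return None
    sub = m[np.ix_(active, active)]
    return scipy.linalg.eigvalsh(sub)


def rmt_threshold(
    c: pd.DataFrame | np.ndarray,
    scan: tuple[float, float] = (0.30, 0.99),
    step: float = 0.01,
    alpha: float = 0.05,
    stability_steps: int = 2,
    on_failure: str = "raise",
) -> tuple[float, pd.DataFrame]:
    """Select the correlation cutoff by the RMT Poisson-transition rule.

    Scans ``scan`` in increments of ``step``; the selected threshold is
    the smallest cutoff whose NNSD is consistent with Poisson
    (goodness-of-fit p > ``alpha``) and stays consistent for the next
    ``stability_steps`` steps.  Returns (threshold, diagnostics) where
    diagnostics tabulates per-cutoff distinct-eigenvalue counts and GOF
    p-values.  When no cutoff qualifies, raises
    :class:`RmtThresholdError` (``on_failure="raise"``) or falls back to
    the scanned cutoff with the best Poisson fit
    (``on_failure="best-fit"``).
    """
    c = np.asarray(c, dtype=float)
    n = c.shape[0]
    if n < 50:
        warnings.warn(
            f"only {n} nodes; the eigenvalue spectrum may be too small for "
            "a reliable NNSD fit",
            stacklevel=2,
        )
    thresholds = np.round(np.arange(scan[0], scan[1] + 1e-9, step), 10)
    pvals = np.full(len(thresholds), np.nan)
    n_eigs = np.zeros(len(thresholds), dtype=int)
    records_upto = 0
    chosen = None
    for i, s in enumerate(thresholds):
        eigs = _threshold_eigenvalues(c, s)
        if eigs is not None:
            n_eigs[i] = len(np.unique(np.round(eigs, 8)))
            spac = _unfolded_spacings(eigs)
            if spac is not None:
                pvals[i] = _poisson_gof_pvalue(spac)
        records_upto = i + 1
        # check whether the cutoff stability_steps back is now confirmed
        j = i - stability_steps
        if j >= 0 and np.all(pvals[j : i + 1] > alpha):
            chosen = thresholds[j]
            break
    diag = pd.DataFrame(
        {
            "threshold": thresholds[:records_upto],
            "n_distinct_eigenvalues": n_eigs[:records_upto],
            "poisson_gof_p": pvals[:records_upto],
        }
    )
    if chosen is None:
        if on_failure == "best-fit" and np.any(~np.isnan(pvals[:records_upto])):
            best = int(np.nanargmax(pvals[:records_upto]))
            return float(thresholds[best]), diag
        raise RmtThresholdError(
            "no cutoff in the scan range gave a stably Poisson-consistent "
            "NNSD; extend the scan range or inspect the diagnostics",
            diagnostics=diag,
        )
    return float(chosen), diag


# ---------------------------------------------------------------------------
# Graph construction & topology


@dataclass
class CorrelationNetwork:
    """Thresholded co-occurrence graph.

    ``graph`` is a simple undirected networkx Graph whose edges carry
    ``r`` (signed correlation), ``weight`` (|r|) and ``sign`` (+1/-1).
    Isolated nodes are excluded from the graph but counted in
    ``n_isolated``.
    """

    graph: nx.Graph
    threshold: float
    n_isolated: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "r": d["r"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "r", "sign"])


def build_network(
    c: pd.DataFrame, s_t: float, node_ids: list[str] | None = None
) -> CorrelationNetwork:
    """Build the co-occurrence graph: edge wherever |r| >= s_t (i != j)."""
    if not 0 < s_t <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if node_ids is None:
        node_ids = list(c.index) if isinstance(c, pd.DataFrame) else [
            str(i) for i in range(np.asarray(c).shape[0])
        ]
    mat = np.asarray(c, dtype=float)
    g = nx.Graph()
    iu, ju = np.triu_indices(mat.shape[0], k=1)
    mask = np.abs(mat[iu, ju]) >= s_t
    for i, j in zip(iu[mask], ju[mask]):
        r = mat[i, j]
        g.add_edge(node_ids[i], node_ids[j], r=float(r), weight=abs(float(r)),
                   sign=1 if r >= 0 else -1)
    n_isolated = len(node_ids) - g.number_of_nodes()
    return CorrelationNetwork(graph=g, threshold=float(s_t), n_isolated=n_isolated)


@dataclass
class NetworkTopology:
    """Global and per-node topology metrics of a co-occurrence graph."""

    n_nodes: int
    n_links: int
    links_per_node: float
    avg_connectivity: float  # avgK = 2L/N
    modularity: float
    connectedness: float  # fraction of node pairs joined by a path
    degree: pd.Series
    betweenness: pd.Series  # normalized by (N-1)(N-2)/2

    def to_dict(self) -> dict:
        return {
            "N": self.n_nodes,
            "L": self.n_links,
            "L/N": self.links_per_node,
            "avgK": self.avg_connectivity,
            "M": self.modularity,
            "Con": self.connectedness,
        }


def _connectedness(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 1.0
    pairs = sum(
        len(comp) * (len(comp) - 1) // 2 for comp in nx.connected_components(g)
    )
    return pairs / (n * (n - 1) / 2)


def _to_igraph(g: nx.Graph) -> tuple[igraph.Graph, list]:
    nodes = list(g.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    ig = igraph.Graph(
        n=len(nodes), edges=[(idx[u], idx[v]) for u, v in g.edges()], directed=False
    )
    return ig, nodes


def _modularity(g: nx.Graph) -> float:
    """Modularity of the greedy (CNM) partition; deterministic, seedless."""
    if g.number_of_edges() == 0:
        return 0.0
    ig, _ = _to_igraph(g)
    clustering = ig.community_fastgreedy().as_clustering()
    return float(ig.modularity(clustering.membership))


def topology(net: CorrelationNetwork | nx.Graph) -> NetworkTopology:
    """Compute N, L, L/N, avgK, modularity, connectedness, centralities.

    The graph is treated as unweighted (edges are presences); modularity
    uses the deterministic greedy (CNM) partition.
    """
    g = net.graph if isinstance(net, CorrelationNetwork) else net
    n, l = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty graph")
    degree = pd.Series(dict(g.degree()), dtype=float).sort_index()
    betweenness = pd.Series(nx.betweenness_centrality(g, normalized=True)).sort_index()
    return NetworkTopology(
        n_nodes=n,
        n_links=l,
        links_per_node=l / n,
        avg_connectivity=2 * l / n,
        modularity=_modularity(g),
        connectedness=_connectedness(g),
        degree=degree,
        betweenness=betweenness,
    )


# ---------------------------------------------------------------------------
# Maslov-Sneppen null model


def maslov_sneppen_rewire(
    g: nx.Graph, n_swaps: int | None = None, seed: int = 0
) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps.

    Proposed swaps that would create self-loops or multi-edges are
    rejected, so the node set, edge count and degree sequence are
    preserved exactly.  The budget (default 100 x L) counts swap
    proposals; on sparse graphs nearly all proposals are accepted.
    Graphs too small to admit any swap are returned unchanged.
    Backed by igraph's C implementation of the double-edge-swap walk.
    """
    l = g.number_of_edges()
    if l < 2 or g.number_of_nodes() < 4:
        return g.copy()
    if n_swaps is None:
        n_swaps = 100 * l
    import random as _random

    igraph.set_random_number_generator(_random.Random(seed))
    ig, nodes = _to_igraph(g)
    ig.rewire(n=n_swaps, mode="simple")
    h = nx.Graph()
    h.add_nodes_from(nodes)
    h.add_edges_from((nodes[e.source], nodes[e.target]) for e in ig.es)
    return h


DEFAULT_NULL_METRICS = ("modularity", "connectedness", "avg_clustering")

_METRIC_FUNCS = {
    "modularity": _modularity,
    "connectedness": _connectedness,
    "avg_clustering": nx.average_clustering,
    "avgK": lambda g: 2 * g.number_of_edges() / g.number_of_nodes(),
    "L/N": lambda g: g.number_of_edges() / g.number_of_nodes(),
}


@dataclass
class NullEnsembleSummary:
    """Empirical-vs-null comparison over Maslov-Sneppen rewirings.

    ``table`` columns: observed, null_mean, null_sd, z.  Z is NaN
    (flagged in ``degenerate``) where the null sd is 0, e.g. for
    metrics fully determined by the degree sequence such as avgK.
    """

    table: pd.DataFrame
    n_random: int
    seed: int
    degenerate: list[str] = field(default_factory=list)


def null_ensemble(
    net: CorrelationNetwork | nx.Graph,
    metrics: tuple[str, ...] = DEFAULT_NULL_METRICS,
    n: int = 100,
    seed: int = 0,
) -> NullEnsembleSummary:
    """Compare topology metrics against ``n`` degree-preserving rewirings."""
    g = net.graph if isinstance(net, CorrelationNetwork) else net
    unknown = [m for m in metrics if m not in _METRIC_FUNCS]
    if unknown:
        raise ValueError(f"unknown metrics {unknown}; choose from {sorted(_METRIC_FUNCS)}")
    observed = {m: _METRIC_FUNCS[m](g) for m in metrics}
    rng = np.random.default_rng(seed)
    null_vals = {m: np.empty(n) for m in metrics}
    for i in range(n):
        h = maslov_sneppen_rewire(g, seed=int(rng.integers(2**31)))
        for m in metrics:
            null_vals[m][i] = _METRIC_FUNCS[m](h)
    rows, degenerate = [], []
    for m in metrics:
        mu = float(null_vals[m].mean())
        sd = float(null_vals[m].std(ddof=1))
        if sd > 0:
            z = (observed[m] - mu) / sd
        else:
            z = np.nan
            degenerate.append(m)
        rows.append(
            {"metric": m, "observed": observed[m], "null_mean": mu,
             "null_sd": sd, "z": z}
        )
    table = pd.DataFrame(rows).set_index("metric")
    return NullEnsembleSummary(table=table, n_random=n, seed=seed,
                               degenerate=degenerate)


# ---------------------------------------------------------------------------
# Keystone ranking


def keystone_species(topo: NetworkTopology, k: int = 10) -> pd.DataFrame:
    """Top-k nodes by combined degree / betweenness rank.

    Nodes are ranked separately by degree (descending) and betweenness
    centrality (descending, average ranks for ties); the keystone score
    is the mean of the two ranks (lower = more central).  Ties are
    broken lexicographically by ASV id.
    """
    ids = topo.degree.index
    rank_deg = pd.Series(
        scipy.stats.rankdata(-topo.degree.to_numpy(), method="average"), index=ids
    )
    rank_btw = pd.Series(
        scipy.stats.rankdata(-topo.betweenness.loc[ids].to_numpy(), method="average"),
        index=ids,
    )
    score = (rank_deg + rank_btw) / 2
    df = pd.DataFrame(
        {
            "degree": topo.degree,
            "betweenness": topo.betweenness.loc[ids],
            "rank_degree": rank_deg,
            "rank_betweenness": rank_btw,
            "score": score,
        }
    )
    # stable sort: lexicographic id order breaks score ties
    df = df.sort_index(kind="mergesort").sort_values("score", kind="mergesort")
    if len(df) < k:
        warnings.warn(
            f"only {len(df)} nodes available for top-{k} keystones", stacklevel=2
        )
    return df.head(k)
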