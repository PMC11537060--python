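"""Alpha/beta diversity, hierarchical clustering and permutation statistics.

Covers the community-level statistics of the workflow: alpha diversity
indices, Bray-Curtis dissimilarity, UPGMA dendrograms, the permutation
tests ANOSIM / PERMANOVA / MRPP / Mantel, variance-inflation-factor
screening of environmental variables, and the effective-number-of-species
(neff) heuristic used to pick a correlation method for association
networks.

ANOSIM, PERMANOVA and Mantel are delegated to scikit-bio; MRPP follows
the classical delta / chance-corrected A formulation with group-size
weights n_g / sum(n_g).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.distance import mantel as _skbio_mantel
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.tree import TreeNode

from .table import AsvTable, RelAbundanceTable

__all__ = [
    "PermTestResult",
    "alpha_diversity",
    "neff",
    "choose_correlation_method",
    "bray_curtis",
    "upgma",
    "anosim",
    "permanova",
    "mrpp",
    "mantel",
    "vif_screen",
]

ALPHA_INDICES = ("richness", "shannon", "simpson", "invsimpson", "pielou")


@dataclass
class PermTestResult:
    """Outcome of a permutation test."""

    name: str
    statistic: float
    n_permutations: int
    p_value: float
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        floor = 1.0 / (self.n_permutations + 1)
        if self.p_value < floor - 1e-12:
            raise ValueError("p-value below permutation resolution")

    def to_record(self) -> dict:
        rec = {
            "statistic": self.name,
            "value": self.statistic,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "seed": self.seed,
        }
        rec.update(self.extras)
        return rec


# ---------------------------------------------------------------------------
# Alpha diversity


def alpha_diversity(counts: np.ndarray, index: str = "shannon") -> float:
    """Alpha diversity of one sample.

    shannon: H = -sum p_i ln p_i (natural log); simpson: 1 - sum p_i^2;
    invsimpson: 1 / sum p_i^2; pielou: H / ln(richness).
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample has zero total count")
    p = counts[counts > 0] / total
    if index == "richness":
        return float(len(p))
    if index == "shannon":
        return float(-(p * np.log(p)).sum())
    if index == "simpson":
        return float(1.0 - (p**2).sum())
    if index == "invsimpson":
        return float(1.0 / (p**2).sum())
    if index == "pielou":
        if len(p) == 1:
            return 0.0
        return float(-(p * np.log(p)).sum() / np.log(len(p)))
    raise ValueError(f"unknown index {index!r}; choose from {ALPHA_INDICES}")


def neff(counts: np.ndarray) -> float:
    """Effective number of species: the inverse Simpson index."""
    return alpha_diversity(counts, "invsimpson")


def choose_correlation_method(
    neff_value: float,
    sparsity_frac: float,
    is_time_series: bool,
    neff_cutoff: float = 13.0,
    sparsity_cutoff: float = 0.5,
) -> dict:
    """Decide whether local similarity analysis (LSA) is appropriate.

    LSA is selected when the community is not a high-diversity
    low-effective-richness composition (neff >= 13), the table is less
    than 50% sparse, and the samples form a time series.  Otherwise the
    failing criteria are reported so a caller can fall back to another
    association measure.
    """
    failed = []
    if neff_value < neff_cutoff:
        failed.append(f"neff <{neff_cutoff:g}")
    if sparsity_frac >= sparsity_cutoff:
        failed.append("sparsity")
    if not is_time_series:
        failed.append("not a time series")
    return {
        "method": "LSA" if not failed else None,
        "failed_criteria": failed,
        "neff": neff_value,
        "sparsity": sparsity_frac,
    }


# ---------------------------------------------------------------------------
# Beta diversity & clustering


def bray_curtis(t: AsvTable | RelAbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix: BC(x, y) = sum|x-y| / sum(x+y)."""
    if isinstance(t, (AsvTable, RelAbundanceTable)):
        data = t.data
    else:
        data = pd.DataFrame(t)
    if data.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    profiles = data.to_numpy(dtype=float).T  # samples x ASVs
    if np.any(profiles.sum(axis=1) == 0):
        raise ValueError("zero-sum sample; Bray-Curtis undefined")
    condensed = pdist(profiles, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(data.columns))


def upgma(d: DistanceMatrix) -> str:
    """Average-linkage (UPGMA) dendrogram of a distance matrix as newick."""
    if d.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    linkage = sch.linkage(d.condensed_form(), method="average")
    tree = TreeNode.from_linkage_matrix(linkage, list(d.ids))
    return str(tree).strip()


# ---------------------------------------------------------------------------
# Permutation tests


def _as_dm(d) -> DistanceMatrix:
    return d if isinstance(d, DistanceMatrix) else DistanceMatrix(d)


def _check_groups(groups: np.ndarray) -> None:
    values, counts = np.unique(np.asarray(groups), return_counts=True)
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        small = values[counts < 2]
        raise ValueError(f"group(s) with fewer than 2 members: {list(small)}")


def anosim(d, groups, n_perm: int = 999, seed: int | None = 0) -> PermTestResult:
    """Analysis of similarities: rank-based R statistic with permutation p."""
    d = _as_dm(d)
    groups = np.asarray(groups)
    _check_groups(groups)
    res = _skbio_anosim(d, groups, permutations=n_perm, seed=seed)
    return PermTestResult(
        name="ANOSIM R",
        statistic=float(res["test statistic"]),
        n_permutations=n_perm,
        p_value=float(res["p-value"]),
        seed=seed,
    )


def permanova(d, groups, n_perm: int = 999, seed: int | None = 0) -> PermTestResult:
    """Permutational MANOVA (pseudo-F computed directly from distances).

    Also reports R^2 = SS_between / SS_total.
    """
    d = _as_dm(d)
    groups = np.asarray(groups)
    _check_groups(groups)
    res = _skbio_permanova(d, groups, permutations=n_perm, seed=seed)
    f = float(res["test statistic"])
    n = len(groups)
    a = len(np.unique(groups))
    # F = (SSA/(a-1)) / (SSW/(n-a))  =>  SSA/SSW = F(a-1)/(n-a)
    ratio = f * (a - 1) / (n - a)
    r2 = ratio / (1.0 + ratio)
    return PermTestResult(
        name="PERMANOVA pseudo-F",
        statistic=f,
        n_permutations=n_perm,
        p_value=float(res["p-value"]),
        seed=seed,
        extras={"R2": r2},
    )


def mrpp(d, groups, n_perm: int = 999, seed: int | None = 0) -> PermTestResult:
    """Multiple response permutation procedure.

    delta = sum_g (n_g / n) * (mean within-group distance of g); the
    chance-corrected within-group agreement A = 1 - delta / E[delta],
    with E[delta] the mean delta over label permutations; one-sided p
    (small delta = cohesive groups), add-one corrected.
    """
    d = _as_dm(d)
    groups = np.asarray(groups)
    _check_groups(groups)
    if len(groups) != d.shape[0]:
        raise ValueError("groups length must match distance matrix size")
    mat = d.data
    n = len(groups)
    rng = np.random.default_rng(seed)

    def delta_for(labels: np.ndarray) -> float:
        total = 0.0
        for g in np.unique(labels):
            idx = np.flatnonzero(labels == g)
            sub = mat[np.ix_(idx, idx)]
            m = len(idx)
            within = sub[np.triu_indices(m, k=1)].mean()
            total += (m / n) * within
        return total

    observed = delta_for(groups)
    perm_deltas = np.empty(n_perm)
    for i in range(n_perm):
        perm_deltas[i] = delta_for(rng.permutation(groups))
    expected = perm_deltas.mean()
    a_stat = 1.0 - observed / expected if expected > 0 else 0.0
    p = (1 + np.sum(perm_deltas <= observed)) / (n_perm + 1)
    return PermTestResult(
        name="MRPP delta",
        statistic=observed,
        n_permutations=n_perm,
        p_value=float(p),
        seed=seed,
        extras={"A": float(a_stat), "expected_delta": float(expected)},
    )


def mantel(
    d1,
    d2,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | None = 0,
) -> PermTestResult:
    """Mantel correlation between two distance matrices (two-sided)."""
    d1, d2 = _as_dm(d1), _as_dm(d2)
    if d1.shape != d2.shape:
        raise ValueError("distance matrices differ in size")
    r, p, n = _skbio_mantel(d1, d2, method=method, permutations=n_perm, seed=seed)
    return PermTestResult(
        name=f"Mantel r ({method})",
        statistic=float(r),
        n_permutations=n_perm,
        p_value=float(p),
        seed=seed,
        extras={"n_samples": int(n)},
    )


# ---------------------------------------------------------------------------
# Environmental variable screening


def vif_screen(env: pd.DataFrame, threshold: float = 20.0) -> tuple[list[str], pd.Series]:
    """Iteratively drop collinear environmental variables by VIF.

    VIF_j = 1 / (1 - R^2_j) from regressing variable j on the remaining
    variables (with intercept).  Constant variables are reported as
    infinite VIF and removed first; then the highest-VIF variable is
    removed until all VIFs are <= threshold.  Returns the retained
    variable names and their final VIFs.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    env = pd.DataFrame(env).astype(float)
    if env.shape[1] < 2:
        raise ValueError("need at least 2 variables")

    def vifs_of(cols: list[str]) -> pd.Series:
        sub = env[cols]
        out = {}
        for j, c in enumerate(cols):
            if np.isclose(sub[c].std(ddof=0), 0.0):
                out[c] = np.inf
                continue
            exog = np.column_stack([np.ones(len(sub)), sub.to_numpy()])
            out[c] = variance_inflation_factor(exog, j + 1)
        return pd.Series(out)

    cols = list(env.columns)
    while len(cols) >= 2:
        v = vifs_of(cols)
        worst = v.idxmax()
        if v[worst] > threshold:
            cols.remove(worst)
        else:
            break
    return cols, vifs_of(cols)
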