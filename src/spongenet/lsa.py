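"""Local similarity analysis (LSA) of ASV time series.

LSA finds the strongest contiguous, possibly time-lagged, co-varying
segment of two standardized series via a dynamic program over partial
sums of products.  With series standardized to zero mean and unit
variance, the local similarity score LS is bounded by 1 in magnitude
and is signed: positive chains capture co-increase, negative chains
capture opposed dynamics.  Significance comes from permuting the time
order; q-values are Benjamini-Hochberg across all tested pairs.

Used here to associate sponge-derived with seawater-derived ASVs
(bipartite sponge-seawater networks): replicates are averaged per time
point, each series is rank normal-score transformed, all cross pairs
are scored, and significant pairs are summarized by sign and habitat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .table import AsvTable, to_relative

__all__ = [
    "standardize_series",
    "local_similarity",
    "timepoint_means",
    "replicate_series",
    "lsa_all_pairs",
    "LsaAnalysis",
    "bipartite_summary",
]


def standardize_series(x: np.ndarray) -> np.ndarray:
    """Rank-based normal-score transform followed by z-scaling.

    Ranks (average for ties) are mapped through the standard-normal
    quantile function with the Blom-style offset rank/(n+1), then scaled
    to mean 0 / sd 1.  Constant series carry no temporal signal and are
    rejected.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 time points")
    if np.all(x == x[0]):
        raise ValueError("constant series cannot be standardized")
    ranks = scipy.stats.rankdata(x)
    z = scipy.stats.norm.ppf(ranks / (len(x) + 1))
    z = z - z.mean()
    sd = z.std(ddof=0)
    return z / sd


def _offset_order(D: int) -> list[int]:
    # smaller |delay| preferred on ties; negative before positive
    return sorted(range(-D, D + 1), key=lambda d: (abs(d), d))


def local_similarity(zx: np.ndarray, zy: np.ndarray, D: int = 1) -> tuple[float, int]:
    """Local similarity score and optimal delay of two standardized series.

    For each alignment offset d in [-D, D] the dynamic program tracks
    positive and negative chains of products zx_i * zy_{i+d}:

        P_i = max(0, P_{i-1} + zx_i * zy_{i+d})
        N_i = max(0, N_{i-1} - zx_i * zy_{i+d})

    LS is the largest chain over all i and d, divided by the series
    length, signed by whether a positive or negative chain attained it.
    ``delay`` = d at the optimum; positive d means y trails x.
    """
    zx = np.asarray(zx, dtype=float)
    zy = np.asarray(zy, dtype=float)
    if zx.shape != zy.shape:
        raise ValueError("series length mismatch")
    n = len(zx)
    best, best_abs, best_d = 0.0, -1.0, 0
    for d in _offset_order(D):
        if d >= 0:
            prod = zx[: n - d] * zy[d:]
        else:
            prod = zx[-d:] * zy[: n + d]
        p = nn = max_p = max_n = 0.0
        for v in prod:
            p = max(0.0, p + v)
            nn = max(0.0, nn - v)
            max_p = max(max_p, p)
            max_n = max(max_n, nn)
        score = max_p if max_p >= max_n else -max_n
        if abs(score) > best_abs:
            best, best_abs, best_d = score, abs(score), d
    return best / n, best_d


def _batch_ls(zx: np.ndarray, zy: np.ndarray, D: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized LS over all pairs: zx (na, n) x zy (nb, n).

    Returns (ls, delay) arrays of shape (na, nb); same recurrence and
    tie-breaking as :func:`local_similarity`.
    """
    na, n = zx.shape
    nb = zy.shape[0]
    best = np.zeros((na, nb))
    best_abs = np.full((na, nb), -1.0)
    best_d = np.zeros((na, nb), dtype=int)
    for d in _offset_order(D):
        if d >= 0:
            prod = zx[:, None, : n - d] * zy[None, :, d:]
        else:
            prod = zx[:, None, -d:] * zy[None, :, : n + d]
        p = np.zeros((na, nb))
        nn = np.zeros((na, nb))
        max_p = np.zeros((na, nb))
        max_n = np.zeros((na, nb))
        for t in range(prod.shape[2]):
            v = prod[:, :, t]
            p = np.maximum(0.0, p + v)
            nn = np.maximum(0.0, nn - v)
            np.maximum(max_p, p, out=max_p)
            np.maximum(max_n, nn, out=max_n)
        score = np.where(max_p >= max_n, max_p, -max_n)
        better = np.abs(score) > best_abs
        best = np.where(better, score, best)
        best_d = np.where(better, d, best_d)
        best_abs = np.maximum(best_abs, np.abs(score))
    return best / n, best_d


def timepoint_means(
    t: AsvTable, timepoint_of: Mapping[str, object]
) -> pd.DataFrame:
    """Average replicate relative abundances per time point.

    Returns an ASV x time-point DataFrame with time points in sorted
    order — the series input to LSA.
    """
    missing = set(t.sample_ids) - set(timepoint_of)
    if missing:
        raise ValueError(f"samples without a time point: {sorted(missing)[:5]}")
    rel = to_relative(t).data
    tp = pd.Series({s: timepoint_of[s] for s in t.sample_ids})
    return rel.T.groupby(tp).mean().T.sort_index(axis=1)


def replicate_series(
    t: AsvTable,
    month_of: Mapping[str, object],
    replicate_of: Mapping[str, object],
) -> pd.DataFrame:
    """Relative-abundance series with replicates concatenated in time order.

    Columns are ordered by (month, replicate); with five months of three
    replicates this yields a 15-point series whose permutation space is
    large enough for useful permutation p-values (the five averaged
    time points admit only 120 reorderings).  Replicates of a month are
    adjacent, so local-similarity windows still track month-scale
    dynamics.
    """
    missing = set(t.sample_ids) - set(month_of)
    if missing:
        raise ValueError(f"samples without a time point: {sorted(missing)[:5]}")
    order = sorted(
        t.sample_ids, key=lambda s: (month_of[s], replicate_of.get(s, 0))
    )
    rel = to_relative(t).data[order]
    rel.columns = range(len(order))
    return rel


@dataclass
class LsaAnalysis:
    """All-pairs LSA outcome.

    ``results`` columns: asv_a, asv_b, ls, delay, p, q, significant.
    ``dropped_a`` / ``dropped_b``: constant series excluded per side.
    """

    results: pd.DataFrame
    dropped_a: list[str] = field(default_factory=list)
    dropped_b: list[str] = field(default_factory=list)
    n_permutations: int = 999
    seed: int | None = None

    def significant(self) -> pd.DataFrame:
        return self.results[self.results["significant"]]


def _standardize_rows(series: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    kept, dropped, rows = [], [], []
    for asv, row in series.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.all(vals == vals[0]):
            dropped.append(asv)
            continue
        kept.append(asv)
        rows.append(standardize_series(vals))
    return (np.array(rows) if rows else np.empty((0, series.shape[1]))), kept, dropped


def lsa_all_pairs(
    series_a: pd.DataFrame,
    series_b: pd.DataFrame,
    D: int = 1,
    n_perm: int = 999,
    seed: int | None = 0,
    q_max: float = 0.05,
) -> LsaAnalysis:
    """LSA over every (ASV in a) x (ASV in b) pair with permutation p.

    ``series_a`` / ``series_b``: ASV x time-point matrices on a shared,
    ordered time axis (see :func:`timepoint_means`).  p is the two-sided
    add-one permutation p-value of |LS| under random reordering of the
    time axis of side b; q is Benjamini-Hochberg across all pairs;
    pairs with q <= ``q_max`` are flagged significant.
    """
    if list(series_a.columns) != list(series_b.columns):
        raise ValueError("series must share an identical ordered time axis")
    za, ids_a, dropped_a = _standardize_rows(series_a)
    zb, ids_b, dropped_b = _standardize_rows(series_b)
    if len(ids_a) == 0 or len(ids_b) == 0:
        return LsaAnalysis(
            results=pd.DataFrame(
                columns=["asv_a", "asv_b", "ls", "delay", "p", "q", "significant"]
            ),
            dropped_a=dropped_a,
            dropped_b=dropped_b,
            n_permutations=n_perm,
            seed=seed,
        )
    ls, delay = _batch_ls(za, zb, D)
    rng = np.random.default_rng(seed)
    n = za.shape[1]
    exceed = np.zeros_like(ls)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ls_perm, _ = _batch_ls(za, zb[:, perm], D)
        exceed += np.abs(ls_perm) >= np.abs(ls) - 1e-12
    p = (1.0 + exceed) / (n_perm + 1.0)
    q = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
    ia, ib = np.meshgrid(np.arange(len(ids_a)), np.arange(len(ids_b)), indexing="ij")
    results = pd.DataFrame(
        {
            "asv_a": np.array(ids_a)[ia.ravel()],
            "asv_b": np.array(ids_b)[ib.ravel()],
            "ls": ls.ravel(),
            "delay": delay.ravel(),
            "p": p.ravel(),
            "q": q.ravel(),
        }
    )
    results["significant"] = results["q"] <= q_max
    return LsaAnalysis(
        results=results,
        dropped_a=dropped_a,
        dropped_b=dropped_b,
        n_permutations=n_perm,
        seed=seed,
    )


def bipartite_summary(
    results: pd.DataFrame,
    groups: Mapping[str, str],
    phylum_of: Mapping[str, str] | None = None,
) -> dict:
    """Summarize significant LSA edges by sign and habitat.

    ``groups`` maps every node to a habitat (sponge / seawater).
    Reports edge counts, positive/negative fractions overall and within
    vs between habitats, and per-phylum edge counts when a phylum
    mapping is supplied.
    """
    sig = results[results["significant"]] if "significant" in results else results
    nodes = set(sig["asv_a"]) | set(sig["asv_b"])
    unmapped = nodes - set(groups)
    if unmapped:
        raise ValueError(f"nodes without a habitat: {sorted(unmapped)[:5]}")
    n_edges = len(sig)
    out: dict = {
        "n_edges": int(n_edges),
        "frac_positive": 0.0,
        "frac_negative": 0.0,
        "habitat_breakdown": {},
        "per_phylum_edges": {},
    }
    if n_edges == 0:
        return out
    pos = sig["ls"] > 0
    out["frac_positive"] = float(pos.mean())
    out["frac_negative"] = float((~pos).mean())
    hab_a = sig["asv_a"].map(groups)
    hab_b = sig["asv_b"].map(groups)
    between = hab_a != hab_b
    for label, mask in [("within_habitat", ~between), ("between_habitat", between)]:
        sub = sig[mask]
        out["habitat_breakdown"][label] = {
            "n_edges": int(len(sub)),
            "frac_positive": float((sub["ls"] > 0).mean()) if len(sub) else 0.0,
            "frac_negative": float((sub["ls"] < 0).mean()) if len(sub) else 0.0,
        }
    if phylum_of is not None:
        counts: dict[str, int] = {}
        for col in ("asv_a", "asv_b"):
            for asv in sig[col]:
                ph = phylum_of.get(asv, "unassigned")
                counts[ph] = counts.get(ph, 0) + 1
        out["per_phylum_edges"] = dict(sorted(counts.items()))
    return out
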