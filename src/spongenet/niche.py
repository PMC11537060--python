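"""Levins niche breadth.

For ASV i with distribution P_ij over r resource states
(sum_j P_ij = 1), Levins' measure is

    B_i = 1 / sum_j P_ij^2

so B = 1 for a full specialist (all mass in one state) and B = r for a
uniform generalist.  The community-level niche width is the arithmetic
mean of B over the included ASVs.  By default every sample of the
analysis group is one resource state and P_ij is the ASV's relative
abundance in state j, renormalized across states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .table import AsvTable, to_relative

__all__ = ["NicheWidthResult", "levins_width", "community_niche_width"]


@dataclass
class NicheWidthResult:
    per_asv: pd.DataFrame  # columns: B, n_states_occupied
    community_mean_B: float
    community_se_B: float
    n_states: int


def levins_width(p: np.ndarray) -> float:
    """Levins B of one ASV from its (unnormalized) profile over states."""
    p = np.asarray(p, dtype=float)
    if p.size == 0 or np.all(p == 0):
        raise ValueError("all-zero profile; niche width undefined")
    if np.any(p < 0):
        raise ValueError("negative abundances")
    p = p / p.sum()
    return float(1.0 / (p**2).sum())


def community_niche_width(
    t: AsvTable,
    states: Mapping[str, str] | None = None,
    min_occupancy: int = 1,
) -> NicheWidthResult:
    """Per-ASV Levins B and the community mean over detected ASVs.

    Parameters
    ----------
    t : AsvTable
    states : mapping sample_id -> state label, optional
        Samples sharing a state are aggregated by their mean relative
        abundance.  Default: every sample is its own state.
    min_occupancy : int
        Include only ASVs present in at least this many states.
    """
    rel = to_relative(t).data
    if states is None:
        states = {s: s for s in t.sample_ids}
    unmapped = set(t.sample_ids) - set(states)
    if unmapped:
        raise ValueError(f"samples without a state mapping: {sorted(unmapped)[:5]}")
    state_of = pd.Series({s: states[s] for s in t.sample_ids})
    # mean relative abundance of each ASV within each state
    profile = rel.T.groupby(state_of).mean().T  # ASVs x states
    r = profile.shape[1]

    occupied = (profile > 0).sum(axis=1)
    keep = occupied >= min_occupancy
    prof = profile.loc[keep]
    occ = occupied[keep]
    if prof.empty:
        raise ValueError("no ASV satisfies the occupancy requirement")
    p = prof.to_numpy(dtype=float)
    p = p / p.sum(axis=1, keepdims=True)
    b = 1.0 / (p**2).sum(axis=1)
    per_asv = pd.DataFrame({"B": b, "n_states_occupied": occ}, index=prof.index)
    se = float(b.std(ddof=1) / np.sqrt(len(b))) if len(b) > 1 else 0.0
    return NicheWidthResult(
        per_asv=per_asv,
        community_mean_B=float(b.mean()),
        community_se_B=se,
        n_states=r,
    )
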