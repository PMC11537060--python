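"""Abundant / dominant / rare taxon classification.

ASVs are partitioned by their minimum (m) and maximum (M) per-sample
relative abundance against two thresholds: an upper threshold u = 1%
and a lower threshold l = 0.01%.

* AT (abundant): never drops below l and reaches u somewhere
  (includes ASVs above u in every sample).
* DT (dominant, i.e. conditionally abundant): below l in some samples
  but at or above u in others.
* RT (rare): below l somewhere and never reaching u (includes ASVs
  below l everywhere).
* MT (moderate): never below l and never reaching u — a cell of the
  (m, M) plane the three-way scheme leaves unnamed; reported
  explicitly rather than forced into a class.

Thresholds are inclusive at l and u ("at least"), strict below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table import RelAbundanceTable

__all__ = [
    "UPPER_THRESHOLD",
    "LOWER_THRESHOLD",
    "AbundanceClassMap",
    "classify_asv",
    "classify_table",
]

UPPER_THRESHOLD = 0.01  # 1%
LOWER_THRESHOLD = 0.0001  # 0.01%

LABELS = ("AT", "DT", "RT", "MT")


def classify_asv(
    p: np.ndarray,
    u: float = UPPER_THRESHOLD,
    l: float = LOWER_THRESHOLD,
) -> str:
    """Classify one ASV from its vector of per-sample relative abundances."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty relative-abundance vector")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("relative abundances must lie in [0, 1]")
    m, M = p.min(), p.max()
    if m >= l:
        return "AT" if M >= u else "MT"
    return "DT" if M >= u else "RT"


@dataclass
class AbundanceClassMap:
    """Per-ASV label plus per-class summary statistics.

    ``labels``: Series asv_id -> label; ``summary``: DataFrame indexed by
    label with columns n_asvs, frac_asvs, frac_reads.
    """

    labels: pd.Series
    summary: pd.DataFrame
    upper: float = UPPER_THRESHOLD
    lower: float = LOWER_THRESHOLD

    def to_frame(self, r: RelAbundanceTable | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"label": self.labels})
        if r is not None:
            df.insert(0, "min_relabund", r.data.min(axis=1))
            df.insert(1, "max_relabund", r.data.max(axis=1))
        return df


def classify_table(
    r: RelAbundanceTable,
    u: float = UPPER_THRESHOLD,
    l: float = LOWER_THRESHOLD,
) -> AbundanceClassMap:
    """Classify every ASV of a relative-abundance table.

    The summary reports, per class, the number of ASVs, their fraction of
    all ASVs, and their fraction of total reads (mean relative abundance
    mass); each fraction column sums to 1.
    """
    vals = r.values
    m = vals.min(axis=1)
    M = vals.max(axis=1)
    labels = np.where(
        m >= l,
        np.where(M >= u, "AT", "MT"),
        np.where(M >= u, "DT", "RT"),
    )
    labels = pd.Series(labels, index=r.data.index, name="label")
    mass = vals.mean(axis=1)  # per-ASV share of reads, averaged over samples
    rows = []
    for lab in LABELS:
        sel = labels == lab
        rows.append(
            {
                "label": lab,
                "n_asvs": int(sel.sum()),
                "frac_asvs": float(sel.mean()),
                "frac_reads": float(mass[sel.to_numpy()].sum() / mass.sum()),
            }
        )
    summary = pd.DataFrame(rows).set_index("label")
    return AbundanceClassMap(labels=labels, summary=summary, upper=u, lower=l)
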