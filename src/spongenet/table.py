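"""Core data model for ASV count tables and sample metadata.

The universal input of the package is an :class:`AsvTable` — a dense
non-negative integer matrix of amplicon sequence variant (ASV) counts,
rows = ASVs, columns = samples — together with per-sample metadata
(host, HMA/LMA phenotype, habitat, month, replicate, environmental
variables).  Tables are read from tab-separated text or BIOM-JSON v1.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AsvTable",
    "RelAbundanceTable",
    "SampleMetadata",
    "AsvTableFormatError",
    "read_asv_table",
    "write_asv_table",
    "read_sample_metadata",
    "read_taxonomy",
    "to_relative",
    "rarefy",
    "filter_prevalence",
    "shared_asv_summary",
]

#: Environmental variables carried in sample metadata (units: temperature
#: in deg C, DO in mg/L, nutrients in umol/L, salinity and pH unitless).
ENV_VARIABLES = (
    "temperature",
    "salinity",
    "DO",
    "pH",
    "NO3",
    "NO2",
    "NH4",
    "DIP",
    "DOP",
    "TDP",
    "TP",
    "SiO3",
)


class AsvTableFormatError(ValueError):
    """Raised for malformed input tables (duplicate ids, negative counts...)."""


def _check_ids(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AsvTableFormatError(f"duplicate {what} ids: {dupes[:5]}")
    return ids


@dataclass
class AsvTable:
    """ASV x sample matrix of non-negative integer counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by ASV id, columns by sample id, integer counts.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = pd.Index(_check_ids(self.data.index, "ASV"), name="asv_id")
        self.data.columns = pd.Index(_check_ids(self.data.columns, "sample"))
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise AsvTableFormatError("counts must be numeric")
        if np.any(~np.isfinite(values.astype(float))):
            raise AsvTableFormatError("counts must be finite")
        if np.any(values < 0):
            raise AsvTableFormatError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise AsvTableFormatError("counts must be integers")
        self.data = self.data.astype(np.int64)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_asvs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_samples(self, sample_ids: Iterable[str]) -> "AsvTable":
        return AsvTable(self.data.loc[:, list(sample_ids)])

    def select_asvs(self, asv_ids: Iterable[str]) -> "AsvTable":
        return AsvTable(self.data.loc[list(asv_ids)])

    def detected_asvs(self) -> list[str]:
        """ASVs with nonzero total count."""
        tot = self.data.sum(axis=1)
        return list(tot.index[tot > 0])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AsvTable) and self.data.equals(other.data)


@dataclass
class RelAbundanceTable:
    """Per-sample relative abundances; each sample column sums to 1."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
            raise AsvTableFormatError("relative abundances must lie in [0, 1]")
        sums = values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise AsvTableFormatError("each sample column must sum to 1")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class SampleMetadata:
    """Per-sample factors (host, phenotype, habitat, month, replicate) + env.

    ``table`` is indexed by sample id with columns ``host``, ``phenotype``
    (HMA / LMA / NA), ``habitat`` (sponge / seawater), ``month``,
    ``replicate`` and any of the environmental variables in
    :data:`ENV_VARIABLES`.
    """

    table: pd.DataFrame

    REQUIRED = ("host", "phenotype", "habitat", "month", "replicate")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise AsvTableFormatError(f"metadata missing column {col!r}")
        self.table.index = pd.Index(
            _check_ids(self.table.index, "sample"), name="sample_id"
        )

    def validate_against(self, t: AsvTable) -> None:
        missing = set(t.sample_ids) - set(self.table.index)
        if missing:
            raise AsvTableFormatError(
                f"samples without metadata: {sorted(missing)[:5]}"
            )
        env = self.env_table()
        if not env.empty:
            vals = env.to_numpy(dtype=float)
            if np.any(np.isinf(vals)):
                raise AsvTableFormatError("environmental values must be finite")

    def env_table(self) -> pd.DataFrame:
        cols = [c for c in ENV_VARIABLES if c in self.table.columns]
        return self.table[cols].astype(float)

    def group(self, by: str) -> Mapping[str, list[str]]:
        """Sample ids grouped by a metadata column."""
        return {
            str(k): list(v) for k, v in self.table.groupby(by, sort=True).groups.items()
        }


# ---------------------------------------------------------------------------
# Readers / writers


def read_asv_table(path: str | Path, format: str = "tsv") -> AsvTable:
    """Read an ASV count table from ``tsv`` or ``biom-json``.

    TSV layout: header row of sample ids, first column ``asv_id``.
    BIOM-JSON v1.0: dense or sparse ``matrix_type`` accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        try:
            df = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise AsvTableFormatError(f"non-numeric counts in {path}: {exc}") from exc
        return AsvTable(df)
    if format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        return _asv_table_from_biom(doc)
    raise ValueError(f"unknown format {format!r}")


def _asv_table_from_biom(doc: dict) -> AsvTable:
    rows = [r["id"] for r in doc["rows"]]
    cols = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(rows), len(cols)))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    else:  # sparse: [row, col, value] triples
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    return AsvTable(pd.DataFrame(mat, index=rows, columns=cols))


def write_asv_table(t: AsvTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        t.data.to_csv(path, sep="\t", index_label="asv_id")
    elif format == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "spongenet",
            "date": "",
            "rows": [{"id": i, "metadata": None} for i in t.asv_ids],
            "columns": [{"id": s, "metadata": None} for s in t.sample_ids],
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [t.n_asvs, t.n_samples],
            "data": t.counts.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata (TSV keyed by ``sample_id``)."""
    return SampleMetadata(pd.read_csv(path, sep="\t", index_col="sample_id"))


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy table (TSV: asv_id then rank columns domain..genus)."""
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


# ---------------------------------------------------------------------------
# Transformations


def to_relative(t: AsvTable) -> RelAbundanceTable:
    """Convert counts to per-sample relative abundances (column sums = 1)."""
    totals = t.sample_totals()
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {list(zero)}")
    return RelAbundanceTable(t.data / totals)


def rarefy(t: AsvTable, depth: int, seed: int | np.random.Generator = 0) -> AsvTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Equivalent to drawing a multivariate-hypergeometric sample per column;
    reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    totals = t.sample_totals()
    too_small = totals.index[totals < depth]
    if len(too_small):
        raise ValueError(
            f"rarefaction depth {depth} exceeds total of sample(s) {list(too_small)}"
        )
    out = np.empty_like(t.counts)
    for j, col in enumerate(t.counts.T):
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return AsvTable(pd.DataFrame(out, index=t.asv_ids, columns=t.sample_ids))


def filter_prevalence(t: AsvTable, min_sample_frac: float = 0.5) -> AsvTable:
    """Keep ASVs detected in strictly more than ``min_sample_frac`` of samples."""
    prevalence = (t.counts > 0).mean(axis=1)
    keep = prevalence > min_sample_frac
    return AsvTable(t.data.loc[keep])


def shared_asv_summary(a: AsvTable, b: AsvTable) -> dict:
    """Unique / shared ASV counts between two tables (Venn-style summary).

    Only ASVs with nonzero total in a table count as detected there.
    """
    set_a, set_b = set(a.detected_asvs()), set(b.detected_asvs())
    shared = set_a & set_b
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_shared": len(shared),
        "frac_of_a": len(shared) / len(set_a) if set_a else 0.0,
        "frac_of_b": len(shared) / len(set_b) if set_b else 0.0,
    }
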