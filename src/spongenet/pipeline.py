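"""End-to-end analysis workflow.

Sequences the full study on real or synthetic inputs: data model ->
abundance classes -> diversity & permutation statistics -> niche
breadth -> per-group co-occurrence networks (RMT threshold, topology,
Maslov-Sneppen nulls, keystones) -> sponge-seawater LSA bipartite
networks — and emits a structured, reproducible report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from . import __version__
from .abundance import classify_table
from .diversity import (
    alpha_diversity,
    anosim,
    bray_curtis,
    choose_correlation_method,
    mantel,
    mrpp,
    neff,
    permanova,
    upgma,
    vif_screen,
)
from .lsa import bipartite_summary, lsa_all_pairs, replicate_series, timepoint_means
from .network import (
    RmtThresholdError,
    build_network,
    keystone_species,
    null_ensemble,
    rmt_threshold,
    spearman_matrix,
    topology,
)
from .niche import community_niche_width
from .synth import generate_experiment
from .table import (
    AsvTable,
    SampleMetadata,
    filter_prevalence,
    read_asv_table,
    read_sample_metadata,
    shared_asv_summary,
    to_relative,
)

logger = logging.getLogger("spongenet")

__all__ = ["PipelineError", "AnalysisReport", "default_config", "run_full_analysis"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def default_config() -> dict:
    """Template configuration (flat, YAML-serializable)."""
    return {
        "preset": "coastal",  # or asv_table/metadata paths instead
        "asv_table": None,
        "metadata": None,
        "seed": 0,
        "depth": None,  # override synthetic sequencing depth
        "prevalence_min_frac": 0.5,
        "network": {
            "max_nodes": 300,  # most-abundant ASVs entering each network
            "n_null": 100,
            "scan": [0.30, 0.99],
            "step": 0.01,
            "alpha": 0.05,
            "keystone_k": 10,
        },
        "lsa": {
            "D": 1,
            "n_perm": 1999,
            "q_max": 0.05,
            "max_per_side": 40,  # most-abundant ASVs per habitat side
            # 'concatenate' keeps replicates as adjacent series points
            # (15-point series); 'average' collapses them to 5 points,
            # whose 120 possible reorderings make permutation p-values
            # too coarse to survive FDR control
            "replicates": "concatenate",
        },
        "out_dir": None,
    }


@dataclass
class AnalysisReport:
    """Structured result of :func:`run_full_analysis`."""

    alpha: dict = field(default_factory=dict)
    abundance_classes: dict = field(default_factory=dict)
    permutation_tests: list = field(default_factory=list)
    shared_asvs: dict = field(default_factory=dict)
    niche_width: dict = field(default_factory=dict)
    networks: dict = field(default_factory=dict)
    lsa_bipartite: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "alpha_diversity": self.alpha,
            "abundance_classes": self.abundance_classes,
            "permutation_tests": self.permutation_tests,
            "shared_asvs": self.shared_asvs,
            "niche_width": self.niche_width,
            "networks": self.networks,
            "lsa_bipartite": self.lsa_bipartite,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=_jsonable, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return decorator


def _merge_config(config: dict | None) -> dict:
    merged = default_config()
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


@_stage("load")
def _load(config: dict) -> tuple[dict[str, AsvTable], SampleMetadata, int]:
    seed = int(config.get("seed", 0))
    if config.get("asv_table"):
        if not config.get("metadata"):
            raise ValueError("config missing field 'metadata'")
        table = read_asv_table(config["asv_table"])
        meta = read_sample_metadata(config["metadata"])
        meta.validate_against(table)
        tables = {
            host: table.select_samples(samples)
            for host, samples in meta.group("host").items()
        }
        return tables, meta, seed
    exp = generate_experiment(
        preset=config.get("preset", "coastal"), seed=seed, depth=config.get("depth")
    )
    return exp.tables, exp.metadata, seed


def _top_abundant(t: AsvTable, k: int) -> AsvTable:
    mass = to_relative(t).data.mean(axis=1).sort_values(ascending=False)
    return t.select_asvs(list(mass.index[: min(k, len(mass))]))


def _phenotype_of(meta: SampleMetadata, host: str) -> str:
    rows = meta.table[meta.table["host"] == host]
    hab = rows["habitat"].iloc[0]
    return "seawater" if hab == "seawater" else str(rows["phenotype"].iloc[0])


@_stage("network")
def _network_stage(
    tables: dict[str, AsvTable],
    config: dict,
    seed: int,
    meta: SampleMetadata | None = None,
) -> tuple[dict, dict[str, nx.Graph]]:
    cfg = config["network"]
    out: dict = {}
    graphs: dict[str, nx.Graph] = {}
    corrs: dict[str, pd.DataFrame] = {}
    for host, table in tables.items():
        filtered = filter_prevalence(table, config["prevalence_min_frac"])
        filtered = _top_abundant(filtered, cfg["max_nodes"])
        if filtered.n_asvs < 10:
            out[host] = {"skipped": f"only {filtered.n_asvs} prevalent ASVs"}
            continue
        corr, dropped = spearman_matrix(filtered)
        try:
            s_t, diag = rmt_threshold(
                corr,
                scan=tuple(cfg["scan"]),
                step=cfg["step"],
                alpha=cfg["alpha"],
            )
            threshold_rule = "rmt"
        except RmtThresholdError as exc:
            # fall back to the scanned cutoff with the best Poisson fit
            diag = exc.diagnostics
            best = diag["poisson_gof_p"].idxmax()
            if np.isnan(diag.loc[best, "poisson_gof_p"]):
                out[host] = {"skipped": "degenerate correlation spectrum"}
                continue
            s_t = float(diag.loc[best, "threshold"])
            threshold_rule = "best-poisson-fit-fallback"
        net = build_network(corr, s_t)
        if net.n_edges == 0:
            out[host] = {"skipped": "no edges at the selected threshold",
                         "threshold": s_t}
            continue
        topo = topology(net)
        nulls = null_ensemble(net, n=cfg["n_null"], seed=seed)
        keystones = keystone_species(topo, k=cfg["keystone_k"])
        edge_signs = [d["sign"] for _, _, d in net.graph.edges(data=True)]
        out[host] = {
            "threshold": s_t,
            "threshold_rule": threshold_rule,
            "n_zero_variance_dropped": len(dropped),
            "n_isolated": net.n_isolated,
            "topology": topo.to_dict(),
            "frac_positive_edges": float(np.mean([s > 0 for s in edge_signs])),
            "null_ensemble": {
                "n_random": nulls.n_random,
                "metrics": nulls.table.reset_index().to_dict(orient="records"),
                "degenerate": nulls.degenerate,
            },
            "keystones": list(keystones.index),
        }
        graphs[host] = net.graph
        corrs[host] = corr
    # cross-group topology comparison at a harmonized cutoff: RMT picks
    # each group its own threshold, and densities at different cutoffs
    # are not comparable, so group contrasts (e.g. avgK) are reported at
    # the strictest per-group threshold.  The contrast of interest is
    # between sponge hosts, so seawater groups do not set the cutoff.
    if len(corrs) >= 2:
        anchor_hosts = list(corrs)
        if meta is not None:
            sponge = [h for h in corrs if _phenotype_of(meta, h) != "seawater"]
            if len(sponge) >= 2:
                anchor_hosts = sponge
        s_common = max(out[h]["threshold"] for h in anchor_hosts)
        comparison = {"common_threshold": s_common, "avgK": {}, "topology": {}}
        for host, corr in corrs.items():
            net = build_network(corr, s_common)
            if net.n_edges == 0:
                comparison["avgK"][host] = 0.0
                comparison["topology"][host] = {"N": 0, "L": 0}
                continue
            topo = topology(net)
            comparison["avgK"][host] = topo.avg_connectivity
            comparison["topology"][host] = topo.to_dict()
        out["_comparison"] = comparison
    return out, graphs


@_stage("lsa")
def _lsa_stage(
    tables: dict[str, AsvTable], meta: SampleMetadata, config: dict, seed: int
) -> dict:
    cfg = config["lsa"]
    seawater_hosts = [
        h for h in tables if _phenotype_of(meta, h) == "seawater"
    ]
    sponge_hosts = [h for h in tables if h not in seawater_hosts]
    if not seawater_hosts or not sponge_hosts:
        return {"skipped": "need both sponge and seawater groups"}
    sw_host = seawater_hosts[0]
    month_of = meta.table["month"].to_dict()
    replicate_of = meta.table["replicate"].to_dict()

    def series_of(table: AsvTable) -> pd.DataFrame:
        if cfg.get("replicates", "concatenate") == "average":
            return timepoint_means(table, month_of)
        return replicate_series(table, month_of, replicate_of)

    out: dict = {}
    sw_table = _top_abundant(
        filter_prevalence(tables[sw_host], config["prevalence_min_frac"]),
        cfg["max_per_side"],
    )
    sw_series = series_of(sw_table)
    # method-selection heuristic reported alongside the analysis
    merged_counts = np.concatenate(
        [tables[h].counts.sum(axis=1) for h in (sponge_hosts[0], sw_host)]
    )
    sparsity = float(np.mean(tables[sw_host].counts == 0))
    out["method_choice"] = choose_correlation_method(
        neff(merged_counts), sparsity, is_time_series=True
    )
    for host in sponge_hosts:
        sp_table = _top_abundant(
            filter_prevalence(tables[host], config["prevalence_min_frac"]),
            cfg["max_per_side"],
        )
        sp_series = series_of(sp_table)
        # a shared ASV id may occur on both sides; disambiguate by side
        a = sp_series.rename(index=lambda i: f"{host}:{i}")
        b = sw_series.rename(index=lambda i: f"{sw_host}:{i}")
        analysis = lsa_all_pairs(
            a, b, D=cfg["D"], n_perm=cfg["n_perm"], seed=seed, q_max=cfg["q_max"]
        )
        habitats = {i: "sponge" for i in a.index}
        habitats.update({i: "seawater" for i in b.index})
        summary = bipartite_summary(analysis.significant(), habitats)
        summary["n_pairs_tested"] = int(len(analysis.results))
        out[host] = summary
    return out


def run_full_analysis(config: dict | None = None) -> AnalysisReport:
    """Run the whole workflow from a configuration mapping.

    The config either names input tables (``asv_table`` + ``metadata``
    TSVs) or a synthetic ``preset`` ('coastal' or 'smp').  All
    randomness derives from ``seed``; rerunning with the same config is
    reproducible.  When ``out_dir`` is set, per-stage TSV/JSON/GraphML/
    newick artifacts are written there.
    """
    config = _merge_config(config)
    tables, meta, seed = _load(config)
    report = AnalysisReport()
    report.provenance = {"config": {k: v for k, v in config.items()},
                         "seed": seed, "version": __version__}

    @_stage("alpha-diversity")
    def alpha_stage() -> dict:
        out = {}
        for host, t in tables.items():
            shannon = [alpha_diversity(c, "shannon") for c in t.counts.T]
            rich = [alpha_diversity(c, "richness") for c in t.counts.T]
            inv = [alpha_diversity(c, "invsimpson") for c in t.counts.T]
            out[host] = {
                "phenotype": _phenotype_of(meta, host),
                "mean_shannon": float(np.mean(shannon)),
                "mean_richness": float(np.mean(rich)),
                "mean_invsimpson": float(np.mean(inv)),
                "n_samples": t.n_samples,
            }
        return out

    @_stage("abundance-classes")
    def classes_stage() -> dict:
        out = {}
        for host, t in tables.items():
            cmap = classify_table(to_relative(t))
            out[host] = cmap.summary.to_dict(orient="index")
        return out

    @_stage("community-stats")
    def stats_stage() -> tuple[list, DistanceMatrix]:
        merged = pd.concat([t.data for t in tables.values()], axis=1)
        merged = merged.fillna(0).astype(np.int64).groupby(level=0).sum()
        merged_t = AsvTable(merged)
        dm = bray_curtis(merged_t)
        hosts = [
            str(meta.table.loc[s, "host"]) for s in dm.ids
        ]
        tests = [
            anosim(dm, hosts, seed=seed).to_record(),
            permanova(dm, hosts, seed=seed).to_record(),
            mrpp(dm, hosts, seed=seed).to_record(),
        ]
        env = meta.env_table().loc[list(dm.ids)]
        if env.shape[1] >= 2 and env.notna().all().all():
            retained, vifs = vif_screen(env)
            envz = (env[retained] - env[retained].mean()) / env[retained].std(ddof=0)
            env_dm = DistanceMatrix(
                squareform(pdist(envz.to_numpy(), metric="euclidean")), ids=dm.ids
            )
            rec = mantel(dm, env_dm, seed=seed).to_record()
            rec["env_variables_retained"] = retained
            tests.append(rec)
        return tests, dm

    @_stage("shared-asvs")
    def shared_stage() -> dict:
        seawater = [h for h in tables if _phenotype_of(meta, h) == "seawater"]
        if not seawater:
            return {}
        sw = tables[seawater[0]]
        return {
            host: shared_asv_summary(tables[host], sw)
            for host in tables
            if host not in seawater
        }

    @_stage("niche-width")
    def niche_stage() -> dict:
        out = {}
        for host, t in tables.items():
            res = community_niche_width(t)
            out[host] = {
                "community_mean_B": res.community_mean_B,
                "community_se_B": res.community_se_B,
                "n_states": res.n_states,
                "n_asvs": int(len(res.per_asv)),
            }
        return out

    report.alpha = alpha_stage()
    report.abundance_classes = classes_stage()
    report.permutation_tests, dm = stats_stage()
    report.shared_asvs = shared_stage()
    report.niche_width = niche_stage()
    report.networks, graphs = _network_stage(tables, config, seed, meta)
    report.lsa_bipartite = _lsa_stage(tables, meta, config, seed)

    out_dir = config.get("out_dir")
    if out_dir:
        _write_artifacts(Path(out_dir), report, tables, meta, dm, graphs)
    return report


@_stage("write-artifacts")
def _write_artifacts(
    out_dir: Path,
    report: AnalysisReport,
    tables: dict[str, AsvTable],
    meta: SampleMetadata,
    dm: DistanceMatrix,
    graphs: dict[str, nx.Graph],
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.to_json(out_dir / "report.json")
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        out_dir / "bray_curtis.tsv", sep="\t"
    )
    (out_dir / "dendrogram.nwk").write_text(upgma(dm) + "\n")
    for host, t in tables.items():
        cmap = classify_table(to_relative(t))
        cmap.to_frame(to_relative(t)).to_csv(
            out_dir / f"classes_{host}.tsv", sep="\t", index_label="asv_id"
        )
    for host, g in graphs.items():
        nx.write_graphml(g, out_dir / f"network_{host}.graphml")
        rows = [
            {"source": u, "target": v, "r": d["r"], "sign": d["sign"]}
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(
            out_dir / f"network_{host}_edges.tsv", sep="\t", index=False
        )
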