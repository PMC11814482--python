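"""End-to-end orchestration: diversity -> assembly -> niche -> networks -> indicators.

One master seed spawns a named substream per stage, so adding a stage never
perturbs earlier stages' draws. Every run writes TSV/JSON artifacts plus a
machine-readable ``report.json`` that validates against the schema shipped at
``assemblyscope/report_schema.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import compute_avd, fit_ncm, partition_processes, turnover_pairs
from .core_io import (read_counts, read_env, read_metadata, read_tree,
                      to_relative_abundance)
from .diversity import (alpha_diversity, bray_curtis_matrix, faith_pd, nmds,
                        permanova, shared_unique_otus, unifrac_matrix)
from .indicators import indval_test
from .networks import build_network, spearman_edges, taxa_env_network
from .niche import classify_habitat_niche

__all__ = ["RunConfig", "run_pipeline", "validate_report", "load_report_schema"]

log = logging.getLogger("assemblyscope")

_STAGES = ("diversity", "assembly", "niche", "networks", "indicators")


@dataclass
class RunConfig:
    """Paths, sizes and thresholds for a full pipeline run."""

    counts: str
    tree: str
    metadata: str
    env: str | None = None
    out_dir: str = "assemblyscope_out"
    n_null: int = 999
    n_perm: int = 999
    seed: int = 42
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    r_min: float = 0.8
    q_max: float = 0.001
    min_prevalence: float = 0.2
    n_env_taxa: int = 20
    rarefy_depth: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_null", "n_perm", "bnti_threshold", "rc_threshold",
                     "r_min", "q_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _stage_seeds(master: int) -> dict:
    children = np.random.SeedSequence(master).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % (2**31 - 1))
            for name, c in zip(_STAGES, children)}


def load_report_schema() -> dict:
    with resources.files("assemblyscope").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict, schema: dict | None = None, path: str = "$") -> None:
    """Validate a report against the (small) JSON-schema subset the schema uses:
    ``type``, ``properties``, ``required``, ``items``."""
    if schema is None:
        schema = load_report_schema()
    expected = schema.get("type")
    type_map = {"object": dict, "array": list, "string": str, "boolean": bool,
                "number": (int, float), "integer": (int, np.integer)}
    if expected is not None and not isinstance(report, type_map[expected]):
        raise ValueError(f"{path}: expected {expected}, got {type(report).__name__}")
    if expected == "object":
        for key in schema.get("required", []):
            if key not in report:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{path}.{key}")
    elif expected == "array":
        items = schema.get("items")
        if items:
            for i, item in enumerate(report):
                validate_report(item, items, f"{path}[{i}]")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig,
                 data: tuple | None = None) -> dict:
    """Execute all stages and write the artifact bundle under ``config.out_dir``.

    ``data`` may supply in-memory ``(counts, tree, groups, env)`` to bypass the
    file readers (the CLI always goes through files). Returns the report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if data is not None:
        counts, tree, groups, env = data
    else:
        counts = read_counts(config.counts)
        tree = read_tree(config.tree)
        groups = read_metadata(config.metadata)
        env = read_env(config.env) if config.env else None
    groups.validate_against(counts)
    tree.check_covers(counts.otu_ids)
    if config.rarefy_depth:
        from .core_io import rarefy

        counts = rarefy(counts, config.rarefy_depth, seed=config.seed)
    counts = counts.drop_empty_otus()
    rel = to_relative_abundance(counts)
    seeds = _stage_seeds(config.seed)
    cfg_dict = _jsonable(asdict(config))
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()[:16]
    report = {
        "provenance": {
            "package": "assemblyscope",
            "version": __version__,
            "master_seed": config.seed,
            "stage_seeds": seeds,
            "config": cfg_dict,
            "config_hash": cfg_hash,
        },
        "stages": {},
    }

    def _log_stage(name, t0, **info):
        log.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0,
                 " ".join(f"{k}={v}" for k, v in info.items()))

    # ---- diversity ----
    t0 = time.time()
    alpha = pd.DataFrame({m: alpha_diversity(counts, m)
                          for m in ("sobs", "chao1", "ace")})
    alpha["faith_pd"] = faith_pd(counts, tree)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
    bc = bray_curtis_matrix(rel)
    dists = {"bray_curtis": bc,
             "unweighted_unifrac": unifrac_matrix(counts, tree, weighted=False),
             "weighted_unifrac": unifrac_matrix(counts, tree, weighted=True)}
    perm_results = {}
    for name, dm in dists.items():
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            out / f"distance_{name}.tsv", sep="\t", index_label="sample_id")
        perm_results[name] = permanova(dm, groups, n_perm=config.n_perm,
                                       seed=seeds["diversity"]).as_dict()
    coords, stress = nmds(bc, k=2, seed=seeds["diversity"])
    coords.to_csv(out / "nmds.tsv", sep="\t", index_label="sample_id")
    venn = shared_unique_otus(counts, groups)
    venn.to_csv(out / "otu_overlap.tsv", sep="\t")
    report["stages"]["diversity"] = {
        "n_otus": len(counts.otu_ids), "n_samples": len(counts.sample_ids),
        "alpha_means": _jsonable(alpha.mean().to_dict()),
        "permanova": _jsonable(perm_results),
        "nmds_stress": float(stress),
        "otu_overlap": _jsonable(venn["n_otus"].to_dict()),
    }
    _log_stage("diversity", t0, n_otus=len(counts.otu_ids))

    # ---- assembly ----
    t0 = time.time()
    ncm = fit_ncm(counts)
    ncm.table.to_csv(out / "ncm_table.tsv", sep="\t")
    (out / "ncm_fit.json").write_text(json.dumps(_jsonable(ncm.summary()), indent=2))
    avd = compute_avd(rel, groups)
    avd.per_sample.to_frame().to_csv(out / "avd.tsv", sep="\t",
                                     index_label="sample_id")
    pairs = turnover_pairs(counts, tree, n_null=config.n_null,
                           seed=seeds["assembly"])
    pairs.to_csv(out / "turnover_pairs.tsv", sep="\t", index=False)
    label = dict(groups.mapping)
    partitions = {"pooled": partition_processes(
        pairs, config.bnti_threshold, config.rc_threshold).as_dict()}
    for g in groups.groups():
        sub = pairs[(pairs["sample_a"].map(label) == g)
                    & (pairs["sample_b"].map(label) == g)]
        if len(sub):
            partitions[g] = partition_processes(
                sub, config.bnti_threshold, config.rc_threshold).as_dict()
    (out / "process_partition.json").write_text(
        json.dumps(_jsonable(partitions), indent=2))
    report["stages"]["assembly"] = {
        "ncm": _jsonable(ncm.summary()),
        "avd_per_group": _jsonable(avd.per_group.to_dict()),
        "process_partition": _jsonable(partitions),
    }
    _log_stage("assembly", t0, n_pairs=len(pairs))

    # ---- niche ----
    t0 = time.time()
    niche = classify_habitat_niche(counts, n_perm=max(config.n_perm, 100),
                                   seed=seeds["niche"], groups=groups)
    niche.table.to_csv(out / "niche_classes.tsv", sep="\t")
    niche.class_abundance_by_group.to_csv(out / "class_abundance_by_group.tsv",
                                          sep="\t")
    report["stages"]["niche"] = {
        "class_counts": _jsonable(niche.class_counts().to_dict()),
        "class_abundance_by_group": _jsonable(
            niche.class_abundance_by_group.to_dict(orient="index")),
    }
    _log_stage("niche", t0, n_classified=len(niche.table))

    # ---- networks ----
    t0 = time.time()
    edges = spearman_edges(rel, min_prevalence=config.min_prevalence)
    graph, stats = build_network(edges, r_min=config.r_min, p_max=config.q_max)
    edges.to_csv(out / "network_edges_all.tsv", sep="\t", index=False)
    import networkx as nx

    nx.write_graphml(graph, out / "network.graphml")
    net_block = {"otu_network": stats.as_dict()}
    if env is not None:
        top = rel.df.mean(axis=1).nlargest(config.n_env_taxa).index
        te = taxa_env_network(rel.df.loc[top], env)
        te.to_csv(out / "taxa_env_edges.tsv", sep="\t", index=False)
        net_block["taxa_env_edges"] = int(len(te))
    report["stages"]["networks"] = _jsonable(net_block)
    _log_stage("networks", t0, n_edges=stats.n_edges)

    # ---- indicators ----
    t0 = time.time()
    iv = indval_test(rel, groups, n_perm=config.n_perm, seed=seeds["indicators"])
    iv.table().to_csv(out / "indval.tsv", sep="\t")
    sig = iv.table().query("p_value < 0.05")
    report["stages"]["indicators"] = {
        "n_otus_tested": int(len(iv.indval)),
        "n_significant": int(len(sig)),
        "top_indicators": _jsonable(
            iv.table().nlargest(5, "max_indval")[["best_group", "max_indval"]]
            .reset_index().to_dict(orient="records")),
    }
    _log_stage("indicators", t0, n_significant=len(sig))

    validate_report(report)
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report
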