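"""End-to-end orchestration: filter -> overlap -> networks -> topology ->
selection -> enrichment -> C-T-P, from one configuration mapping.

The configuration (usually loaded from YAML) names the input files and the
thresholds; every default mirrors the conventional printed values (OB 30,
DL 0.18, PPI confidence 0.7, alpha 0.05, hub multiplier 2, top 20
pathways), so a "standard" run needs only the input paths.  Stages execute
in a fixed order; a failure aborts with the stage name and cause.  The
result is a :class:`RunReport` that serializes losslessly to JSON, plus
one file per artifact in the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import yaml

from . import __version__
from .adme import AdmeCriteria, filter_compounds
from .enrichment import enrich, screen_top, write_enrichment_table
from .errors import ConfigError, HerbnetError, PipelineError
from .io import (read_compound_table, read_compound_target_map, read_gene_list,
                 read_gmt, read_scored_edges, write_compound_table,
                 write_gene_list, write_network)
from .networks import build_ct_network, build_ctp_network, build_ppi
from .targets import CompoundTargetMap, TargetSet, intersect_targets, \
    merge_disease_sources, union_targets
from .topology import (SelectionRule, annotate_centrality, centrality_table,
                       class_summary, select_nodes, write_centrality_table)

logger = logging.getLogger("herbnet")

__all__ = ["RunReport", "run_pipeline", "load_config", "validate_config", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS: dict[str, float | int] = {
    "ob_min": 30.0,
    "dl_min": 0.18,
    "ppi_min_score": 0.7,
    "alpha": 0.05,
    "hub_multiplier": 2.0,
    "top_n": 20,
}

DEFAULT_OPTIONS: dict[str, Any] = {
    "score_scale": "unit",
    "keep_isolates": False,
    "use_adjusted": False,
    "universe": "collection",   # or "drug" / "query"
    "blocklist": [],
    "hub_combine": "AND",
    "ctp_target_combine": "DC_ONLY",
}


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    version: str = __version__
    config: dict = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    class_stats: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    selections: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))

    def check_consistency(self) -> None:
        """Raise if cross-count identities are violated."""
        c = self.counts
        for net in ("cot", "ctp"):
            if f"{net}_edges" in c and f"{net}_sum_target_dc" in c:
                if c[f"{net}_edges"] != c[f"{net}_sum_target_dc"]:
                    raise HerbnetError(
                        f"{net}: edge count {c[f'{net}_edges']} != "
                        f"sum of target degrees {c[f'{net}_sum_target_dc']}")
        for key, sel in self.selections.items():
            nk = f"n_{key}"
            if nk in c and c[nk] != len(sel):
                raise HerbnetError(f"selection count {nk} inconsistent with list length")


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a YAML mapping")
    return cfg


def validate_config(cfg: dict) -> dict:
    """Fill defaults and check consistency; returns the effective config."""
    inputs = cfg.get("inputs") or {}
    for key in ("compounds", "compound_targets", "disease_targets", "ppi_edges", "gene_sets"):
        if key not in inputs:
            raise ConfigError(f"inputs.{key} is required")
    disease = inputs["disease_targets"]
    if isinstance(disease, str):
        disease = [disease]
    if not disease:
        raise ConfigError("inputs.disease_targets must name at least one file")
    paths = [inputs["compounds"], inputs["compound_targets"],
             *disease, inputs["ppi_edges"], inputs["gene_sets"]]
    missing = [p for p in paths if not os.path.exists(p)]
    if missing:
        raise ConfigError(f"input file(s) not found: {missing}")

    thresholds = {**DEFAULT_THRESHOLDS, **(cfg.get("thresholds") or {})}
    unknown = set(thresholds) - set(DEFAULT_THRESHOLDS)
    if unknown:
        raise ConfigError(f"unknown threshold(s): {sorted(unknown)}")
    if not (0 < thresholds["alpha"] <= 1):
        raise ConfigError(f"alpha must be in (0, 1], got {thresholds['alpha']}")
    if not (0 <= thresholds["ppi_min_score"] <= 1):
        raise ConfigError("ppi_min_score must be in [0, 1]")
    if thresholds["hub_multiplier"] <= 0:
        raise ConfigError("hub_multiplier must be positive")
    if thresholds["top_n"] < 0:
        raise ConfigError("top_n must be >= 0")

    options = {**DEFAULT_OPTIONS, **(cfg.get("options") or {})}
    unknown = set(options) - set(DEFAULT_OPTIONS)
    if unknown:
        raise ConfigError(f"unknown option(s): {sorted(unknown)}")
    if options["universe"] not in ("collection", "drug", "query"):
        raise ConfigError("options.universe must be 'collection', 'drug' or 'query'")

    return {"inputs": {**inputs, "disease_targets": disease},
            "thresholds": thresholds, "options": options}


def run_pipeline(config: dict, out_dir) -> RunReport:
    """Execute the full chain and write every artifact under ``out_dir``."""
    cfg = validate_config(config)
    inputs, thr, opt = cfg["inputs"], cfg["thresholds"], cfg["options"]
    os.makedirs(out_dir, exist_ok=True)
    report = RunReport(config=cfg)
    out = lambda name: os.path.join(out_dir, name)

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return _StageGuard(name)

    with stage("adme_filter"):
        compounds = read_compound_table(inputs["compounds"])
        active, rejected = filter_compounds(
            compounds, AdmeCriteria(thr["ob_min"], thr["dl_min"]))
        report.counts["compounds_retrieved"] = len(compounds)
        report.counts["compounds_active"] = len(active)
        write_compound_table(active, out("active_compounds.tsv"))

    with stage("target_sets"):
        active_ids = {r.compound_id for r in active}
        raw_pairs = read_compound_target_map(inputs["compound_targets"])
        pairs = {(c, t) for c, t in raw_pairs if c in active_ids}
        ctmap = CompoundTargetMap(pairs)
        drug = union_targets(ctmap)
        report.counts["target_rows_raw"] = len(raw_pairs)
        report.counts["drug_targets"] = len(drug)
        sources = [TargetSet(os.path.basename(p), read_gene_list(p))
                   for p in inputs["disease_targets"]]
        disease = merge_disease_sources(sources)
        report.counts["disease_targets"] = len(disease)
        overlap = intersect_targets(drug, disease)
        report.counts["overlap_targets"] = len(overlap)
        write_gene_list(drug.symbols, out("drug_targets.txt"))
        write_gene_list(disease.symbols, out("disease_targets.txt"))
        write_gene_list(overlap.symbols, out("overlap_targets.txt"))

    with stage("networks"):
        ct = build_ct_network(ctmap)
        cot = build_ct_network(ctmap, restrict_targets=overlap)
        edges = read_scored_edges(inputs["ppi_edges"], score_scale=opt["score_scale"])
        ppi = build_ppi(edges, overlap, min_score=thr["ppi_min_score"],
                        keep_isolates=opt["keep_isolates"])
        for name, net in (("ct", ct), ("cot", cot), ("ppi", ppi)):
            report.counts[f"{name}_nodes"] = net.n_nodes
            report.counts[f"{name}_edges"] = net.n_edges
        write_network(ct, out("ct_network.graphml"))

    with stage("topology"):
        cot_table = centrality_table(cot)
        report.counts["cot_sum_target_dc"] = int(
            cot_table.loc[cot_table["kind"] == "target", "dc"].sum())
        annotate_centrality(cot, cot_table)
        write_network(cot, out("cot_network.graphml"))
        write_centrality_table(cot_table, out("cot_centrality.tsv"))

        if ppi.n_nodes:
            ppi_table = centrality_table(ppi)
            med = ppi_table[["dc", "bc"]].median()
            report.class_stats["ppi"] = {"median": [float(med["dc"]), float(med["bc"])]}
            rule = SelectionRule("median", thr["hub_multiplier"],
                                 opt["hub_combine"], strict=True)
            hubs = select_nodes(ppi_table, rule)
            if opt["hub_combine"] == "AND":
                dc_only = select_nodes(ppi_table, dataclasses.replace(rule, combine="DC_ONLY"))
                excluded = sorted(set(dc_only) - set(hubs))
                if excluded:
                    report.warnings.append(
                        "hub rule inconsistency: node(s) pass 2x-median DC but fail "
                        f"2x-median BC and are excluded by the AND rule: {excluded}")
            report.selections["hub_targets"] = hubs
            report.counts["n_hub_targets"] = len(hubs)
            annotate_centrality(ppi, ppi_table)
            write_network(ppi, out("ppi_network.graphml"))
            write_centrality_table(ppi_table, out("ppi_centrality.tsv"))
        else:
            report.selections["hub_targets"] = []
            report.counts["n_hub_targets"] = 0
            report.warnings.append("PPI network is empty; no hub targets")

    with stage("enrichment"):
        collection = read_gmt(inputs["gene_sets"])
        if opt["universe"] == "collection":
            universe = TargetSet("universe", collection.all_genes())
        elif opt["universe"] == "drug":
            universe = drug
        else:
            universe = overlap
        rows = enrich(overlap, collection, universe,
                      alpha=thr["alpha"], use_adjusted=opt["use_adjusted"])
        report.counts["enriched_terms"] = len(rows)
        kept = screen_top(rows, thr["top_n"], opt["blocklist"])
        report.counts["screened_terms"] = len(kept)
        report.selections["pathways_screened"] = [r.term_id for r in kept]
        write_enrichment_table(rows, out("enrichment.tsv"))

    if thr["top_n"] == 0 or not kept:
        report.warnings.append("C-T-P stage skipped: no screened pathways (top_n=0 "
                               "or empty enrichment)")
    else:
        with stage("ctp"):
            ctp = build_ctp_network(cot, collection, [r.term_id for r in kept])
            report.counts["ctp_nodes"] = ctp.n_nodes
            report.counts["ctp_edges"] = ctp.n_edges
            ctp_table = centrality_table(ctp)
            report.counts["ctp_sum_target_dc"] = int(
                ctp_table.loc[ctp_table["kind"] == "target", "dc"].sum())
            if not ctp_table.empty:
                stats = class_summary(ctp_table, "mean")
                report.class_stats["ctp"] = {f"mean_{k}": list(v) for k, v in stats.items()}
                for kind, combine in (("compound", "AND"),
                                      ("target", opt["ctp_target_combine"]),
                                      ("pathway", "AND")):
                    sub = ctp_table[ctp_table["kind"] == kind]
                    rule = SelectionRule("mean", 1.0, combine, strict=True)
                    sel = select_nodes(sub, rule)
                    report.selections[f"ctp_{kind}s"] = sel
                    report.counts[f"n_ctp_{kind}s"] = len(sel)
            annotate_centrality(ctp, ctp_table)
            write_network(ctp, out("ctp_network.graphml"))
            write_centrality_table(ctp_table, out("ctp_centrality.tsv"))

    report.check_consistency()
    with open(out("report.json"), "w", encoding="utf-8") as fh:
        fh.write(report.to_json() + "\n")
    return report


class _StageGuard:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, (ConfigError, PipelineError)):
            raise PipelineError(self.name, exc) from exc
        return False
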