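"""Bundled reference tables from a published network-pharmacology case study
of *Prunella vulgaris* against subacute thyroiditis.

The study screened 60 herbal compounds down to 11 actives (OB >= 30%,
DL >= 0.18), collected 126 drug targets and 2207 disease targets with an
overlap of 83 therapeutic targets, built a high-confidence PPI network
(77 nodes, 383 edges) and a tripartite compound-target-pathway network
over its screened top-20 pathways, and selected nodes with the 2x-median
hub rule and the above-class-average rule.  The printed per-node tables
are shipped here as plain TSV so the package's topology and selection
operations can be exercised against published values without any database
access.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_active_compounds", "load_hub_table", "load_ctp_table", "STUDY_COUNTS"]

#: Study-level input sizes, used as inputs when reproducing derived
#: quantities (e.g. the hub percentage is #hubs / n_overlap).
STUDY_COUNTS = {
    "n_compounds_retrieved": 60,
    "n_active_compounds": 11,
    "n_drug_targets": 126,
    "n_disease_targets": 2207,
    "n_overlap": 83,
    "ppi_nodes": 77,
    "ppi_edges": 383,
    "ppi_median_dc": 7.0,
    "ppi_median_bc": 0.00287026,
}


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("herbnet").joinpath(f"data/reference/{name}")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_active_compounds() -> pd.DataFrame:
    """The 11 active compounds: compound_id, name, ob, dl, cot_degree."""
    return _load("pv_sat_active_compounds.tsv")


def load_hub_table() -> pd.DataFrame:
    """The 18 PPI hub targets with their dc and bc."""
    return _load("pv_sat_ppi_hubs.tsv")


def load_ctp_table() -> pd.DataFrame:
    """The 65-row C-T-P centrality table: node, kind, dc, bc.

    Column layout matches :func:`herbnet.topology.centrality_table`, so
    :func:`~herbnet.topology.class_summary` and
    :func:`~herbnet.topology.select_nodes` apply directly.
    """
    return _load("pv_sat_ctp_centrality.tsv")
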