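"""Node centralities and threshold-based node selection.

Two centralities drive the whole analysis:

* DC (degree centrality): the number of edges incident to a node, reported
  as a plain integer count, not the degree/(n-1) fraction.
* BC (betweenness centrality): the fraction of all-pairs shortest paths
  passing through a node (endpoints excluded), computed by Brandes'
  algorithm on unweighted, undirected graphs.  Normalized by
  (n-1)(n-2)/2 by default — the convention of Cytoscape's NetworkAnalyzer,
  under which published BC tables with values << 1 were produced.  On
  disconnected graphs pair dependencies accumulate within components while
  the normalization still uses the full n, which shrinks BC on fragmented
  networks; this matches NetworkAnalyzer and is deliberate.

Selection statistics, applied to a centrality table:

* hub rule — nodes whose DC and BC strictly exceed 2x the network-wide
  median (the classic hub-target screen on a PPI network);
* above-average rule — nodes exceeding 1x the per-class mean, used on
  tripartite compound-target-pathway tables.

Both are instances of one parametrized :class:`SelectionRule`.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .networks import TypedNetwork

__all__ = ["centrality_table", "class_summary", "SelectionRule", "select_nodes",
           "annotate_centrality"]


def centrality_table(net: TypedNetwork, normalized: bool = True) -> pd.DataFrame:
    """Per-node DC and BC as a DataFrame with columns node, kind, dc, bc.

    Rows are ordered by DC descending, BC descending, then node id, the
    order in which topology tables are conventionally printed.
    """
    g = net.graph
    bc = nx.betweenness_centrality(g, normalized=normalized)
    rows = [(n, g.nodes[n]["kind"], g.degree[n], bc[n]) for n in g.nodes]
    df = pd.DataFrame(rows, columns=["node", "kind", "dc", "bc"])
    return (df.sort_values(["dc", "bc", "node"], ascending=[False, False, True])
              .reset_index(drop=True))


def class_summary(table: pd.DataFrame, statistic: str = "mean"
                  ) -> dict[str, tuple[float, float]]:
    """Per-class (dc, bc) mean or median.

    The median of an even-count class is the midpoint of the two central
    order statistics.  Raises on an empty table.
    """
    if statistic not in ("mean", "median"):
        raise ValidationError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    if table.empty:
        raise ValidationError("cannot summarize an empty centrality table")
    agg = table.groupby("kind")[["dc", "bc"]].agg(statistic)
    return {kind: (float(row["dc"]), float(row["bc"])) for kind, row in agg.iterrows()}


def _overall_summary(table: pd.DataFrame, statistic: str) -> tuple[float, float]:
    if table.empty:
        raise ValidationError("cannot summarize an empty centrality table")
    agg = table[["dc", "bc"]].agg(statistic)
    return float(agg["dc"]), float(agg["bc"])


@dataclass(frozen=True)
class SelectionRule:
    """Thresholding rule over a centrality table.

    ``statistic`` ('median' or 'mean') and ``multiplier`` define the
    thresholds multiplier x statistic(dc) and multiplier x statistic(bc);
    ``combine`` says whether a node must exceed both ('AND'), either
    ('OR'), or only the degree threshold ('DC_ONLY'); ``strict`` chooses >
    versus >=; ``per_class`` computes the statistics within each node
    class instead of over the whole table.

    The hub screen is ``SelectionRule('median', 2, 'AND', strict=True)``;
    the above-class-average screen is
    ``SelectionRule('mean', 1, 'AND', strict=True, per_class=True)``.
    """

    statistic: str = "median"
    multiplier: float = 2.0
    combine: str = "AND"
    strict: bool = True
    per_class: bool = False

    def __post_init__(self):
        if self.statistic not in ("median", "mean"):
            raise ValidationError(f"statistic must be 'median' or 'mean', got {self.statistic!r}")
        if self.combine not in ("AND", "OR", "DC_ONLY"):
            raise ValidationError(f"combine must be AND, OR or DC_ONLY, got {self.combine!r}")
        if not self.multiplier > 0:
            raise ValidationError(f"multiplier must be positive, got {self.multiplier}")


def select_nodes(table: pd.DataFrame, rule: SelectionRule) -> list[str]:
    """Nodes passing ``rule``, sorted by dc desc, bc desc, then node id.

    Thresholds are computed from the same table at full floating-point
    precision; any rounding belongs to reporting, never to selection.
    """
    if table.empty:
        return []
    if rule.per_class:
        stats = class_summary(table, rule.statistic)
    else:
        stats = None
        dc_stat, bc_stat = _overall_summary(table, rule.statistic)

    selected = []
    for row in table.itertuples(index=False):
        if stats is not None:
            dc_stat, bc_stat = stats[row.kind]
        thr_dc = rule.multiplier * dc_stat
        thr_bc = rule.multiplier * bc_stat
        dc_ok = row.dc > thr_dc if rule.strict else row.dc >= thr_dc
        bc_ok = row.bc > thr_bc if rule.strict else row.bc >= thr_bc
        if rule.combine == "AND":
            ok = dc_ok and bc_ok
        elif rule.combine == "OR":
            ok = dc_ok or bc_ok
        else:  # DC_ONLY
            ok = dc_ok
        if ok:
            selected.append((row.dc, row.bc, row.node))
    selected.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return [node for _, _, node in selected]


def annotate_centrality(net: TypedNetwork, table: pd.DataFrame) -> None:
    """Attach dc/bc from ``table`` as node attributes (e.g. before export)."""
    for row in table.itertuples(index=False):
        net.graph.nodes[row.node]["dc"] = int(row.dc)
        net.graph.nodes[row.node]["bc"] = float(row.bc)


def write_centrality_table(table: pd.DataFrame, path) -> None:
    """Write node, kind, dc, bc as TSV; BC printed with 8 decimals."""
    out = table.copy()
    out["bc"] = out["bc"].map(lambda v: f"{v:.8f}")
    out.to_csv(path, sep="\t", index=False)
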