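"""Typed undirected networks and the three construction rules.

Nodes carry a class label (compound, target, pathway, protein).  All
graphs are simple and undirected: repeated evidence for a compound-target
pair collapses to one edge, so node degrees count distinct partners.

* C-T: bipartite compound–target graph over all targets of the active
  compounds.
* C-OT: the same restricted to "overlapping" (therapeutic) targets.
* PPI: confidence-filtered protein–protein interactions among the
  therapeutic targets.
* C-T-P: tripartite compound–target–pathway graph over a selected pathway
  list; every edge has exactly one target endpoint.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx

from .errors import ValidationError
from .io import GeneSetCollection, ScoredEdge
from .targets import CompoundTargetMap, TargetSet

logger = logging.getLogger("herbnet")

__all__ = ["TypedNetwork", "build_ct_network", "build_ppi", "build_ctp_network"]

NODE_KINDS = ("compound", "target", "pathway", "protein")


class TypedNetwork:
    """A simple undirected graph whose nodes carry a class label.

    Thin wrapper over :class:`networkx.Graph`; the underlying graph is
    exposed as :attr:`graph` for analysis, but mutation should go through
    :meth:`add_node` / :meth:`add_edge`, which enforce the invariants
    (known class, no self-loops, edges only between existing nodes).
    """

    def __init__(self):
        self.graph = nx.Graph()

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: str, kind: str) -> None:
        if kind not in NODE_KINDS:
            raise ValidationError(f"unknown node class {kind!r}; expected one of {NODE_KINDS}")
        existing = self.graph.nodes.get(node_id)
        if existing is not None and existing.get("kind") != kind:
            raise ValidationError(
                f"node {node_id!r} already present with class {existing.get('kind')!r}")
        self.graph.add_node(node_id, kind=kind)

    def add_edge(self, a: str, b: str, **attrs) -> None:
        if a == b:
            raise ValidationError(f"self-loop on {a!r} not allowed")
        for n in (a, b):
            if n not in self.graph:
                raise ValidationError(f"edge endpoint {n!r} is not a declared node")
        self.graph.add_edge(a, b, **attrs)

    # -- queries ----------------------------------------------------------
    def kind(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["kind"]

    def nodes(self, kind: str | None = None) -> set[str]:
        if kind is None:
            return set(self.graph.nodes)
        return {n for n, d in self.graph.nodes(data="kind") if d == kind}

    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node_id: str) -> int:
        return self.graph.degree[node_id]

    def drop_isolates(self) -> int:
        """Remove degree-0 nodes in place; returns how many were removed."""
        isolates = list(nx.isolates(self.graph))
        self.graph.remove_nodes_from(isolates)
        return len(isolates)

    def is_isomorphic_to(self, other: "TypedNetwork") -> bool:
        return nx.is_isomorphic(self.graph, other.graph,
                                node_match=lambda a, b: a.get("kind") == b.get("kind"))


def build_ct_network(ctmap: CompoundTargetMap,
                     restrict_targets: TargetSet | None = None) -> TypedNetwork:
    """Bipartite compound-target network.

    With ``restrict_targets=None`` this is the full C-T network; passing
    the therapeutic-target set gives the C-OT network.  Compounds whose
    targets are all filtered out are dropped (with a logged warning) so
    the node count is #compounds kept + #targets kept.
    """
    net = TypedNetwork()
    kept: dict[str, set[str]] = {}
    for cid, sym in ctmap.pairs:
        if restrict_targets is not None and sym not in restrict_targets:
            continue
        kept.setdefault(cid, set()).add(sym)
    dropped = ctmap.compounds - set(kept)
    if dropped:
        logger.warning("build_ct_network: dropped %d isolated compound(s): %s",
                       len(dropped), ", ".join(sorted(dropped)[:5]))
    for cid, targets in kept.items():
        net.add_node(cid, "compound")
        for sym in targets:
            net.add_node(sym, "target")
            net.add_edge(cid, sym)
    return net


def build_ppi(edges: Iterable[ScoredEdge], members: TargetSet,
              min_score: float = 0.7, keep_isolates: bool = False) -> TypedNetwork:
    """Protein-protein interaction network among ``members``.

    Keeps edges whose endpoints are both members and whose confidence is at
    least ``min_score`` (the conventional "high confidence" cutoff is 0.7).
    Members left without any surviving edge are excluded unless
    ``keep_isolates`` is set, mirroring how interaction databases report
    only connected query proteins.
    """
    if not (0.0 <= min_score <= 1.0):
        raise ValidationError(f"min_score must be in [0, 1], got {min_score}")
    net = TypedNetwork()
    if keep_isolates:
        for sym in members:
            net.add_node(sym, "protein")
    for e in edges:
        if e.score < min_score:
            continue
        if e.node_a not in members or e.node_b not in members:
            continue
        net.add_node(e.node_a, "protein")
        net.add_node(e.node_b, "protein")
        net.add_edge(e.node_a, e.node_b, score=e.score)
    return net


def build_ctp_network(cot: TypedNetwork, pathway_membership: GeneSetCollection,
                      selected_pathways: Sequence[str]) -> TypedNetwork:
    """Tripartite compound-target-pathway network.

    Starts from a C-OT network and a list of selected pathway term ids
    (typically the screened top-N enrichment results).  Targets are kept
    only if they belong to at least one selected pathway; compounds only if
    they still connect to a kept target.  Edges are the surviving
    compound-target pairs plus target-pathway memberships — never
    compound-pathway — so every edge has exactly one target endpoint.
    """
    unknown = [t for t in selected_pathways if t not in pathway_membership]
    if unknown:
        raise ValidationError(f"unknown pathway term id(s): {unknown}")

    cot_targets = cot.nodes("target")
    memberships: list[tuple[str, str]] = []   # (target, term)
    kept_targets: set[str] = set()
    for term in selected_pathways:
        for sym in pathway_membership[term].members & cot_targets:
            memberships.append((sym, term))
            kept_targets.add(sym)

    net = TypedNetwork()
    for sym in kept_targets:
        net.add_node(sym, "target")
    for term in selected_pathways:
        net.add_node(term, "pathway")
    for sym, term in memberships:
        net.add_edge(sym, term)
    for cid in cot.nodes("compound"):
        hit = {t for t in cot.graph.neighbors(cid)} & kept_targets
        if not hit:
            logger.info("build_ctp_network: compound %s has no target in the "
                        "selected pathways; dropped", cid)
            continue
        net.add_node(cid, "compound")
        for sym in hit:
            net.add_edge(cid, sym)
    # pathways with no member among the C-OT targets stay as isolated nodes
    # only if explicitly selected; drop them to keep the graph tidy
    empty = [t for t in selected_pathways if net.degree(t) == 0]
    if empty:
        logger.info("build_ctp_network: %d selected pathway(s) had no member "
                    "among the targets; dropped", len(empty))
        net.graph.remove_nodes_from(empty)
    return net
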