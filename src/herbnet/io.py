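"""Readers and writers for the tabular and graph formats the pipeline touches.

All tabular inputs are UTF-8 TSV with a header row; lines starting with
``#`` are treated as comments everywhere.  Gene symbols are normalized on
the way in (see :mod:`herbnet.symbols`), never on the way out.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import FormatError, ValidationError
from .symbols import normalize_symbol

logger = logging.getLogger("herbnet")

__all__ = [
    "CompoundRecord", "ScoredEdge", "GeneSet", "GeneSetCollection",
    "read_compound_table", "write_compound_table",
    "read_gene_list", "write_gene_list",
    "read_scored_edges", "write_scored_edges",
    "read_gmt", "write_gmt",
    "read_compound_target_map", "write_compound_target_map",
    "write_network", "read_network",
]


# ---------------------------------------------------------------------------
# domain records

@dataclass(frozen=True)
class CompoundRecord:
    """One candidate herbal ingredient with its pharmacokinetic screen scores.

    ``ob`` is oral bioavailability in percent (0–100): the fraction of an
    orally administered dose reaching systemic circulation.  ``dl`` is
    drug-likeness (0–1): similarity of the structure to known drugs.  Both
    are database-precomputed inputs, never derived here.
    """

    compound_id: str
    name: str
    ob: float | None
    dl: float | None

    def __post_init__(self):
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if self.ob is not None and not (0.0 <= self.ob <= 100.0):
            raise ValidationError(f"OB must be in [0, 100], got {self.ob} for {self.compound_id}")
        if self.dl is not None and not (0.0 <= self.dl <= 1.0):
            raise ValidationError(f"DL must be in [0, 1], got {self.dl} for {self.compound_id}")


@dataclass(frozen=True)
class ScoredEdge:
    """An undirected protein-protein interaction with a confidence in [0, 1]."""

    node_a: str
    node_b: str
    score: float

    def __post_init__(self):
        if self.node_a == self.node_b:
            raise ValidationError(f"self-interaction {self.node_a!r} is not a valid edge")
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score must be in [0, 1], got {self.score}")

    @property
    def key(self) -> tuple[str, str]:
        """Order-free identity of the pair."""
        return (self.node_a, self.node_b) if self.node_a <= self.node_b else (self.node_b, self.node_a)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    members: frozenset[str]


class GeneSetCollection:
    """A keyed collection of annotated gene sets (e.g. pathways)."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            self.add(gs)

    def add(self, gs: GeneSet) -> None:
        if gs.term_id in self._sets:
            raise ValidationError(f"duplicate term id {gs.term_id!r}")
        if not gs.members:
            raise ValidationError(f"gene set {gs.term_id!r} has no members")
        self._sets[gs.term_id] = gs

    def __len__(self):
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, term_id):
        return term_id in self._sets

    def __getitem__(self, term_id: str) -> GeneSet:
        return self._sets[term_id]

    @property
    def term_ids(self) -> list[str]:
        return list(self._sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self:
            out |= gs.members
        return out


# ---------------------------------------------------------------------------
# TSV helpers

def _tsv_rows(path):
    """Yield (line_number, fields) skipping blank and comment lines."""
    with open(path, encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or not any(f.strip() for f in row):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            yield i, row


def _find_column(header: Sequence[str], candidates: Sequence[str], logical: str, path) -> int:
    lowered = [h.strip().lower() for h in header]
    for cand in candidates:
        if cand in lowered:
            return lowered.index(cand)
    raise FormatError(
        f"missing required column for {logical!r} (accepted headers: {', '.join(candidates)})",
        path=path,
    )


def _parse_float(text: str, what: str, path, line: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"non-numeric {what}: {text!r}", path=path, line=line) from None


# ---------------------------------------------------------------------------
# compound tables

_COMPOUND_DIALECT = {
    "id": ("compound_id", "id", "number", "mol_id", "molecule id"),
    "name": ("name", "compound name", "compound", "molecule name"),
    "ob": ("ob", "ob (%)", "ob%", "ob_percent"),
    "dl": ("dl", "drug-likeness", "drug likeness"),
}


def read_compound_table(path, dialect: Mapping[str, str] | None = None) -> list[CompoundRecord]:
    """Read a compound table (TSV with id, name, OB %, DL columns).

    ``dialect`` optionally maps the logical names ``id``/``name``/``ob``/``dl``
    to the actual column headers; otherwise common headers are recognized
    case-insensitively.  Duplicate compound ids and out-of-range or
    non-numeric scores are rejected with the offending line number.
    """
    rows = _tsv_rows(path)
    try:
        header_line, header = next(rows)
    except StopIteration:
        raise FormatError("empty compound table (no header)", path=path) from None

    idx: dict[str, int] = {}
    for logical, candidates in _COMPOUND_DIALECT.items():
        cands = (dialect[logical].strip().lower(),) if dialect and logical in dialect else candidates
        idx[logical] = _find_column(header, cands, logical, path)

    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for line, row in rows:
        if len(row) <= max(idx.values()):
            raise FormatError(f"row has {len(row)} fields, expected at least {max(idx.values()) + 1}",
                              path=path, line=line)
        cid = row[idx["id"]].strip()
        if cid in seen:
            raise FormatError(f"duplicate compound id {cid!r}", path=path, line=line)
        seen.add(cid)
        ob_text, dl_text = row[idx["ob"]].strip(), row[idx["dl"]].strip()
        ob = None if ob_text in ("", "NA") else _parse_float(ob_text, "OB", path, line)
        dl = None if dl_text in ("", "NA") else _parse_float(dl_text, "DL", path, line)
        try:
            records.append(CompoundRecord(cid, row[idx["name"]].strip(), ob, dl))
        except ValidationError as exc:
            raise FormatError(str(exc), path=path, line=line) from None
    return records


def write_compound_table(records: Iterable[CompoundRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["compound_id", "name", "ob", "dl"])
        for r in records:
            w.writerow([r.compound_id, r.name,
                        "" if r.ob is None else repr(r.ob),
                        "" if r.dl is None else repr(r.dl)])


# ---------------------------------------------------------------------------
# gene lists

def read_gene_list(path, column: str | None = None, aliases=None) -> set[str]:
    """Read gene symbols, one per line, or from a named TSV column.

    Symbols are normalized; blanks and comments are ignored; duplicates
    (after normalization) collapse silently.
    """
    symbols: set[str] = set()
    if column is None:
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                text = raw.strip()
                if not text or text.startswith("#"):
                    continue
                symbols.add(normalize_symbol(text.split("\t")[0], aliases))
    else:
        rows = _tsv_rows(path)
        try:
            _, header = next(rows)
        except StopIteration:
            return symbols
        col = _find_column(header, (column.strip().lower(),), column, path)
        for line, row in rows:
            if col < len(row) and row[col].strip():
                symbols.add(normalize_symbol(row[col], aliases))
    symbols.discard("")
    return symbols


def write_gene_list(symbols: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sorted(symbols):
            fh.write(s + "\n")


# ---------------------------------------------------------------------------
# scored edges (STRING-style)

_EDGE_NODE_A = ("node_a", "protein1", "node1", "source", "#node1")
_EDGE_NODE_B = ("node_b", "protein2", "node2", "target")
_EDGE_SCORE = ("score", "combined_score", "confidence")


def read_scored_edges(path, score_scale: str = "unit", aliases=None) -> list[ScoredEdge]:
    """Read a confidence-scored edge list.

    ``score_scale`` must be declared: ``"unit"`` for scores already in
    [0, 1], ``"thousand"`` for integer 0–1000 exports (divided by 1000).
    The scale is never guessed from magnitude — silent misscaling would
    corrupt any downstream confidence cutoff.  Self-loops are dropped (with
    a logged count); duplicate unordered pairs collapse to the maximum score.
    """
    if score_scale not in ("unit", "thousand"):
        raise ValidationError(f"score_scale must be 'unit' or 'thousand', got {score_scale!r}")
    rows = _tsv_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        return []
    ia = _find_column(header, _EDGE_NODE_A, "node_a", path)
    ib = _find_column(header, _EDGE_NODE_B, "node_b", path)
    isc = _find_column(header, _EDGE_SCORE, "score", path)

    best: dict[tuple[str, str], float] = {}
    self_loops = 0
    for line, row in rows:
        a = normalize_symbol(row[ia], aliases)
        b = normalize_symbol(row[ib], aliases)
        raw = _parse_float(row[isc], "score", path, line)
        if score_scale == "thousand":
            if not (0 <= raw <= 1000):
                raise FormatError(f"score {raw} outside declared thousand scale [0, 1000]",
                                  path=path, line=line)
            score = raw / 1000.0
        else:
            if not (0.0 <= raw <= 1.0):
                raise FormatError(f"score {raw} outside declared unit scale [0, 1]",
                                  path=path, line=line)
            score = raw
        if a == b:
            self_loops += 1
            continue
        key = (a, b) if a <= b else (b, a)
        if key not in best or score > best[key]:
            best[key] = score
    if self_loops:
        logger.info("read_scored_edges: dropped %d self-loop(s) from %s", self_loops, path)
    return [ScoredEdge(a, b, s) for (a, b), s in sorted(best.items())]


def write_scored_edges(edges: Iterable[ScoredEdge], path, score_scale: str = "unit") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["node_a", "node_b", "score"])
        for e in edges:
            a, b = e.key
            if score_scale == "thousand":
                w.writerow([a, b, int(round(e.score * 1000))])
            else:
                w.writerow([a, b, repr(e.score)])


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path, aliases=None) -> GeneSetCollection:
    """Read a GMT file: ``term<TAB>description<TAB>member...`` per line."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8", newline="") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError("GMT lines need >= 3 tab-separated fields "
                                  "(term, description, members...)", path=path, line=i)
            term, desc = fields[0].strip(), fields[1].strip()
            members = frozenset(normalize_symbol(f, aliases) for f in fields[2:] if f.strip())
            try:
                coll.add(GeneSet(term, desc, members))
            except ValidationError as exc:
                raise FormatError(str(exc), path=path, line=i) from None
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.term_id, gs.name, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# compound -> target mapping

def read_compound_target_map(path, aliases=None) -> set[tuple[str, str]]:
    """Read deduplicated (compound_id, gene symbol) pairs from a 2-column TSV."""
    rows = _tsv_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        return set()
    ic = _find_column(header, ("compound_id", "compound", "id", "mol_id"), "compound_id", path)
    it = _find_column(header, ("target", "gene", "symbol", "gene_symbol"), "target", path)
    pairs: set[tuple[str, str]] = set()
    for line, row in rows:
        cid = row[ic].strip()
        sym = normalize_symbol(row[it], aliases)
        if not cid or not sym:
            raise FormatError("empty compound id or target symbol", path=path, line=line)
        pairs.add((cid, sym))
    return pairs


def write_compound_target_map(pairs: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["compound_id", "target"])
        for cid, sym in sorted(pairs):
            w.writerow([cid, sym])


# ---------------------------------------------------------------------------
# typed network export / import

NETWORK_FORMATS = ("sif", "graphml", "edge-tsv")

#: every edge is untyped in this pipeline; SIF requires an interaction string
SIF_INTERACTION = "interacts"


def _node_sidecar(path) -> str:
    return str(path) + ".nodes.tsv"


def _write_node_table(net, path) -> None:
    attrs = sorted({k for _, d in net.graph.nodes(data=True) for k in d if k != "kind"})
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["node_id", "kind", *attrs])
        for node in sorted(net.graph.nodes):
            data = net.graph.nodes[node]
            w.writerow([node, data["kind"], *[repr(data[a]) if a in data else "" for a in attrs]])


def write_network(net, path, format: str = "graphml") -> None:
    """Serialize a :class:`~herbnet.networks.TypedNetwork`.

    ``graphml`` carries node classes and numeric attributes natively.  For
    ``sif`` and ``edge-tsv`` a sidecar ``<path>.nodes.tsv`` holds the node
    class table (SIF itself has no attribute syntax), so a round trip
    reconstructs an isomorphic network with identical classes for every
    supported format.
    """
    if format not in NETWORK_FORMATS:
        raise ValidationError(f"unknown network format {format!r}; "
                              f"supported: {', '.join(NETWORK_FORMATS)}")
    g = net.graph
    if format == "graphml":
        nx.write_graphml(g, path)
        return
    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            isolated = set(nx.isolates(g))
            for a, b in sorted(tuple(sorted(e)) for e in g.edges):
                fh.write(f"{a}\t{SIF_INTERACTION}\t{b}\n")
            for node in sorted(isolated):
                fh.write(f"{node}\n")
    else:  # edge-tsv
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["node_a", "node_b", "score"])
            for a, b in sorted(tuple(sorted(e)) for e in g.edges):
                score = g.edges[a, b].get("score", "")
                w.writerow([a, b, "" if score == "" else repr(score)])
    _write_node_table(net, _node_sidecar(path))


def read_network(path, format: str = "graphml"):
    """Inverse of :func:`write_network`."""
    from .networks import TypedNetwork  # deferred: networks imports io types

    if format not in NETWORK_FORMATS:
        raise ValidationError(f"unknown network format {format!r}; "
                              f"supported: {', '.join(NETWORK_FORMATS)}")
    net = TypedNetwork()
    if format == "graphml":
        g = nx.read_graphml(path)
        for node, data in g.nodes(data=True):
            net.add_node(node, data["kind"])
            for k, v in data.items():
                if k != "kind":
                    net.graph.nodes[node][k] = v
        for a, b, data in g.edges(data=True):
            net.add_edge(a, b, **data)
        return net

    # sif / edge-tsv: node classes come from the sidecar
    kinds: dict[str, str] = {}
    extra: dict[str, dict[str, float]] = {}
    with open(_node_sidecar(path), encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        attrs = header[2:]
        for row in reader:
            if not row:
                continue
            kinds[row[0]] = row[1]
            extra[row[0]] = {a: float(v) for a, v in zip(attrs, row[2:]) if v != ""}
    for node, kind in kinds.items():
        net.add_node(node, kind)
        net.graph.nodes[node].update(extra[node])

    if format == "sif":
        with open(path, encoding="utf-8") as fh:
            for i, raw in enumerate(fh, start=1):
                fields = raw.rstrip("\n").split("\t")
                if len(fields) == 1:
                    continue  # isolated node, already present from sidecar
                if len(fields) < 3:
                    raise FormatError("SIF lines need 1 or >= 3 fields", path=path, line=i)
                src = fields[0]
                for dst in fields[2:]:
                    net.add_edge(src, dst)
    else:
        for line, row in _tsv_rows(path):
            if row[0] == "node_a":
                continue
            if len(row) < 2:
                raise FormatError("edge-tsv rows need node_a and node_b", path=path, line=line)
            if len(row) > 2 and row[2] != "":
                net.add_edge(row[0], row[1], score=float(row[2]))
            else:
                net.add_edge(row[0], row[1])
    return net
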