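"""Hypergeometric over-representation analysis (ORA) of gene sets.

Given a query gene set (here: the therapeutic targets), an annotated
collection (pathways), and a background universe of N genes, each term
with K annotated genes and an overlap of k with the n-gene query is scored
by the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),

i.e. the chance of seeing at least k annotated genes in a random n-gene
query.  Benjamini–Hochberg adjusted p-values are always computed alongside;
the default screen keeps raw p < alpha, mirroring the "P < 0.05" convention
of enrichment portals, with an option to screen on the adjusted values
instead.

The choice of universe is explicit: either all genes annotated in the
collection (default) or the query's own background — it is never guessed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import GeneSetCollection
from .targets import TargetSet

logger = logging.getLogger("herbnet")

__all__ = ["EnrichmentRow", "hypergeom_tail", "bh_adjust", "enrich", "screen_top",
           "top_per_aspect"]


@dataclass(frozen=True)
class EnrichmentRow:
    """One gene set with its overlap counts and p-values.

    k = |query ∩ set|, K = set size within the universe, n = query size
    within the universe, N = universe size.
    """

    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float
    members: tuple[str, ...] = ()


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    Bounds are validated strictly; k = 0 returns exactly 1.0.
    """
    if not (0 <= k <= min(K, n) and k <= n <= N and k <= K <= N):
        raise ValidationError(f"invalid hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X > k-1) = P(X >= k); scipy evaluates this in log space
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    ps = list(pvalues)
    if not ps:
        return []
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"p-value outside [0, 1]: {p}")
    _, adj, _, _ = multipletests(ps, method="fdr_bh")
    return [float(a) for a in adj]


def enrich(query: TargetSet, collection: GeneSetCollection, universe: TargetSet,
           alpha: float | None = 0.05, use_adjusted: bool = False) -> list[EnrichmentRow]:
    """Score every term of ``collection`` against ``query`` within ``universe``.

    Query symbols outside the universe are dropped with a logged count, and
    term members are intersected with the universe, so the 2x2 margins are
    consistent.  Only terms with k >= 1 are reported, sorted by p ascending
    with ties broken by term id.  When ``alpha`` is given, rows failing the
    screen (raw p, or adjusted p when ``use_adjusted``) are removed; pass
    ``alpha=None`` to keep everything.
    """
    if len(universe) == 0:
        raise ValidationError("enrichment universe is empty")
    uni = universe.symbols
    q = query.symbols & uni
    dropped = len(query.symbols) - len(q)
    if dropped:
        logger.info("enrich: dropped %d query symbol(s) outside the universe", dropped)
    n, N = len(q), len(uni)

    rows: list[EnrichmentRow] = []
    for gs in sorted(collection, key=lambda s: s.term_id):
        members = gs.members & uni
        K = len(members)
        overlap = members & q
        k = len(overlap)
        if k == 0:
            continue
        p = hypergeom_tail(k, K, n, N)
        rows.append(EnrichmentRow(gs.term_id, gs.name, k, K, n, N, p, p,
                                  tuple(sorted(overlap))))
    if not rows:
        return []
    adj = bh_adjust([r.p for r in rows])
    rows = [replace(r, p_adj=a) for r, a in zip(rows, adj)]
    rows.sort(key=lambda r: (r.p, r.term_id))
    if alpha is not None:
        key = (lambda r: r.p_adj) if use_adjusted else (lambda r: r.p)
        rows = [r for r in rows if key(r) < alpha]
    return rows


def screen_top(rows: Sequence[EnrichmentRow], top_n: int,
               blocklist: Iterable[str] = ()) -> list[EnrichmentRow]:
    """Drop rows whose term name matches a blocklist pattern, keep the first
    ``top_n`` of the remainder.

    Matching is case-insensitive substring on term names.  Enrichment
    reports routinely contain terms irrelevant to the disease under study
    (annotation cross-talk); the blocklist makes that manual curation step
    explicit and reproducible.  It ships empty.
    """
    patterns = [b.lower() for b in blocklist]
    kept = [r for r in rows
            if not any(pat in r.term_name.lower() for pat in patterns)]
    return kept[:max(0, top_n)]


_ASPECT_RE = re.compile(r"^(BP|MF|CC)\b[:|\s]*", re.IGNORECASE)


def term_aspect(term_name: str) -> str:
    """Extract a GO aspect tag (BP/MF/CC) from a term description, else 'NA'."""
    m = _ASPECT_RE.match(term_name.strip())
    return m.group(1).upper() if m else "NA"


def top_per_aspect(rows: Sequence[EnrichmentRow], top_n: int = 10
                   ) -> dict[str, list[EnrichmentRow]]:
    """Group rows by GO aspect and keep the ``top_n`` best per aspect.

    Rows are assumed already sorted by p; terms without a recognizable
    aspect tag collect under 'NA'.
    """
    grouped: dict[str, list[EnrichmentRow]] = {}
    for r in rows:
        grouped.setdefault(term_aspect(r.term_name), [])
        if len(grouped[term_aspect(r.term_name)]) < top_n:
            grouped[term_aspect(r.term_name)].append(r)
    return grouped


def write_enrichment_table(rows: Sequence[EnrichmentRow], path) -> None:
    """TSV with columns term_id, term_name, k, K, n, N, p, p_adj, members."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tterm_name\tk\tK\tn\tN\tp\tp_adj\tmembers\n")
        for r in rows:
            fh.write(f"{r.term_id}\t{r.term_name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                     f"{r.p:.6g}\t{r.p_adj:.6g}\t{','.join(r.members)}\n")
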