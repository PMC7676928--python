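"""Synthetic inputs with controlled statistical structure.

Network-pharmacology inputs are database exports (compound tables,
compound-target maps, disease gene lists, scored interaction edges,
pathway annotations) that cannot be redistributed.  This module generates
stand-ins whose *shape* is controlled exactly — how many compounds pass the
ADME screen, how large the drug/disease target overlap is, how many
interaction edges clear the confidence cutoff, which pathway terms carry a
planted enrichment signal — so the full pipeline runs and can be tested
end-to-end with known ground truth.

Counts are constructed, not sampled: the overlap set is chosen first and
padded, the active-compound count is exact, and the interaction edge count
and its high-confidence fraction are exact.  Planted enrichment, by
contrast, is stochastic: each planted term draws Binomial(size, strength)
of its members from the query, so a strength equal to the query's
background frequency degenerates to (approximately) the null process.

Every generator is a pure function of its :class:`SimConfig`; random
streams are split per generator from the master seed, so adding a
generator never perturbs the others.

The default configuration mirrors a published herb-vs-disease study shape:
60 compounds of which 11 pass the screen, compound degrees matching that
study's printed degree column, 126 drug targets, 2207 disease targets, an
overlap of 83, and 500 interaction edges of which exactly 383 score >= 0.7.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io import CompoundRecord, GeneSet, GeneSetCollection, ScoredEdge
from .targets import CompoundTargetMap, TargetSet

__all__ = ["SimConfig", "simulate_compound_table", "simulate_target_universe",
           "simulate_ppi", "simulate_gene_sets"]

#: per-compound degrees of the 11 active ingredients in the reference study
REFERENCE_DEGREES: tuple[int, ...] = (68, 37, 32, 27, 24, 16, 11, 5, 4, 4, 3)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    ``degree_spec`` is either an explicit per-active-compound degree list
    or a distribution spec ``{"dist": "uniform_int", "low": a, "high": b}``.
    ``ppi_score_mix`` is (fraction of edges scoring >= 0.7, beta shape for
    the spread within each score band).  ``planted_terms`` lists
    (term index, strength) pairs, strength being the probability that a
    member of that set is drawn from the query rather than the background.
    """

    seed: int = 0
    n_compounds: int = 60
    frac_active: float = 11 / 60
    degree_spec: Sequence[int] | Mapping = REFERENCE_DEGREES
    n_drug_targets: int = 126
    n_disease_targets: int = 2207
    n_overlap: int = 83
    ppi_edge_count: int = 500
    ppi_score_mix: tuple[float, float] = (383 / 500, 2.0)
    n_pathways: int = 90
    pathway_size_range: tuple[int, int] = (10, 60)
    planted_terms: tuple[tuple[int, float], ...] = ((0, 0.6),)

    def __post_init__(self):
        if not (0.0 <= self.frac_active <= 1.0):
            raise ValidationError("frac_active must be in [0, 1]")
        if self.n_overlap > min(self.n_drug_targets, self.n_disease_targets):
            raise ValidationError("n_overlap cannot exceed either target-set size")
        if min(self.n_compounds, self.n_drug_targets, self.n_disease_targets,
               self.n_overlap, self.ppi_edge_count, self.n_pathways) < 0:
            raise ValidationError("all counts must be >= 0")
        frac_high, spread = self.ppi_score_mix
        if not (0.0 <= frac_high <= 1.0) or spread <= 0:
            raise ValidationError("ppi_score_mix must be (fraction in [0,1], shape > 0)")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ValidationError("pathway_size_range must satisfy 0 < min <= max")

    @property
    def n_active(self) -> int:
        return round(self.frac_active * self.n_compounds)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["degree_spec"] = (dict(self.degree_spec) if isinstance(self.degree_spec, Mapping)
                            else list(self.degree_spec))
        d["planted_terms"] = [list(t) for t in self.planted_terms]
        return d


# stream indices: one per generator, fixed forever
_STREAM_COMPOUNDS, _STREAM_TARGETS, _STREAM_PPI, _STREAM_GENESETS = range(4)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def _compound_id(i: int) -> str:
    return f"CMP{i:04d}"


def simulate_compound_table(cfg: SimConfig) -> list[CompoundRecord]:
    """Compound table in which exactly ``round(frac_active * n_compounds)``
    rows pass the OB >= 30 / DL >= 0.18 screen.

    Actives draw OB ~ U[30, 60] and DL ~ U[0.18, 0.8]; the rest fail at
    least one criterion (low OB, low DL, or both).  The first
    ``n_active`` compound ids are the actives, which keeps the active id
    set deterministic across generators.
    """
    rng = _rng(cfg, _STREAM_COMPOUNDS)
    records: list[CompoundRecord] = []
    n_active = cfg.n_active
    for i in range(1, cfg.n_compounds + 1):
        if i <= n_active:
            ob = float(rng.uniform(30.0, 60.0))
            dl = float(rng.uniform(0.18, 0.8))
        else:
            mode = rng.integers(0, 3)
            ob = float(rng.uniform(2.0, 29.9)) if mode in (0, 2) else float(rng.uniform(30.0, 60.0))
            dl = float(rng.uniform(0.01, 0.17)) if mode in (1, 2) else float(rng.uniform(0.18, 0.8))
        records.append(CompoundRecord(_compound_id(i), f"compound-{i:04d}",
                                      round(ob, 2), round(dl, 2)))
    return records


def active_compound_ids(cfg: SimConfig) -> list[str]:
    return [_compound_id(i) for i in range(1, cfg.n_active + 1)]


def _resolve_degrees(cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    n_active = cfg.n_active
    if isinstance(cfg.degree_spec, Mapping):
        spec = dict(cfg.degree_spec)
        if spec.get("dist") != "uniform_int":
            raise ValidationError(f"unsupported degree distribution {spec.get('dist')!r}")
        lo, hi = int(spec["low"]), int(spec["high"])
        if not (1 <= lo <= hi):
            raise ValidationError("degree distribution needs 1 <= low <= high")
        degrees = [int(d) for d in rng.integers(lo, hi + 1, size=n_active)]
    else:
        degrees = [int(d) for d in cfg.degree_spec]
        if len(degrees) != n_active:
            raise ValidationError(
                f"degree_spec lists {len(degrees)} degrees but {n_active} compounds are active")
    for d in degrees:
        if not (1 <= d <= cfg.n_drug_targets):
            raise ValidationError(
                f"infeasible degree {d}: must be in [1, n_drug_targets={cfg.n_drug_targets}]")
    if sum(degrees) < cfg.n_drug_targets:
        raise ValidationError("sum of degrees is too small to hit every drug target")
    return degrees


def simulate_target_universe(cfg: SimConfig
                             ) -> tuple[CompoundTargetMap, TargetSet, TargetSet]:
    """Compound-target map plus drug and disease target sets.

    By construction |drug| = n_drug_targets, |disease| = n_disease_targets
    and |drug ∩ disease| = n_overlap exactly; compound degrees follow
    ``degree_spec``; every drug target is hit by at least one compound.
    Symbols are neutral ``G000001``-style tokens so they can never collide
    with the gene-symbol alias table.
    """
    rng = _rng(cfg, _STREAM_TARGETS)
    degrees = _resolve_degrees(cfg, rng)
    compounds = active_compound_ids(cfg)

    drug_syms = [f"G{i:06d}" for i in range(1, cfg.n_drug_targets + 1)]
    # the overlap is chosen first (constructively), then the disease set is
    # padded with disease-only tokens
    overlap = list(rng.choice(drug_syms, size=cfg.n_overlap, replace=False))
    disease_only = [f"G{i:06d}" for i in range(cfg.n_drug_targets + 1,
                                               cfg.n_drug_targets + 1
                                               + cfg.n_disease_targets - cfg.n_overlap)]
    disease = TargetSet("disease", set(overlap) | set(disease_only))
    drug = TargetSet("drug", drug_syms)

    # phase 1 — coverage: deal every drug target to some compound with
    # remaining quota; phase 2 — fill each compound's quota with fresh targets
    quota = dict(zip(compounds, degrees))
    hits: dict[str, set[str]] = {c: set() for c in compounds}
    shuffled = list(drug_syms)
    rng.shuffle(shuffled)
    for sym in shuffled:
        open_compounds = [c for c in compounds if len(hits[c]) < quota[c]]
        c = open_compounds[int(rng.integers(0, len(open_compounds)))]
        hits[c].add(sym)
    for c in compounds:
        need = quota[c] - len(hits[c])
        if need > 0:
            pool = [s for s in drug_syms if s not in hits[c]]
            hits[c].update(rng.choice(pool, size=need, replace=False))
    pairs = {(c, s) for c, syms in hits.items() for s in syms}
    return CompoundTargetMap(pairs), drug, disease


def simulate_ppi(cfg: SimConfig, members: TargetSet) -> list[ScoredEdge]:
    """Scored edge list among ``members`` straddling the 0.7 cutoff.

    Exactly ``ppi_edge_count`` distinct unordered pairs; exactly
    ``round(frac_high * ppi_edge_count)`` of them score in [0.7, 1), the
    rest in [0.15, 0.7).  Within each band scores follow a symmetric
    Beta(shape, shape) spread.
    """
    if len(members) == 0:
        raise ValidationError("simulate_ppi needs a nonempty member set")
    rng = _rng(cfg, _STREAM_PPI)
    syms = sorted(members.symbols)
    m = len(syms)
    max_edges = m * (m - 1) // 2
    if cfg.ppi_edge_count > max_edges:
        raise ValidationError(
            f"requested {cfg.ppi_edge_count} edges but only {max_edges} pairs exist")
    pair_idx = rng.choice(max_edges, size=cfg.ppi_edge_count, replace=False)
    frac_high, shape = cfg.ppi_score_mix
    n_high = round(frac_high * cfg.ppi_edge_count)

    edges: list[ScoredEdge] = []
    for rank, flat in enumerate(sorted(int(i) for i in pair_idx)):
        # unrank the flat index into an (i, j) pair, i < j
        i = int((2 * m - 1 - np.sqrt((2 * m - 1) ** 2 - 8 * flat)) // 2)
        offset = flat - (i * (2 * m - i - 1)) // 2
        j = i + 1 + int(offset)
        spread = float(rng.beta(shape, shape))
        if rank < n_high:
            score = 0.7 + 0.3 * spread
            score = min(score, 0.999999)
        else:
            score = 0.15 + 0.55 * spread
            score = min(score, 0.699999)
        edges.append(ScoredEdge(syms[i], syms[j], score))
    return edges


def simulate_gene_sets(cfg: SimConfig, universe: TargetSet,
                       query: TargetSet) -> GeneSetCollection:
    """Pathway annotation with optional planted enrichment.

    ``n_pathways`` sets with sizes uniform in ``pathway_size_range``.
    Planted terms draw Binomial(size, strength) members from the query
    (capped at the query size) and the rest from the background; all other
    terms sample uniformly from the universe, i.e. the central
    hypergeometric null.
    """
    if not query.symbols <= universe.symbols:
        raise ValidationError("query must be a subset of the universe")
    rng = _rng(cfg, _STREAM_GENESETS)
    uni = sorted(universe.symbols)
    q = sorted(query.symbols)
    background = sorted(universe.symbols - query.symbols)
    planted = dict(cfg.planted_terms)
    for idx in planted:
        if not (0 <= idx < cfg.n_pathways):
            raise ValidationError(f"planted term index {idx} out of range")

    lo, hi = cfg.pathway_size_range
    sets = []
    for i in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(uni))
        if i in planted:
            strength = planted[i]
            n_q = int(rng.binomial(size, strength))
            n_q = min(n_q, len(q), size)
            n_bg = min(size - n_q, len(background))
            members = (list(rng.choice(q, size=n_q, replace=False))
                       + list(rng.choice(background, size=n_bg, replace=False)))
        else:
            members = list(rng.choice(uni, size=size, replace=False))
        sets.append(GeneSet(f"PATH{i:04d}", f"simulated pathway {i}", frozenset(members)))
    return GeneSetCollection(sets)
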