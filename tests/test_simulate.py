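import dataclasses

import pytest

from herbnet.adme import filter_compounds
from herbnet.errors import ValidationError
from herbnet.networks import build_ppi
from herbnet.simulate import (SimConfig, simulate_compound_table,
                              simulate_gene_sets, simulate_ppi,
                              simulate_target_universe)
from herbnet.targets import TargetSet, intersect_targets


class TestSimConfig:
    def test_defaults_are_study_shaped(self):
        cfg = SimConfig()
        assert cfg.n_active == 11
        assert cfg.n_overlap == 83

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(n_drug_targets=10, n_disease_targets=100, n_overlap=11)


class TestCompoundTable:
    def test_exact_active_count(self):
        cfg = SimConfig(seed=3)
        records = simulate_compound_table(cfg)
        active, _ = filter_compounds(records)
        assert len(records) == 60 and len(active) == 11

    def test_deterministic(self):
        a = simulate_compound_table(SimConfig(seed=5))
        b = simulate_compound_table(SimConfig(seed=5))
        assert a == b

    def test_frac_active_zero(self):
        cfg = SimConfig(seed=1, frac_active=0.0,
                        degree_spec={"dist": "uniform_int", "low": 1, "high": 5})
        active, _ = filter_compounds(simulate_compound_table(cfg))
        assert active == []


class TestTargetUniverse:
    def test_exact_counts(self, small_cfg):
        ctmap, drug, disease = simulate_target_universe(small_cfg)
        assert len(drug) == small_cfg.n_drug_targets
        assert len(disease) == small_cfg.n_disease_targets
        assert len(intersect_targets(drug, disease)) == small_cfg.n_overlap

    def test_default_shape_counts(self):
        ctmap, drug, disease = simulate_target_universe(SimConfig(seed=2))
        assert (len(drug), len(disease)) == (126, 2207)
        assert len(drug.symbols & disease.symbols) == 83

    def test_explicit_degrees_and_coverage(self):
        degrees = (10, 8, 6, 6, 5)
        cfg = SimConfig(seed=4, n_compounds=10, frac_active=0.5,
                        degree_spec=degrees, n_drug_targets=20,
                        n_disease_targets=50, n_overlap=10,
                        ppi_edge_count=20)
        ctmap, drug, _ = simulate_target_universe(cfg)
        got = sorted((ctmap.degree(c) for c in ctmap.compounds), reverse=True)
        assert got == sorted(degrees, reverse=True)
        assert ctmap.targets == drug.symbols  # every drug target is hit

    def test_infeasible_degree_rejected(self):
        cfg = SimConfig(seed=1, n_compounds=4, frac_active=0.5,
                        degree_spec=(30, 5), n_drug_targets=20,
                        n_disease_targets=30, n_overlap=5, ppi_edge_count=5)
        with pytest.raises(ValidationError, match="degree"):
            simulate_target_universe(cfg)

    def test_deterministic(self, small_cfg):
        a = simulate_target_universe(small_cfg)
        b = simulate_target_universe(small_cfg)
        assert a[0].pairs == b[0].pairs and a[2].symbols == b[2].symbols


class TestPpi:
    def test_exact_edge_count_and_high_fraction(self, small_cfg):
        _, drug, disease = simulate_target_universe(small_cfg)
        overlap = TargetSet("ov", drug.symbols & disease.symbols)
        edges = simulate_ppi(small_cfg, overlap)
        assert len(edges) == small_cfg.ppi_edge_count
        n_high = sum(1 for e in edges if e.score >= 0.7)
        assert n_high == round(small_cfg.ppi_score_mix[0] * small_cfg.ppi_edge_count)

    def test_fraction_one_all_survive_cutoff(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, ppi_score_mix=(1.0, 2.0))
        _, drug, disease = simulate_target_universe(cfg)
        overlap = TargetSet("ov", drug.symbols & disease.symbols)
        net = build_ppi(simulate_ppi(cfg, overlap), overlap, min_score=0.7)
        assert net.n_edges == cfg.ppi_edge_count

    def test_fraction_zero_empty_network(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, ppi_score_mix=(0.0, 2.0))
        _, drug, disease = simulate_target_universe(cfg)
        overlap = TargetSet("ov", drug.symbols & disease.symbols)
        net = build_ppi(simulate_ppi(cfg, overlap), overlap, min_score=0.7)
        assert net.n_edges == 0

    def test_too_many_edges_rejected(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, ppi_edge_count=10**6)
        _, drug, disease = simulate_target_universe(cfg)
        overlap = TargetSet("ov", drug.symbols & disease.symbols)
        with pytest.raises(ValidationError, match="pairs"):
            simulate_ppi(cfg, overlap)

    def test_deterministic(self, small_cfg):
        _, drug, disease = simulate_target_universe(small_cfg)
        overlap = TargetSet("ov", drug.symbols & disease.symbols)
        assert simulate_ppi(small_cfg, overlap) == simulate_ppi(small_cfg, overlap)


class TestGeneSets:
    def test_sizes_and_membership(self, small_cfg):
        _, drug, disease = simulate_target_universe(small_cfg)
        overlap = TargetSet("ov", drug.symbols & disease.symbols)
        coll = simulate_gene_sets(small_cfg, disease, overlap)
        assert len(coll) == small_cfg.n_pathways
        lo, hi = small_cfg.pathway_size_range
        for gs in coll:
            assert lo <= len(gs.members) <= hi
            assert gs.members <= disease.symbols

    def test_query_must_be_subset(self, small_cfg):
        with pytest.raises(ValidationError):
            simulate_gene_sets(small_cfg, TargetSet("u", {"A"}),
                               TargetSet("q", {"B"}))

    def test_planted_index_validated(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, planted_terms=((999, 0.5),))
        _, drug, disease = simulate_target_universe(small_cfg)
        overlap = TargetSet("ov", drug.symbols & disease.symbols)
        with pytest.raises(ValidationError, match="index"):
            simulate_gene_sets(cfg, disease, overlap)

    def test_background_strength_rank_is_approximately_uniform(self):
        """A 'planted' term whose strength equals the query's background
        frequency is statistically indistinguishable from a null term, so
        its enrichment rank over many seeds is close to uniform
        (chi-square over rank deciles)."""
        from scipy.stats import chisquare

        from herbnet.enrichment import enrich

        universe = TargetSet("u", {f"G{i:06d}" for i in range(1, 501)})
        query = TargetSet("q", {f"G{i:06d}" for i in range(1, 51)})
        background = len(query) / len(universe)  # 0.1
        n_terms = 20
        ranks = []
        for seed in range(200):
            cfg = SimConfig(seed=seed, n_pathways=n_terms,
                            pathway_size_range=(20, 40),
                            planted_terms=((0, background),))
            coll = simulate_gene_sets(cfg, universe, query)
            rows = enrich(query, coll, universe, alpha=None)
            rank = next((i + 1 for i, r in enumerate(rows)
                         if r.term_id == "PATH0000"), n_terms)
            ranks.append(rank)
        counts = [sum(1 for r in ranks if lo < r <= lo + 2)
                  for lo in range(0, n_terms, 2)]
        assert chisquare(counts).pvalue > 0.005, counts
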