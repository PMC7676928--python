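import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from herbnet import SimConfig
from herbnet.reference import load_active_compounds, load_ctp_table, load_hub_table

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def compound_table() -> pd.DataFrame:
    """The 11 published active compounds with OB, DL and C-OT degree."""
    return load_active_compounds()


@pytest.fixture(scope="session")
def hub_table() -> pd.DataFrame:
    return load_hub_table()


@pytest.fixture(scope="session")
def ctp_table() -> pd.DataFrame:
    return load_ctp_table()


@pytest.fixture
def small_cfg() -> SimConfig:
    """A scaled-down synthetic study that runs in milliseconds."""
    return SimConfig(
        seed=11,
        n_compounds=30,
        frac_active=0.3,
        degree_spec={"dist": "uniform_int", "low": 5, "high": 15},
        n_drug_targets=40,
        n_disease_targets=120,
        n_overlap=25,
        ppi_edge_count=80,
        ppi_score_mix=(0.7, 2.0),
        n_pathways=30,
        pathway_size_range=(8, 25),
        planted_terms=((0, 0.7),),
    )


@pytest.fixture
def sim_fixture_dir(tmp_path, small_cfg):
    """Write the scaled synthetic study to disk as pipeline input files."""
    from herbnet import (simulate_compound_table, simulate_gene_sets,
                         simulate_ppi, simulate_target_universe)
    from herbnet.io import (write_compound_table, write_compound_target_map,
                            write_gene_list, write_gmt, write_scored_edges)
    from herbnet.targets import TargetSet

    cfg = small_cfg
    compounds = simulate_compound_table(cfg)
    ctmap, drug, disease = simulate_target_universe(cfg)
    overlap = TargetSet("overlap", drug.symbols & disease.symbols)
    ppi = simulate_ppi(cfg, overlap)
    collection = simulate_gene_sets(cfg, disease, overlap)

    d = tmp_path / "fixtures"
    d.mkdir()
    write_compound_table(compounds, d / "compounds.tsv")
    write_compound_target_map(ctmap.pairs, d / "compound_targets.tsv")
    write_gene_list(disease.symbols, d / "disease.txt")
    write_scored_edges(ppi, d / "ppi.tsv")
    write_gmt(collection, d / "pathways.gmt")
    return d


def pipeline_config(fixture_dir, **overrides) -> dict:
    cfg = {
        "inputs": {
            "compounds": str(fixture_dir / "compounds.tsv"),
            "compound_targets": str(fixture_dir / "compound_targets.tsv"),
            "disease_targets": [str(fixture_dir / "disease.txt")],
            "ppi_edges": str(fixture_dir / "ppi.tsv"),
            "gene_sets": str(fixture_dir / "pathways.gmt"),
        },
    }
    cfg.update(overrides)
    return cfg
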