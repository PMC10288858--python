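"""Shared fixtures: small simulated cohorts reused across test modules."""

from __future__ import annotations

import pandas as pd
import pytest

from mitoscreen.synthdata import SimConfig, simulate_cohort, simulate_networks


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition cohort with planted candidates and networks."""
    cfg = SimConfig(seed=42)
    cm, meta, annot, truth = simulate_cohort(cfg)
    ppi, catalog, targets, reports = simulate_networks(truth, cfg)
    return {
        "config": cfg,
        "cm": cm,
        "meta": meta,
        "annot": annot,
        "truth": truth,
        "ppi": ppi,
        "catalog": catalog,
        "targets": targets,
        "reports": reports,
    }


@pytest.fixture(scope="session")
def null_sim():
    """Null cohort (no planted DEGs), 2 batches, 30 vs 30 per sex."""
    cfg = SimConfig(seed=7, frac_deg=0.0, n_candidates=0, n_hubs=0, n_support=0, frac_braak3=0.0)
    cm, meta, annot, truth = simulate_cohort(cfg)
    return {"config": cfg, "cm": cm, "meta": meta, "annot": annot, "truth": truth}


@pytest.fixture()
def validated_gene_stats():
    """Network statistics of the four experimentally validated genes
    (degrees in the male/female PPI networks and distinct up/down
    targeting-miRNA counts), used as the worked example for the
    candidate criteria."""
    stats = pd.DataFrame(
        [
            {"gene_id": "VCP", "degree_male": 56.0, "degree_female": 61.0, "n_up_mirna": 10, "n_down_mirna": 1},
            {"gene_id": "ARF1", "degree_male": 33.0, "degree_female": 46.0, "n_up_mirna": 17, "n_down_mirna": 4},
            {"gene_id": "GABARAPL1", "degree_male": 37.0, "degree_female": 45.0, "n_up_mirna": 17, "n_down_mirna": 2},
            {"gene_id": "ACTB", "degree_male": 29.0, "degree_female": float("nan"), "n_up_mirna": 22, "n_down_mirna": 12},
        ]
    )
    de_male = pd.DataFrame(
        {
            "gene_id": ["VCP", "ARF1", "GABARAPL1", "ACTB"],
            "log2fc": [-0.11, -0.21, -0.23, -0.17],
            "is_deg": [True, True, True, True],
            "direction": ["down", "down", "down", "down"],
        }
    )
    de_female = pd.DataFrame(
        {
            "gene_id": ["VCP", "ARF1", "GABARAPL1", "ACTB"],
            "log2fc": [-0.10, -0.10, -0.28, -0.05],
            "is_deg": [True, True, True, False],
            "direction": ["down", "down", "down", "none"],
        }
    )
    return stats, {"male": de_male, "female": de_female}
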