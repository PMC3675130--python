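import numpy as np
import pandas as pd
import pytest

from pathgwas.containers import Cohort, GeneCatalog, PathwayCatalog
from pathgwas.simulate import SimulationConfig, simulate_cohort


@pytest.fixture
def tiny_cohort():
    """Hand-built 8-sample × 4-SNP cohort with one missing call."""
    g = np.array(
        [
            [0, 1, 2, 0],
            [1, 0, 1, 0],
            [2, 1, 0, 1],
            [0, 0, 1, 0],
            [1, 2, 0, 1],
            [0, 1, 1, 0],
            [np.nan, 0, 2, 0],
            [1, 1, 0, 1],
        ],
        dtype=float,
    )
    return Cohort(
        sample_ids=[f"s{i}" for i in range(8)],
        phenotype=[1, 1, 1, 1, 0, 0, 0, 0],
        age=[50, 60, 55, 45, 62, 58, 49, 53],
        gender=[0, 1, 0, 1, 0, 1, 0, 1],
        smoking=[1, 0, 1, 0, 1, 0, 0, 1],
        genotypes=g,
        snp_ids=["rs1", "rs2", "rs3", "rs4"],
        snp_chrom=["chr1", "chr1", "chr2", "chr2"],
        snp_pos=[100, 50_000, 100, 80_000],
    )


@pytest.fixture
def gene_catalog():
    return GeneCatalog(
        pd.DataFrame(
            {
                "symbol": ["GA", "GB", "GC"],
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [90, 60_000, 50],
                "end": [200, 70_000, 150],
                "strand": ["+", "-", "+"],
            }
        )
    )


@pytest.fixture
def pathway_catalog():
    return PathwayCatalog(
        names=["P1", "P2", "P3"],
        sources=["src", "src", "src"],
        members=[("GA", "GB"), ("GB", "GC"), ("GA",)],
    )


@pytest.fixture(scope="session")
def null_sim():
    """Small global-null study shared by read-only tests."""
    cfg = SimulationConfig(
        n_cases=250, n_controls=350, n_genes=60, n_snps_per_gene=(1, 4),
        n_pathways=6, genes_per_pathway=20, missing_rate=0.02, seed=42,
    )
    return simulate_cohort(cfg)
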