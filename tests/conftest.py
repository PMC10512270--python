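import numpy as np
import pandas as pd
import pytest

import ploidypaint as pp


@pytest.fixture(scope="session")
def coverage150():
    return pp.CoverageModel(mean_depth=150.0, overdispersion=20.0)


@pytest.fixture(scope="session")
def error005():
    return pp.ErrorModel(rate=0.005)


@pytest.fixture(scope="session")
def mosaic_spec():
    """Two-contig random mosaic with all four ancestry states and at
    least one long (>=30 kb) LOH tract."""
    return pp.MosaicSpec.random(
        {"c1": 600_000, "c2": 400_000}, mean_block_bp=40_000, seed=100
    )


@pytest.fixture(scope="session")
def mosaic_sim(mosaic_spec, coverage150, error005):
    table, truth = pp.simulate_hybrid_mosaic(
        mosaic_spec, coverage=coverage150, error=error005, seed=102
    )
    return table, truth


@pytest.fixture(scope="session")
def panel():
    """Hybrid metagenome plus haploid lineage panel, donor = vulpina."""
    spec = pp.MosaicSpec.random(
        {"c1": 1_200_000}, mean_block_bp=60_000, het_density=0.012, seed=7
    )
    return pp.simulate_ancestry_panel(spec, seed=8)


def make_sites(contig, positions, ref_depth, alt_depth):
    """Hand-build a SiteCountTable for toy fixtures."""
    n = len(positions)
    df = pd.DataFrame(
        {
            "contig": contig,
            "pos0": positions,
            "ref": ["A"] * n,
            "alt": ["G"] * n,
            "ref_depth": ref_depth,
            "alt_depth": alt_depth,
        }
    )
    return pp.SiteCountTable(df)
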