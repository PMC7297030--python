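import numpy as np
import pandas as pd
import pytest

from afddmap import CrossConfig, GenomeSpec, simulate_experiment


@pytest.fixture(scope="session")
def small_config() -> CrossConfig:
    """A fast desk-top cross: 2 x 6 Mb genome, 120 offspring, pools 8/12."""
    return CrossConfig(
        genome=GenomeSpec(
            chromosomes=(("chr1", 6_000_000), ("chr2", 6_000_000)),
            snv_density=3.0e-4,
        ),
        dominant_locus=("chr1", 5_000_000),
        suppressor_loci=(("chr1", 3_500_000), ("chr2", 3_000_000)),
        suppressor_genotypes=(("Rr", "Rr"), ("rr", "Rr")),
        n_offspring=120,
        penetrance=(0.9, 0.6),
        pool_sizes=(8, 12),
    )


@pytest.fixture(scope="session")
def small_run(small_config):
    return simulate_experiment(small_config, seed=4242)


@pytest.fixture(scope="session")
def medium_config() -> CrossConfig:
    """Large enough for the density scan to have genuine background windows."""
    return CrossConfig(
        genome=GenomeSpec(
            chromosomes=(("chr1", 20_000_000), ("chr2", 20_000_000),
                         ("chr3", 20_000_000)),
            snv_density=1.0e-4,
        ),
        dominant_locus=("chr1", 12_500_000),
        suppressor_loci=(("chr1", 10_500_000), ("chr2", 8_500_000)),
        suppressor_genotypes=(("Rr", "Rr"), ("rr", "Rr")),
        n_offspring=200,
        pool_sizes=(12, 14),
    )


@pytest.fixture(scope="session")
def default_run():
    """One full default-scale experiment, shared across tests."""
    return simulate_experiment(seed=777)


@pytest.fixture()
def pool_frame():
    """Hand-written pool variant table exercising every QC rule."""
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 8,
            "pos": np.arange(1, 9) * 100,
            "ref": ["A", "A", "A", "A", "A", "A", "AT", "A"],
            "alt": ["G", "G", "G", "G", "A", "AT", "A", "G"],
            "depth": [100, 19, 201, 9, 100, 100, 100, 50],
            "alt_count": [50, 10, 100, 5, 40, 40, 40, 1],
            "af": [50.0, 52.6, 49.8, 55.6, 40.0, 40.0, 40.0, 2.0],
        }
    )
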