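import numpy as np
import pandas as pd
import pytest

from herdscan import simulate
from herdscan.cohort import Cohort, make_samples, make_variants


def random_cohort(
    rng: np.random.Generator,
    n_sites: int = 50,
    n_samples: int = 6,
    chrom_length: int = 100_000,
    missing_rate: float = 0.0,
    populations: tuple = ("A", "B"),
) -> Cohort:
    """Small unphased cohort with arbitrary genotypes, for exact oracles."""
    pos = np.sort(rng.choice(chrom_length, size=n_sites, replace=False)) + 1
    g = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = -1
    pops = [populations[i % len(populations)] for i in range(n_samples)]
    return Cohort(
        variants=make_variants("1", pos),
        samples=make_samples([f"s{i}" for i in range(n_samples)], pops),
        genotypes=g,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bn_cohort():
    """Two Balding-Nichols populations at F = 0.1, phased."""
    cfg = simulate.SimConfig(
        n_pops=2, n_per_pop=20, chrom_lengths={"1": 2_000_000},
        density=1e-3, pop_f=(0.1, 0.1), seed=7,
    )
    cohort, truth = simulate.sim_balding_nichols(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def demo_fixture(tmp_path_factory):
    """On-disk demo fixture (VCF + popmap + chrom sizes) for pipeline runs."""
    d = tmp_path_factory.mktemp("demo_fixture")
    cfg = simulate.SimConfig(
        n_pops=2, n_per_pop=8, chrom_lengths={"1": 1_500_000, "2": 1_000_000},
        density=1e-3, pop_f=(0.05, 0.05), seed=42,
    )
    cohort, truth = simulate.sim_balding_nichols(cfg)
    cohort, truth = simulate.plant_autozygosity(
        cohort, "P1_000", [("1", 200_001, 700_000)], error_rate=0.01,
        seed=43, truth=truth,
    )
    simulate.write_fixture(cohort, truth, str(d))
    sizes = d / "chrom_sizes.tsv"
    sizes.write_text("1\t1500000\n2\t1000000\n")
    return d
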