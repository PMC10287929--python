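import numpy as np
import pytest

from ervscape.io_formats import GenomeSpec, Interval
from ervscape.synthetic_data import SimConfig, TEFamilyConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """The full default study conditions, one fixed seed, shared per session."""
    return simulate(SimConfig(seed=11))


def small_config(seed: int = 3) -> SimConfig:
    """Scaled-down simulation for fast unit/integration tests."""
    cfg = SimConfig(seed=seed)
    cfg.n_chroms = 2
    cfg.chrom_length = 300_000
    cfg.te_families = {
        "MERVL-int": TEFamilyConfig("ERVL", 30, 4800, 900, 400),
        "MT2_Mm": TEFamilyConfig("ERVL", 25, 480, 60, 320),
        "IAPEz-int": TEFamilyConfig("ERVK", 20, 4500, 400, 400, fragmented_fraction=0.5),
        "B1_Mm": TEFamilyConfig("SINE", 15, 150, 20, 100),
    }
    cfg.bound_fraction = {"MERVL-int": 0.8, "MT2_Mm": 0.6, "IAPEz-int": 0.7}
    cfg.n_decoy_peaks = 10
    cfg.n_genes = 60
    cfg.n_2c_genes = 12
    cfg.n_cells_control = 900
    cfg.n_cells_depleted = 800
    cfg.mnase_background_per_bp = 0.005
    return cfg


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture
def toy_genome():
    return GenomeSpec(("chr1", "chr2"), (10_000, 5_000))


def random_intervals(rng: np.random.Generator, genome: GenomeSpec, n: int):
    """Uniform random valid intervals for oracle fixtures."""
    out = []
    for _ in range(n):
        chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
        clen = genome.lengths[chrom]
        start = int(rng.integers(0, clen - 1))
        end = int(rng.integers(start + 1, min(clen, start + 500) + 1))
        out.append(Interval(chrom, start, end))
    return out
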