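import numpy as np
import pytest

from epireprog.genome import GenomeLayout, GenomicInterval, RegionSet
from epireprog.signal import RegionActivityMatrix, SignalTrack, normalize_library
from epireprog.simulate import SimulationConfig


@pytest.fixture
def genome():
    return GenomeLayout({"chr1": 100_000, "chr2": 100_000})


@pytest.fixture
def constant_track(genome):
    """2.0 per 100-bp bin on every chromosome."""
    data = {c: np.full(s // 100, 2.0) for c, s in genome.chrom_sizes.items()}
    return SignalTrack("const", 100, data)


def make_count_matrix(x, r, conditions=("cond", "ref"), lib_x=1e6, lib_r=1e6):
    """Two-condition activity matrix from raw counts with given library sizes."""
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    ids = [f"chr1:{i * 1000}-{i * 1000 + 500}" for i in range(len(x))]
    m = RegionActivityMatrix(ids, list(conditions), np.column_stack([x, r]))
    return normalize_library(m, {conditions[0]: lib_x, conditions[1]: lib_r})


def small_sim_config(seed: int, **overrides) -> SimulationConfig:
    """Scaled-down simulation used by the integration tests."""
    base = dict(
        seed=seed,
        chrom_length=450_000,
        n_regions=30,
        cluster_spec=[
            [[1, 4, 4, 1, 1, 1], 6],
            [[1, 1, 1, 4, 4, 4], 6],
            [[1, 0.25, 0.25, 0.25, 0.25, 0.25], 6],
        ],
        se_count=4,
        n_typical_peaks=10,
        n_tads=6,
        tad_width=60_000,
        shifted_tad_index=1,
        punctuated_tad_index=4,
        n_footprint_sites=30,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def intervals(chrom, pairs):
    return RegionSet([GenomicInterval(chrom, s, e) for s, e in pairs])
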