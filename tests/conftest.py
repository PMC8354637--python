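import numpy as np
import pytest

from seclipkit.clusters import SampleLibrary
from seclipkit.intervals import GenomicInterval
from seclipkit.simulate import SimulationConfig, simulate_clip, simulate_genome


def tile_reads(interval: GenomicInterval, count: int, read_length: int = 30):
    """Deterministic read tiling of a cluster interval (test helper)."""
    if count <= 0:
        return []
    L = min(read_length, len(interval))
    span = len(interval) - L
    return [
        GenomicInterval(
            interval.chrom,
            interval.start + ((i * span) // max(count - 1, 1) if span else 0),
            interval.start + ((i * span) // max(count - 1, 1) if span else 0) + L,
            interval.strand,
        )
        for i in range(count)
    ]


def library_from_sites(sites, sample, replicate, library_size=1_000_000):
    """Build a SampleLibrary from (interval, read count) pairs."""
    reads = []
    for iv, n in sites:
        reads.extend(tile_reads(iv, n))
    return SampleLibrary(
        sample=sample, replicate=replicate, total_mapped_reads=library_size, reads=reads
    )


@pytest.fixture(scope="session")
def small_simulation():
    """One modest synthetic experiment shared across tests."""
    cfg = SimulationConfig(seed=7, n_genes=200, n_target_genes=60)
    annotation, sequences, ts_table, truth = simulate_genome(cfg)
    libraries = simulate_clip(annotation, truth, cfg)
    return cfg, annotation, sequences, ts_table, truth, libraries
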