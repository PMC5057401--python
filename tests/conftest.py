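import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from amplicall.align import align_reads
from amplicall.fixtures import synthetic_amplicon, toy_gene
from amplicall.simulate import SampleSpec, SimConfig, simulate_sample


@pytest.fixture(scope="session")
def toy():
    """(AmpliconRef, TranscriptModel) of the bundled toy minus-strand gene."""
    return toy_gene()


@pytest.fixture(scope="session")
def small_ref():
    return synthetic_amplicon(800, seed=5)


@pytest.fixture(scope="session")
def sim_batch(small_ref):
    """120 full-length default-error reads of the 800-bp amplicon, aligned."""
    cfg = SimConfig(samples=[SampleSpec("S1", "", [])], n_reads=120,
                    full_length_fraction=1.0, seed=17)
    reads = simulate_sample(small_ref, cfg, "S1")
    alns, stats = align_reads(
        [(r.read_id, r.sequence) for r in reads], small_ref, band=48, sample_id="S1"
    )
    return reads, alns, stats
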