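import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from splicescape.models import GenomeSequence, TranscriptModel
from splicescape.synthetic import SimulationConfig, simulate


def random_transcript(rng: np.random.Generator, gene_id="G", tid="t",
                      strand=None, max_exons=6, contig="chr1") -> TranscriptModel:
    """A random multi-exon transcript used by structural tests."""
    k = int(rng.integers(2, max_exons + 1))
    pos = int(rng.integers(0, 50))
    exons = []
    for _ in range(k):
        e = pos + int(rng.integers(30, 200))
        exons.append((pos, e))
        pos = e + int(rng.integers(40, 300))
    strand = strand or ("+" if rng.random() < 0.5 else "-")
    return TranscriptModel(tid, gene_id, contig, strand, exons)


@pytest.fixture(scope="session")
def small_bundle():
    """Default-condition simulation shared across read-only tests."""
    return simulate(SimulationConfig(seed=1, n_genes=40))


@pytest.fixture(scope="session")
def ir_bundle():
    """Intron-retention-only simulation for ORF/PTC tests."""
    return simulate(SimulationConfig(
        seed=21, n_genes=60, as_fraction=1.0, event_mix={"IR": 1.0}))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_genome() -> GenomeSequence:
    return GenomeSequence({"chr1": "ACGT" * 2500})
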