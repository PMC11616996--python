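import numpy as np
import pytest

from clipsplice.genome import GenomeSequence, TranscriptModel
from clipsplice.synth import SyntheticConfig, SyntheticDataset


def small_synthetic_config(seed: int = 1, **overrides) -> SyntheticConfig:
    """A fast desk-scale configuration used across tests."""
    defaults = dict(
        seed=seed, n_genes=60,
        n_se_included=10, n_se_skipped=8, n_se_nondiff=10, n_se_lowread=2,
        n_other={"RI": (3, 2), "MXE": (3, 2), "A5SS": (2, 1), "A3SS": (2, 1)},
        n_peaks={"minus": 300, "plus": 300},
        n_de_up=10, n_de_down=8,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset() -> SyntheticDataset:
    return SyntheticDataset.generate(small_synthetic_config(seed=1))


@pytest.fixture
def two_exon_plus() -> TranscriptModel:
    return TranscriptModel(
        transcript_id="t1", gene_id="g1", contig="chr1", strand="+",
        exons=[(0, 100), (200, 300)], cds_span=(50, 250))


@pytest.fixture
def two_exon_minus() -> TranscriptModel:
    return TranscriptModel(
        transcript_id="t1", gene_id="g1", contig="chr1", strand="-",
        exons=[(0, 100), (200, 300)], cds_span=(50, 250))


def random_transcript(rng: np.random.Generator, contig: str = "chr1",
                      start: int = 0) -> TranscriptModel:
    """Small random multi-exon protein-coding transcript for oracle tests."""
    n_exons = int(rng.integers(2, 6))
    pos = start + int(rng.integers(0, 50))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(20, 120))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(30, 200))
    span = (exons[0][0], exons[-1][1])
    lo = int(rng.integers(span[0], span[0] + (exons[0][1] - exons[0][0])))
    hi = int(rng.integers(exons[-1][0] + 1, span[1] + 1))
    if hi <= lo:
        lo, hi = exons[0][0] + 1, exons[-1][1] - 1
    strand = "+" if rng.random() < 0.5 else "-"
    return TranscriptModel(
        transcript_id=f"tx{int(rng.integers(1e6))}", gene_id="g",
        contig=contig, strand=strand, exons=exons, cds_span=(lo, hi))


def random_genome_for(models, rng: np.random.Generator) -> GenomeSequence:
    length = max(m.span[1] for m in models) + 10
    bases = rng.choice(list("ACGT"), size=length)
    return GenomeSequence({models[0].contig: "".join(bases)})
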