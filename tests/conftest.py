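import numpy as np
import pytest

from hotregions.genome import (
    ChromatinStateTrack,
    GeneModel,
    GenomeSpec,
    GenomicInterval,
    PeakSet,
)
from hotregions.simulate import SimConfig


@pytest.fixture(scope="session")
def genome10() -> GenomeSpec:
    """Single 10-Mb chromosome."""
    return GenomeSpec({"chr1": 10_000_000})


@pytest.fixture(scope="session")
def genome_small() -> GenomeSpec:
    return GenomeSpec({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_peakset(
    regulator: str,
    genome: GenomeSpec,
    n: int,
    rng: np.random.Generator,
    width: int = 200,
) -> PeakSet:
    """Uniform random peaks of fixed width, one per draw."""
    peaks = []
    for _ in range(n):
        chrom = genome.chrom_names[int(rng.integers(0, len(genome)))]
        start = int(rng.integers(0, genome.length(chrom) - width))
        peaks.append(
            GenomicInterval(chrom, start, start + width, summit=start + width // 2)
        )
    return PeakSet(regulator, "test", peaks)


@pytest.fixture(scope="session")
def toy_genes() -> list[GeneModel]:
    """Two genes on one chromosome used by the annotation fixtures.

    geneA: + strand, tx [20_000, 30_000), CDS [22_000, 28_000),
           exons [20_000,23_000) [25_000,28_500)
           (5' UTR 20_000-22_000, 3' UTR 28_000-28_500, intron 23_000-25_000)
    geneB: - strand, tx [50_000, 60_000), CDS [52_000, 58_000),
           single exon spanning the transcript (TSS at 59_999).
    """
    gene_a = GeneModel(
        gene_id="geneA",
        chrom="chr1",
        strand="+",
        tx_start=20_000,
        tx_end=30_000,
        cds_start=22_000,
        cds_end=28_000,
        exons=[(20_000, 23_000), (25_000, 28_500)],
    )
    gene_b = GeneModel(
        gene_id="geneB",
        chrom="chr1",
        strand="-",
        tx_start=50_000,
        tx_end=60_000,
        cds_start=52_000,
        cds_end=58_000,
        exons=[(50_000, 60_000)],
    )
    return [gene_a, gene_b]


@pytest.fixture(scope="session")
def toy_state_track() -> ChromatinStateTrack:
    """Hand-placed five-state segments on chr1."""
    segs = [
        GenomicInterval("chr1", 0, 5_000, name="BLACK"),
        GenomicInterval("chr1", 5_000, 6_000, name="BLUE"),
        GenomicInterval("chr1", 6_000, 8_000, name="RED"),
        GenomicInterval("chr1", 8_000, 9_000, name="YELLOW"),
        GenomicInterval("chr1", 9_000, 10_000, name="GREEN"),
        GenomicInterval("chr1", 10_000, 20_000, name="BLACK"),
        # gene A body: 100 bp of BLUE at its start, then YELLOW
        GenomicInterval("chr1", 20_000, 20_100, name="BLUE"),
        GenomicInterval("chr1", 20_100, 30_000, name="YELLOW"),
        # gene B body: two 60-bp BLUE islands
        GenomicInterval("chr1", 51_000, 51_060, name="BLUE"),
        GenomicInterval("chr1", 53_000, 53_060, name="BLUE"),
    ]
    return ChromatinStateTrack(segs)


@pytest.fixture(scope="session")
def tiny_sim_config() -> SimConfig:
    """Desk-scale synthetic study small enough for per-test use."""
    return SimConfig(
        seed=11,
        n_chroms=1,
        chrom_length=1_000_000,
        n_trfs=16,
        n_loci={"HOT": 6, "WARM": 6, "COLD": 6},
        multiplicity={"HOT": 16, "WARM": 8, "COLD": 2},
        n_genes=10,
    )
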