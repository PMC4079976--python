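"""Synthetic genomes with planted co-occupancy structure.

The generator emulates the structure of a multi-TRF ChIP peak
collection: a set of loci is planted along the genome, each bound by a
controlled number of distinct factors (its multiplicity) with Gaussian
positional jitter of the summits, on top of a uniform Poisson
background of factor-specific peaks.  Multiplicities are chosen per
expected occupancy class — >= 15 factors for HOT, <= 3 for COLD,
intermediate for WARM — so classifier recovery can be scored against
known truth.  Auxiliary tracks are generated consistently with the
planted loci: a five-color chromatin segmentation with a BLACK majority
and BLUE painted over designated Polycomb-target genes, a conservation
track elevated at low-occupancy loci and depressed at HOT centers, two
enhancer sets whose "open" class favours high-multiplicity loci, a
variant track with elevated density at HOT loci, and a random-uniform
genome sequence with a consensus motif planted at HOT loci.

Everything is driven by a single :class:`SimConfig` whose seed fully
determines every output; independent named substreams keep the pieces
reproducible independently of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .genome import (
    ChromatinStateTrack,
    EnhancerSet,
    GeneModel,
    GenomeSpec,
    GenomicInterval,
    PeakSet,
    ScoreTrack,
    STATE_PRIORITY,
)

__all__ = [
    "SimConfig",
    "PlantedLocus",
    "SyntheticTruth",
    "SimBundle",
    "make_genome_spec",
    "plan_loci",
    "make_genome_and_genes",
    "make_chromatin_track",
    "make_peak_collection",
    "make_aux_tracks",
    "simulate_all",
    "write_truth",
    "expected_class",
]

_LOCUS_SPACING = 5_000  # bp between planted-locus slots
_EDGE_MARGIN = 2_000  # keep loci away from chromosome ends

_STATE_WEIGHTS = {"BLACK": 0.50, "YELLOW": 0.18, "RED": 0.12, "GREEN": 0.12, "BLUE": 0.08}


def expected_class(multiplicity: int, hot: float = 15, cold: float = 3) -> str:
    if multiplicity >= hot:
        return "HOT"
    if multiplicity <= cold:
        return "COLD"
    return "WARM"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the standard desk-scale study: a 2 x 5-Mb genome,
    25 factors, 50 planted loci per class at multiplicities 20 / 8 / 2
    with 25-bp summit jitter, and a background of 1e-6 peaks per bp per
    factor.
    """

    seed: int
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_trfs: int = 25
    n_loci: Mapping[str, int] = field(
        default_factory=lambda: {"HOT": 50, "WARM": 50, "COLD": 50}
    )
    multiplicity: Mapping[str, int] = field(
        default_factory=lambda: {"HOT": 20, "WARM": 8, "COLD": 2}
    )
    jitter_sd: float = 25.0
    peak_width_mean: float = 200.0
    peak_width_sd: float = 40.0
    min_peak_width: int = 50
    background_rate: float = 1e-6
    # genes
    n_genes: int = 80
    gene_length: int = 8_000
    exons_per_gene: int = 3
    pc_target_fraction: float = 0.25
    # chromatin
    state_segment_length: int = 2_000
    pc_blue_length: int = 150
    # sequence / motif
    motif: str = "GAGAG"
    motif_rate: float = 0.8
    # conservation
    conservation_high: float = 0.8
    conservation_low: float = 0.2
    conservation_baseline: float = 0.45
    conservation_halfwidth: int = 150
    # enhancers
    enhancer_width: int = 300
    enhancer_prob: Mapping[str, float] = field(
        default_factory=lambda: {"HOT": 0.9, "WARM": 0.5, "COLD": 0.9}
    )
    enhancer_open_prob: Mapping[str, float] = field(
        default_factory=lambda: {"HOT": 0.9, "WARM": 0.5, "COLD": 0.1}
    )
    # variants
    variant_rate: float = 2e-3
    variant_hot_ratio: float = 2.0
    variant_window: int = 300

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_chroms", "chrom_length", "n_trfs", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if max(self.multiplicity.values(), default=0) > self.n_trfs:
            raise ValueError("multiplicity cannot exceed n_trfs")


@dataclass(frozen=True)
class PlantedLocus:
    chrom: str
    center: int
    multiplicity: int
    expected_class: str


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic peak collection."""

    planted_loci: list[PlantedLocus]
    background_rate: float
    jitter_sd: float
    seed: int

    def by_class(self, cls: str) -> list[PlantedLocus]:
        return [p for p in self.planted_loci if p.expected_class == cls]


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    """Named deterministic substream of the config seed."""
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(stream.encode())])
    )


def make_genome_spec(config: SimConfig) -> GenomeSpec:
    return GenomeSpec(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    )


def plan_loci(config: SimConfig) -> list[PlantedLocus]:
    """Deterministic planted-locus layout shared by every generator.

    Loci occupy distinct slots spaced 5 kb apart (>= 2.5 kb separation
    after within-slot jitter), away from chromosome ends, with class
    labels shuffled across slots.
    """
    genome = make_genome_spec(config)
    rng = _rng(config, "loci")
    slots: list[tuple[str, int]] = []
    for chrom in genome.chrom_names:
        usable = genome.length(chrom) - 2 * _EDGE_MARGIN
        for k in range(max(usable // _LOCUS_SPACING, 0)):
            slots.append((chrom, _EDGE_MARGIN + k * _LOCUS_SPACING + _LOCUS_SPACING // 2))
    want = [
        (cls, config.multiplicity[cls])
        for cls in ("HOT", "WARM", "COLD")
        for _ in range(config.n_loci.get(cls, 0))
    ]
    if len(want) > len(slots):
        raise ValueError(
            f"cannot place {len(want)} loci in {len(slots)} slots; "
            "enlarge the genome or reduce n_loci"
        )
    chosen = rng.choice(len(slots), size=len(want), replace=False)
    loci = []
    for (cls, mult), slot_idx in zip(want, chosen):
        chrom, base = slots[int(slot_idx)]
        center = int(base + rng.integers(-_LOCUS_SPACING // 4, _LOCUS_SPACING // 4 + 1))
        loci.append(PlantedLocus(chrom, center, mult, cls))
    loci.sort(key=lambda p: (p.chrom, p.center))
    return loci


def make_genome_and_genes(
    config: SimConfig,
) -> tuple[GenomeSpec, list[GeneModel], dict[str, str]]:
    """Genome spec, non-overlapping gene models and random sequence.

    Genes are packed on an even grid with seeded jitter, alternating
    strands; a seeded subset is flagged ``pc_target`` for the chromatin
    generator to cover with BLUE.  Sequence is uniform random ACGT with
    the consensus motif written in at HOT loci (probability
    ``motif_rate``).
    """
    genome = make_genome_spec(config)
    span = config.gene_length
    if config.chrom_length < 10 * span:
        raise ValueError("chrom_length must be >= 10x gene span")
    genes: list[GeneModel] = []
    if config.n_genes > 0:
        rng = _rng(config, "genes")
        per_chrom = -(-config.n_genes // max(config.n_chroms, 1))  # ceil
        pitch = config.chrom_length // (per_chrom + 1)
        if pitch <= span:
            raise ValueError("too many genes to pack without overlap")
        gene_idx = 0
        for chrom in genome.chrom_names:
            for k in range(per_chrom):
                if gene_idx >= config.n_genes:
                    break
                slack = pitch - span
                start = int(k * pitch + rng.integers(0, slack))
                end = start + span
                strand = "+" if gene_idx % 2 == 0 else "-"
                # evenly sized exons with fixed-fraction introns
                n_ex = max(config.exons_per_gene, 1)
                exon_len = span // (2 * n_ex)
                exons = []
                for e in range(n_ex):
                    a = start + e * (span // n_ex)
                    exons.append((a, min(a + exon_len, end)))
                cds_start = exons[0][0] + exon_len // 2
                cds_end = exons[-1][1] - exon_len // 4
                genes.append(
                    GeneModel(
                        gene_id=f"gene{gene_idx:04d}",
                        chrom=chrom,
                        strand=strand,
                        tx_start=start,
                        tx_end=end,
                        cds_start=cds_start,
                        cds_end=cds_end,
                        exons=exons,
                        pc_target=bool(rng.random() < config.pc_target_fraction),
                    )
                )
                gene_idx += 1
    sequences = _make_sequences(config, genome)
    return genome, genes, sequences


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _make_sequences(config: SimConfig, genome: GenomeSpec) -> dict[str, str]:
    rng = _rng(config, "sequence")
    motif_rng = _rng(config, "motif")
    sequences: dict[str, str] = {}
    planted = {
        (p.chrom, p.center): p
        for p in plan_loci(config)
        if p.expected_class == "HOT"
    }
    for chrom in genome.chrom_names:
        arr = _BASES[rng.integers(0, 4, size=genome.length(chrom), dtype=np.uint8)]
        sequences[chrom] = arr.tobytes().decode("ascii")
    if config.motif:
        mutable = {c: bytearray(s, "ascii") for c, s in sequences.items()}
        for (chrom, center), locus in sorted(planted.items()):
            if motif_rng.random() < config.motif_rate:
                start = max(min(center, len(mutable[chrom]) - len(config.motif)), 0)
                mutable[chrom][start : start + len(config.motif)] = config.motif.encode()
        sequences = {c: b.decode("ascii") for c, b in mutable.items()}
    return sequences


def _paint(segments: list[list], start: int, end: int, state: str) -> list[list]:
    """Overwrite [start,end) with *state* in a sorted tiling of
    [s,e,state] triples, splitting segments as needed."""
    out = []
    for s, e, st in segments:
        if e <= start or s >= end:
            out.append([s, e, st])
            continue
        if s < start:
            out.append([s, start, st])
        if e > end:
            out.append([end, e, st])
    out.append([start, end, state])
    out.sort()
    return out


def make_chromatin_track(
    config: SimConfig, genes: Sequence[GeneModel]
) -> ChromatinStateTrack:
    """Five-state tiling of the genome.

    Segment labels are drawn with a BLACK-majority weight (~half the
    genome, as in the Drosophila five-color segmentation); every gene
    flagged ``pc_target`` then gets a BLUE stretch (>= pc_blue_length
    bp) painted inside its gene unit so Pc-target calls have planted
    positives.
    """
    genome = make_genome_spec(config)
    rng = _rng(config, "chromatin")
    states = list(_STATE_WEIGHTS)
    weights = np.array([_STATE_WEIGHTS[s] for s in states])
    weights = weights / weights.sum()
    segments_all: list[GenomicInterval] = []
    for chrom in genome.chrom_names:
        length = genome.length(chrom)
        bounds = list(range(0, length, config.state_segment_length)) + [length]
        tiling: list[list] = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if a < b:
                label = states[int(rng.choice(len(states), p=weights))]
                tiling.append([a, b, label])
        for gene in genes:
            if gene.chrom != chrom or not gene.pc_target:
                continue
            blue_len = min(config.pc_blue_length, gene.tx_end - gene.tx_start)
            tiling = _paint(tiling, gene.tx_start, gene.tx_start + blue_len, "BLUE")
        for s, e, st in tiling:
            segments_all.append(GenomicInterval(chrom, s, e, name=st))
    return ChromatinStateTrack(segments_all)


def _draw_peak(
    chrom: str,
    length: int,
    summit: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> GenomicInterval:
    width = max(
        config.min_peak_width,
        int(round(rng.normal(config.peak_width_mean, config.peak_width_sd))),
    )
    width = min(width, length)
    summit = int(np.clip(summit, 0, length - 1))
    start = int(np.clip(summit - width // 2, 0, length - width))
    return GenomicInterval(chrom, start, start + width, summit=summit)


def make_peak_collection(
    config: SimConfig,
) -> tuple[list[PeakSet], SyntheticTruth]:
    """Peak sets for all factors plus the planted ground truth.

    At each planted locus, ``multiplicity`` distinct factors (seeded
    draw without replacement) each place one peak whose summit is
    Normal(center, jitter_sd) truncated to the chromosome; every factor
    additionally receives Poisson background peaks placed uniformly.
    """
    genome = make_genome_spec(config)
    loci = plan_loci(config)
    rng = _rng(config, "peaks")
    trf_names = [f"TRF{i + 1:02d}" for i in range(config.n_trfs)]
    peaks_per_trf: dict[str, list[GenomicInterval]] = {t: [] for t in trf_names}
    for locus in loci:
        length = genome.length(locus.chrom)
        members = rng.choice(config.n_trfs, size=locus.multiplicity, replace=False)
        for trf_idx in members:
            summit = int(round(rng.normal(locus.center, config.jitter_sd)))
            peaks_per_trf[trf_names[int(trf_idx)]].append(
                _draw_peak(locus.chrom, length, summit, config, rng)
            )
    for trf in trf_names:
        for chrom in genome.chrom_names:
            length = genome.length(chrom)
            n_bg = int(rng.poisson(config.background_rate * length))
            for summit in rng.integers(0, length, size=n_bg):
                peaks_per_trf[trf].append(
                    _draw_peak(chrom, length, int(summit), config, rng)
                )
    peaksets = [PeakSet(trf, "sim", peaks_per_trf[trf]) for trf in trf_names]
    truth = SyntheticTruth(loci, config.background_rate, config.jitter_sd, config.seed)
    return peaksets, truth


def make_aux_tracks(
    config: SimConfig,
    truth: SyntheticTruth,
    genes: Sequence[GeneModel] | None = None,
) -> tuple[ScoreTrack, list[EnhancerSet], list[tuple[str, int]]]:
    """Conservation, enhancer and variant tracks consistent with truth.

    Conservation is ``conservation_high`` over center +/- halfwidth at
    planted COLD/WARM loci, ``conservation_low`` at HOT centers, and
    ``conservation_baseline`` elsewhere (the genome-average level).  Two enhancer sets (contexts
    S2sim/OSCsim) place enhancers at planted loci with per-class
    probability, labelled open with per-class probability — open
    enhancers favour high-multiplicity loci.  Variants fall uniformly
    at ``variant_rate`` per bp, boosted by ``variant_hot_ratio`` inside
    HOT-locus windows.  Gene models are accepted for interface
    stability; the default tracks do not depend on them.
    """
    genome = make_genome_spec(config)
    hw = config.conservation_halfwidth
    runs = []
    windows_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for locus in truth.planted_loci:
        value = (
            config.conservation_low
            if locus.expected_class == "HOT"
            else config.conservation_high
        )
        start = max(locus.center - hw, 0)
        end = min(locus.center + hw, genome.length(locus.chrom))
        runs.append((GenomicInterval(locus.chrom, start, end), value))
        windows_by_chrom[locus.chrom].append((start, end))
    # genome-wide baseline between the locus windows, approximating the
    # typical genome-average conservation level
    if config.conservation_baseline > 0:
        for chrom, windows in windows_by_chrom.items():
            cursor = 0
            for start, end in sorted(windows):
                if start > cursor:
                    runs.append(
                        (GenomicInterval(chrom, cursor, start), config.conservation_baseline)
                    )
                cursor = max(cursor, end)
            if cursor < genome.length(chrom):
                runs.append(
                    (GenomicInterval(chrom, cursor, genome.length(chrom)),
                     config.conservation_baseline)
                )
    conservation = ScoreTrack(runs)

    enh_rng = _rng(config, "enhancers")
    enhancer_sets = []
    for context in ("S2sim", "OSCsim"):
        ivs, labels = [], []
        for locus in truth.planted_loci:
            if enh_rng.random() >= config.enhancer_prob.get(locus.expected_class, 0.0):
                continue
            label = (
                "open"
                if enh_rng.random() < config.enhancer_open_prob.get(locus.expected_class, 0.0)
                else "closed"
            )
            half = config.enhancer_width // 2
            start = max(locus.center - half, 0)
            end = min(locus.center + half, genome.length(locus.chrom))
            ivs.append(GenomicInterval(locus.chrom, start, end))
            labels.append(label)
        enhancer_sets.append(EnhancerSet(context, ivs, labels))

    var_rng = _rng(config, "variants")
    variants: list[tuple[str, int]] = []
    for chrom in genome.chrom_names:
        length = genome.length(chrom)
        n_bg = int(var_rng.poisson(config.variant_rate * length))
        variants.extend((chrom, int(p)) for p in var_rng.integers(0, length, size=n_bg))
    extra_rate = config.variant_rate * (config.variant_hot_ratio - 1.0)
    if extra_rate > 0:
        for locus in truth.by_class("HOT"):
            length = genome.length(locus.chrom)
            lo = max(locus.center - config.variant_window, 0)
            hi = min(locus.center + config.variant_window, length)
            n_extra = int(var_rng.poisson(extra_rate * (hi - lo)))
            variants.extend(
                (locus.chrom, int(p)) for p in var_rng.integers(lo, hi, size=n_extra)
            )
    variants.sort()
    return conservation, enhancer_sets, variants


@dataclass
class SimBundle:
    """Everything one synthetic study produces."""

    config: SimConfig
    genome: GenomeSpec
    genes: list[GeneModel]
    sequences: dict[str, str]
    chromatin: ChromatinStateTrack
    peaksets: list[PeakSet]
    truth: SyntheticTruth
    conservation: ScoreTrack
    enhancers: list[EnhancerSet]
    variants: list[tuple[str, int]]


def simulate_all(config: SimConfig) -> SimBundle:
    """Run every generator with consistent truth."""
    genome, genes, sequences = make_genome_and_genes(config)
    chromatin = make_chromatin_track(config, genes)
    peaksets, truth = make_peak_collection(config)
    conservation, enhancers, variants = make_aux_tracks(config, truth, genes)
    return SimBundle(
        config, genome, genes, sequences, chromatin, peaksets, truth,
        conservation, enhancers, variants,
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tcenter\tmultiplicity\texpected_class\n")
        for p in truth.planted_loci:
            fh.write(f"{p.chrom}\t{p.center}\t{p.multiplicity}\t{p.expected_class}\n")


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    for key in ("n_loci", "multiplicity", "enhancer_prob", "enhancer_open_prob"):
        d[key] = dict(d[key])
    return d
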