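"""Core genomic data types.

All coordinates are 0-based, half-open (BED convention). Any 1-based
input format is converted at the reader boundary, so every type in this
module carries a single internal convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GenomeSpec",
    "GenomicInterval",
    "PeakSet",
    "ChromatinStateTrack",
    "GeneModel",
    "ScoreTrack",
    "EnhancerSet",
    "CHROMATIN_STATES",
    "STATE_PRIORITY",
]

#: The five chromatin colors of the Drosophila five-state segmentation,
#: listed in annotation priority order (highest first).  BLUE is the
#: Polycomb-associated repressive state; YELLOW and RED are the two
#: active states; BLACK is the large silent state.
STATE_PRIORITY: tuple[str, ...] = ("BLUE", "RED", "YELLOW", "GREEN", "BLACK")
CHROMATIN_STATES: frozenset[str] = frozenset(STATE_PRIORITY)


class GenomeSpec:
    """Ordered chromosome names and lengths.

    Parameters
    ----------
    chrom_lengths
        Mapping of chromosome name to length in bp.  Iteration order of
        the mapping defines the canonical chromosome order used by every
        sorted output.
    """

    def __init__(self, chrom_lengths: Mapping[str, int]):
        names = list(chrom_lengths)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in chrom_lengths.items():
            if int(length) < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._lengths: dict[str, int] = {n: int(chrom_lengths[n]) for n in names}

    @property
    def chrom_names(self) -> list[str]:
        return list(self._lengths)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def chrom_order(self, chrom: str) -> int:
        """Index of *chrom* in the canonical order (for sorting)."""
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(chrom) from None

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeSpec) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"GenomeSpec({self._lengths!r})"


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally with a summit.

    ``summit`` is the single-bp point estimate of a binding position
    (narrowPeak column 10); when absent, point queries fall back to the
    interval midpoint.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    summit: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def point(self) -> int:
        """Summit if present, midpoint otherwise."""
        return self.summit if self.summit is not None else self.midpoint

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, new_start: int) -> "GenomicInterval":
        """Copy placed at *new_start*, preserving length and summit offset."""
        delta = new_start - self.start
        summit = None if self.summit is None else self.summit + delta
        return replace(self, start=new_start, end=self.end + delta, summit=summit)


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


@dataclass
class PeakSet:
    """One regulator-in-context ChIP peak set — the atomic analysis input.

    Peaks are kept sorted by (chrom, start); per-chromosome peaks need
    not be disjoint.
    """

    regulator: str
    context: str
    peaks: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sort_intervals(self.peaks)

    @property
    def label(self) -> str:
        return f"{self.regulator}_{self.context}"

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.peaks)

    def summits_on(self, chrom: str) -> list[int]:
        """Sorted summit (or midpoint) positions on one chromosome."""
        return sorted(p.point for p in self.peaks if p.chrom == chrom)

    def subset(self, keep: Sequence[bool]) -> "PeakSet":
        kept = [p for p, k in zip(self.peaks, keep) if k]
        return PeakSet(self.regulator, self.context, kept)


@dataclass
class ChromatinStateTrack:
    """Genome segmentation into the five chromatin colors.

    Segments must be non-overlapping within a chromosome and labelled
    with one of the five states.
    """

    segments: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.segments = sort_intervals(self.segments)
        prev: GenomicInterval | None = None
        for seg in self.segments:
            if seg.name not in CHROMATIN_STATES:
                raise ValueError(f"unknown chromatin state {seg.name!r}")
            if prev is not None and prev.chrom == seg.chrom and seg.start < prev.end:
                raise ValueError(
                    f"overlapping state segments at {seg.chrom}:{seg.start}"
                )
            prev = seg

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class GeneModel:
    """A gene with transcript extent, CDS and exon blocks.

    TSS is ``tx_start`` on the + strand and ``tx_end`` (exclusive
    coordinate, i.e. the last transcribed base + 1) on the − strand.
    A gene without CDS (non-coding) has ``cds_start == cds_end``.
    ``pc_target`` is an optional annotation flag used by the synthetic
    generator to mark genes deliberately given Polycomb (BLUE) chromatin.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: list[tuple[int, int]]
    pc_target: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start >= tx_end")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.gene_id}: CDS outside transcript")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = self.tx_start - 1
        for a, b in self.exons:
            if a >= b:
                raise ValueError(f"{self.gene_id}: empty exon ({a},{b})")
            if a < self.tx_start or b > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon outside transcript")
            if a < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = b

    @property
    def tss(self) -> int:
        """Transcription start position (0-based bp)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def has_cds(self) -> bool:
        return self.cds_end > self.cds_start


class ScoreTrack:
    """Sparse per-base score track (e.g. phastCons conservation).

    Stored as disjoint sorted runs of constant value; uncovered bases
    score 0 by convention (the absent-score default of conservation
    tracks).
    """

    def __init__(self, runs: Iterable[tuple[GenomicInterval, float]]):
        import numpy as np

        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, value in runs:
            v = float(value)
            if not np.isfinite(v):
                raise ValueError(f"non-finite track value at {iv.chrom}:{iv.start}")
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, v))
        self._runs: dict[str, tuple] = {}
        for chrom, rs in by_chrom.items():
            rs.sort()
            starts = np.array([r[0] for r in rs], dtype=np.int64)
            ends = np.array([r[1] for r in rs], dtype=np.int64)
            values = np.array([r[2] for r in rs], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping score runs on {chrom}")
            self._runs[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return list(self._runs)

    def iter_runs(self) -> Iterator[tuple[GenomicInterval, float]]:
        for chrom, (starts, ends, values) in self._runs.items():
            for s, e, v in zip(starts, ends, values):
                yield GenomicInterval(chrom, int(s), int(e)), float(v)

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean over [start, end); uncovered bases = 0."""
        if end <= start:
            raise ValueError("empty query interval")
        total = 0.0
        if chrom in self._runs:
            import numpy as np

            starts, ends, values = self._runs[chrom]
            lo = int(np.searchsorted(ends, start, side="right"))
            hi = int(np.searchsorted(starts, end, side="left"))
            if hi > lo:
                s = np.maximum(starts[lo:hi], start)
                e = np.minimum(ends[lo:hi], end)
                total = float(np.sum((e - s) * values[lo:hi]))
        return total / (end - start)

    def values(self, chrom: str, start: int, end: int):
        """Dense per-base values over [start, end) as a numpy array."""
        import numpy as np

        out = np.zeros(end - start, dtype=float)
        if chrom in self._runs:
            starts, ends, values = self._runs[chrom]
            lo = int(np.searchsorted(ends, start, side="right"))
            hi = int(np.searchsorted(starts, end, side="left"))
            for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
                out[max(s - start, 0) : max(min(e, end) - start, 0)] = v
        return out


@dataclass
class EnhancerSet:
    """Enhancers from one cell context, each labelled open or closed.

    "Open" enhancers coincide with accessible (DNase I hypersensitive)
    DNA; "closed" enhancers are active episomally but inaccessible in
    their native chromatin.
    """

    cell_context: str
    enhancers: list[GenomicInterval] = field(default_factory=list)
    class_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.enhancers) != len(self.class_labels):
            raise ValueError("enhancers and class_labels differ in length")
        bad = set(self.class_labels) - {"open", "closed"}
        if bad:
            raise ValueError(f"enhancer class labels must be open/closed, got {bad}")

    def of_class(self, label: str) -> list[GenomicInterval]:
        return [e for e, c in zip(self.enhancers, self.class_labels) if c == label]

    def __len__(self) -> int:
        return len(self.enhancers)
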