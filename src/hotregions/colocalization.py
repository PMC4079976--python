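"""Permutation-based TRF-TRF colocalization Z-scores.

For a pair of peak sets the colocalization statistic is the number of
peaks of the smaller set that overlap (>= 1 bp) at least one peak of the
other.  The null distribution comes from repeatedly re-placing the first
set's peaks uniformly at random on their own chromosomes (length- and
chromosome-preserving shuffle, overlaps among shuffled peaks allowed)
while the second set stays fixed; Z = (observed - null mean) / null sd.
An optional mask (typically HOT-region extents) removes peaks of both
sets that overlap any masked interval before any computation, which
isolates the pairwise signal from the promiscuous co-binding at HOT
regions.

Two entry points: :func:`coloc_matrix` computes every unordered pair of
a collection with per-pair deterministic RNG streams, and
:class:`ColocalizationModel` wraps it in a model/results pair.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSpec, GenomicInterval, PeakSet
from .intervals import IntervalIndex, merge_intervals

__all__ = [
    "PairwiseColoc",
    "ColocMatrix",
    "shuffle_peaks",
    "pairwise_zscore",
    "coloc_matrix",
    "trf_region_enrichment",
    "ColocalizationModel",
    "ColocalizationResults",
]

DEFAULT_N_PERM = 10_000


@dataclass(frozen=True)
class PairwiseColoc:
    """One pairwise colocalization result.

    degenerate is set when a Z-score could not be defined (an empty set
    after masking, or a zero-variance null that the observed count does
    not match).
    """

    set_a: str
    set_b: str
    observed: int
    null_mean: float
    null_sd: float
    z: float
    n_perm: int
    degenerate: bool = False


def shuffle_peaks(peakset: PeakSet, genome: GenomeSpec, rng: np.random.Generator) -> PeakSet:
    """Chromosome- and length-preserving uniform re-placement.

    Each peak keeps its chromosome and length; its start is redrawn
    uniformly on [0, chrom_length - length] and the summit offset is
    preserved relative to the start.
    """
    moved = []
    for peak in peakset.peaks:
        space = genome.length(peak.chrom) - peak.length
        if space < 0:
            raise ValueError(
                f"peak of length {peak.length} exceeds chromosome {peak.chrom}"
            )
        new_start = int(rng.integers(0, space + 1))
        moved.append(peak.shifted(new_start))
    return PeakSet(peakset.regulator, peakset.context, moved)


def _masked(peakset: PeakSet, mask_index: IntervalIndex | None) -> PeakSet:
    if mask_index is None:
        return peakset
    kept = [p for p in peakset.peaks if not mask_index.any_overlap(p)]
    return PeakSet(peakset.regulator, peakset.context, kept)


class _MergedSubject:
    """Merged subject intervals per chromosome for fast overlap counting."""

    def __init__(self, peaks: Sequence[GenomicInterval]):
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        for iv in merge_intervals(peaks):
            starts.setdefault(iv.chrom, []).append(iv.start)
            ends.setdefault(iv.chrom, []).append(iv.end)
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {
            c: (np.asarray(starts[c]), np.asarray(ends[c])) for c in starts
        }

    def count_overlapping(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """For row-vectors of query starts/ends (any shape), a boolean
        array marking queries that overlap >= 1 subject interval."""
        if chrom not in self.by_chrom:
            return np.zeros(starts.shape, dtype=bool)
        s_sub, e_sub = self.by_chrom[chrom]
        # a query [s,e) overlaps some merged interval iff the first
        # interval with end > s exists and starts before e
        idx = np.searchsorted(e_sub, starts, side="right")
        hit = idx < len(s_sub)
        safe = np.where(hit, idx, 0)
        return hit & (s_sub[safe] < ends)


def _observed_count(a: PeakSet, subject: _MergedSubject) -> int:
    count = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in a.peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, peaks in by_chrom.items():
        starts = np.array([p.start for p in peaks])
        ends = np.array([p.end for p in peaks])
        count += int(subject.count_overlapping(chrom, starts, ends).sum())
    return count


def _null_counts(
    a: PeakSet,
    subject: _MergedSubject,
    genome: GenomeSpec,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Overlap counts for n_perm shuffles of *a*, vectorized per chromosome."""
    totals = np.zeros(n_perm, dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for p in a.peaks:
        by_chrom.setdefault(p.chrom, []).append(p.length)
    for chrom, lengths in by_chrom.items():
        lengths_arr = np.asarray(lengths, dtype=np.int64)
        space = genome.length(chrom) - lengths_arr
        if np.any(space < 0):
            raise ValueError(f"peak longer than chromosome {chrom}")
        # (n_perm, n_peaks) random starts; integers high is exclusive
        starts = rng.integers(0, space + 1, size=(n_perm, len(lengths_arr)))
        ends = starts + lengths_arr
        totals += subject.count_overlapping(chrom, starts, ends).sum(axis=1)
    return totals


def _zscore(observed: int, null: np.ndarray) -> tuple[float, float, float, bool]:
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    if null_sd == 0.0:
        if observed == null_mean:
            return null_mean, 0.0, 0.0, False
        return null_mean, 0.0, float("nan"), True
    return null_mean, null_sd, (observed - null_mean) / null_sd, False


def pairwise_zscore(
    a: PeakSet,
    b: PeakSet,
    genome: GenomeSpec,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
    mask: Sequence[GenomicInterval] | None = None,
) -> PairwiseColoc:
    """Permutation Z-score for the overlap of peak set *a* with *b*.

    *a* is shuffled; *b* stays fixed.  With a mask, peaks of both sets
    overlapping any mask interval are removed first.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    mask_index = IntervalIndex(mask) if mask else None
    a_m, b_m = _masked(a, mask_index), _masked(b, mask_index)
    if len(a_m) == 0 or len(b_m) == 0:
        return PairwiseColoc(
            a.label, b.label, 0, float("nan"), float("nan"), float("nan"),
            n_perm, degenerate=True,
        )
    subject = _MergedSubject(b_m.peaks)
    observed = _observed_count(a_m, subject)
    null = _null_counts(a_m, subject, genome, n_perm, rng)
    null_mean, null_sd, z, degenerate = _zscore(observed, null)
    return PairwiseColoc(a.label, b.label, observed, null_mean, null_sd, z, n_perm, degenerate)


def _pair_seed(master_seed: int, label_a: str, label_b: str) -> int:
    """Deterministic per-pair seed, independent of input order."""
    lo, hi = sorted((label_a, label_b))
    digest = hashlib.sha256(f"{master_seed}|{lo}|{hi}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ColocMatrix:
    """All-pairs colocalization results."""

    identifiers: list[str]
    cells: dict[frozenset, PairwiseColoc]
    n_perm: int
    masked: bool = False

    def get(self, label_a: str, label_b: str) -> PairwiseColoc:
        return self.cells[frozenset((label_a, label_b))]

    def z_frame(self) -> pd.DataFrame:
        """Square symmetric Z matrix (diagonal NaN)."""
        n = len(self.identifiers)
        mat = np.full((n, n), np.nan)
        idx = {lab: i for i, lab in enumerate(self.identifiers)}
        for key, cell in self.cells.items():
            la, lb = tuple(key)
            i, j = idx[la], idx[lb]
            mat[i, j] = mat[j, i] = cell.z
        return pd.DataFrame(mat, index=self.identifiers, columns=self.identifiers)

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for i, la in enumerate(self.identifiers):
            for lb in self.identifiers[i + 1 :]:
                c = self.get(la, lb)
                rows.append(
                    {
                        "set_a": c.set_a,
                        "set_b": c.set_b,
                        "observed": c.observed,
                        "null_mean": c.null_mean,
                        "null_sd": c.null_sd,
                        "z": c.z,
                        "degenerate": c.degenerate,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["set_a", "set_b", "observed", "null_mean", "null_sd", "z", "degenerate"],
        )


def coloc_matrix(
    sets: Sequence[PeakSet],
    genome: GenomeSpec,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    mask: Sequence[GenomicInterval] | None = None,
) -> ColocMatrix:
    """Pairwise Z-score matrix over every unordered pair of peak sets.

    Each pair gets its own RNG stream derived from the master seed and
    the sorted pair labels, so results do not depend on input order.
    Within a pair the smaller set is shuffled (ties broken by label).
    """
    if len(sets) < 2:
        raise ValueError("need at least two peak sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate peak-set identifiers")
    cells: dict[frozenset, PairwiseColoc] = {}
    for i, a in enumerate(sets):
        for b in sets[i + 1 :]:
            first, second = sorted((a, b), key=lambda s: (len(s), s.label))
            rng = np.random.default_rng(_pair_seed(seed, a.label, b.label))
            cells[frozenset((a.label, b.label))] = pairwise_zscore(
                first, second, genome, n_perm=n_perm, rng=rng, mask=mask
            )
    return ColocMatrix(labels, cells, n_perm, masked=mask is not None and len(mask) > 0)


def trf_region_enrichment(
    peakset: PeakSet,
    regions: Sequence[GenomicInterval],
    genome: GenomeSpec,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
) -> PairwiseColoc:
    """Z-score for a peak set's enrichment in a fixed region set
    (e.g. binding at HOT regions); the peak set is shuffled, the
    regions stay fixed."""
    if not regions:
        raise ValueError("regions must be non-empty")
    rng = rng if rng is not None else np.random.default_rng()
    if len(peakset) == 0:
        return PairwiseColoc(
            peakset.label, "regions", 0, float("nan"), float("nan"), float("nan"),
            n_perm, degenerate=True,
        )
    subject = _MergedSubject(regions)
    observed = _observed_count(peakset, subject)
    null = _null_counts(peakset, subject, genome, n_perm, rng)
    null_mean, null_sd, z, degenerate = _zscore(observed, null)
    return PairwiseColoc(
        peakset.label, "regions", observed, null_mean, null_sd, z, n_perm, degenerate
    )


class ColocalizationModel:
    """Model object for the all-pairs colocalization analysis.

    fit() computes the full matrix; pass ``mask`` (typically HOT-region
    extents from :class:`~hotregions.occupancy.OccupancyResults`) to
    compute the HOT-excluded variant.
    """

    def __init__(
        self,
        peaksets: Sequence[PeakSet],
        genome: GenomeSpec,
        mask: Sequence[GenomicInterval] | None = None,
    ):
        self.peaksets = list(peaksets)
        self.genome = genome
        self.mask = list(mask) if mask is not None else None

    def fit(self, n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> "ColocalizationResults":
        matrix = coloc_matrix(
            self.peaksets, self.genome, n_perm=n_perm, seed=seed, mask=self.mask
        )
        return ColocalizationResults(self, matrix)


@dataclass
class ColocalizationResults:
    model: ColocalizationModel
    matrix: ColocMatrix = field(default=None)  # type: ignore[assignment]

    @property
    def z_matrix(self) -> pd.DataFrame:
        return self.matrix.z_frame()

    def to_frame(self) -> pd.DataFrame:
        return self.matrix.long_frame()

    def summary(self) -> str:
        long = self.matrix.long_frame()
        ok = long[~long["degenerate"]]
        lines = [
            "Pairwise colocalization",
            "=" * 48,
            f"Peak sets:   {len(self.matrix.identifiers)}",
            f"Pairs:       {len(long)} ({int(long['degenerate'].sum())} degenerate)",
            f"Permutations:{self.matrix.n_perm:>6}",
            f"Masked:      {self.matrix.masked}",
        ]
        if len(ok):
            lines += [
                f"Z range:     [{ok['z'].min():.2f}, {ok['z'].max():.2f}]",
                f"Z median:    {ok['z'].median():.2f}",
            ]
        return "\n".join(lines)
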