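"""HOT/WARM/COLD occupancy-region detection.

The occupancy score ("complexity") of a genomic position measures how
many distinct transcription-related factors (TRFs) bind at or near it.
Peak centers of all factors are pooled and a Gaussian kernel density
(300-bp bandwidth, unnormalized kernel ``exp(-d^2 / 2h^2)``) is scanned
along each chromosome; every local maximum of the density is a candidate
region.  The complexity of a candidate is the sum, over peak sets, of
the kernelized distance to that set's nearest peak center, counting only
sets contributing at least 0.1.  With the unnormalized kernel a factor
bound exactly at the candidate contributes 1, so complexity is on the
scale of "number of co-bound factors": candidates with complexity >= 15
are HOT, <= 3 are COLD, and everything between is WARM.

The module exposes both the individual algorithm steps (``kde_density``,
``find_candidates``, ``region_complexity``, ``classify_regions``) and a
model/results pair (:class:`OccupancyModel` / :class:`OccupancyResults`)
for the common fit-then-inspect workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeSpec, GenomicInterval, PeakSet

__all__ = [
    "OccupancyParams",
    "OccupancyRegion",
    "kde_density",
    "find_candidates",
    "region_complexity",
    "classify_regions",
    "classify_complexity",
    "OccupancyModel",
    "OccupancyResults",
]

#: Kernel contributions beyond this many bandwidths are truncated; each
#: dropped term is < 1.3e-14, far below every tolerance in use.
_TRUNCATE_BW = 8.0

#: Density below which a local maximum is not reported as a candidate.
_MIN_CANDIDATE_DENSITY = 1e-3


@dataclass(frozen=True)
class OccupancyParams:
    """Tunable parameters of the occupancy classifier.

    bandwidth
        Gaussian kernel bandwidth h in bp.
    min_contribution
        Minimum kernelized contribution for a peak set to count toward
        a candidate's complexity.
    hot_threshold / cold_threshold
        Complexity >= hot_threshold -> HOT; <= cold_threshold -> COLD;
        strictly between -> WARM.
    region_halfwidth
        Half-width of the reported region extent around the density
        maximum; defaults to one bandwidth.
    grid_step
        Density scan step in bp; must be <= bandwidth / 10 to resolve
        every maximum of the kernel.
    """

    bandwidth: float = 300.0
    min_contribution: float = 0.1
    hot_threshold: float = 15.0
    cold_threshold: float = 3.0
    region_halfwidth: int | None = None
    grid_step: int = 10

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if not (0 < self.min_contribution < 1):
            raise ValueError("min_contribution must be in (0, 1)")
        if self.cold_threshold >= self.hot_threshold:
            raise ValueError("cold_threshold must be < hot_threshold")
        if self.grid_step <= 0 or self.grid_step > self.bandwidth / 10:
            raise ValueError("grid_step must be in (0, bandwidth/10]")

    @property
    def halfwidth(self) -> int:
        return int(self.bandwidth) if self.region_halfwidth is None else self.region_halfwidth


@dataclass
class OccupancyRegion:
    """A classified density maximum.

    complexity equals the sum of the listed contributor contributions;
    every contribution is >= the min_contribution cutoff.
    """

    chrom: str
    center: int
    extent: GenomicInterval
    complexity: float
    contributors: list[tuple[str, float]]
    region_class: str

    @property
    def n_contributors(self) -> int:
        return len(self.contributors)


def kde_density(
    peak_centers: Sequence[int] | np.ndarray,
    positions: Sequence[int] | np.ndarray,
    params: OccupancyParams | None = None,
) -> np.ndarray:
    """Unnormalized Gaussian kernel density at the given positions.

    density(x) = sum_c exp(-(x - c)^2 / (2 h^2)) over all centers c on
    the same chromosome.  The full sum is evaluated (no truncation), so
    the result matches a brute-force oracle to rounding error even at
    positions far from every center.  An empty center list gives
    density 0 everywhere.
    """
    params = params or OccupancyParams()
    h = params.bandwidth
    centers = np.asarray(sorted(peak_centers), dtype=float)
    pos = np.atleast_1d(np.asarray(positions, dtype=float))
    out = np.zeros(pos.shape, dtype=float)
    if centers.size == 0:
        return out
    inv = 1.0 / (2.0 * h * h)
    # chunk positions to bound the (positions x centers) workspace
    chunk = max(1, int(4e6 // max(centers.size, 1)))
    for i in range(0, pos.size, chunk):
        d = pos[i : i + chunk, None] - centers[None, :]
        out[i : i + chunk] = np.exp(-d * d * inv).sum(axis=1)
    return out


def _scan_density(centers: np.ndarray, chrom_length: int, params: OccupancyParams):
    """Density on the regular scan grid [0, chrom_length) step grid_step.

    Adds each center's kernel to its grid window; O(n_centers * window).
    """
    step = params.grid_step
    h = params.bandwidth
    n_grid = int(np.ceil(chrom_length / step))
    grid = np.arange(n_grid, dtype=np.int64) * step
    density = np.zeros(n_grid, dtype=float)
    radius = _TRUNCATE_BW * h
    inv = 1.0 / (2.0 * h * h)
    for c in centers:
        a = max(int(np.ceil((c - radius) / step)), 0)
        b = min(int(np.floor((c + radius) / step)) + 1, n_grid)
        if b > a:
            d = grid[a:b] - c
            density[a:b] += np.exp(-d * d * inv)
    return grid, density


def find_candidates(
    density: np.ndarray,
    grid: np.ndarray,
    min_density: float = _MIN_CANDIDATE_DENSITY,
) -> list[int]:
    """Local maxima of a gridded density scan.

    A maximum must be strictly greater than both neighbouring distinct
    values; a flat plateau reports its leftmost grid point.  Maxima with
    density below *min_density* are discarded.
    """
    density = np.asarray(density, dtype=float)
    if density.size == 0:
        return []
    # run-length encode so plateaus collapse to single runs
    change = np.flatnonzero(np.diff(density) != 0)
    run_starts = np.concatenate(([0], change + 1))
    run_values = density[run_starts]
    out: list[int] = []
    for k, (start, value) in enumerate(zip(run_starts, run_values)):
        if value < min_density:
            continue
        left_ok = k == 0 or run_values[k - 1] < value
        right_ok = k == len(run_values) - 1 or run_values[k + 1] < value
        if left_ok and right_ok:
            out.append(int(grid[start]))
    return out


def region_complexity(
    center: int,
    peaksets: Sequence[PeakSet],
    chrom: str,
    params: OccupancyParams | None = None,
    summit_cache: dict[tuple[str, str], np.ndarray] | None = None,
) -> tuple[float, list[tuple[str, float]]]:
    """Complexity of a candidate center and its contributing peak sets.

    For each peak set the contribution is the kernelized distance to the
    set's nearest peak center on the chromosome, i.e.
    ``max_s exp(-(center - s)^2 / 2 h^2)``; sets below the
    min_contribution cutoff are excluded.  All peak sets are summed —
    density maxima are not owned by any single regulator, and with the
    unit kernel this makes complexity approximate the number of
    co-bound factors.
    """
    params = params or OccupancyParams()
    inv = 1.0 / (2.0 * params.bandwidth**2)
    contributors: list[tuple[str, float]] = []
    total = 0.0
    for ps in peaksets:
        if summit_cache is not None:
            key = (ps.label, chrom)
            summits = summit_cache.get(key)
            if summits is None:
                summits = np.asarray(ps.summits_on(chrom), dtype=float)
                summit_cache[key] = summits
        else:
            summits = np.asarray(ps.summits_on(chrom), dtype=float)
        if summits.size == 0:
            continue
        idx = int(np.searchsorted(summits, center))
        best = np.inf
        if idx < summits.size:
            best = summits[idx] - center
        if idx > 0:
            best = min(abs(best), abs(center - summits[idx - 1]))
        c = float(np.exp(-(best * best) * inv))
        if c >= params.min_contribution:
            contributors.append((ps.label, c))
            total += c
    return total, contributors


def classify_complexity(complexity: float, params: OccupancyParams) -> str:
    if complexity >= params.hot_threshold:
        return "HOT"
    if complexity <= params.cold_threshold:
        return "COLD"
    return "WARM"


def classify_regions(
    peaksets: Sequence[PeakSet],
    genome: GenomeSpec,
    params: OccupancyParams | None = None,
) -> list[OccupancyRegion]:
    """Full occupancy scan: density, candidates, complexity, class.

    Density is computed per chromosome (kernels never straddle
    chromosome boundaries).  Output is sorted by (chromosome order,
    center).
    """
    if not peaksets:
        raise ValueError("need at least one PeakSet")
    params = params or OccupancyParams()
    regions: list[OccupancyRegion] = []
    cache: dict[tuple[str, str], np.ndarray] = {}
    for chrom in genome.chrom_names:
        length = genome.length(chrom)
        centers = np.sort(
            np.concatenate(
                [np.asarray(ps.summits_on(chrom), dtype=float) for ps in peaksets]
            )
        )
        if centers.size == 0:
            continue
        grid, density = _scan_density(centers, length, params)
        for center in find_candidates(density, grid):
            complexity, contributors = region_complexity(
                center, peaksets, chrom, params, summit_cache=cache
            )
            hw = params.halfwidth
            extent = GenomicInterval(
                chrom, max(center - hw, 0), min(center + hw, length)
            )
            regions.append(
                OccupancyRegion(
                    chrom=chrom,
                    center=center,
                    extent=extent,
                    complexity=complexity,
                    contributors=contributors,
                    region_class=classify_complexity(complexity, params),
                )
            )
    return regions


class OccupancyModel:
    """Occupancy classifier over a collection of ChIP peak sets.

    Parameters
    ----------
    peaksets
        The TRF peak sets to pool.
    genome
        Chromosome names and lengths.
    params
        :class:`OccupancyParams`; defaults follow the published
        procedure (300-bp bandwidth, 0.1 cutoff, 15/3 thresholds).

    Examples
    --------
    >>> res = OccupancyModel(peaksets, genome).fit()
    >>> res.class_counts()["HOT"]
    """

    def __init__(
        self,
        peaksets: Sequence[PeakSet],
        genome: GenomeSpec,
        params: OccupancyParams | None = None,
    ):
        self.peaksets = list(peaksets)
        self.genome = genome
        self.params = params or OccupancyParams()

    def fit(self) -> "OccupancyResults":
        regions = classify_regions(self.peaksets, self.genome, self.params)
        return OccupancyResults(self, regions)


@dataclass
class OccupancyResults:
    """Fitted occupancy regions with tabular and summary views."""

    model: OccupancyModel
    regions: list[OccupancyRegion] = field(default_factory=list)

    def of_class(self, region_class: str) -> list[OccupancyRegion]:
        return [r for r in self.regions if r.region_class == region_class]

    def class_counts(self) -> dict[str, int]:
        counts = {"HOT": 0, "WARM": 0, "COLD": 0}
        for r in self.regions:
            counts[r.region_class] += 1
        return counts

    def extents(self, region_class: str | None = None) -> list[GenomicInterval]:
        regs = self.regions if region_class is None else self.of_class(region_class)
        return [r.extent for r in regs]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chrom": r.chrom,
                "center": r.center,
                "start": r.extent.start,
                "end": r.extent.end,
                "complexity": r.complexity,
                "class": r.region_class,
                "n_contributors": r.n_contributors,
                "contributors": ";".join(f"{n}:{c:.4f}" for n, c in r.contributors),
            }
            for r in self.regions
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "chrom",
                "center",
                "start",
                "end",
                "complexity",
                "class",
                "n_contributors",
                "contributors",
            ],
        )

    def to_bed(self, path, region_class: str) -> None:
        """BED6 of one class: name = class, score = 10x complexity
        rounded, capped at 1000 (BED score range)."""
        regs = self.of_class(region_class)
        with open(path, "w") as fh:
            for r in regs:
                score = min(int(round(r.complexity * 10)), 1000)
                fh.write(
                    f"{r.chrom}\t{r.extent.start}\t{r.extent.end}\t"
                    f"{r.region_class}\t{score}\t.\n"
                )

    def summary(self) -> str:
        counts = self.class_counts()
        p = self.model.params
        comp = np.array([r.complexity for r in self.regions])
        lines = [
            "Occupancy classification",
            "=" * 48,
            f"Peak sets:        {len(self.model.peaksets)}",
            f"Regions:          {len(self.regions)}",
            f"  HOT  (>= {p.hot_threshold:g}):  {counts['HOT']}",
            f"  WARM:           {counts['WARM']}",
            f"  COLD (<= {p.cold_threshold:g}):   {counts['COLD']}",
            f"Bandwidth:        {p.bandwidth:g} bp",
            f"Contribution cut: {p.min_contribution:g}",
        ]
        if comp.size:
            lines.append(
                f"Complexity:       median {np.median(comp):.2f}, max {comp.max():.2f}"
            )
        return "\n".join(lines)
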