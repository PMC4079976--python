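"""Peak annotation: genomic feature categories, chromatin states,
target genes and Polycomb-target calls.

Feature categories follow the classic promoter / coding / downstream /
intron / intergenic partition: promoter = within 1 kb upstream of a TSS
or in the 5' UTR; downstream = 3' UTR or within 200 bp past the gene
end; coding = CDS; intron = transcribed non-exonic DNA.  A peak is
classified by its summit (midpoint when no summit), and when the point
falls in features of several genes the priority is
promoter > downstream > coding > intron.

Chromatin-state assignment uses whole-peak overlap with the five-color
segmentation and the priority BLUE > RED > YELLOW > GREEN > BLACK when a
peak touches several states.  A gene is called a Polycomb (Pc) target
when its gene unit [tx_start, tx_end) contains at least 100 bp of BLUE
chromatin, summed over segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import (
    ChromatinStateTrack,
    GeneModel,
    GenomicInterval,
    PeakSet,
    STATE_PRIORITY,
)
from .intervals import IntervalIndex

__all__ = [
    "FEATURE_CATEGORIES",
    "AnnotationParams",
    "GeneFeatureIndex",
    "assign_genomic_feature",
    "assign_target_gene",
    "assign_chromatin_state",
    "chromatin_state_fractions",
    "feature_fractions",
    "pc_target_call",
    "annotate_peakset",
]

FEATURE_CATEGORIES = ("promoter", "coding", "downstream", "intron", "intergenic")

#: Category precedence when a point hits features of multiple genes:
#: regulatory categories outrank transcribed ones.
_FEATURE_PRIORITY = ("promoter", "downstream", "coding", "intron")

_STATE_RANK = {state: i for i, state in enumerate(STATE_PRIORITY)}


@dataclass(frozen=True)
class AnnotationParams:
    """Distance parameters of the annotation rules (bp unless noted).

    promoter_upstream: promoter window upstream of the TSS.
    downstream_extent: downstream window past the gene end.
    tss_assign_max: maximum peak-to-TSS distance for target-gene
        assignment.
    pc_min_blue: minimum summed BLUE bp in a gene unit for a Pc call.
    blue_preference_min: fraction (not bp); a TRF "prefers" BLUE when
        strictly more than this fraction of its peaks sit in BLUE.
    """

    promoter_upstream: int = 1000
    downstream_extent: int = 200
    tss_assign_max: int = 10_000
    pc_min_blue: int = 100
    blue_preference_min: float = 0.35

    def __post_init__(self) -> None:
        if min(self.promoter_upstream, self.downstream_extent,
               self.tss_assign_max, self.pc_min_blue) <= 0:
            raise ValueError("all distance parameters must be positive")
        if not (0 < self.blue_preference_min < 1):
            raise ValueError("blue_preference_min must be in (0,1)")


def _subtract(block: tuple[int, int], holes: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference block \\ union(holes), holes sorted disjoint."""
    out = []
    cur = block[0]
    for a, b in holes:
        a, b = max(a, block[0]), min(b, block[1])
        if a >= b:
            continue
        if a > cur:
            out.append((cur, a))
        cur = max(cur, b)
    if cur < block[1]:
        out.append((cur, block[1]))
    return out


def _gene_feature_intervals(gene: GeneModel, params: AnnotationParams):
    """Per-gene sub-feature intervals, strand aware.

    Yields (category, start, end) half-open blocks.  For genes without
    CDS there are no coding/UTR blocks: exonic hits fall through to the
    intron-priority level, i.e. the whole transcript is intron-level.
    """
    feats: list[tuple[str, int, int]] = []
    up = params.promoter_upstream
    down = params.downstream_extent
    if gene.strand == "+":
        feats.append(("promoter", max(gene.tx_start - up, 0), gene.tx_start))
        feats.append(("downstream", gene.tx_end, gene.tx_end + down))
    else:
        feats.append(("promoter", gene.tx_end, gene.tx_end + up))
        feats.append(("downstream", max(gene.tx_start - down, 0), gene.tx_start))
    if gene.has_cds:
        utr5: list[tuple[int, int]] = []
        utr3: list[tuple[int, int]] = []
        cds: list[tuple[int, int]] = []
        for a, b in gene.exons:
            lo = (a, min(b, gene.cds_start))
            hi = (max(a, gene.cds_end), b)
            mid = (max(a, gene.cds_start), min(b, gene.cds_end))
            if lo[0] < lo[1]:
                (utr5 if gene.strand == "+" else utr3).append(lo)
            if hi[0] < hi[1]:
                (utr3 if gene.strand == "+" else utr5).append(hi)
            if mid[0] < mid[1]:
                cds.append(mid)
        feats += [("promoter", a, b) for a, b in utr5]  # 5' UTR counts as promoter
        feats += [("downstream", a, b) for a, b in utr3]  # 3' UTR counts as downstream
        feats += [("coding", a, b) for a, b in cds]
        exonic = sorted(gene.exons)
        for a, b in _subtract((gene.tx_start, gene.tx_end), exonic):
            feats.append(("intron", a, b))
    else:
        # non-coding gene: entire transcript classifies at intron priority
        feats.append(("intron", gene.tx_start, gene.tx_end))
    return [(c, a, b) for c, a, b in feats if a < b]


class GeneFeatureIndex:
    """Point-queryable index of gene sub-features for a gene collection."""

    def __init__(self, genes: Iterable[GeneModel], params: AnnotationParams | None = None):
        self.params = params or AnnotationParams()
        labelled: list[GenomicInterval] = []
        self._tss: dict[str, list[tuple[int, str]]] = {}
        for gene in genes:
            for cat, a, b in _gene_feature_intervals(gene, self.params):
                labelled.append(GenomicInterval(gene.chrom, a, b, name=cat))
            self._tss.setdefault(gene.chrom, []).append((gene.tss, gene.gene_id))
        for chrom in self._tss:
            self._tss[chrom].sort()
        self._index = IntervalIndex(labelled)

    def feature_at(self, chrom: str, pos: int) -> str:
        hits = {iv.name for iv in self._index.overlapping_point(chrom, pos)}
        for cat in _FEATURE_PRIORITY:
            if cat in hits:
                return cat
        return "intergenic"

    def nearest_tss(self, chrom: str, pos: int) -> tuple[int, str] | None:
        """(distance, gene_id) of the nearest TSS; lexicographically
        smallest gene_id on exact distance ties."""
        tss = self._tss.get(chrom)
        if not tss:
            return None
        best: tuple[int, str] | None = None
        for t, gid in tss:
            d = abs(pos - t)
            if best is None or d < best[0] or (d == best[0] and gid < best[1]):
                best = (d, gid)
        return best


def assign_genomic_feature(
    peak: GenomicInterval,
    genes: Sequence[GeneModel] | GeneFeatureIndex,
    params: AnnotationParams | None = None,
) -> str:
    """Feature category of a peak's summit (or midpoint)."""
    index = genes if isinstance(genes, GeneFeatureIndex) else GeneFeatureIndex(genes, params)
    return index.feature_at(peak.chrom, peak.point)


def assign_target_gene(
    peak: GenomicInterval,
    genes: Sequence[GeneModel] | GeneFeatureIndex,
    params: AnnotationParams | None = None,
) -> str | None:
    """Gene whose TSS is nearest the peak point, if within the
    assignment window (default <= 10 kb); ties break to the
    lexicographically smallest gene_id."""
    index = genes if isinstance(genes, GeneFeatureIndex) else GeneFeatureIndex(genes, params)
    hit = index.nearest_tss(peak.chrom, peak.point)
    if hit is None or hit[0] > index.params.tss_assign_max:
        return None
    return hit[1]


def assign_chromatin_state(
    peak: GenomicInterval, track: ChromatinStateTrack | IntervalIndex
) -> str:
    """Highest-priority chromatin state overlapping the peak (>= 1 bp),
    BLUE > RED > YELLOW > GREEN > BLACK; 'unassigned' when no state
    segment touches the peak."""
    index = track if isinstance(track, IntervalIndex) else IntervalIndex(track.segments)
    hits = index.overlapping(peak)
    if not hits:
        return "unassigned"
    return min((seg.name for seg in hits), key=_STATE_RANK.__getitem__)


def chromatin_state_fractions(
    peakset: PeakSet, track: ChromatinStateTrack | IntervalIndex
) -> dict[str, float]:
    """Fraction of a set's peaks assigned to each chromatin state
    (including 'unassigned'); fractions sum to 1."""
    if len(peakset) == 0:
        raise ValueError("empty peak set")
    index = track if isinstance(track, IntervalIndex) else IntervalIndex(track.segments)
    counts = {state: 0 for state in STATE_PRIORITY}
    counts["unassigned"] = 0
    for peak in peakset:
        counts[assign_chromatin_state(peak, index)] += 1
    n = len(peakset)
    return {state: c / n for state, c in counts.items()}


def feature_fractions(
    peakset: PeakSet, genes: Sequence[GeneModel] | GeneFeatureIndex,
    params: AnnotationParams | None = None,
) -> dict[str, float]:
    if len(peakset) == 0:
        raise ValueError("empty peak set")
    index = genes if isinstance(genes, GeneFeatureIndex) else GeneFeatureIndex(genes, params)
    counts = {cat: 0 for cat in FEATURE_CATEGORIES}
    for peak in peakset:
        counts[index.feature_at(peak.chrom, peak.point)] += 1
    n = len(peakset)
    return {cat: c / n for cat, c in counts.items()}


def pc_target_call(
    gene: GeneModel,
    track: ChromatinStateTrack,
    params: AnnotationParams | None = None,
) -> bool:
    """True iff the gene unit [tx_start, tx_end) contains >= pc_min_blue
    bp of BLUE chromatin, summed over BLUE segments."""
    params = params or AnnotationParams()
    blue_bp = 0
    for seg in track.segments:
        if seg.name != "BLUE" or seg.chrom != gene.chrom:
            continue
        ov = min(seg.end, gene.tx_end) - max(seg.start, gene.tx_start)
        if ov > 0:
            blue_bp += ov
    return blue_bp >= params.pc_min_blue


def annotate_peakset(
    peakset: PeakSet,
    genes: Sequence[GeneModel] | GeneFeatureIndex,
    track: ChromatinStateTrack | None = None,
    params: AnnotationParams | None = None,
) -> pd.DataFrame:
    """Per-peak annotation table (feature, chromatin state, target gene)."""
    index = genes if isinstance(genes, GeneFeatureIndex) else GeneFeatureIndex(genes, params)
    state_index = IntervalIndex(track.segments) if track is not None else None
    rows = []
    for peak in peakset:
        row = {
            "chrom": peak.chrom,
            "start": peak.start,
            "end": peak.end,
            "point": peak.point,
            "feature": index.feature_at(peak.chrom, peak.point),
            "target_gene": assign_target_gene(peak, index),
        }
        row["state"] = (
            assign_chromatin_state(peak, state_index) if state_index is not None else None
        )
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "point", "feature", "state", "target_gene"]
    )
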