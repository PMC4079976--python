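"""Interval-query engine.

Thin wrapper over :mod:`intervaltree` providing half-open overlap queries
(>= 1 shared bp) used by every downstream module.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .genome import GenomicInterval

__all__ = ["IntervalIndex", "query_overlaps", "merge_intervals", "total_coverage"]


class IntervalIndex:
    """Per-chromosome interval trees over a fixed interval collection."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All stored intervals sharing >= 1 bp with *query*, sorted."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [node.data for node in tree.overlap(query.start, query.end)]
        hits.sort(key=lambda iv: (iv.start, iv.end))
        return hits

    def any_overlap(self, query: GenomicInterval) -> bool:
        tree = self._trees.get(query.chrom)
        return tree is not None and tree.overlaps(query.start, query.end)

    def overlapping_point(self, chrom: str, pos: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [node.data for node in tree.at(pos)]
        hits.sort(key=lambda iv: (iv.start, iv.end))
        return hits


def query_overlaps(
    query: GenomicInterval, subject: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Subject intervals sharing >= 1 bp with *query* under half-open
    semantics.  Builds a transient index; for repeated queries against
    the same subject, construct an :class:`IntervalIndex` once."""
    return IntervalIndex(subject).overlapping(query)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as disjoint sorted intervals (labels dropped).

    Book-ended intervals ([a,b) and [b,c)) are merged into one run.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def total_coverage(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct bp covered by the intervals (union length)."""
    return sum(iv.length for iv in merge_intervals(intervals))
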