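"""Readers and writers for the plain-text genomic formats the pipeline
consumes: BED3/BED6, ENCODE narrowPeak, bedGraph, BED12 gene models,
chromosome-sizes TSV and FASTA (via Biopython).

All readers convert to the package's 0-based half-open convention at the
boundary and raise :class:`ParseError` naming the offending line.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import (
    ChromatinStateTrack,
    EnhancerSet,
    GeneModel,
    GenomeSpec,
    GenomicInterval,
    ScoreTrack,
    sort_intervals,
)

__all__ = [
    "ParseError",
    "read_intervals",
    "write_intervals",
    "write_narrowpeak",
    "read_score_track",
    "write_score_track",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gene_models",
    "write_gene_models",
    "read_chromatin_track",
    "write_chromatin_track",
    "read_fasta",
    "write_fasta",
    "read_enhancers",
    "write_enhancers",
]


class ParseError(ValueError):
    """Malformed line in a text genomic format."""

    def __init__(self, path: str | os.PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _coords(path, lineno, fields):
    if len(fields) < 3:
        raise ParseError(path, lineno, f"expected >= 3 columns, got {len(fields)}")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from None
    if start >= end:
        raise ParseError(path, lineno, f"start {start} >= end {end}")
    if start < 0:
        raise ParseError(path, lineno, f"negative start {start}")
    return fields[0], start, end


def read_intervals(path, format: str = "bed") -> list[GenomicInterval]:
    """Read a BED (3+ columns) or 10-column ENCODE narrowPeak file.

    narrowPeak summit = start + column-10 offset; a -1 offset means the
    summit was not called and the interval midpoint is used instead.
    Returned intervals are sorted by (chrom, start).
    """
    if format not in {"bed", "narrowPeak"}:
        raise ValueError(f"unknown interval format {format!r}")
    out: list[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        chrom, start, end = _coords(path, lineno, fields)
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = None
        if len(fields) > 4 and fields[4] not in {".", ""}:
            try:
                score = float(fields[4])
            except ValueError:
                raise ParseError(path, lineno, f"non-numeric score {fields[4]!r}") from None
        summit = None
        if format == "narrowPeak":
            if len(fields) != 10:
                raise ParseError(
                    path, lineno, f"narrowPeak needs 10 columns, got {len(fields)}"
                )
            try:
                offset = int(fields[9])
            except ValueError:
                raise ParseError(path, lineno, f"bad summit offset {fields[9]!r}") from None
            summit = None if offset == -1 else start + offset
            if summit is not None and not (start <= summit < end):
                raise ParseError(path, lineno, f"summit {summit} outside interval")
            if summit is None:
                summit = (start + end) // 2
        try:
            out.append(GenomicInterval(chrom, start, end, name=name, score=score, summit=summit))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return sort_intervals(out)


def write_intervals(intervals: Iterable[GenomicInterval], path, format: str = "bed") -> None:
    """Write intervals as BED, sorted by (chrom, start).

    BED6 columns are emitted when any interval carries a name or score
    ('.' placeholders, strand '.'); otherwise BED3.
    """
    if format != "bed":
        raise ValueError(f"unsupported output format {format!r}")
    ivs = sort_intervals(intervals)
    bed6 = any(iv.name is not None or iv.score is not None for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if bed6:
                score = "." if iv.score is None else f"{iv.score:g}"
                name = iv.name if iv.name is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_narrowpeak(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as 10-column ENCODE narrowPeak (summit offset in
    column 10, -1 when absent)."""
    ivs = sort_intervals(intervals)
    with open(path, "w") as fh:
        for iv in ivs:
            name = iv.name if iv.name is not None else "."
            score = 0 if iv.score is None else int(round(iv.score))
            offset = -1 if iv.summit is None else iv.summit - iv.start
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\t0\t-1\t-1\t{offset}\n"
            )


def read_score_track(path) -> ScoreTrack:
    """Read a 4-column bedGraph into a :class:`ScoreTrack`.

    Overlapping runs are a validation error (no silent merging).
    """
    runs: list[tuple[GenomicInterval, float]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(path, lineno, f"bedGraph needs 4 columns, got {len(fields)}")
        chrom, start, end = _coords(path, lineno, fields)
        try:
            value = float(fields[3])
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric value {fields[3]!r}") from None
        runs.append((GenomicInterval(chrom, start, end), value))
    return ScoreTrack(runs)


def write_score_track(track: ScoreTrack, path) -> None:
    with open(path, "w") as fh:
        for iv, value in track.iter_runs():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:g}\n")


def read_chrom_sizes(path) -> GenomeSpec:
    """Two-column TSV (name, length) -> :class:`GenomeSpec`."""
    lengths: dict[str, int] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, "expected name<TAB>length")
        try:
            lengths[fields[0]] = int(fields[1])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer length {fields[1]!r}") from None
    return GenomeSpec(lengths)


def write_chrom_sizes(genome: GenomeSpec, path) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f"{chrom}\t{genome.length(chrom)}\n")


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from BED12 (thickStart/thickEnd = CDS)."""
    genes: list[GeneModel] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 12:
            raise ParseError(path, lineno, f"BED12 needs 12 columns, got {len(fields)}")
        chrom, start, end = _coords(path, lineno, fields)
        name, strand = fields[3], fields[5]
        try:
            cds_start, cds_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad BED12 block fields: {exc}") from None
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise ParseError(path, lineno, "block count mismatch")
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        try:
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    exons=exons,
                )
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
            sizes = ",".join(str(b - a) for a, b in g.exons)
            offsets = ",".join(str(a - g.tx_start) for a, b in g.exons)
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.cds_start}\t{g.cds_end}\t0\t{len(g.exons)}\t{sizes},\t{offsets},\n"
            )


def read_chromatin_track(path) -> ChromatinStateTrack:
    """BED with the state color in the name column -> state track."""
    segs = read_intervals(path, format="bed")
    return ChromatinStateTrack(segs)


def write_chromatin_track(track: ChromatinStateTrack, path) -> None:
    write_intervals(track.segments, path)


def read_fasta(path) -> dict[str, str]:
    """Chromosome name -> uppercase sequence string."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_enhancers(path, cell_context: str = "") -> EnhancerSet:
    """BED whose name column carries the open/closed class label."""
    ivs = read_intervals(path, format="bed")
    labels = []
    for iv in ivs:
        if iv.name not in {"open", "closed"}:
            raise ValueError(f"enhancer {iv.chrom}:{iv.start} lacks open/closed label")
        labels.append(iv.name)
    return EnhancerSet(cell_context=cell_context, enhancers=list(ivs), class_labels=labels)


def write_enhancers(enhancers: EnhancerSet, path) -> None:
    with open(path, "w") as fh:
        for iv, label in zip(enhancers.enhancers, enhancers.class_labels):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t.\t.\n")
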