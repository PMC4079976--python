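"""End-to-end pipeline: simulate (or load) -> occupancy -> colocalization
-> annotation -> region statistics.

Every numeric threshold lives in the parameter objects gathered by
:class:`PipelineConfig`; nothing is inlined in the stage code.  Stage
seeds are derived from the master seed plus the stage name, so each
stochastic stage is reproducible independently of stage order.
Outputs land in a fixed layout under the run directory with a JSON
manifest of record counts and file checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import io as hio
from .annotation import (
    AnnotationParams,
    GeneFeatureIndex,
    annotate_peakset,
    assign_chromatin_state,
    chromatin_state_fractions,
    feature_fractions,
    pc_target_call,
)
from .colocalization import ColocalizationModel, trf_region_enrichment
from .genome import GenomicInterval
from .intervals import IntervalIndex
from .occupancy import OccupancyModel, OccupancyParams
from .region_stats import (
    central_score_test,
    conservation_profile,
    enhancer_overlap,
    filter_enriched_terms,
    motif_enrichment,
    snp_density,
)
from .simulate import SimConfig, simulate_all, write_truth

__all__ = [
    "RealInputs",
    "PipelineConfig",
    "RunReport",
    "StageRecord",
    "run_pipeline",
    "order_matrix_rows",
]


@dataclass(frozen=True)
class RealInputs:
    """Paths to pre-computed inputs for a real-data run."""

    chrom_sizes: str
    peak_files: Mapping[str, str]  # label -> path
    peak_format: str = "narrowPeak"
    genes: str | None = None
    chromatin: str | None = None
    conservation: str | None = None
    fasta: str | None = None
    enhancers: Mapping[str, str] = field(default_factory=dict)  # context -> path
    variants: str | None = None
    gene_terms: str | None = None  # TSV gene<TAB>term


@dataclass
class PipelineConfig:
    """One place for every input path and numeric parameter.

    Exactly one of ``sim`` (synthetic mode) and ``inputs`` (real mode)
    must be set; the master seed is mandatory in synthetic mode and
    drives every stochastic stage.
    """

    out_dir: str
    seed: int | None = None
    sim: SimConfig | None = None
    inputs: RealInputs | None = None
    occupancy: OccupancyParams = field(default_factory=OccupancyParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    n_perm: int = 1000
    hot_enrichment_z: float = 50.0
    motif: str = "GAGAG"
    n_random_motif: int = 100
    geneset_alpha: float = 1e-5
    enhancer_significance: float = 1e-20
    conservation_flank: int = 1000
    conservation_window: int = 10
    central_width: int = 100

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("exactly one of sim / inputs must be set")
        if self.sim is not None and self.seed is None:
            self.seed = self.sim.seed


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class StageRecord:
    name: str
    wall_time_s: float
    counts: dict
    outputs: list[str]


@dataclass
class RunReport:
    out_dir: str
    stages: list[StageRecord] = field(default_factory=list)
    checksums: dict = field(default_factory=dict)

    def counts(self, stage: str) -> dict:
        for rec in self.stages:
            if rec.name == stage:
                return rec.counts
        raise KeyError(stage)

    def to_json(self, path) -> None:
        payload = {
            "out_dir": self.out_dir,
            "stages": [
                {
                    "name": s.name,
                    "wall_time_s": round(s.wall_time_s, 3),
                    "counts": s.counts,
                    "outputs": s.outputs,
                }
                for s in self.stages
            ],
            "checksums": self.checksums,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def order_matrix_rows(matrix: pd.DataFrame) -> list:
    """Display ordering of matrix rows by agglomerative clustering
    (Euclidean distance, average linkage), deterministic with ties
    resolved to input order.  Two rows keep the input order."""
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite cells")
    if len(matrix) < 2:
        raise ValueError("need >= 2 rows")
    if len(matrix) == 2:
        return list(matrix.index)
    link = hierarchy.linkage(pdist(values, metric="euclidean"), method="average")
    order = hierarchy.leaves_list(link)
    return [matrix.index[i] for i in order]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_real(inputs: RealInputs):
    from .genome import EnhancerSet, PeakSet

    genome = hio.read_chrom_sizes(inputs.chrom_sizes)
    peaksets = []
    for label, path in inputs.peak_files.items():
        regulator, _, context = label.partition("_")
        peaksets.append(
            PeakSet(regulator, context or "na", hio.read_intervals(path, inputs.peak_format))
        )
    genes = hio.read_gene_models(inputs.genes) if inputs.genes else []
    chromatin = hio.read_chromatin_track(inputs.chromatin) if inputs.chromatin else None
    conservation = hio.read_score_track(inputs.conservation) if inputs.conservation else None
    sequences = hio.read_fasta(inputs.fasta) if inputs.fasta else None
    enhancers = [
        hio.read_enhancers(path, context) for context, path in inputs.enhancers.items()
    ]
    variants = None
    if inputs.variants:
        variants = [(iv.chrom, iv.start) for iv in hio.read_intervals(inputs.variants)]
    term_map = None
    if inputs.gene_terms:
        term_map = {}
        with open(inputs.gene_terms) as fh:
            for line in fh:
                if line.strip():
                    gene, term = line.rstrip("\n").split("\t")[:2]
                    term_map.setdefault(gene, []).append(term)
    return genome, peaksets, genes, chromatin, conservation, sequences, enhancers, variants, term_map


def _synthetic_term_map(genes) -> dict[str, list[str]]:
    """Simple annotation-term table for synthetic genes: a shared term
    for the planted Pc-target program, one per chromosome, one per
    strand."""
    term_map: dict[str, list[str]] = {}
    for g in genes:
        terms = [f"located_{g.chrom}", "plus_strand" if g.strand == "+" else "minus_strand"]
        terms.append("pc_program" if g.pc_target else "non_pc_program")
        term_map[g.gene_id] = terms
    return term_map


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in dependency order and write the manifest.

    Rerunning with the same config reproduces identical outputs:
    deterministic stages byte-for-byte, seeded stochastic stages
    value-for-value (hence also byte-for-byte here).
    """
    out = Path(config.out_dir)
    report = RunReport(str(out))
    all_outputs: list[Path] = []

    def record(stage: str, t0: float, counts: dict, files: Sequence[Path]):
        report.stages.append(
            StageRecord(stage, time.monotonic() - t0, counts, [str(f) for f in files])
        )
        all_outputs.extend(files)

    # ---- stage: simulate / load -------------------------------------
    stage = "simulate" if config.sim is not None else "load"
    t0 = time.monotonic()
    try:
        in_dir = out / "inputs"
        in_dir.mkdir(parents=True, exist_ok=True)
        files: list[Path] = []
        if config.sim is not None:
            bundle = simulate_all(config.sim)
            genome, genes, sequences = bundle.genome, bundle.genes, bundle.sequences
            chromatin, peaksets, truth = bundle.chromatin, bundle.peaksets, bundle.truth
            conservation, enhancers, variants = (
                bundle.conservation, bundle.enhancers, bundle.variants,
            )
            term_map = _synthetic_term_map(genes)
            hio.write_chrom_sizes(genome, in_dir / "genome.sizes")
            hio.write_gene_models(genes, in_dir / "genes.bed12")
            hio.write_chromatin_track(chromatin, in_dir / "chromatin_states.bed")
            hio.write_score_track(conservation, in_dir / "conservation.bedgraph")
            hio.write_fasta(sequences, in_dir / "genome.fa")
            write_truth(truth, in_dir / "truth.tsv")
            peak_dir = in_dir / "peaks"
            peak_dir.mkdir(exist_ok=True)
            for ps in peaksets:
                hio.write_narrowpeak(ps.peaks, peak_dir / f"{ps.label}.narrowPeak")
                files.append(peak_dir / f"{ps.label}.narrowPeak")
            for enh in enhancers:
                hio.write_enhancers(enh, in_dir / f"enhancers_{enh.cell_context}.bed")
                files.append(in_dir / f"enhancers_{enh.cell_context}.bed")
            with open(in_dir / "variants.bed", "w") as fh:
                for chrom, pos in variants:
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")
            files += [
                in_dir / "genome.sizes", in_dir / "genes.bed12",
                in_dir / "chromatin_states.bed", in_dir / "conservation.bedgraph",
                in_dir / "genome.fa", in_dir / "truth.tsv", in_dir / "variants.bed",
            ]
            counts = {
                "peaksets": len(peaksets),
                "peaks": sum(len(ps) for ps in peaksets),
                "planted_loci": len(truth.planted_loci),
                "planted_peaks": sum(p.multiplicity for p in truth.planted_loci),
                "genes": len(genes),
            }
        else:
            (genome, peaksets, genes, chromatin, conservation, sequences,
             enhancers, variants, term_map) = _load_real(config.inputs)
            truth = None
            counts = {
                "peaksets": len(peaksets),
                "peaks": sum(len(ps) for ps in peaksets),
                "genes": len(genes),
            }
        record(stage, t0, counts, files)
    except Exception as exc:  # noqa: BLE001 - abort names the stage
        raise PipelineError(stage, exc) from exc

    # ---- stage: occupancy -------------------------------------------
    t0 = time.monotonic()
    try:
        occ_dir = out / "occupancy"
        occ_dir.mkdir(exist_ok=True)
        occ = OccupancyModel(peaksets, genome, config.occupancy).fit()
        frame = occ.to_frame()
        frame.to_csv(occ_dir / "regions.tsv", sep="\t", index=False)
        files = [occ_dir / "regions.tsv"]
        for cls in ("HOT", "WARM", "COLD"):
            occ.to_bed(occ_dir / f"{cls.lower()}.bed", cls)
            files.append(occ_dir / f"{cls.lower()}.bed")
        record("occupancy", t0, occ.class_counts() | {"regions": len(occ.regions)}, files)
    except Exception as exc:
        raise PipelineError("occupancy", exc) from exc

    # ---- stage: coloc -----------------------------------------------
    t0 = time.monotonic()
    try:
        coloc_dir = out / "coloc"
        coloc_dir.mkdir(exist_ok=True)
        seed = stage_seed(config.seed or 0, "coloc")
        files = []
        hot_extents = occ.extents("HOT")
        for tag, mask in (("all", None), ("nohot", hot_extents)):
            res = ColocalizationModel(peaksets, genome, mask=mask).fit(
                n_perm=config.n_perm, seed=seed
            )
            z = res.z_matrix
            z_filled = z.fillna(0.0)
            order = order_matrix_rows(z_filled) if len(z) >= 2 else list(z.index)
            z.loc[order, order].to_csv(coloc_dir / f"z_matrix_{tag}.tsv", sep="\t")
            res.to_frame().to_csv(coloc_dir / f"pairs_{tag}.tsv", sep="\t", index=False)
            files += [coloc_dir / f"z_matrix_{tag}.tsv", coloc_dir / f"pairs_{tag}.tsv"]
        # per-TRF enrichment at HOT regions
        enrich_rows = []
        if hot_extents:
            for ps in peaksets:
                rng = np.random.default_rng(stage_seed(seed, f"hot_enrich|{ps.label}"))
                r = trf_region_enrichment(ps, hot_extents, genome, config.n_perm, rng)
                enrich_rows.append(
                    {
                        "peakset": ps.label,
                        "observed": r.observed,
                        "null_mean": r.null_mean,
                        "null_sd": r.null_sd,
                        "z": r.z,
                        "hot_enriched": (not r.degenerate) and r.z > config.hot_enrichment_z,
                    }
                )
        pd.DataFrame(enrich_rows).to_csv(
            coloc_dir / "hot_enrichment.tsv", sep="\t", index=False
        )
        files.append(coloc_dir / "hot_enrichment.tsv")
        record("coloc", t0, {"pairs": len(peaksets) * (len(peaksets) - 1) // 2,
                             "n_perm": config.n_perm}, files)
    except Exception as exc:
        raise PipelineError("coloc", exc) from exc

    # ---- stage: annotate --------------------------------------------
    t0 = time.monotonic()
    try:
        if chromatin is None:
            raise ValueError("chromatin state track is required")
        ann_dir = out / "annotate"
        ann_dir.mkdir(exist_ok=True)
        gene_index = GeneFeatureIndex(genes, config.annotation)
        state_index = IntervalIndex(chromatin.segments)
        per_peak = []
        frac_rows = []
        for ps in peaksets:
            table = annotate_peakset(ps, gene_index, chromatin, config.annotation)
            table.insert(0, "peakset", ps.label)
            per_peak.append(table)
            fr = {"peakset": ps.label}
            fr |= {f"state_{k}": v for k, v in
                   chromatin_state_fractions(ps, state_index).items()}
            fr |= {f"feat_{k}": v for k, v in
                   feature_fractions(ps, gene_index).items()}
            frac_rows.append(fr)
        peaks_table = pd.concat(per_peak, ignore_index=True)
        peaks_table.to_csv(ann_dir / "peak_annotation.tsv", sep="\t", index=False)
        frac_table = pd.DataFrame(frac_rows).set_index("peakset")
        frac_table.to_csv(ann_dir / "fractions.tsv", sep="\t")
        # Pc-target calls and BLUE-preference cross-table
        pc_rows = [
            {"gene_id": g.gene_id, "pc_target_call": pc_target_call(g, chromatin, config.annotation)}
            for g in genes
        ]
        pd.DataFrame(pc_rows).to_csv(ann_dir / "pc_targets.tsv", sep="\t", index=False)
        blue_rows = []
        for ps in peaksets:
            blue = chromatin_state_fractions(ps, state_index)["BLUE"]
            blue_rows.append(
                {"peakset": ps.label, "blue_fraction": blue,
                 "blue_preferring": blue > config.annotation.blue_preference_min}
            )
        pd.DataFrame(blue_rows).to_csv(ann_dir / "blue_preference.tsv", sep="\t", index=False)
        # region-class annotation (regions re-annotated like peaks)
        region_rows = []
        for r in occ.regions:
            region_rows.append(
                {
                    "chrom": r.chrom,
                    "center": r.center,
                    "class": r.region_class,
                    "feature": gene_index.feature_at(r.chrom, r.center),
                    "state": assign_chromatin_state(r.extent, state_index),
                }
            )
        pd.DataFrame(region_rows).to_csv(ann_dir / "region_annotation.tsv", sep="\t", index=False)
        files = [ann_dir / "peak_annotation.tsv", ann_dir / "fractions.tsv",
                 ann_dir / "pc_targets.tsv", ann_dir / "blue_preference.tsv",
                 ann_dir / "region_annotation.tsv"]
        record("annotate", t0,
               {"annotated_peaks": len(peaks_table), "genes": len(genes)}, files)
    except Exception as exc:
        raise PipelineError("annotate", exc) from exc

    # ---- stage: stats -----------------------------------------------
    t0 = time.monotonic()
    try:
        st_dir = out / "stats"
        st_dir.mkdir(exist_ok=True)
        files = []
        regions_by_class = {cls: occ.extents(cls) for cls in ("HOT", "WARM", "COLD")}
        if conservation is not None:
            prof_frames = []
            for cls, regs in regions_by_class.items():
                if regs:
                    prof = conservation_profile(
                        regs, conservation, config.conservation_flank,
                        config.conservation_window,
                    ).to_frame()
                    prof.insert(0, "region_class", cls)
                    prof_frames.append(prof)
            pd.concat(prof_frames, ignore_index=True).to_csv(
                st_dir / "conservation_profiles.tsv", sep="\t", index=False
            )
            files.append(st_dir / "conservation_profiles.tsv")
            tests = []
            pairs = [("COLD", "HOT"), ("WARM", "HOT"), ("COLD", "WARM")]
            for a, b in pairs:
                if len(regions_by_class[a]) >= 2 and len(regions_by_class[b]) >= 2:
                    ma, mb, p = central_score_test(
                        regions_by_class[a], regions_by_class[b], conservation,
                        config.central_width,
                    )
                    tests.append({"group_a": a, "group_b": b,
                                  "mean_a": ma, "mean_b": mb, "p": p})
            pd.DataFrame(tests).to_csv(st_dir / "central_conservation.tsv",
                                       sep="\t", index=False)
            files.append(st_dir / "central_conservation.tsv")
        for enh in enhancers:
            table = enhancer_overlap(enh, regions_by_class, config.enhancer_significance)
            table.to_csv(st_dir / f"enhancer_overlap_{enh.cell_context}.tsv",
                         sep="\t", index=False)
            files.append(st_dir / f"enhancer_overlap_{enh.cell_context}.tsv")
        if sequences is not None:
            rows = []
            rng = np.random.default_rng(stage_seed(config.seed or 0, "motif"))
            for cls, regs in regions_by_class.items():
                if regs:
                    frac, enr = motif_enrichment(
                        regs, sequences, config.motif,
                        n_random=config.n_random_motif, rng=rng,
                    )
                    rows.append({"region_class": cls, "fraction": frac,
                                 "enrichment": enr})
            pd.DataFrame(rows).to_csv(st_dir / "motif_enrichment.tsv",
                                      sep="\t", index=False)
            files.append(st_dir / "motif_enrichment.tsv")
        if variants is not None:
            snp_density(regions_by_class, variants).to_csv(
                st_dir / "snp_density.tsv", sep="\t", index=False
            )
            files.append(st_dir / "snp_density.tsv")
        if term_map is not None and genes:
            universe = [g.gene_id for g in genes]
            # a gene is targeted by a class when a region center falls
            # within the TSS assignment window of its TSS
            win = config.annotation.tss_assign_max
            targets = {}
            for cls in ("HOT", "COLD"):
                idx = IntervalIndex(regions_by_class[cls])
                targets[cls] = {
                    g.gene_id
                    for g in genes
                    if idx.overlapping_point(g.chrom, g.tss)
                    or idx.any_overlap(
                        GenomicInterval(g.chrom, max(g.tss - win, 0), g.tss + win)
                    )
                }
            hot_only = sorted(targets["HOT"] - targets["COLD"])
            cold_only = sorted(targets["COLD"] - targets["HOT"])
            both = sorted(targets["HOT"] & targets["COLD"])
            table = filter_enriched_terms(
                {"HOT_only": hot_only, "HOT_and_COLD": both, "COLD_only": cold_only},
                universe, term_map, alpha=config.geneset_alpha,
            )
            table.to_csv(st_dir / "geneset_enrichment.tsv", sep="\t", index=False)
            files.append(st_dir / "geneset_enrichment.tsv")
        record("stats", t0, {"classes": {c: len(r) for c, r in regions_by_class.items()}},
               files)
    except Exception as exc:
        raise PipelineError("stats", exc) from exc

    for path in all_outputs:
        report.checksums[str(Path(path).relative_to(out))] = _sha256(Path(path))
    report.to_json(out / "manifest.json")
    return report
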