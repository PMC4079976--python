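"""Synthetic-data generator: determinism, planted structure, tracks."""

import dataclasses

import numpy as np
import pytest

from hotregions.genome import CHROMATIN_STATES
from hotregions.intervals import IntervalIndex
from hotregions.simulate import (
    SimConfig,
    expected_class,
    make_aux_tracks,
    make_chromatin_track,
    make_genome_and_genes,
    make_genome_spec,
    make_peak_collection,
    plan_loci,
    simulate_all,
)


def small_config(**overrides):
    base = dict(
        seed=3,
        n_chroms=1,
        chrom_length=1_000_000,
        n_trfs=20,
        n_loci={"HOT": 5, "WARM": 5, "COLD": 5},
        multiplicity={"HOT": 18, "WARM": 8, "COLD": 2},
        n_genes=10,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestConfig:
    def test_multiplicity_cannot_exceed_trfs(self):
        with pytest.raises(ValueError):
            small_config(n_trfs=10)

    def test_expected_class_thresholds(self):
        assert expected_class(15) == "HOT"
        assert expected_class(14) == "WARM"
        assert expected_class(3) == "COLD"
        assert expected_class(4) == "WARM"


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        b1 = simulate_all(small_config())
        b2 = simulate_all(small_config())
        assert b1.sequences == b2.sequences
        assert [(p.chrom, p.center, p.multiplicity) for p in b1.truth.planted_loci] == [
            (p.chrom, p.center, p.multiplicity) for p in b2.truth.planted_loci
        ]
        for ps1, ps2 in zip(b1.peaksets, b2.peaksets):
            assert [(p.start, p.end, p.summit) for p in ps1.peaks] == [
                (p.start, p.end, p.summit) for p in ps2.peaks
            ]
        assert b1.variants == b2.variants
        assert [(s.start, s.end, s.name) for s in b1.chromatin.segments] == [
            (s.start, s.end, s.name) for s in b2.chromatin.segments
        ]

    def test_different_seed_different_sequence(self):
        b1 = simulate_all(small_config(seed=1))
        b2 = simulate_all(small_config(seed=2))
        assert b1.sequences != b2.sequences


class TestGenomeAndGenes:
    def test_zero_genes_valid_genome(self):
        genome, genes, seqs = make_genome_and_genes(small_config(n_genes=0))
        assert genes == []
        assert genome.total_length == 1_000_000
        assert len(seqs["chr1"]) == 1_000_000

    def test_genes_within_bounds_nonoverlapping_both_strands(self):
        genome, genes, _ = make_genome_and_genes(small_config())
        assert len(genes) == 10
        strands = {g.strand for g in genes}
        assert strands == {"+", "-"}
        by_chrom = {}
        for g in genes:
            assert 0 <= g.tx_start < g.tx_end <= genome.length(g.chrom)
            by_chrom.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            make_genome_and_genes(small_config(n_genes=500))

    def test_sequence_alphabet(self):
        _, _, seqs = make_genome_and_genes(small_config())
        assert set(seqs["chr1"][:10_000]) <= set("ACGT")


class TestChromatinTrack:
    def test_tiling_covers_genome_disjointly(self):
        config = small_config()
        _, genes, _ = make_genome_and_genes(config)
        track = make_chromatin_track(config, genes)
        total = sum(s.length for s in track.segments)
        assert total == make_genome_spec(config).total_length
        # disjoint & sorted is enforced by the track type itself
        assert {s.name for s in track.segments} <= CHROMATIN_STATES

    def test_black_majority_fraction(self):
        config = SimConfig(seed=8)  # default 2 x 5 Mb for a stable estimate
        _, genes, _ = make_genome_and_genes(config)
        track = make_chromatin_track(config, genes)
        genome = make_genome_spec(config)
        black = sum(s.length for s in track.segments if s.name == "BLACK")
        assert 0.4 <= black / genome.total_length <= 0.6

    def test_pc_target_genes_have_planted_blue(self):
        config = small_config(pc_target_fraction=0.5)
        _, genes, _ = make_genome_and_genes(config)
        track = make_chromatin_track(config, genes)
        flagged = [g for g in genes if g.pc_target]
        assert flagged, "expected at least one pc-target gene at fraction 0.5"
        for g in flagged:
            blue = sum(
                max(0, min(s.end, g.tx_end) - max(s.start, g.tx_start))
                for s in track.segments
                if s.name == "BLUE" and s.chrom == g.chrom
            )
            assert blue >= 100


class TestPeakCollection:
    def test_planted_peak_count(self):
        config = small_config(
            n_loci={"HOT": 10}, multiplicity={"HOT": 20}, background_rate=0.0
        )
        peaksets, truth = make_peak_collection(config)
        assert sum(len(ps) for ps in peaksets) == 200
        assert len(truth.planted_loci) == 10

    def test_zero_jitter_summits_exactly_at_centers(self):
        config = small_config(jitter_sd=0.0, background_rate=0.0)
        peaksets, truth = make_peak_collection(config)
        centers = {(p.chrom, p.center) for p in truth.planted_loci}
        for ps in peaksets:
            for peak in ps.peaks:
                assert (peak.chrom, peak.summit) in centers

    def test_background_free_single_locus_multiplicity(self):
        config = small_config(
            n_loci={"COLD": 1}, multiplicity={"COLD": 3}, background_rate=0.0
        )
        peaksets, truth = make_peak_collection(config)
        assert sum(len(ps) for ps in peaksets) == 3
        # three distinct TRFs
        assert sum(1 for ps in peaksets if len(ps) == 1) == 3

    def test_truth_multiplicity_recomputable_from_peaks(self):
        config = small_config(background_rate=1e-6)
        peaksets, truth = make_peak_collection(config)
        window = 3 * config.jitter_sd
        ok = 0
        for locus in truth.planted_loci:
            n = sum(
                1
                for ps in peaksets
                if any(
                    abs(s - locus.center) <= window
                    for s in ps.summits_on(locus.chrom)
                )
            )
            ok += n == locus.multiplicity
        assert ok >= 0.99 * len(truth.planted_loci)

    def test_all_peaks_valid_against_genome(self):
        config = small_config()
        genome = make_genome_spec(config)
        peaksets, _ = make_peak_collection(config)
        for ps in peaksets:
            for p in ps.peaks:
                assert 0 <= p.start < p.end <= genome.length(p.chrom)
                assert p.start <= p.summit < p.end


class TestAuxTracks:
    def test_conservation_levels_by_class(self):
        config = small_config()
        _, truth = make_peak_collection(config)
        track, _, _ = make_aux_tracks(config, truth)
        for locus in truth.planted_loci:
            mean = track.mean(locus.chrom, locus.center - 50, locus.center + 50)
            if locus.expected_class == "HOT":
                assert mean == pytest.approx(config.conservation_low)
            else:
                assert mean == pytest.approx(config.conservation_high)

    def test_certain_enhancer_placement_at_hot_loci(self):
        config = small_config(
            enhancer_prob={"HOT": 1.0, "WARM": 0.0, "COLD": 0.0},
            enhancer_open_prob={"HOT": 1.0},
        )
        _, truth = make_peak_collection(config)
        _, enhancer_sets, _ = make_aux_tracks(config, truth)
        for enh in enhancer_sets:
            index = IntervalIndex(enh.of_class("open"))
            for locus in truth.by_class("HOT"):
                assert index.overlapping_point(locus.chrom, locus.center)
            assert len(enh.of_class("closed")) == 0

    def test_variant_density_ratio_near_planted_two(self):
        config = SimConfig(seed=12)  # default scale for >= 1000 variants
        _, truth = make_peak_collection(config)
        _, _, variants = make_aux_tracks(config, truth)
        assert len(variants) >= 1_000
        genome = make_genome_spec(config)
        hot_windows = [
            (l.chrom, l.center - config.variant_window, l.center + config.variant_window)
            for l in truth.by_class("HOT")
        ]
        hot_bp = sum(e - s for _, s, e in hot_windows)
        in_hot = sum(
            1
            for chrom, pos in variants
            if any(c == chrom and s <= pos < e for c, s, e in hot_windows)
        )
        hot_density = in_hot / hot_bp
        rest_density = (len(variants) - in_hot) / (genome.total_length - hot_bp)
        ratio = hot_density / rest_density
        assert 1.6 <= ratio <= 2.4


class TestPlanLoci:
    def test_loci_well_separated(self):
        loci = plan_loci(small_config())
        by_chrom = {}
        for l in loci:
            by_chrom.setdefault(l.chrom, []).append(l.center)
        for centers in by_chrom.values():
            centers.sort()
            assert all(b - a >= 2_000 for a, b in zip(centers, centers[1:]))

    def test_class_counts_match_config(self):
        config = small_config()
        loci = plan_loci(config)
        for cls, n in config.n_loci.items():
            assert sum(1 for l in loci if l.expected_class == cls) == n

    def test_too_many_loci_rejected(self):
        with pytest.raises(ValueError, match="slots"):
            plan_loci(small_config(n_loci={"COLD": 100_000}))
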