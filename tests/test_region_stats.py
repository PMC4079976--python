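"""Conservation profiles, rank-sum / chi-square / hypergeometric
statistics, motif scanning and variant density."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import comb

from hotregions.genome import EnhancerSet, GenomicInterval, ScoreTrack
from hotregions.region_stats import (
    central_score_test,
    chi_square_2x2,
    conservation_profile,
    enhancer_overlap,
    filter_enriched_terms,
    geneset_enrichment,
    iupac_to_regex,
    motif_enrichment,
    motif_fraction,
    rank_sum_test,
    region_center,
    reverse_complement,
    snp_density,
)


def constant_track(value: float, length: int = 1_000_000) -> ScoreTrack:
    return ScoreTrack([(GenomicInterval("chr1", 0, length), value)])


def regions_at(centers, halfwidth=300):
    return [GenomicInterval("chr1", c - halfwidth, c + halfwidth) for c in centers]


class TestConservationProfile:
    def test_constant_track_constant_profile(self):
        prof = conservation_profile(regions_at([10_000, 50_000]), constant_track(0.5))
        assert np.allclose(prof.mean_score, 0.5)
        assert prof.n_regions == 2
        assert np.allclose(prof.offsets, -prof.offsets[::-1])  # symmetric

    def test_central_plateau_recovered(self):
        centers = [10_000, 50_000]
        runs = [(GenomicInterval("chr1", c - 50, c + 50), 1.0) for c in centers]
        prof = conservation_profile(regions_at(centers), ScoreTrack(runs))
        central = np.abs(prof.offsets) < 50
        distal = np.abs(prof.offsets) > 100
        assert np.allclose(prof.mean_score[central], 1.0)
        assert np.allclose(prof.mean_score[distal], 0.0)

    def test_across_region_unweighted_mean(self):
        runs = [
            (GenomicInterval("chr1", 10_000 - 50, 10_000 + 50), 0.2),
            (GenomicInterval("chr1", 50_000 - 50, 50_000 + 50), 0.8),
        ]
        prof = conservation_profile(regions_at([10_000, 50_000]), ScoreTrack(runs))
        central = np.abs(prof.offsets) < 5
        assert np.allclose(prof.mean_score[central], 0.5)

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError):
            conservation_profile([], constant_track(1.0))

    def test_window_must_divide_span(self):
        with pytest.raises(ValueError):
            conservation_profile(regions_at([10_000]), constant_track(1.0),
                                 flank=1000, window=3)

    def test_all_ones_track_gives_ones_everywhere(self):
        prof = conservation_profile(regions_at([5_000, 12_345, 77_000]),
                                    constant_track(1.0))
        assert np.allclose(prof.mean_score, 1.0)


def exact_ranksum_oracle(x, y):
    """Two-sided exact rank-sum p by enumeration of group assignments."""
    pooled = sorted(list(x) + list(y))
    n, na = len(pooled), len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # distinct values
    u_obs = sum(ranks[v] for v in x) - na * (na + 1) / 2
    us = []
    for combo in itertools.combinations(range(n), na):
        u = sum(i + 1 for i in combo) - na * (na + 1) / 2
        us.append(u)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestRankSum:
    def test_extreme_small_groups_exact_p(self):
        assert rank_sum_test(np.array([1, 2, 3]), np.array([4, 5, 6])) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        x = np.array([2.0, 2.0, 2.0])
        assert rank_sum_test(x, x.copy()) == 1.0

    @pytest.mark.parametrize("na,nb", [(2, 2), (2, 3), (3, 3), (3, 4), (4, 4),
                                       (2, 5), (4, 5), (5, 5)])
    def test_matches_enumeration_for_small_groups(self, na, nb, rng):
        x = rng.normal(size=na)
        y = rng.normal(size=nb)
        assert rank_sum_test(x, y) == pytest.approx(exact_ranksum_oracle(x, y))

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            if rank_sum_test(x, y) < 0.05:
                hits += 1
        assert 0.03 <= hits / n_rep <= 0.07

    def test_central_score_test_separates_groups(self):
        hi_vals, lo_vals = (0.88, 0.90, 0.92), (0.08, 0.10, 0.12)
        runs = [(GenomicInterval("chr1", c - 50, c + 50), v)
                for c, v in zip((10_000, 20_000, 30_000), hi_vals)]
        runs += [(GenomicInterval("chr1", c - 50, c + 50), v)
                 for c, v in zip((50_000, 60_000, 70_000), lo_vals)]
        track = ScoreTrack(runs)
        hi = regions_at([10_000, 20_000, 30_000])
        lo = regions_at([50_000, 60_000, 70_000])
        mean_hi, mean_lo, p = central_score_test(hi, lo, track)
        assert mean_hi == pytest.approx(0.9)
        assert mean_lo == pytest.approx(0.1)
        assert p == pytest.approx(0.1)  # exact extreme for 3 vs 3


class TestChiSquare:
    def test_balanced_table_statistic_zero(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_strong_association_closed_form(self):
        stat, _ = chi_square_2x2([[90, 10], [10, 90]])
        assert stat == pytest.approx(128.0)

    def test_matches_closed_form_on_random_tables(self, rng):
        for _ in range(100):
            table = rng.integers(1, 200, size=(2, 2)).astype(float)
            stat, _ = chi_square_2x2(table)
            row = table.sum(axis=1, keepdims=True)
            col = table.sum(axis=0, keepdims=True)
            expected = row @ col / table.sum()
            oracle = float(((table - expected) ** 2 / expected).sum())
            assert stat == pytest.approx(oracle)


class TestEnhancerOverlap:
    def test_fraction_counting(self):
        enh = EnhancerSet(
            "S2",
            [GenomicInterval("chr1", c, c + 100) for c in (1_000, 5_000, 9_000)],
            ["open", "open", "open"],
        )
        regions = {"HOT": [GenomicInterval("chr1", 900, 1_200),
                           GenomicInterval("chr1", 4_950, 5_050),
                           GenomicInterval("chr1", 20_000, 20_500)]}
        table = enhancer_overlap(enh, regions)
        assert table.loc[0, "open_fraction"] == pytest.approx(2 / 3)
        assert not table.loc[0, "computable"] == True or table.loc[0, "n_closed"] == 0

    def test_open_closed_contrast_significant(self):
        open_e = [GenomicInterval("chr1", 1000 * i, 1000 * i + 100) for i in range(100)]
        closed_e = [GenomicInterval("chr1", 500_000 + 1000 * i, 500_000 + 1000 * i + 100)
                    for i in range(100)]
        enh = EnhancerSet("S2", open_e + closed_e, ["open"] * 100 + ["closed"] * 100)
        regions = {"HOT": [GenomicInterval("chr1", 0, 200_000)]}
        table = enhancer_overlap(enh, regions, significance=1e-20)
        assert table.loc[0, "open_fraction"] == 1.0
        assert table.loc[0, "closed_fraction"] == 0.0
        assert bool(table.loc[0, "significant"])

    def test_missing_class_not_computable(self):
        enh = EnhancerSet("S2", [GenomicInterval("chr1", 0, 100)], ["open"])
        table = enhancer_overlap(enh, {"HOT": [GenomicInterval("chr1", 0, 50)]})
        assert not bool(table.loc[0, "computable"])


class TestMotif:
    def test_overlapping_forward_matches_count_once(self):
        seqs = {"chr1": "TTGAGAGAGTT"}
        frac = motif_fraction([GenomicInterval("chr1", 0, 11)], seqs, "GAGAG")
        assert frac == 1.0

    def test_reverse_strand_match(self):
        seqs = {"chr1": "AACTCTCAAA"}
        frac = motif_fraction([GenomicInterval("chr1", 0, 10)], seqs, "GAGAG")
        assert frac == 1.0  # CTCTC is revcomp of GAGAG

    def test_absent_motif(self):
        seqs = {"chr1": "AAAAAAAAAA"}
        assert motif_fraction([GenomicInterval("chr1", 0, 10)], seqs, "GAGAG") == 0.0

    def test_iupac_degenerate_codes(self):
        assert iupac_to_regex("GAGAGR").fullmatch("GAGAGA")
        with pytest.raises(ValueError):
            iupac_to_regex("GAX")

    def test_region_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            motif_fraction([GenomicInterval("chr1", 0, 50)], {"chr1": "ACGT"}, "GAGAG")

    def test_planted_motif_enriched_over_random(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, size=200_000))
        # plant the motif at region centers
        seq = list(seq)
        centers = [5_000 + 10_000 * i for i in range(15)]
        for c in centers:
            seq[c : c + 5] = list("GAGAG")
        seqs = {"chr1": "".join(seq)}
        regions = [GenomicInterval("chr1", c - 20, c + 20) for c in centers]
        frac, enr = motif_enrichment(regions, seqs, "GAGAG", n_random=50,
                                     rng=np.random.default_rng(1))
        assert frac == 1.0
        assert enr > 1.0

    def test_fraction_invariant_under_genome_reverse_complement(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, size=10_000))
        regions = [GenomicInterval("chr1", s, s + 200)
                   for s in rng.integers(0, 9_800, size=30)]
        frac = motif_fraction(regions, {"chr1": seq}, "GAGAG")
        rc = reverse_complement(seq)
        mirrored = [GenomicInterval("chr1", len(seq) - r.end, len(seq) - r.start)
                    for r in regions]
        frac_rc = motif_fraction(mirrored, {"chr1": rc}, "GAGAG")
        assert frac == frac_rc


def hypergeom_oracle(N, K, n, k):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = comb(N, n, exact=True)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += comb(K, j, exact=True) * comb(N - K, n - j, exact=True)
    return acc / total


class TestGenesetEnrichment:
    def test_small_example_exact(self):
        universe = [f"g{i}" for i in range(10)]
        term_map = {g: (["T"] if i < 5 else []) for i, g in enumerate(universe)}
        (res,) = geneset_enrichment(["g0", "g1"], universe, term_map)
        assert res.p == pytest.approx(10 / 45)
        assert res.p_bonferroni == pytest.approx(10 / 45)  # single term

    def test_zero_hits_p_one(self):
        universe = ["a", "b", "c"]
        term_map = {"a": ["T"], "b": [], "c": []}
        (res,) = geneset_enrichment(["b"], universe, term_map)
        assert res.p == 1.0

    def test_matches_enumeration_small_universe(self):
        for N, K, n in [(6, 3, 2), (8, 4, 3), (10, 5, 2), (12, 6, 5)]:
            universe = [f"g{i}" for i in range(N)]
            term_map = {g: (["T"] if i < K else []) for i, g in enumerate(universe)}
            for k in range(0, min(K, n) + 1):
                selected = universe[:k] + universe[K : K + (n - k)]
                (res,) = geneset_enrichment(selected, universe, term_map)
                expected = hypergeom_oracle(N, K, n, k) if k > 0 else 1.0
                assert res.p == pytest.approx(expected, rel=1e-12)

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            geneset_enrichment(["zz"], ["a"], {"a": []})

    def test_bonferroni_multiplier_counts_terms(self):
        universe = [f"g{i}" for i in range(10)]
        term_map = {g: ["T1", "T2"] if i < 5 else ["T2"] for i, g in enumerate(universe)}
        results = {r.term: r for r in geneset_enrichment(universe[:3], universe, term_map)}
        assert results["T1"].p_bonferroni == pytest.approx(min(results["T1"].p * 2, 1.0))

    def test_filter_retains_term_enriched_in_one_list(self):
        universe = [f"g{i}" for i in range(40)]
        term_map = {g: (["hit"] if i < 10 else ["other"]) for i, g in enumerate(universe)}
        table = filter_enriched_terms(
            {"A": universe[:10], "B": universe[30:]}, universe, term_map, alpha=1e-3
        )
        assert set(table["term"]) == {"hit"}


class TestSnpDensity:
    def test_density_arithmetic(self):
        regions = {"HOT": [GenomicInterval("chr1", 0, 1_000)]}
        variants = [("chr1", p) for p in range(0, 1_000, 100)]
        table = snp_density(regions, variants)
        assert table.loc[0, "density"] == pytest.approx(0.01)

    def test_no_variants_zero_density(self):
        regions = {"HOT": [GenomicInterval("chr1", 0, 1_000)]}
        table = snp_density(regions, [])
        assert table.loc[0, "density"] == 0.0

    def test_zero_bp_flagged(self):
        table = snp_density({"HOT": []}, [("chr1", 5)])
        assert not bool(table.loc[0, "computable"])

    def test_two_to_one_planted_ratio_recovered(self):
        rng = np.random.default_rng(99)
        hot = [GenomicInterval("chr1", 0, 500_000)]
        cold = [GenomicInterval("chr1", 500_000, 1_000_000)]
        variants = [("chr1", int(p)) for p in rng.integers(0, 500_000, size=2_000)]
        variants += [("chr1", int(p)) for p in rng.integers(500_000, 1_000_000, size=1_000)]
        table = snp_density({"HOT": hot, "COLD": cold}, variants).set_index("region_class")
        ratio = table.loc["HOT", "density"] / table.loc["COLD", "density"]
        assert 1.6 <= ratio <= 2.4
        assert table.loc["HOT", "p_vs_COLD"] < 1e-10
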