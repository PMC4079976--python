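"""Downstream statistics over occupancy region classes.

Covers the comparative analyses that follow region classification:
conservation meta-profiles and central-window rank tests, overlap of
open/closed enhancer classes with region classes (chi-square),
consensus-motif occurrence and enrichment relative to random regions,
hypergeometric gene-set enrichment with Bonferroni correction, and
variant (SNP) density per region class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeSpec, GenomicInterval, ScoreTrack, EnhancerSet
from .intervals import IntervalIndex, merge_intervals, total_coverage

__all__ = [
    "ConservationProfile",
    "EnrichmentResult",
    "conservation_profile",
    "central_score_test",
    "enhancer_overlap",
    "motif_enrichment",
    "geneset_enrichment",
    "filter_enriched_terms",
    "snp_density",
    "iupac_to_regex",
    "region_center",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHSWN", "TGCAYRMKVBHDSWN")


def region_center(region: GenomicInterval) -> int:
    """Deterministic region center: floor((start + end) / 2)."""
    return (region.start + region.end) // 2


@dataclass
class ConservationProfile:
    """Across-region mean score per window, centred on region centers.

    offsets are window midpoints relative to the region center and are
    symmetric about 0.
    """

    offsets: np.ndarray
    mean_score: np.ndarray
    n_regions: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean_score": self.mean_score})


def conservation_profile(
    regions: Sequence[GenomicInterval],
    track: ScoreTrack,
    flank: int = 1000,
    window: int = 10,
) -> ConservationProfile:
    """Windowed conservation meta-profile over center +/- flank.

    Per region, each window's mean is the length-weighted track mean
    (uncovered bases 0); the profile is the unweighted across-region
    mean per window.  Windows extending past a chromosome edge use the
    0 default for out-of-range bases.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    if (2 * flank) % window != 0:
        raise ValueError("window must divide 2*flank")
    n_win = 2 * flank // window
    offsets = -flank + window * np.arange(n_win) + window / 2
    acc = np.zeros(n_win)
    for region in regions:
        c = region_center(region)
        lo = c - flank
        for w in range(n_win):
            a, b = lo + w * window, lo + (w + 1) * window
            a_clip = max(a, 0)
            if a_clip < b:
                # out-of-range prefix counts as 0 via length-weighting
                acc[w] += track.mean(region.chrom, a_clip, b) * (b - a_clip) / window
    return ConservationProfile(offsets, acc / len(regions), len(regions))


def _central_means(
    regions: Sequence[GenomicInterval], track: ScoreTrack, width: int
) -> np.ndarray:
    half = width // 2
    out = []
    for region in regions:
        c = region_center(region)
        a, b = max(c - half, 0), c + half
        out.append(track.mean(region.chrom, a, b))
    return np.asarray(out)


def rank_sum_test(x: np.ndarray, y: np.ndarray, exact_max_n: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null enumeration for combined n <= exact_max_n (and no ties
    requirement from scipy's exact path is respected by falling back to
    the normal approximation with continuity correction when ties are
    present); otherwise the normal approximation with continuity
    correction.  All-tied samples give p = 1.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    n = len(x) + len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n
    method = "exact" if (n <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def central_score_test(
    regions_a: Sequence[GenomicInterval],
    regions_b: Sequence[GenomicInterval],
    track: ScoreTrack,
    width: int = 100,
) -> tuple[float, float, float]:
    """Compare central-window conservation between two region groups.

    Returns (mean_a, mean_b, p) where the means are per-region central
    means averaged per group and p is the two-sided Wilcoxon rank-sum
    p-value over the per-region means.
    """
    if len(regions_a) < 2 or len(regions_b) < 2:
        raise ValueError("need >= 2 regions per group")
    a = _central_means(regions_a, track, width)
    b = _central_means(regions_b, track, width)
    return float(a.mean()), float(b.mean()), rank_sum_test(a, b)


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a 2x2 table.

    A table with identical rows (statistic 0) gives p = 1.
    """
    table = np.asarray(table, float)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def enhancer_overlap(
    enhancers: EnhancerSet,
    regions_by_class: Mapping[str, Sequence[GenomicInterval]],
    significance: float = 1e-20,
) -> pd.DataFrame:
    """Fractions of open and closed enhancers overlapping each region
    class, with a 2x2 chi-square (enhancer class x overlapped-or-not,
    no continuity correction) per region class.

    Returns one row per region class with columns open_fraction,
    closed_fraction, chi2, p, significant (p < *significance*) and
    computable (False when an enhancer class is empty).
    """
    open_e = enhancers.of_class("open")
    closed_e = enhancers.of_class("closed")
    rows = []
    for cls, regions in regions_by_class.items():
        index = IntervalIndex(regions)
        n_open_hit = sum(index.any_overlap(e) for e in open_e)
        n_closed_hit = sum(index.any_overlap(e) for e in closed_e)
        computable = len(open_e) > 0 and len(closed_e) > 0
        row = {
            "region_class": cls,
            "n_open": len(open_e),
            "n_closed": len(closed_e),
            "open_fraction": n_open_hit / len(open_e) if open_e else np.nan,
            "closed_fraction": n_closed_hit / len(closed_e) if closed_e else np.nan,
            "computable": computable,
        }
        if computable:
            table = np.array(
                [
                    [n_open_hit, len(open_e) - n_open_hit],
                    [n_closed_hit, len(closed_e) - n_closed_hit],
                ]
            )
            if table.sum(axis=0).min() == 0:
                # a zero margin (nobody/everybody overlapped) -> no test
                row.update(chi2=np.nan, p=np.nan, significant=False)
            else:
                chi2, p = chi_square_2x2(table)
                row.update(chi2=chi2, p=p, significant=p < significance)
        else:
            row.update(chi2=np.nan, p=np.nan, significant=False)
        rows.append(row)
    return pd.DataFrame(rows)


def iupac_to_regex(consensus: str) -> re.Pattern:
    if not consensus:
        raise ValueError("empty consensus")
    try:
        pattern = "".join(IUPAC[c] for c in consensus.upper())
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r}") from None
    return re.compile(pattern)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _has_motif(seq: str, fwd: re.Pattern, rev: re.Pattern) -> bool:
    return bool(fwd.search(seq) or rev.search(seq))


def motif_fraction(
    regions: Sequence[GenomicInterval],
    sequences: Mapping[str, str],
    consensus: str,
) -> float:
    """Share of regions containing >= 1 consensus match on either strand."""
    fwd = iupac_to_regex(consensus)
    rev = iupac_to_regex(reverse_complement(consensus))
    n_hit = 0
    for region in regions:
        seq = sequences[region.chrom]
        if region.end > len(seq):
            raise ValueError(f"region {region.chrom}:{region.start}-{region.end} outside sequence")
        if _has_motif(seq[region.start : region.end], fwd, rev):
            n_hit += 1
    return n_hit / len(regions)


def motif_enrichment(
    regions: Sequence[GenomicInterval],
    sequences: Mapping[str, str],
    consensus: str,
    n_random: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Motif occurrence in regions vs length/chromosome-matched random
    regions.

    Returns (fraction_with_motif, enrichment) where enrichment is the
    observed fraction divided by the mean fraction over *n_random*
    random region sets; a zero baseline yields enrichment = inf.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    rng = rng if rng is not None else np.random.default_rng()
    fraction = motif_fraction(regions, sequences, consensus)
    fwd = iupac_to_regex(consensus)
    rev = iupac_to_regex(reverse_complement(consensus))
    baseline = 0.0
    for _ in range(n_random):
        n_hit = 0
        for region in regions:
            seq = sequences[region.chrom]
            start = int(rng.integers(0, len(seq) - region.length + 1))
            if _has_motif(seq[start : start + region.length], fwd, rev):
                n_hit += 1
        baseline += n_hit / len(regions)
    baseline /= n_random
    enrichment = fraction / baseline if baseline > 0 else float("inf")
    return fraction, enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one annotation term."""

    term: str
    k: int  # selected genes carrying the term
    n: int  # selected genes
    K: int  # universe genes carrying the term
    N: int  # universe size
    p: float
    p_bonferroni: float


def geneset_enrichment(
    selected: Sequence[str],
    universe: Sequence[str],
    term_map: Mapping[str, Sequence[str]],
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment per term, Bonferroni
    corrected over the number of terms represented in the universe.

    term_map maps gene -> iterable of term identifiers and must cover
    the universe (genes with no terms map to an empty list).
    """
    selected_set = set(selected)
    universe_set = set(universe)
    if not selected_set <= universe_set:
        raise ValueError("selected genes must be a subset of the universe")
    term_universe: dict[str, set[str]] = {}
    for gene in universe_set:
        for term in term_map.get(gene, ()):  # type: ignore[call-overload]
            term_universe.setdefault(term, set()).add(gene)
    n_terms = len(term_universe)
    N, n = len(universe_set), len(selected_set)
    out = []
    for term in sorted(term_universe):
        genes = term_universe[term]
        K = len(genes)
        k = len(genes & selected_set)
        # upper tail P(X >= k); k = 0 gives p = 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(p, 1.0)
        out.append(
            EnrichmentResult(term, k, n, K, N, p, min(p * n_terms, 1.0))
        )
    return out


def filter_enriched_terms(
    gene_lists: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    term_map: Mapping[str, Sequence[str]],
    alpha: float = 1e-5,
) -> pd.DataFrame:
    """Enrichment across several gene lists (e.g. HOT-only, HOT+COLD,
    COLD-only targets), retaining terms whose Bonferroni-corrected p is
    <= *alpha* in at least one list.

    Returns a long-format table (list_name, term, k, n, K, N, p,
    p_bonferroni) restricted to the retained terms.
    """
    frames = []
    for name, genes in gene_lists.items():
        for res in geneset_enrichment(genes, universe, term_map):
            frames.append({"list_name": name, **res.__dict__})
    table = pd.DataFrame(
        frames, columns=["list_name", "term", "k", "n", "K", "N", "p", "p_bonferroni"]
    )
    if table.empty:
        return table
    keep = table.groupby("term")["p_bonferroni"].min()
    retained = set(keep[keep <= alpha].index)
    return table[table["term"].isin(retained)].reset_index(drop=True)


def snp_density(
    regions_by_class: Mapping[str, Sequence[GenomicInterval]],
    variants: Sequence[tuple[str, int]],
) -> pd.DataFrame:
    """Variant density (variants per bp of non-overlapping class
    territory) per region class, with pairwise two-proportion z-tests.

    variants are (chrom, position) pairs.  Returns one row per class
    (density, n_variants, total_bp, computable) with pairwise test
    columns z_vs_<other> and p_vs_<other>.
    """
    per_class = {}
    for cls, regions in regions_by_class.items():
        merged = merge_intervals(regions) if regions else []
        index = IntervalIndex(merged)
        bp = total_coverage(merged) if merged else 0
        count = sum(
            1 for chrom, pos in variants if index.overlapping_point(chrom, pos)
        )
        per_class[cls] = (count, bp)
    rows = []
    classes = list(per_class)
    for cls in classes:
        count, bp = per_class[cls]
        row = {
            "region_class": cls,
            "n_variants": count,
            "total_bp": bp,
            "density": count / bp if bp > 0 else np.nan,
            "computable": bp > 0,
        }
        for other in classes:
            if other == cls:
                continue
            c2, bp2 = per_class[other]
            if bp > 0 and bp2 > 0:
                p_pool = (count + c2) / (bp + bp2)
                se = np.sqrt(p_pool * (1 - p_pool) * (1 / bp + 1 / bp2))
                z = ((count / bp) - (c2 / bp2)) / se if se > 0 else 0.0
                row[f"z_vs_{other}"] = z
                row[f"p_vs_{other}"] = 2 * stats.norm.sf(abs(z))
            else:
                row[f"z_vs_{other}"] = np.nan
                row[f"p_vs_{other}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
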