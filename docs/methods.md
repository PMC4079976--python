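# Methods

This note documents the models and procedures implemented in
`hotregions`, the parameters that matter, the design choices made where
the published procedure is ambiguous, and what the synthetic data do
and do not establish.

## Occupancy model

The input is a collection of peak sets, one per transcription-related
factor (TRF) per context. Each peak contributes a single point — its
summit, or its midpoint when no summit was called. All points from all
factors on a chromosome are pooled and an **unnormalized Gaussian
kernel density** is evaluated:

    density(x) = Σ_c exp( −(x − c)² / (2 h²) ),   h = 300 bp

Every local maximum of the density along the chromosome is a candidate
region. Its **complexity** (occupancy score) is

    complexity = Σ_r  max_s exp( −(center − s)² / (2 h²) )

where the sum runs over peak sets r, the max over that set's summits s
on the chromosome, and only sets contributing at least
`min_contribution = 0.1` are counted. Because the kernel is
unnormalized, a factor bound exactly at the candidate contributes 1,
so complexity is on the scale of "number of co-bound factors".
Regions with complexity ≥ 15 are classified HOT, ≤ 3 COLD, strictly
between WARM.

Design choices where the procedure is underdetermined:

- **All peak sets contribute.** The complexity sum does not exclude an
  "owning" regulator: candidates are density maxima and are owned by
  no single set. This keeps complexity ≈ co-bound factor count, which
  is what makes the ≥15/≤3 thresholds interpretable. Both thresholds
  are parameters (`hot_threshold`, `cold_threshold`) for users who
  prefer a different mapping between complexity and factor count.
- **Per-chromosome density.** Kernels never straddle chromosome
  boundaries; cross-chromosome distances are meaningless.
- **Scan grid.** The density is scanned on a 10-bp grid (≤ h/10,
  enough to resolve every maximum of a 300-bp kernel). Plateau maxima
  report their leftmost grid point; maxima below density 1e-3 are
  dropped (they can only arise from kernel tails).
- **Exact vs truncated kernels.** Pointwise density (`kde_density`)
  evaluates the full sum so it agrees with a brute-force oracle to
  rounding error. The gridded scan truncates terms beyond 8 bandwidths
  (each < 1.3e-14), which cannot move any reported maximum.
- **Region extent.** The published procedure never defines HOT-region
  boundaries; the reported extent is center ± one bandwidth
  (`region_halfwidth`, configurable).

## Colocalization null

For a pair of peak sets, the statistic is the number of peaks of the
first set overlapping (≥ 1 bp, half-open) at least one peak of the
second. The null re-places the first set's peaks uniformly at random
on their own chromosomes, preserving chromosome and length (summit
offset preserved relative to the start; overlaps among shuffled peaks
allowed), with the second set fixed; `Z = (obs − null mean)/null sd`
with the sample sd over `n_perm` shuffles. The original analysis
delegates its null to an external statistics service whose exact model
is not recoverable; the implemented null is the standard simple
length-preserving shuffle and is documented as such. Per unordered
pair the smaller set is shuffled (ties broken by label) and the RNG
stream is derived from the master seed plus the sorted pair labels, so
the matrix is independent of input order. A zero-variance null gives
Z = 0 when the observation equals the null mean and is otherwise
flagged degenerate rather than reported as ±inf.

Masked variants (e.g. "HOT regions excluded") remove the peaks of
*both* sets that touch any masked interval before any counting, which
isolates pairwise specificity from promiscuous co-binding at HOT loci.

Default `n_perm` is 10,000 at the library level, matching the
published procedure; the bundled pipeline and tests run 1,000, which
bounds the Z resolution at roughly ±0.03 on the null sd and is the
package's desk-scale default.

## Annotation rules

Feature categories partition peaks by their summit point:

- promoter — within 1 kb upstream of a TSS, or in the 5′ UTR;
- downstream — 3′ UTR, or within 200 bp past the gene end;
- coding — CDS; intron — transcribed, non-exonic;
- intergenic — none of the above.

When the point hits features of several genes the priority is
promoter > downstream > coding > intron (regulatory categories above
transcribed ones; the published category list states no multi-gene
rule). Non-coding genes have no CDS/UTR sub-features; hits inside them
classify at intron priority. Target genes are assigned by nearest TSS
within 10 kb, exact ties to the lexicographically smallest gene id.

Chromatin states use whole-peak overlap with priority
BLUE > RED > YELLOW > GREEN > BLACK; peaks touching no segment are
"unassigned". A gene is a Polycomb target when its gene unit
[tx_start, tx_end) contains ≥ 100 bp of BLUE summed over segments. A
factor "prefers" BLUE when strictly more than 35% of its peaks are
assigned BLUE.

## Region statistics

- **Conservation profiles**: per region, 10-bp-window means of the
  score track over center ± 1 kb (uncovered bases score 0, the
  absent-score convention of conservation tracks); the profile is the
  unweighted across-region mean. Region center is floor((start+end)/2).
- **Central-window test**: per-region mean over the central 100 bp;
  two-sided Wilcoxon rank-sum between groups — exact enumeration for
  combined n ≤ 20 without ties, normal approximation with continuity
  correction otherwise; all-tied groups give p = 1.
- **Enhancer overlap**: per occupancy class, the fraction of open and
  of closed enhancers overlapped, with a 2×2 Pearson χ² (no Yates
  correction — the regime of interest is far from small counts) and a
  significance flag at p < 1e-20.
- **Motif occurrence**: share of regions containing ≥ 1 match of an
  IUPAC consensus on either strand (overlapping matches allowed);
  enrichment is this share divided by its mean over 100 sets of
  length- and chromosome-matched uniform-random regions. The default
  consensus is GAGAG (the classic Trl/GAGA-factor element),
  configurable.
- **Gene-set enrichment**: hypergeometric upper tail P(X ≥ k) per
  term, Bonferroni-corrected by the number of terms represented in the
  universe (no term-hierarchy handling); the three-list helper keeps
  terms passing ≤ 1e-5 in at least one of the HOT-only / HOT+COLD /
  COLD-only lists.
- **Variant density**: variants per bp of the class's merged
  territory, with pairwise two-proportion z-tests.

## Synthetic data

The generator plants loci on a slot grid (5-kb pitch, ≥ 2.5-kb
separation after jitter, ≥ 2 kb from chromosome ends). Default study
conditions: 2 chromosomes × 5 Mb, 25 factors, 50 loci per class at
multiplicities 20 (HOT), 8 (WARM), 2 (COLD), summit jitter
Normal(0, 25 bp), peak widths Normal(200, 40) clipped at ≥ 50 bp,
background 1e-6 peaks/bp/factor (~10 background peaks per factor).
Factors at a locus are drawn without replacement so multiplicity
equals the distinct-factor count. Every output derives from one seed
through named substreams, so each generator is reproducible on its
own.

Consistent auxiliary tracks:

- chromatin: a five-color tiling with BLACK-majority weights
  (~50% BLACK, matching the published genome share) in 2-kb segments;
  genes flagged `pc_target` (25% by default) get a ≥ 150-bp BLUE
  stretch painted inside the gene unit;
- conservation: 0.8 over ±150 bp at COLD/WARM loci, 0.2 at HOT
  centers, and a genome-wide baseline of 0.45 elsewhere — the typical
  genome-average conservation level, which also gives background
  (unplanted) binding regions a realistic non-zero score;
- enhancers: two contexts; enhancers placed at planted loci with
  per-class probability and labelled open with per-class probability
  (open favours HOT, closed favours COLD);
- variants: uniform at 2e-3/bp with a 2× rate inside ±300 bp of HOT
  loci;
- sequence: uniform ACGT with the consensus motif written at HOT loci
  (rate 0.8).

What the synthetic data do **not** emulate: ChIP signal shape and
read-level noise, realistic nucleotide composition, width differences
between ChIP-chip and ChIP-seq peaks, correlated factor families,
chromatin-state autocorrelation, and genuinely graded occupancy (the
planted multiplicities are three point masses). Passing recovery tests
therefore demonstrates the algorithmic chain — density → candidates →
complexity → class → downstream statistics — under controlled truth,
not performance on real compendium-scale data (hundreds of ChIP data
sets), whose headline counts this package makes no claim to reproduce.

## Numerical and degenerate-input conventions

- All coordinates 0-based half-open; overlap = ≥ 1 shared bp.
- narrowPeak summit −1 falls back to the interval midpoint (a summit
  is required by the density scan).
- Score tracks reject overlapping runs at read time (no silent merge);
  uncovered bases score 0.
- Empty peak sets or empty-after-masking pairs are flagged degenerate,
  never silently dropped.
- Matrix display ordering uses agglomerative clustering (Euclidean,
  average linkage) with ties resolved to input order; two rows keep
  input order.
- Stage seeds are `master*1_000_003 + crc32(stage)` mod 2³¹; per-pair
  colocalization seeds hash the sorted pair labels, so neither stage
  order nor input order changes results.

## Problem sizes used by the bundled checks

The test suite and the acceptance script run the default synthetic
study (10 Mb, 25 factors, 150 loci, ~1,750 peaks), a 50-seed null
calibration of the permutation Z (200-peak sets on 10 Mb, 1,000
permutations), and two full pipeline runs for the determinism check —
the package's chosen desk-scale conditions.

## Known limitations

- The permutation null ignores chromatin segmentation and
  accessibility structure (no GAT/GSC-style conditioning).
- Complexity-to-factor-count calibration is exact only for exactly
  coincident summits; jitter shrinks contributions slightly below 1,
  so the HOT threshold of 15 corresponds to ~15 factors only when
  jitter ≪ bandwidth.
- Gene-set enrichment treats terms as flat labels; no ontology depth
  selection.
- Annotation is gene-level, not isoform-aware.
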