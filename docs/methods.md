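# Methods

This note records the statistical model behind each stage, the defaults
and why they hold, what the synthetic data does and does not emulate, and
the design choices made where the method left room.

## Coordinates and interval conventions

All coordinates are 0-based half-open (`[start, end)`), BED-native.
Distance from a point (a TSS) to an interval is measured to the nearest
*included* base (`end − 1`), never to the exclusive end, so an adjacent
interval is 1 bp away and `[100, 200)` vs `[200, 300)` do not overlap.
Nearest-gene ties break by smaller distance, then lexicographically
smaller gene id — the method itself is silent on ties and determinism is
required. Peak extension re-centres on `floor((start+end)/2)` and clips
the left edge at 0, so extended widths are exactly `2·flank` except at a
chromosome start. Consensus regions are reported as maximal runs of
coverage by ≥ `min_sets` *distinct* input sets (each set is merged
internally first so a fragmented replicate cannot double-count); the
sweep processes starts before ends at equal positions so abutting
coverage forms one region. Two promoter windows coexist deliberately:
1.5 kb for peak-to-gene assignment and the association universe, 1 kb for
genomic-category annotation — both are exposed as parameters rather than
reconciled, since the analyses use them at different stages.

## Statistical primitives

`fisher_2x2` reports the classic two-sided p (sum of hypergeometric
probabilities ≤ the observed table's, at fixed margins; verified against
exact rational enumeration for all margins ≤ 40) and a *cross-product*
odds ratio `ad/bc`, not the conditional MLE, with 0.5 added to all four
cells when any is zero (Haldane–Anscombe) so `log2_or` stays finite. The
cross-product is the reproducible closed form behind log2 OR displays.
BH adjustment is the standard step-up (statsmodels), input order
preserved, capped at 1. Cohen's D uses the pooled-SD denominator
`s_p² = ((n_x−1)s_x² + (n_y−1)s_y²)/(n_x+n_y−2)` with *sample* variances —
the standard definition. k-means is k-means++ with 25 restarts and a
fixed seed (determinism and objective quality are the contract; the
original analyses used a different implementation and bit-compatibility
is not claimed). The rank-sum test is exact (full enumeration) for
tie-free samples with both n ≤ 20 and the tie-corrected normal
approximation otherwise; the t test defaults to the equal-variance pooled
statistic, with Welch available.

## Differential testing

The internal differential test is deliberately simple plumbing: counts
are CPM-normalised, shifted by +1, log2-transformed, and each feature gets
a two-sample t test with BH across features within the contrast. It
defaults to the *pooled* Student t rather than Welch: at the study scale
of 4 replicates per condition the Welch degrees-of-freedom estimate is
conservative (measured type-I ≈ 0.039 at nominal 0.05 on null
negative-binomial data, versus ≈ 0.048–0.051 for the pooled test across
seeds), and the group variances are exchangeable by design. Externally
computed differential tables are first-class inputs. Direction labels use
strict inequality at the FDR threshold (`adj_p < 0.05`), and a zero
log2FC is never called, so `up/down/ns` partition the features
deterministically.

## Cross-layer association

The pair universe is *all* linked pairs measured in both layers, not only
ever-differential ones: this makes the `d` cell well-defined and the test
a standard enrichment (the alternative reading is available via
pre-filtering the pair list). A gene contributes at most one promoter-peak
pair (the single closest peak within 1.5 kb); distal pairs may be
many-to-one. Admissible cells require the target contrast's late day to
be the same or later than the source's; where layers sit on different
day grids (proteomics sampled every 2 days), target days are mapped to
the nearest source-grid day with ties to the *later* day, so a day-10
protein contrast aligns with the day-12 grid point. BH families are
entire pair groups — all tests of one group adjusted together — not
per-time-point. On planted conditional coupling
(P(target up | source up) = 0.8 vs 0.2, analytic OR 16) the recovered
log2 OR is unbiased within Monte-Carlo error at n = 2000 pairs.

## TF activity and the permuted-site null

A TF's activity for a contrast is the unweighted mean of per-site log2
accessibility fold changes over its in-peak sites (sites extended 50 bp
each side; overlap ties go to the larger-overlap, then lexicographically
smaller peak). An optional weighting by motif match score exists but the
default is unweighted — the activity statistic is defined as a mean of
genome-wide differences. Significance is Cohen's D between the TF's
per-site fold-change *distribution* and the pooled distribution of
permuted binding-site sets: same-size random draws (without replacement
per draw) from all other TFs' in-peak sites. Standardising by the
per-site spread makes D an effect size independent of site count — a TF
whose sites are a random subset of the pool concentrates near D = 0
(observed |D| ≈ 0.05 at 200 sites), while a planted one-pooled-SD shift
scores D ≈ 2. An alternative null that compares distributions of
*means* was considered and rejected: its D behaves like a z-score of the
TF's sampling noise, so |D| > 1 fires on ~32% of null TFs, which no
useful threshold survives. `min_sites = 50` (relaxed in the toy analysis
scripts) guards rare motifs; `d_threshold = 1` defines the significance
call. PWM scanning scores log2 odds against a uniform 0.25 background
with a pseudocount, on both strands, keeping windows scoring at least
`min_score_frac` (default 0.8) of the motif's maximum attainable score;
windows containing N are skipped.

## Chromatin states and the co-bound comparison

Mean mark signal over a peak is the length-weighted bedGraph average with
uncovered bases counting as 0 (not missing), so sparse tracks compare on
one scale. Regulatory grouping z-scores each track before k-means
(constant tracks are dropped; they carry no information) and reports
per-group mean z-signatures; merging of visually similar groups is a
judgement call left to the analyst. Co-occupancy requires factor sets to
be pre-merged to non-overlapping regions, but the ≥1 bp overlap fraction
is invariant to that merge (property-tested). The three-way partition
reports co-bound regions at the coordinates of the factor under study
(the A side), and the three groups are disjoint and cover every input
peak. Group comparisons attach expression to peaks by nearest TSS.

## Interactome scoring

Interactor calling applies the exclusive / ≥4-fold branches strictly per
replicate: *exclusive* requires bait-side detection in every replicate
and IgG zero in every replicate; *enriched* requires IgG > 0 and fold ≥
`min_fold` in every replicate. Mixed patterns (IgG zero in one replicate,
positive in the other) are rejected — the only reading under which both
branches stay mutually exclusive and per-replicate. Protein intensity per
cell type is the mean over bait runs (not the max); intensities are used
as provided, with upstream normalisation assumed done (or emulated by the
generator). The association rate divides each protein's protein/bait
intensity ratio in one cell type by the same ratio in the other, log2 —
bait normalisation makes it invariant to global run scaling, and swapping
the cell types negates every score. Residuals from the least-squares line
of rate on expression change flag recruitment-regulated candidates.

## Synthetic data

Generators are pure functions of `(config, seed)`; re-runs are
byte-identical. The toy genome is 2 × 200 kb with 100 genes tiled in the
first half of each chromosome and distal peaks slot-tiled in the
gene-free second half (400 peaks total, 80% of genes get one promoter
peak within 1.5 kb whose planted gene is the actual nearest TSS). The
time design mirrors the modelled study: RNA/ATAC on days 0/4/8/12 with 4
replicates, proteomics every 2 days to day 10 with 2 replicates. Counts
are negative-binomial (dispersion 0.1) around log-normal baselines
(log2 mean 7, SD 1.5) with log-normal library sizes (CV 0.2) — values at
which a planted |log2FC| ≥ 1 is reliably detectable at 4 replicates;
proteins are log-normal (SD 0.25) around an RNA-lagged trajectory.
Cross-layer coupling is conditional-directional: a source-layer change at
step *t* propagates its sign to the target layer at *t* + 4 days with
probability 0.8, against a 0.2 base rate (analytic OR 16). ChIP peaks are
anchored near distinct gene TSSs and drawn from four regulatory
archetypes (active promoter / active enhancer / poised / quiescent) with
multiplicative signal noise; a 30% co-bound subset receives an
overlapping partner peak, a +2 shift on H3K27ac/H3K4me1, and a +2 log2
shift on nearest-gene expression. Only peaks with clearance from their
neighbours are eligible for co-binding, so the planted co-bound labels
coincide exactly with the ≥1 bp overlap partition. Pull-down tables plant
30 exclusive, 30 enriched (folds 5–16) and 140 background proteins
(folds 0.5–3) with the bait ~1000× above the interactor distribution,
and a per-protein log2 association-rate drawn N(0, 1) that the scoring
recovers exactly at zero noise.

What the generators do **not** emulate: read-level data, GC or
mappability structure, realistic motif content (sequence is uniform
ACGT), peak-width and signal distributions of real ChIP, correlated
replicate structure beyond library-size noise, and missing-value
mechanisms of real proteomics. Passing tests therefore demonstrate that
the *procedures* are correct and calibrated under their stated models,
not that real data meets those models.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at toy scale —
oracle checks on 10 kb chromosomes and ≤ 500-pair universes, 50-seed
recovery loops, 100-rep null calibrations, an end-to-end association run
at 600 genes — sizes chosen so the full suite completes in well under a
minute-scale budget while keeping Monte-Carlo error far below the asserted
tolerances. Degenerate inputs are contracts, not crashes: all-zero 2×2
tables, empty peak sets and zero library sizes raise; zero pooled SD
returns signed infinity (or 0 for equal means); all-tied rank-sum returns
p = 1; a too-small site pool falls back to sampling with replacement with
a warning.

## Known limitations

The internal differential test is a stand-in for count-model fits and is
less powerful than a negative-binomial GLM at low counts. The association
universe choice (all pairs vs ever-differential pairs) changes the OR's
interpretation; both are possible but only the default is calibrated
here. The permuted-site null ignores site-to-site correlation within a
peak (sites in one peak share counts), which real data would exhibit.
Exact rank-sum p values are only computed for n ≤ 20 without ties.
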