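# Methods

This note documents the models, conventions and numerical choices behind
`topoturn`, and what the synthetic-data tests do and do not establish about
real data.

## Coordinate and track conventions

All intervals are 0-based half-open (BED). Blacklist exclusion removes any
record overlapping a blacklist interval by ≥ 1 bp, applied at the fragment
and interval level before any statistic; abutting records are kept. A
coverage track stores one float per fixed-width bin per chromosome; a bin's
value is the mean per-base fragment depth (fragment bp in the bin divided by
the bin width), so a bin fully covered by one fragment reads 1.0 and total
mass Σ(value × width) equals total fragment bp exactly. Profile-grade tracks
default to 10-bp bins; genome-wide correlations use 10-kb bins.

Each track carries a `normalization_state` tag (`raw`, `spike_scaled`,
`znormalized`, `log2_ratio`). Operations check tags rather than trusting
call order: replicate averaging requires a shared state, and the ratio
operation requires both inputs in the same state, which enforces the
documented pipeline order — spike-scale each library, combine replicates,
then take the ratio.

## Spike-in normalization

CUT&RUN-style libraries carry an exogenous spike-in whose read count is
proportional to sequencing depth for a fixed spike-in input. Tracks are
scaled by `scale_constant / spike_in_count` with `scale_constant` = 10,000.
The constant is arbitrary: it cancels in every ratio, correlation, and
rank-based statistic downstream; only the division by the spike count
matters, making libraries of different depth comparable. The property this
buys — and the one the tests assert — is depth invariance: the same sample
sequenced twice as deep yields the same scaled track within sampling error.
Spike scaling deliberately does **not** absorb genuine global signal
changes between conditions; in the simulator the spike count is therefore
binomial in a condition-invariant nominal depth, not in the realized
library size.

## ΔTOP1cc

ΔTOP1cc is the per-bin log₂ ratio of prolonged-damage (30′ CPT) over
steady-state (5′ CPT) TOP1cc coverage. A pseudocount ψ = 0.5 (per bin, on
the scaled coverage scale) prevents infinities while perturbing high-signal
bins negligibly; bins with zero coverage in *both* conditions carry no
evidence and are masked as missing rather than reported as 0. Sign
convention: ΔTOP1cc > 0 means accumulation (impaired turnover).

Z-normalization uses the population SD; at genome scale the sample/
population distinction is immaterial but must be fixed for exact tests.
Z-normalization, where used, is applied to the *input* coverage tracks,
never to the ratio track itself: recentering the ratio at zero would
destroy the interpretation of its sign. An explicit flag exposes the other
order for comparison, off by default.

## Stratified statistics

Per gene, ΔTOP1cc is averaged (bp-weighted, missing bins excluded) over
TSS ± 250 bp. Genes are ranked by expression and split into four
rank-balanced quartiles (sizes differing by ≤ 1; ties broken by stable
input order). All six pairwise quartile contrasts are tested with a
two-sided Mann–Whitney *U*, reported unadjusted (a Benjamini–Hochberg
helper is available but off by default, matching the convention of
reporting raw pairwise p values for this contrast). The *U* test uses full
enumeration of all C(n₁+n₂, n₁) labelings when the pooled sample has ≤ 12
observations without ties — exact by construction — and otherwise a normal
approximation with tie correction and 0.5 continuity correction, clamped at
z = 0 so that identical samples give p = 1. The asymptotic branch is
cross-checked against an independent reference implementation in the tests.

TOP1 peaks are scored by mean occupancy signal over the peak (max-based
scoring behind a flag), ranked, and split into tertiles; the top and bottom
tertiles are kept, the middle discarded. All-equal scores fall back to
stable input order with a warning.

## Metaprofiles and LOESS

Reference-point matrices average track signal into positional bins across a
[−upstream, +downstream) window per anchor; minus-strand rows are flipped
so column 0 is always 5′-most. Windows extending past chromosome ends are
missing, not zero — zero-filling would fabricate depletion at boundaries —
and missing cells are excluded from column means. LOESS smoothing is
degree-1 local regression with tricube weights over the nearest
⌈span·n⌉ points, no robustness iterations (delegated to statsmodels
`lowess` with `it=0`); span 0.15 by default, 0.025 for fine-grained TSS
profiles. Local linear fitting reproduces exactly linear profiles and is
shift- and scale-equivariant, which the property tests assert.

## Jaccard permutation test

The genomic Jaccard index is intersection bp over union bp of the two
flattened interval sets (undefined, and an error, when both are empty).
The null relocates **both** sets independently per iteration: each interval
keeps its length and is placed uniformly among all valid start positions,
chromosomes weighted by their number of valid starts; placements
overlapping the blacklist are rejected and redrawn. Shuffled intervals may
overlap one another, matching the default of the standard shuffle tool.
The empirical p uses the add-one estimator (1 + #{null ≥ observed})/(n+1),
which cannot return 0 and is uniformly distributed under the null — a
calibration test verifies the p < 0.05 rate over 200 independent-null runs
against the exact binomial band. Randomness everywhere uses the Philox
counter-based generator seeded by a single recorded integer.

TSS-proximity classification uses the peak midpoint: distance ≤ 3 kb to
the nearest TSS is proximal, > 10 kb distal; the thresholds leave a 3–10 kb
gap class, which is reported explicitly (`excluded`) so the partition is
exhaustive.

## Synthetic-data generative model

The default scenario is a 4 × 2 Mbp genome, 400 genes, 300 TOP1 hotspots
(70% TSS-linked, linked TSS sampled without replacement with probability
proportional to expression), 200 macroH2A1.1 domains of which enough are
centered on randomly chosen hotspots to cover 50% of hotspot midpoints,
and a blacklist of ~0.5% of the genome. Expression is log-normal
(log-mean 1, log-SD 1); normalized expression is e = expression / max.
Hotspot widths are ~N(1000, 200²) bp (≥ 200), domain widths
~N(5000, 1000²) bp (≥ 1 kb) — peaks narrow, domains broad.

CUT&RUN libraries place 100,000 fragment midpoints from a mixture with
density F = 20 inside the target's true intervals and 1 elsewhere (IgG:
F = 1 everywhere); lengths ~N(150, 25²) bp. CAD-Seq libraries draw Poisson
fragment counts from three additive components — per hotspot at
λ = 0.2 fragments/bp of hotspot, per gene TSS ± 500 bp at 0.05 fragments/bp
(every transcribed gene engages TOP1, not only genes under a called peak),
and uniform background at 0.001 fragments/bp — with lengths
~N(1000, 150²) bp, emulating ~1 kb sonication fragments.

The turnover model: under prolonged damage a source with normalized
expression e and binary macroH2A1.1 occupancy m emits at

    intensity × (1 + δ · e · (1 − ρ · m · [genotype = control]))

with turnover deficit δ = 3 for both genotypes and protection strength
ρ = 1. In control cells macroH2A1.1-covered sites therefore accumulate
nothing (full protection); in knockdown cells accumulation scales with
expression everywhere. The expected ΔTOP1cc at a covered site is thus 0 in
control and log₂(1 + δ·e) in knockdown — the closed form the recovery
experiment checks, restricted to covered, top-quartile, *isolated* hotspots
(no neighboring hotspot midpoint within 3 kb), because fragments from a
close neighbor with a different amplification factor contaminate the
window and the single-source closed form no longer applies. δ was chosen
for statistical detectability at desk scale; the real effect size is not
quantified by violin distributions alone.

What the simulator does *not* model: sequence content, mappability,
read errors, fragment-size selection, duplicate structure, copy-number or
chromatin-accessibility biases, replication-associated damage, and any
spatial correlation beyond the placed features. Passing tests therefore
demonstrate correctness of the *analysis* under a known generative model,
not robustness to every artifact of real libraries.

## Monte-Carlo and tolerance choices

The recovery experiment uses 100 replicate library pairs per genotype on a
fixed genome and compares the replicate mean to the closed form within 3
Monte-Carlo SE; per-replicate variation is dominated by the spike-count
log-ratio (SD ≈ 0.03) plus Poisson window noise. The end-to-end signature
suite runs the full pipeline on 5 seeds at the default scenario with 1000
permutation shuffles. Brute-force per-base oracles (bitmap Jaccard,
per-base depth, per-base window means) back the interval arithmetic on
≤ 10-kb random genomes; an external interval-arithmetic tool is used as an
additional oracle for the Jaccard index where available. IgG
non-enrichment is accepted within [2/3, 3/2] of the genome mean, a wide
band that sampling error at the default library size never approaches
unless enrichment is real.

## Known limitations

- The permutation null preserves interval lengths but not inter-peak
  spacing, GC or mappability structure; against real data a
  structure-matched null would be more conservative.
- The Mann–Whitney exact path enumerates only up to 12 pooled observations;
  mid-sized tied samples rely on the corrected normal approximation.
- bigWig is not read or written; bedGraph is the serialization format.
- Heatmap rendering, scale-regions (gene-body) profiles and row clustering
  are out of scope.
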