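# topoturn

Genomic analysis of **TOP1 cleavage-complex (TOP1cc) turnover** and its
relationship to the histone variant **macroH2A1.1**.

DNA topoisomerase 1 relaxes transcription-associated supercoiling through a
covalent TOP1:DNA intermediate, the TOP1cc. Camptothecin (CPT) traps this
intermediate; whether trapped TOP1ccs are cleared or accumulate is a repair
phenotype with direct relevance to TOP1-inhibitor chemotherapy. `topoturn`
implements the sequencing-side analysis used to study this process:

- **Coverage tracks** from aligned-fragment libraries (CUT&RUN, CAD-Seq),
  with exogenous spike-in normalization, replicate averaging/merging,
  ENCODE-style blacklist exclusion, and Z-normalization
  (*Z = (score − mean)/SD*).
- **ΔTOP1cc**, the turnover statistic: the per-bin log₂ ratio of TOP1cc
  coverage after prolonged damage (30′ CPT) over steady state (5′ CPT),

  ΔTOP1cc = log₂ ( (cov₃₀′ + ψ) / (cov₅′ + ψ) ),  ψ = pseudocount,

  where ΔTOP1cc > 0 means damage-induced TOP1cc accumulation, i.e. impaired
  turnover.
- **Stratified statistics**: per-gene mean ΔTOP1cc over TSS ± 250 bp grouped
  by RNA-seq expression quartile (Q1 bottom 25% … Q4 top 25%) with two-sided
  Mann–Whitney *U* tests for all pairwise quartile contrasts; TOP1 peaks
  split into top/bottom tertiles of macroH2A1.1 occupancy.
- **Metaprofiles**: strand-oriented reference-point signal matrices around
  TSS or peak centers (the computeMatrix/plotProfile analog), with LOESS
  smoothing (tricube, degree-1 local regression; span 0.15 by default).
- **Colocalization**: the genomic Jaccard index (intersection bp / union bp)
  with a permutation null from random relocation of both interval sets
  within genome bounds (*n* = 1000 shuffles by default) and an add-one
  empirical p value.
- **Synthetic data**: a generator for genomes, TOP1 hotspots, macroH2A1.1
  domains, expression tables, and CUT&RUN/CAD-Seq fragment libraries with a
  known turnover-deficit parameter δ, so every statistic above can be tested
  against closed-form ground truth. See `docs/methods.md` for the generative
  model.

All coordinates are 0-based half-open (BED convention). Standard text
formats are used throughout: chrom.sizes, BED3/BED6, bedGraph, TSV, JSON.

## Worked example

Run the end-to-end demo: simulate a 4 × 2 Mbp genome with 400 genes, 300
TOP1 hotspots and 200 macroH2A1.1 domains, build all tracks, and compute
every headline statistic:

```sh
topoturn demo --out demo_out --seed 1
```

This prints (abridged):

```
[PASS] jaccard_colocalization: {"observed": 0.1468, "null_mean": 0.0288,
       "empirical_p": 0.000999, "z_score": 26.7}
[PASS] quartile_monotonicity_kd: {"medians": [0.070, 0.185, 0.346, 0.734],
       "q4_vs_q1_p": 3.5e-33}
[PASS] tertile_gap: {"mean_gap_mh_high": 0.357, "mean_gap_mh_low": 0.035}
[PASS] igg_no_enrichment: {"hotspot_over_genome_ratio": 0.995}
```

Reading the four lines:

1. The observed macroH2A1.1 × TOP1 Jaccard index (0.147) far exceeds its
   shuffled null (mean 0.029); over 1000 shuffles no permutation reaches it,
   so the empirical p is 1/1001 — the two interval sets colocalize
   non-randomly.
2. In the macroH2A1.1-knockdown arm, median ΔTOP1cc at TSS ± 250 bp rises
   monotonically across expression quartiles (0.07 → 0.73): TOP1cc
   accumulation after damage is strongest at highly transcribed genes.
3. The knockdown-vs-control ΔTOP1cc gap is ten-fold larger at
   macroH2A1.1-high TOP1 peaks (0.357) than at macroH2A1.1-low peaks
   (0.035): the protection is occupancy-dependent.
4. The IgG control library shows no hotspot enrichment (ratio ≈ 1), as a
   non-specific antibody should.

`demo_out/` additionally contains bedGraph tracks, LOESS-smoothed TSS
profiles, the per-quartile test JSONs, the Jaccard null distribution, and a
`manifest.json` recording every seed and parameter needed to re-run the
analysis identically.

Individual pipeline stages are available as subcommands (`simulate`,
`coverage`, `normalize`, `delta`, `profile`, `quartiles`, `tertiles`,
`jaccard`, `classify-tss`, `correlate`) and as library functions
(`import topoturn`).

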