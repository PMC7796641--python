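# blowcore

Longitudinal core-microbiota analysis of cetacean **blow** (exhaled breath
condensate) 16S amplicon count tables.

Blow sampling is a non-invasive window into the airway microbiota of dolphins
and whales, and a candidate biomarker of respiratory health. The analytical
question it raises is one of *temporal stability*: does each animal carry a
persistent, individual-specific airway community (an **intra-core**), and how
much of the community is shared across animals at a time point (an
**inter-core**)? Answering it from zOTU/ASV count tables requires a chain of
steps that this package implements as a tested, reusable pipeline:

1. **QC / decontamination cascade** — taxonomy screening (Archaea,
   chloroplasts, mitochondria), a global relative-abundance filter, a
   per-sample read-depth cutoff, prevalence-based technical-contaminant
   identification against negative controls and extraction blanks, and the
   same prevalence rule against pooled water samples. Prevalence scores are
   one-sided association probabilities from the 2×2 presence table
   (chi-square with continuity correction, or the exact hypergeometric tail
   when any expected cell is below 5); a taxon with score < 0.5 in the
   contaminant direction is removed.
2. **Alpha diversity** — rarefaction by multivariate hypergeometric
   subsampling, richness *S*, Shannon-Wiener *H* (nats), bias-corrected
   Chao1 `S + F₁(F₁−1)/(2(F₂+1))`, ACE (rare cutoff 10), Good's coverage
   `(1 − F₁/N)·100`, exact expected rarefaction curves, and linear
   mixed-model tests of subject and time effects (random intercept for the
   complementary factor, continuous AR(1) residuals over weeks, ML
   likelihood-ratio tests).
3. **Beta diversity** — Bray-Curtis dissimilarity on unrarefied counts and
   2-D non-metric MDS minimizing Kruskal stress-1.
4. **Multivariate abundance testing** — a log-link negative-binomial GLM per
   taxon with `log(library size)` offsets; a community-level
   **sum-of-likelihood-ratio** statistic for any factor, calibrated by
   **PIT-trap residual resampling** (whole sample rows of the
   probability-integral-transform residual matrix, preserving cross-taxon
   dependence); step-down maxT adjusted per-taxon p-values; McFadden-style
   deviance partitioning between subject identity and time; and a
   subject-vs-time random-effect SD ratio from per-taxon Laplace NB mixed
   models.
5. **Core detection** — per-subject intra-core sets (taxa present in every
   sample across specified weeks, with ±1-week substitution for missing
   samples), seeded random inter-core sets per week, read-fraction summaries
   and sharing histograms.

Because real blow data are not required to exercise any of this, the package
ships a first-class **synthetic cohort generator** that plants known
intra-/inter-core structure, water-taxon leakage, technical contaminants and
subject/time random effects with known SD ratio — every stage is validated by
recovering what was planted.

## Worked example

Simulate a cohort of 13 dolphins sampled at study weeks 2, 6, 11, 19, 28 and
37 (plus water and technical-control samples), filter it, and detect cores:

```
$ blowcore simulate --seed 3 --out demo
wrote cohort with 119 samples x 2148 taxa to demo

$ blowcore filter --counts demo/counts.tsv --metadata demo/metadata.tsv \
    --taxonomy demo/taxonomy.tsv --out demo_filt
78 samples x 1461 taxa after filtering

$ blowcore core --counts demo_filt/filtered_counts.tsv \
    --metadata demo/metadata.tsv --out demo_core
inter-core week 19: 30 taxa (subjects: D01, D02, D03, D04, D05, D06, D10, D11, D12, D13)
...
intra-core D01: 195 taxa
intra-core D02: 163 taxa
...
```

Reading these numbers: the generator planted 2148 taxa (1471 true blow taxa,
520 water-associated, 157 technical contaminants); the cascade removed the
contaminant and water pools and kept 78 blow samples. Each subject's
intra-core — taxa present in all four samples of weeks 6, 11, 19 and 28 —
holds roughly 160–200 taxa, and ten randomly selected subjects share a few
dozen taxa at any one week. `demo_core/core_abundance.tsv` carries the
per-sample core read fractions (intra-cores average ~0.75 of the reads in
this configuration; inter-cores ~0.25).

The full pipeline, with a machine-readable run ledger, is one command:

```
blowcore run --preset paper --seed 7 --out run7
```

Identical seeds give byte-identical ledgers and outputs.

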