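# microeuk

Analysis toolkit for **paired DNA/RNA amplicon surveys of marine microbial
eukaryotes (protists)**: table-level filtering and rarefaction, the standard
alpha/beta-diversity panel, and per-OTU **RNA:DNA ratios as a proxy of
relative metabolic activity** across water-column depth strata. It is aimed
at microbial ecologists who already have post-clustering artifacts — an OTU
count table, a PR2-style taxonomy, a rooted OTU phylogeny, and sample
metadata — from co-extracted rRNA-gene (DNA) and rRNA-transcript (RNA, i.e.
cDNA) libraries.

## The method

DNA libraries mix signal from active, dormant, and dead cells plus
extracellular DNA; rRNA transcripts decay quickly, so the RNA library skews
toward metabolically active taxa. For one co-extracted library pair at a
given site and depth, after both libraries are rarefied to a common depth
*N*, each OTU *i* present in **both** libraries (the shared-OTU rule)
contributes one observation

    r_i = (x_i^RNA / N) / (x_i^DNA / N) = x_i^RNA / x_i^DNA ,

and the relative activity of a major taxonomic group *g* in depth stratum
*s* (shallow ≤ 100 m < middle ≤ 600 m < deep) is the arithmetic mean of the
pooled per-OTU ratios. Strata are compared pairwise per group with a
two-level one-way ANOVA F-test (equivalent to a pooled-variance two-sided
t-test) at P < 0.05.

Around this sit the standard steps, all implemented and cross-checked
against independent references:

* **preprocess** — removal of Metazoa/Unassigned OTUs (with per-sample
  removed-read percentages), singleton removal, seeded
  multivariate-hypergeometric rarefaction to the minimum library size;
* **alpha** — observed OTUs, bias-corrected Chao1, ACE, Shannon (bits),
  Simpson dominance *D* and 1/*D*, Faith's phylogenetic diversity;
* **beta** — Bray-Curtis on square-root-transformed relative abundances,
  unweighted UniFrac, UPGMA dendrograms, PCoA, seeded ANOSIM and simple
  Mantel permutation tests;
* **simulate** — a generator of survey-shaped paired DNA/RNA tables with
  lognormal abundances, depth-dependent composition, planted per-group
  activity multipliers, and a metazoan contaminant fraction decaying with
  depth, plus ground truth for recovery tests.

## Worked example

Run the full pipeline on the built-in survey-shaped synthetic dataset
(2 sites × 8 depths × 2 nucleic-acid sources = 32 samples, 16 pairs,
20,204 reads per library):

```python
from microeuk import run_pipeline

results = run_pipeline(
    {"seed": 42,
     "simulate": {"paper_shaped": True, "seed": 7, "n_otus_per_group": 30},
     "permutations": 999},
    out_dir="run1",
)
```

This prints a bundle into `run1/` and returns a summary; with these seeds:

```
rarefaction_depth: 14025        (min protist library, at H7.5D)
n_samples: 32   n_pairs: 16
anosim_acid: R = 0.792, p = 0.001
mantel_bray_unifrac: r = 0.786, p = 0.001
mantel_bray_depth:   r = 0.643, p = 0.001
```

The ANOSIM shows what the method is designed to detect: samples separate by
nucleic-acid source before depth (the DNA and RNA pictures of one community
differ more than communities differ among themselves), while the Mantel
correlation against the depth-difference matrix confirms the depth gradient
within each source. `table1_twin.tsv` holds the per-sample read accounting
and diversity panel, e.g.

```
sample_id  clean_reads  metazoa_pct  protist_reads  observed_otus  chao1  shannon  simpson_D  faith_pd
F3.25D     20204        29.1         14294          452            452.0  7.69     0.009      1012.5
```

`table2_twin.tsv` holds the group × stratum activity summary
(mean RNA:DNA ratio, observation count, and the three pairwise p-values per
group). Because RNA proportions renormalize within each library, the means
are interpretable as contrasts against the community average — a group with
mean ratio 2.4 in deep water is 2.4× more transcript-rich per gene copy
than the average of the community it sits in:

```
major_group      mean_shallow  mean_middle  mean_deep  p_shallow_middle  p_shallow_deep  p_middle_deep
Bacillariophyta  0.745         1.378        2.393      0.000             0.000           0.005
Cercozoa         0.738         0.898        0.910      0.000             0.000           0.744
```

The same stages are available from the shell via the `microeuk` CLI
(`simulate`, `preprocess`, `alpha`, `beta`, `activity`, `pipeline`); see
`microeuk --help`.

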