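# Methods

## Scope and data model

The package operates on post-clustering artifacts of a paired DNA/RNA
(rRNA gene / rRNA transcript) amplicon survey: an integer OTU × sample
count table (TSV or BIOM v1 sparse JSON), a ranked PR2-style taxonomy per
OTU, a rooted branch-length phylogeny over OTU tips (Newick), and sample
metadata (site, depth in m, nucleic-acid source). Read-level processing
(merging, quality filtering, chimera removal, clustering, taxonomy
assignment) is out of scope; the pipeline starts where those tools end.

Samples are keyed by (site, depth, acid) and duplicates are rejected rather
than merged. Depth strata are a pure function of depth: shallow ≤ 100 m <
middle ≤ 600 m < deep. The cut points at 100 m and 600 m cleanly separate
the enumerated sampling depths of the motivating survey design (5–75 m,
200–500 m, 1,000–3,900 m) while keeping the function total for any depth.

Taxonomy handling: the supergroup is the second rank of the lineage, except
that Metazoa (which PR2 nests under Opisthokonta) and fully unassigned
lineages are surfaced as their own screening labels. Major groups (the
rows of the activity summary) are resolved by case-insensitive substring
matching of an ordered pattern table against the lineage, first match wins.
The table ships as an editable TSV because PR2 rank spellings vary between
database versions; order matters (MALV-II before MALV-I; MAST is matched by
the clade prefix `mast-` so that e.g. *Mastigamoeba* is not captured).

## Preprocessing

1. **Taxon screening.** OTUs whose supergroup is Metazoa or Unassigned are
   dropped; the per-sample removed-read percentage is reported at one
   decimal with half-up rounding, matching how such accounting is usually
   printed.
2. **Singleton removal** defaults to per-sample scope (cells equal to 1 are
   zeroed), because dereplication and singleton screening happen within
   each library; a global scope (drop OTUs with table-wide total 1) is
   available.
3. **Rarefaction** draws one multivariate-hypergeometric sample per library
   (subsampling reads without replacement), so every retained library has
   exactly the target depth and no cell exceeds its input count. The target
   defaults to the minimum library size after filtering. Libraries below
   the target are dropped with a warning, not an error. One seeded draw is
   used rather than an average over draws; the draw is deterministic given
   the seed.

## Diversity panel

With `S_obs` observed OTUs, `F_i` the number of OTUs seen exactly `i`
times, and `p_i` relative abundances:

* **Chao1** uses the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`
  throughout (defined when F2 = 0); the classic form is behind a flag.
* **ACE** uses the standard rare/abundant cutoff of 10. When the rare-class
  coverage `C_ace = 1 − F1/N_rare` is zero the estimator is undefined and
  the bias-corrected Chao1 is returned.
* **Shannon** is reported in bits (base 2). The choice is forced by the
  magnitudes such panels report for ~1,000-OTU subsampled libraries
  (values above `ln S_obs`, e.g. 8.06 with 1,092 OTUs, are only attainable
  in base 2); natural log is a flag.
* **Simpson** is returned as the dominance `D = Σ p_i²` together with its
  inverse, since published tables are ambiguous about which of the two
  "Simpson" denotes; D is what the twin table prints.
* **Faith PD** is the total branch length of the minimal subtree spanning
  the observed tips *including the path to the root*, the convention of the
  common toolchains. Implemented over an edge × tip incidence matrix; OTUs
  absent from the tree raise unless pruning is requested.

Bray-Curtis runs on square-root-transformed within-library relative
abundances (damping dominant OTUs), unweighted UniFrac on presence/absence
via the same edge matrix. ANOSIM uses average ranks for ties and
R = (mean between − mean within rank)/(M/2); Mantel uses Pearson
correlation of lower triangles with joint row/column permutation. Both use
the conservative permutation p-value `(1 + #{stat_perm ≥ stat_obs})/
(n_perm + 1)` with a mandatory seed; 9,999 permutations by default. PCoA is
classical scaling of `−½ J D² J`; negative eigenvalues are reported, never
corrected (Cailliez-style corrections change the geometry silently). UPGMA
is group-average linkage with heights at half the merge dissimilarity, so
cophenetic distances reproduce ultrametric inputs exactly.

## RNA:DNA activity procedure

For each co-extracted pair rarefied to a common depth, only OTUs with at
least one read in **both** libraries enter (shared-OTU rule); this also
guarantees finite ratios without pseudo-counts. The per-OTU ratio is the
quotient of RNA over DNA relative abundances, which at equal depth is the
raw count quotient. The pooling unit is the OTU-within-pair observation;
cell means are arithmetic (an alternative per-pair-mean aggregation and a
log-ratio option exist behind flags, since ratios are right-skewed).
Pairwise stratum comparisons use a two-level one-way ANOVA on the pooled
ratios, identical to the pooled-variance two-sided t-test (F = t²).

**Interpretation caveats.**

* RNA proportions renormalize within each library, so only *contrasts*
  between groups (or against the community average) are identifiable, not
  absolute activities.
* The shared-OTU rule conditions both counts on being ≥ 1. For an OTU whose
  expected count in one library is small, `E[x/y | x ≥ 1, y ≥ 1]` exceeds
  the ratio of expectations (for a Poisson numerator with mean μ the
  inflation is `1/(1 − e^{−μ})`: +58% at μ = 1, +5% at μ = 3, negligible
  beyond μ ≈ 5). Mean ratios of groups dominated by OTUs near the
  detection threshold are therefore biased upward, and anything that makes
  expected counts differ between strata — e.g. a contaminant fraction that
  decays with depth and so shifts the rarefaction depth budget — produces
  *real* distributional differences between strata that the F-test will
  detect even when the planted activity is flat. Calibration designs must
  keep per-OTU expected counts well above the threshold and hold every
  depth-dependent ingredient fixed under the null.

## Synthetic data generator

The generator emulates the post-clustering state of a two-site,
multi-depth paired survey; it does **not** simulate reads, PCR/copy-number
bias, or chimeras, so passing tests say nothing about upstream artifacts in
real data.

* Per-OTU base abundances are lognormal (defaults μ = 0, σ = 1.5, giving
  realistic singleton/doubleton tails so Chao1/ACE are exercised), scaled
  per group (`abundance_scale`) because real groups differ widely in DNA
  read share.
* Group composition tilts along depth as `exp(slope × depth/km)`.
* DNA libraries are multinomial draws at a fixed size (default 20,204, the
  motivating survey's uniform depth).
* RNA libraries are multinomial with expected proportions equal to the
  *realized* DNA counts times the planted per-group, per-stratum activity
  multiplier α, renormalized: the same physical cells underlie both
  co-extracted libraries, so transcript abundance is gene abundance times
  activity. Conditioning on the realized DNA draw also keeps null (α ≡ 1)
  per-OTU ratios centred near 1; with independent draws the random
  denominator would inflate them by `E[1/y]`.
* A metazoan fraction `f₀ e^{−depth/λ}` (defaults f₀ = 0.30, λ = 1,200 m,
  spanning the ~3–42% range such surveys report) is added and
  down-weighted ×0.3 in RNA.
* The phylogeny is a random coalescent-style join tree with exp(1) branch
  lengths — sufficient for PD/UniFrac mechanics, no substitution model.

`paper_shaped_fixture()` reproduces the survey design exactly: sites F3
(25–2,000 m) and H7 (5–3,900 m), eight depths each, 32 samples, 16 pairs,
with the 17 major groups planted at field-realistic α values. The default
richness (30 OTUs/group) is deliberately below the ~2,800 OTUs of a real
survey; it exercises every code path while keeping examples quick.

**Calibration designs** (used by the acceptance checks):

* `recovery_config` plants α = 8 (Ciliophora-like, DNA-rare, scale 0.3),
  α = 1 (reference), α = 0.5 (Dinophyceae-like, DNA-abundant, scale 2.0)
  uniformly across strata, 250 OTUs/group, 3 sites × 3 mid-water depths at
  library size 20,204. The abundance scales mirror the field pattern and,
  per the conditioning analysis above, keep every group's expected
  post-renormalization RNA count well above the presence threshold; the
  planted contrasts 8 and 0.5 are then recovered within ~8% over ten
  seeds, comfortably inside the 15% design tolerance.
* `null_calibration_config` sets α ≡ 1 with zero depth slopes *and* zero
  contaminant fraction (a valid null must be identical across strata, see
  caveats), 3 groups × 250 OTUs, one depth per stratum at 3 sites.
  Measured over ten seeds: all group × stratum means within 1.0 ± 0.09 and
  pairwise rejections near the nominal 5%.

## Numerical and reproducibility choices

* All randomness flows from `numpy.random.Generator`s; the pipeline splits
  one root seed into per-stage seeds via `SeedSequence.spawn`, so reruns of
  the same config + seed are byte-identical (outputs carry no timestamps).
* Ties: argmin/argmax over table columns break lexicographically; UPGMA
  inherits SciPy's deterministic index-order tie-break; ANOSIM uses average
  ranks for tied distances.
* Degenerate inputs: all-zero samples yield missing markers in the alpha
  panel and errors in Bray-Curtis; zero-variance distance matrices flag the
  Mantel correlation as undefined (NaN); pairs with no shared OTUs are
  skipped with a warning.
* Percentages are half-up rounded at one decimal at the reporting boundary
  only; internal computation is full precision.

## Known limitations

* RNA:DNA ratios proxy relative, not absolute, activity; rRNA copy-number
  variation and life-cycle effects are not modelled or corrected.
* The shared-OTU conditioning bias (above) is inherent to the published
  procedure, not removed by this implementation; treat group means built
  on near-threshold OTUs with caution.
* The generator's multinomial sampling ignores overdispersion between PCR
  replicates and any taxon-specific amplification bias.
* Unweighted UniFrac is quadratic in samples with a Python pair loop —
  fine for tens of samples, not for thousands.
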