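# Methods

This note documents the models, conventions and numerical choices behind
`filterforensics`, in the spirit of the methods documentation shipped by
statistical packages: what each procedure assumes, which knobs matter, and
what the synthetic generator does and does not emulate.

## The analysis chain

The pipeline conditions a samples × OTUs count table in a fixed order:

1. **Global-singleton removal** — OTUs whose total count over *all* samples
   is exactly 1 are dropped. Such reads are indistinguishable from
   sequencing error and their retention inflates membership statistics.
2. **Negative-control subtraction** — per sampling method, the read count
   observed for each OTU in that method's negative control is subtracted
   raw (reads, not proportions) from each field sample of the same method,
   clamped at zero. An optional depth-proportional mode is not the default
   because controls and samples were sequenced under the same library
   normalization, so raw reads are the comparable scale. The operation is
   idempotent once a count reaches zero.
3. **Rarefaction** — every sample is subsampled *without replacement* to a
   common depth (by default the post-subtraction minimum sample total).
   The draw is multivariate hypergeometric (sequential marginal
   conditioning via NumPy's generator), which is exact and O(#OTUs) rather
   than O(#reads). A single draw is used — no rarefaction averaging — and
   the seed is a required pipeline argument. Samples under the depth are
   dropped with a warning.

Reordering steps 1–3 changes results (a control read subtracted before
rarefaction removes more than one subtracted after), so the driver fixes
the order and the tests assert it.

## qPCR quantification

Standard curves are ordinary least squares of mean Cq on log₁₀ copies over
a ≥3-point, ≥2-decade dilution series; amplification efficiency is
`10^(−1/slope) − 1` (slope −log₂10 ≈ −3.3219 ⇔ efficiency 1). Sample wells
are inverted individually (`10^((cq−intercept)/slope)`) and the triplicate
is averaged **on the copy scale**, because copies are the quantity of
interest; the systematic (Jensen) difference from mean-Cq-then-convert is
≈2 % at sd(Cq) = 0.3 cycles. Copies are scaled by the template dilution
(default 1:100), converted to genomes with an extensible operon-copy map
(7 for *E. coli* O157 16S, 54 for *A. niger* 18S), scaled to the whole
extract by elution/template volume, and normalized per cm² of filter
(per mg of dust where mass exists — vacuum samples only; wet methods do
not yield a mass). Cq values outside the calibrated curve range flag the
result rather than failing it. Melt-curve QC is carried as a boolean flag,
not modeled.

Repeatability is the coefficient of variation (n−1 standard deviation /
mean) over the replicates of a method, with percentile-bootstrap CIs
(default 10,000 resamples). CV differences between methods resample each
group independently; each group's resampling stream is keyed to its own
data so the difference statistic is exactly antisymmetric under a matched
seed. Zero-exclusion is reported at both 95 % and 90 % because method
contrasts can clear one bar and not the other. Note the percentile
bootstrap *undercovers* at n = 7 (simulated coverage ≈75 % for a nominal
95 % interval under a lognormal with CV 0.3), and the sample CV itself is
downward-biased for heavy-tailed data at small n — severely so for large
CVs (median sample CV ≈ 0.81 under a generative lognormal CV of 1.2 at
n = 7). Comparisons of CVs across methods are unaffected in direction, but
absolute CV estimates at this sample size should be read as lower bounds.

## Diversity and membership

Rank-abundance profiles are the mean and SE (sd/√n, n−1 sd) of log(x+1)
counts per OTU within a method, ranked by mean descending with ties broken
by OTU id for determinism. The "minimum OTUs for 50 % of reads" statistic
orders OTUs by that log-mean ranking (the plotted quantity) and accumulates
*raw* rarefied counts; a raw-count ordering is available behind a flag.
The core microbiome of a method is the set of OTUs with count > 0 in every
replicate (no minimum-abundance threshold), reported as a percentage of
the OTUs observed in the group and of the group's reads. "Appears only
once" is occupancy-based (present in exactly one sample) — the count-1
reading would be vacuous after global-singleton removal.

## Beta diversity and ordination

Morisita-Horn is `1 − 2Σxy/((dx+dy)XY)`, invariant to scaling either
sample. Weighted UniFrac sums branch lengths weighted by the absolute
difference in the fraction of each sample's reads descending from the
branch; the normalized variant divides by the same sum with `+` in place of
`−`, bounding it in [0, 1]. The normalized variant is the pipeline default
(comparable across pairs); the raw variant — which satisfies the triangle
inequality — is available. Branch proportions are accumulated in a single
postorder pass per table, so an all-pairs matrix costs one tree traversal
plus O(n² · branches) cheap vector work. OTU leaves are matched by exact
label; an OTU with reads missing from the tree is a hard error.

PCoA is classical scaling: eigendecomposition of the Gower-centered
−½D² matrix. Coordinates are reported for positive eigenvalues only;
proportion explained is relative to the positive-eigenvalue total, and
negative-eigenvalue mass (Morisita-Horn matrices need not be Euclidean) is
retained for the dispersion test, which subtracts squared distances in the
"imaginary" axes: `d = √max(0, d²_real − d²_imag)`.

## Permutation statistics

PERMANOVA is the one-factor adonis partition: `SS_total = Σ_{i<j} d²/n`,
`SS_within` pooled per group with its own n_g, pseudo-F with (k−1, n−k)
degrees of freedom, and `R² = SS_between/SS_total`. The p-value permutes
group labels with the add-one convention `(hits+1)/(n_perm+1)` — p is never
0 and bottoms out at 0.001 for 999 permutations. When the number of
*distinct* label assignments is ≤ the requested permutations the null is
enumerated exhaustively and p is the exact tail fraction (identity
included). R² can be negative on strongly heteroscedastic non-Euclidean
matrices; this matches vegan's adonis2 exactly (verified in tests) and is
reported as computed. Only the one-factor design is implemented; factors
such as method and household are tested in separate runs.

The dispersion test computes each sample's distance to its group centroid
in the full (real + imaginary) PCoA space, then a one-way ANOVA F over
those distances; the global p permutes the group labels of the distances,
and the parametric F p-value is reported alongside. Pairwise comparisons
use Tukey's HSD on the distances (classical ANOVA degrees of freedom); a
label-permutation |Δmean| alternative sits behind a flag. Singleton groups
get dispersion 0 with a warning.

The Mantel statistic is the Pearson correlation of the n(n−1)/2 upper-tri
entries, with joint row/column permutation of the second matrix, one-sided
(greater), exhaustive when n! fits in the permutation budget. The
core-vs-global variant restricts the table to a method's core OTUs
(renormalizing to proportions over the core by default — distances must be
well defined; a `--no-renormalize-core` flag disables it), recomputes the
distance matrix over *all* samples, and correlates it with the all-OTU
matrix.

All stochastic operations are bit-reproducible given (inputs, seed,
n_perm/n_boot); the pipeline derives fixed per-stage seeds from one master
seed so adding permutations in one stage never shifts another.

## The synthetic generator

The generator emulates a method-comparison design: one filter, three
recovery methods (cut, swab, vacuum) × 7 replicates, each replicate a
composite of five 2.5 × 2.5 cm patches (sampled area 31.25 cm²).

- **True community**: lognormal(0, σ) relative abundances over n_otus,
  normalized. σ = 2 gives the long right tail in which the top ~1 % of
  OTUs carry >30 % of reads.
- **Method bias**: per-OTU multiplicative recovery factors. By default the
  cut method suppresses a randomly designated "hydrophobic" 10 % of OTUs
  by ×0.2, emulating the loss of hydrophobic-walled taxa to buffer elution
  and prefiltration; swab and vacuum are neutral.
- **Replicate noise**: each patch is a Dirichlet draw with concentration
  `dispersion_m` around the biased community (the bias-weighted community
  is renormalized so the *total* concentration equals the dispersion
  parameter regardless of bias scale); the replicate composition is the
  mean of the 5 patch draws and reads are multinomial at a Poisson depth.
  Defaults: concentration 20 for cut, 500 for swab/vacuum — the regime in
  which cut replicates visibly scatter. Dirichlet-multinomial is the
  standard overdispersed count model for microbiome replicates.
- **Contamination**: per method, a random ~1 % OTU subset receives Poisson
  counts at rate `contamination_rate × depth`, forming the negative-control
  profile.
- **qPCR**: per-replicate genome density per cm² is lognormal around the
  method's median density (defaults: bacteria 15 380 / 623 / 324 GCN/cm²
  for vacuum/swab/cut; fungi 79 / 9 / 1) with per-method generative CVs
  (bacteria 0.35/0.31/1.24; fungi 0.42/0.32/1.86), encoded to Cq
  triplicates through a perfect-efficiency synthetic standard curve plus
  0.05-cycle well noise. The quantification chain inverts this exactly at
  zero noise.
- **Tree and taxonomy**: a random bifurcating tree (sequential random
  joins, exponential(1) branch lengths) and lineages drawn from a small
  pool that includes the indicator-panel taxa, so attribution summaries
  exercise real matches.

Default sizes are 2,000 OTUs at depth 20,000 (bacteria) and 500 OTUs at
depth 2,000 (fungi) — rich enough to preserve long-tail behavior while the
full two-assay pipeline completes in seconds on one CPU. Tests use smaller
tables (≈120–300 OTUs, depths 1,200–3,000) and reduced permutation counts
where only calibration, not effect size, is at stake; the simulation-heavy
checks (type-I error, CV recovery) run 100–500 replicate datasets each.

What the generator does **not** emulate: sequence-level artifacts (PCR
error, chimeras), spatial autocorrelation across the filter face beyond
patch compositing, taxon-specific extraction chemistry beyond a scalar
bias, or database-dependent taxonomy uncertainty. Passing tests therefore
demonstrate the statistical machinery's correctness and calibration under
a plausible generative model, not field performance on any particular
filter.

## Known limitations

- Multi-factor PERMANOVA (interactions, strata) is out of scope.
- HDF5 BIOM is not read; use BIOM-JSON 1.0 or classic TSV.
- The indicator panels for soil, marine, insect and allergenic-fungal
  sources are intentionally partial lists (flagged `partial=True`); the
  outdoor-fungal category has no curated members and is omitted.
- Absolute CV estimates at n = 7 are downward-biased for heavy-tailed
  data, and percentile-bootstrap CIs undercover (see the qPCR section);
  between-method CV *comparisons* remain directionally sound.
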