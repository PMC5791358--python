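# filterforensics

Repeatability analysis for **filter forensics** — using a home's HVAC filter
as a long-term, spatially integrated air sampler and assaying its dust for
bacterial (16S) and fungal (ITS) communities. The package asks the question a
method-comparison study asks: *if you sample the same filter repeatedly with
different dust-recovery methods (cutting + elution, swabbing, vacuuming), how
repeatable are the quantities and communities you recover, and how much of
the variation is attributable to the method?*

It is written for microbiome researchers who have OTU count tables, sample
metadata, a phylogeny, and qPCR records — or who want to study the behavior
of this analysis chain on fully synthetic data with known ground truth.

## What it computes

Given a samples × OTUs count table (classic `#OTU ID` TSV or BIOM-JSON 1.0):

- **Conditioning** — global-singleton removal; subtraction of
  negative-control reads per sampling method (clamped at zero); rarefaction
  to a common depth by exact multivariate-hypergeometric subsampling.
- **qPCR quantification** — standard-curve OLS of Cq on log₁₀ copies
  (efficiency `10^(−1/slope) − 1`), inversion of sample Cq triplicates to
  copies, conversion to genome copies via rRNA operon counts (7 for
  *E. coli* O157, 54 for *A. niger*), normalization per filter area and per
  dust mass; repeatability as CV = sd/mean over replicates with 10,000-draw
  percentile-bootstrap CIs, and bootstrap CIs for CV differences between
  methods.
- **Alpha diversity / membership** — OTU richness; log(x+1) rank-abundance
  curves with standard errors; the minimum number of OTUs holding 50 % of
  reads; the core microbiome (OTUs present in every replicate of a method)
  as % of OTUs and % of reads; occupancy-singleton fraction.
- **Beta diversity** — Morisita-Horn and weighted UniFrac (raw and
  normalized) distances; PCoA with negative-eigenvalue accounting.
- **Permutation statistics** — one-factor PERMANOVA
  (R² = SS_between/SS_total, label-permutation p, exhaustive enumeration at
  small n); homogeneity of multivariate dispersions (distances to group
  centroids in PCoA space, ANOVA-F permutation test, Tukey HSD pairwise);
  Mantel tests, including core-vs-global community correlation.
- **Source attribution** — summed relative abundance over curated indicator
  panels (human-indicator families, skin/stool genera, soil/marine/insect
  taxa, allergenic and skin-associated fungi), summarized per method as
  mean ± SE.
- **Synthetic studies** — a generator emulating the study design (3 methods
  × 7 replicates, five 2.5 × 2.5 cm patches composited per sample,
  lognormal long-tailed communities, Dirichlet-multinomial replicate noise,
  method-specific recovery bias and dispersion, contamination, qPCR with
  per-method generative CVs) so every stage is testable without data
  downloads.

## Worked example

```python
import filterforensics as ff
from filterforensics.synthetic import bacteria_scenario, simulate_study

study = simulate_study(bacteria_scenario(), seed=1)
rarefied, depth = ff.preprocess_pipeline(
    study.table, study.controls, study.metadata, depth="auto", seed=1)
dm = ff.distance_matrix(rarefied, "weighted_unifrac_normalized", study.tree)
groups = study.metadata.groups_for(dm.ids)
print(ff.permanova(dm, groups, n_perm=999, seed=1))
print({g: round(v.mean(), 3)
       for g, v in ff.dispersion_test(dm, groups, seed=1).group_distances.items()})
```

prints (seed 1):

```
PermanovaResult(pseudo_F=1.9357..., r_squared=0.1770..., p_value=0.001,
                n_permutations=999, seed=1, exhaustive=False)
{'cut': 0.238, 'swab': 0.07, 'vacuum': 0.069}
```

The PERMANOVA p of 0.001 (the floor at 999 permutations) says sampling
method explains a significant share of community distance variance; the
mean distances-to-centroid show cut replicates are ~3× more dispersed than
swab or vacuum replicates — the generator's low cut Dirichlet concentration
(20 vs 500) recovered as the method's poorer repeatability.

The same analysis runs from the shell:

```bash
filterforensics simulate --assay both --seed 1 --outdir sim/
filterforensics run --studydir sim/ --seed 1 --out report.json
```

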