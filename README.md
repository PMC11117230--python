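# biphasic

Phylomorphometrics of biphasic life cycles: tools to ask whether the
larval and adult shapes of the same species evolve together or
independently — the adaptive decoupling question — on a dated
phylogeny.

Organisms with complex life cycles (the motivating case is anuran
amphibians: tadpoles vs frogs) express largely different morphologies
before and after metamorphosis, often in different ecological niches.
If selection optimizes each stage separately, larval and adult shape
spaces should carry distinct evolutionary signals: different
phylogenetic structure, different allometry, different disparity
dynamics, and little between-stage correlation. `biphasic` implements
the full analysis battery for testing this, plus a synthetic-data
engine that generates complete studies with known structure so every
stage is testable without any specimen data.

## What it computes

Given 2D landmark configurations (TPS) for larvae, a linear
measurement table (CSV, possibly with missing cells) for adults, a
time-calibrated tree (Newick), and a species factor table:

- **Shape spaces** — Generalized Procrustes Analysis (GPA) for
  landmarks; log-shape ratios (LSR), ln of each measurement over the
  species' geometric mean, for linear data; iterative-PCA imputation
  of missing cells; PCA morphospaces.
- **Structure and allometry** — Procrustes ANOVA with sequential sums
  of squares and residual-randomization permutation (RRPP);
  multivariate shape ~ ln(size) × family regressions with regression
  scores and a predicted-shape PC1.
- **Phylogenetic signal** — Blomberg's K on PC1 scores, with
  K = (MSE0/MSE) / E[MSE0/MSE] under Brownian motion (BM), so K ≈ 1
  under BM and K > 1 when relatives are more similar than BM expects;
  permutation significance.
- **History in morphospace** — BM ancestral reconstruction (GLS
  conditional expectations), phylomorphospace and traitgram
  coordinates, Stayton's C1–C4 convergence measures with a
  BM-simulation null and multi-tree uncertainty, and
  disparity-through-time by branch interpolation (sum of variances at
  time-bin midpoints).
- **Decoupling battery** — Euclidean dissimilarities per stage, a
  Spearman Mantel test, and half-sample disparity correlations
  (floor(n/2) species per draw, same subset for both stages), overall
  and per family.

All stochastic routines are pure functions of their inputs and an
integer seed.

## Worked example

```python
import biphasic as bp
import pandas as pd

study = bp.make_study(seed=1)          # 83 species, 4 families, coupled stages
aligned = bp.gpa(study.landmarks)      # Procrustes superimposition
species = pd.Series({c.specimen_id: c.species for c in study.landmarks})
larval = bp.species_mean_shapes(aligned, species)
adult = bp.log_shape_ratios(bp.impute_pca(study.measurements).table)
adult_vals = adult.values.loc[larval.index]

larval_pca, adult_pca = bp.pca(larval), bp.pca(adult_vals)
print(f"larval PC1+PC2: {100*larval_pca.var_explained[:2].sum():.1f}%")
print(f"adult  PC1+PC2: {100*adult_pca.var_explained[:2].sum():.1f}%")

k_l = bp.blomberg_k(study.tree, larval_pca.scores["PC1"], nperm=999, seed=0)
k_a = bp.blomberg_k(study.tree, adult_pca.scores["PC1"], nperm=999, seed=0)
print(f"Blomberg's K  larval {k_l.K:.2f} (p={k_l.p:.3f})  adult {k_a.K:.2f} (p={k_a.p:.3f})")

dec = bp.decoupling_summary(larval, adult_vals,
                            groups=study.factors["family"], seed=0)
print(f"Mantel r = {dec.mantel.r:.3f} (p = {dec.mantel.p:.4f})")
print(f"half-sample disparity correlation r = {dec.disparity.r:.3f}")
```

prints

```
larval PC1+PC2: 72.5%
adult  PC1+PC2: 56.2%
Blomberg's K  larval 1.96 (p=0.001)  adult 0.05 (p=0.384)
Mantel r = 0.057 (p = 0.0982)
half-sample disparity correlation r = -0.059
```

Read: the first two PCs summarize most of each shape space; larval
shape is strongly phylogenetically structured (K ≈ 2, significant)
while adult shape is not (K ≈ 0.05); and the between-stage shape
correlation is low — the decoupled regime the generator's default
coupling (`rho = 0.3`) builds in.

## Command line

```sh
biphasic simulate --out demo_data --seed 1        # write a full synthetic study
biphasic run-all --config demo.yml --out demo_out # run the whole pipeline
```

with a YAML config naming the four input files plus permutation/
simulation sizes (`nperm`, `nsim`, `n_iter`, `seed`, ...; unknown keys
are rejected). Individual stages are exposed as subcommands
(`impute`, `gpa`, `lsr`, `pca`, `anova`, `allometry`, `signal`,
`convergence`, `dtt`, `decouple`). The pipeline writes one JSON/CSV
report per stage plus a manifest with per-stage seeds and timings;
reruns with the same config are bit-identical apart from the timings.

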