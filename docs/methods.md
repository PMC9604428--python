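# Methods

This document records the statistical model, the estimators, the generator,
the numerical conventions, and the deliberate design decisions of `fanoise`.

## 1. Variance partition of bilateral traits

For a gene measured on the two sides of an individual, write `u = log l`
and `v = log r` (log base natural or 2; the base is carried on every
matrix and converted explicitly — variances convert by `1/ln(2)² ≈ 2.081`
between log2 and natural scale).

Assume each side's log value has variance `η²` and the two sides correlate
at `ρ`. Then

- `eta2_ext = Var(u + v) = 2η²(1 + ρ)` — the canalization / extrinsic part,
- `eta2_int = Var(u − v) = 2η²(1 − ρ)` — the fluctuating-asymmetry /
  intrinsic part,

and exactly, at the sample level with any data,

```
¼(eta2_ext + eta2_int) = ½(Var u + Var v)        (partition identity)
```

`per_gene_noise_components` computes both with unbiased (`n−1`) sample
variances. Unbiased divisors are used in *all* descriptive estimation;
maximum-likelihood (`1/n`) divisors appear only inside the distributional
fits of `models.py`. Small cohorts (11–12 individuals) make this divisor
visible, so the convention is declared once and applied throughout.

## 2. The 2×2 eigen decomposition (`eigen2x2`)

Stack the paired values into an `n × 2` matrix and eigen-decompose its
(column-centered, `n−1`-divisor) covariance. Because the covariance always
removes column means, per-side additive constants (log-scale library-size
factors) and additive directional asymmetry `δ` drop out exactly.

- **Trace conservation** (exact): `λ_ext + λ_int = Var u + Var v`.
- **Component assignment is by orientation, not magnitude**: "extrinsic" is
  the eigenvalue whose eigenvector lies within 45° of `(1,1)/√2`. Indexing
  by magnitude (`λ1 > λ2`) silently breaks when fluctuating asymmetry
  dominates canalization; when orientation and magnitude disagree the
  result is flagged `assignment_conflict` and orientation is honored.
- **Multiplicative asymmetry**: if `v ≈ a·u`, the first eigenvector rotates
  to `(1, a)/√(1+a²)` and `λ_int` stays clean of the `(1−a)` contamination
  that inflates the naive `Var(u − v)`. On the raw (non-gene-centered)
  stacked matrix, `2λ_int ≈ (2a/(1+a²))²·(1+a²)σ²_e`, within 5% of the
  generative per-side-average intrinsic variance `(1+a²)σ²_e` for
  `a ∈ [0.8, 1.25]`.
- **Equal-side-variance diagnostic**: mapping eigenvalues to noise
  components assumes `Var u ≈ Var v`; a warning fires when the ratio falls
  outside `[2/3, 3/2]`. The diagnostic only applies to gene-centered
  inputs — non-centered per-individual matrices are dominated by gene
  means on both sides, where the ratio is uninformative.

## 3. Pooling across genes (`center_genewise`, `pooled_noise`)

To pool a multi-gene panel, each gene is centered by its mean over all
left *and* right entries, and the centered pairs are stacked. Exactness
status of the centering step:

- `Var(U* − V*) = Var(U − V)` holds **exactly** (the same per-gene constant
  is subtracted from both sides).
- The corresponding *eigenvalue* identity — `λ_int` of the raw stacked
  matrix equals `λ_int` of the gene-centered one — is exact **only under
  equal side variances** (e.g. on side-exchange-symmetric data, where the
  covariance is bisymmetric and the eigenvectors are exactly `(1,±1)/√2`).
  On generic cohorts the discrepancy is small but real (order `1e−4` on a
  13-gene × 12-individual cohort). The test suite asserts the identity at
  `1e−10` only where it is mathematically exact, and bounds the generic
  discrepancy loosely.
- **Gene-centering assumes `a = 1`.** Under multiplicative directional
  asymmetry, centering with the mean over both sides leaves a
  `(1−a)·b_i` gene-mean residual along the `(1,−1)` direction, inflating
  `λ_int` by `(1−a)²·Var(b)/2`. For asymmetry-robust intrinsic estimation
  use the non-centered eigen route (`eigen2x2(M.stacked(),
  centered=False)`), whose `λ_ext` is in turn flagged unusable because it
  absorbs gene-mean variance.
- Pooled estimates of the *extrinsic* component carry a `(J−1)/J` bias with
  `J` individuals per gene (gene-centering spends one degree of freedom per
  gene); per-gene estimation with unbiased divisors avoids this and is the
  route used when unbiasedness matters.

`individual_intrinsic_noise` applies the same eigen machinery to one
individual's `genes × 2` matrix (non-centered) and reports
`η̂_int = √(2λ_int)`. `pairwise_reference_free_intrinsic_noise` is a
reference-gene-free variant built from all pairwise ΔCt differences.

## 4. Distributional models (`models.py`)

Group/covariate effects on noise are modeled with a heteroscedastic normal
location-scale family: `y ~ Normal(μ(x), σ(x))` with identity link on the
location and log link on the scale.

- **Saturated group model** (`fit_group_location_scale`): closed-form ML,
  `μ̂_k = mean`, `σ̂_k = ML sd`; `se(log σ̂_k) = 1/√(2n_k)`. Groups need
  ≥ 3 observations.
- **Regression** (`fit_location_scale_regression`): Fisher scoring with the
  block-diagonal information — a weighted-least-squares step for the
  location and a Newton step with information `2XᵀX` for the log-scale
  coefficients. Coefficients are named `alpha0, alpha` (location) and
  `beta0, beta` (log scale).
- **Comparison**: Wald statistic `w = (θ̂₁ − θ̂₂)/√(se₁² + se₂²)` against
  the standard normal; all pairwise group contrasts in one call form one
  FDR family, adjusted by Benjamini–Hochberg (delegated to
  `statsmodels.stats.multitest.multipletests`; a brute-force step-up
  oracle backs it in the tests).
- Comparing `σ` is equivalent to comparing `η = √2·σ` (the rescaling
  cancels in `w`); `noise_from_scale` maps fitted scales to `η̂` with a
  delta-method 95% CI.
- `adjust_for_litter_size` removes the linear litter-size trend from log
  mass (OLS residuals plus the grand mean) before noise regression.

Calibration facts verified by the suite: type-I error of the scale Wald
test at two null groups of n=12 is ≈ 0.057 over 10⁴ replicates (the
`1/√(2n)` standard error is mildly anticonservative at this n — accepted
band 0.04–0.08); all four regression coefficients fall within 2 se of
truth ≥ 93% of the time at n=200.

## 5. Subset-based genome-wide estimation (`subsets.py`)

If a global control variable sets each individual's developmental
instability, intrinsic noise estimated from a few genes should rank
individuals like the all-gene estimate. `subset_correlation_curve` draws
seeded random gene subsets, computes per-sample `η̂_int` per subset, and
records the across-sample Pearson (or Spearman) correlation with the
full-panel estimate; the per-size median is the summary.

`positional_trend` tests monotone association of noise with a positional
coordinate: Spearman rho with a seeded two-sided permutation p-value
(`(#{|null| ≥ |obs|} + 1)/(B + 1)`). Rank-based: no linearity or
normality assumptions. At n = 27 this test has ~30% power against a
gradient of 1 residual SD across the range and ~90% against 2.5 SDs.

## 6. The generator (`simulate.py`)

Per gene `i`, individual `j`:

```
u_ij = b_i + s_ij + e^L_ij
v_ij = a (b_i + s_ij + e^R_ij) + δ
```

with `b_i ~ Normal(gene_mean_mean, gene_mean_sd)` (baselines),
`s_ij ~ Normal(0, drive_sd)` (shared drive → extrinsic noise),
`e^L, e^R ~ Normal(0, side_sd_j)` independent (→ intrinsic noise), and
`side_sd_j = side_noise_sd × group multiplier × lognormal individual
multiplier` (SD `individual_dispersion` on the log scale). The lognormal
individual multiplier is the "global control variable" the subset analysis
detects.

Closed-form truths recorded with each draw: per-individual intrinsic
variance `(1 + a²)·side_sd_j²` (reduces to `2·side_sd²` at `a = 1`), the
pooled per-group means of the same, and `eta2_ext(a=1) = 4·drive_sd² +
2·side_noise_sd²`.

Parameter defaults and their rationale:

| parameter | default | rationale |
|---|---|---|
| `n_genes`, groups | 13; 11/12/12 | typical small RT-qPCR cohort geometry |
| `side_noise_sd` | 0.59/√2 ≈ 0.417 | so that SD(u−v) ≈ 0.59 ΔCt cycles, a realistic bilateral qPCR fluctuation |
| `tech_rep_sd` | 0.135/√2 | per-well technical noise so SD(rep1−rep2) = 0.135 cycles |
| `drive_sd` | 0.3 | moderate left/right correlation (ρ ≈ 0.34 with the default side SD) |
| `individual_dispersion` | 0.2 (0.3 in subset demos) | 0.3 gives a ~3-fold spread of per-sample noise across 27 draws |
| `litter_effect` | −0.02/pup | real crowding effect so the adjustment path is exercised |
| trait coefficients | see `SimulationConfig` | negative `alpha` (noisier ⇒ smaller/less PLGF), positive `beta` (noisier ⇒ more variable) |

`simulate_qpcr_dataset` maps log2 abundances to Ct via
`Ct = 35 − log2(abundance)` with a highly expressed reference transcript
("18S") carrying its own small bilateral fluctuation, duplicate wells per
measurement. `simulate_traits` draws `log(trait) ~ Normal(alpha0 +
alpha·log η_int, exp(beta0 + beta·log η_int))`, with a litter-size effect
on mass only. The same seed reproduces every output bit-exactly; changing
only `δ` leaves all decomposition outputs unchanged.

Scope limits: the generator produces log-scale matrices directly — no
read-count or FPKM mechanics, no amplification-efficiency modeling, no
missingness mechanism (readers handle missing sides by drop-and-report,
never imputation).

## 7. Input/output conventions

- Long-format TSV/CSV: `gene_id, individual_id, side, value` (+ optional
  `replicate, group, sex, position`); side labels case-insensitive
  (`left/l/L`), normalized to `L`/`R`, and exchangeable — swapping labels
  changes no variance output.
- Ct tables: replicate wells averaged first, then `dCt = Ct_gene − Ct_ref`
  per side; the reference gene is excluded from the returned panel;
  individuals missing reference wells are dropped with a warning. `dCt` is
  treated as an affine log2 abundance; its sign is never interpreted
  (variances are sign-invariant).
- Raw count/FPKM matrices: genes containing any zero across samples are
  dropped (counted in a `FilterReport`) before log transform.
- Writers emit full-precision values (`repr` of Python floats) and readers
  parse with round-trip float precision, so write→read is bit-exact.
- `write_results` writes DataFrames as TSV, mappings as JSON, plus a
  `manifest.json` with sha256 checksums, the run config, and the seed;
  byte-identical across runs given identical inputs.

## 8. Problem sizes and runtime

All shipped analyses are desk-scale: the full test suite (including the
ten acceptance criteria, with Monte-Carlo replicate counts of 10³–10⁴)
runs in well under a minute on one CPU; `scripts/acceptance.py` (27
samples × 1000 genes × 1000 subsets) runs in ~5 s. These sizes are the
package's own verification choices.

## 9. Known limitations

- The eigenvalue-vs-centering identity and the eigenvalue→component
  mapping are exact only under equal side variances (see section 3); the
  package warns rather than corrects.
- Gene-centered pooled estimation assumes no multiplicative directional
  asymmetry; use the non-centered route when `a ≠ 1` is plausible.
- `se(log σ̂) = 1/√(2n)` is asymptotic; at n ≈ 12 the scale Wald test is
  mildly anticonservative and ML scale estimates carry an `O(1/n)`
  downward bias.
- Subset correlations are computed on overlapping draws against the same
  full-panel estimate; they quantify ranking fidelity, not independent
  replication.
- No plotting: all outputs are tables/JSON by design.
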