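# Methods

This note documents the models, conventions and design choices behind
`prsgxe`: what the synthetic-data generator does and does not emulate,
how each analysis stage is defined, and which numerical decisions matter.

## The two-cohort design

The pipeline mirrors a common polygenic study layout: a *discovery*
cohort of unrelated individuals with a continuous alcohol-problems
phenotype supplies GWAS weights; an independent *target* cohort of
adolescent twins supplies the outcome (a 0–30 alcohol-problems sum score),
two ordinal environments (parental knowledge and peer deviance, each 4–16
with high = more risk), sex, and family/zygosity structure. The real
cohorts of this design are access-controlled, so everything here runs on
synthetic cohorts with matched statistical structure.

## Synthetic-data generator

### Genotypes

Haplotypes are drawn through a Gaussian copula: within each LD block of
`ld_block_size` SNPs, a latent AR(1) Gaussian vector with lag-1
correlation `ld_rho` is thresholded at the per-SNP MAF quantile, giving
correlated binary haplotypes; blocks are independent. Dosage = sum of two
haplotypes. The closed-form dosage correlation of adjacent SNPs (the
standardized bivariate-normal orthant probability) is exposed as
`expected_adjacent_dosage_corr` and verified against brute-force
simulation in the tests. MAFs are uniform on `maf_range` (default
0.05–0.5).

Twin families come from explicit parental haplotypes: each family has
four parental haplotypes; a child receives one from each parent. MZ
co-twins copy both transmissions (dosage rows are bitwise identical); DZ
co-twins redraw each transmission independently, so expected
identity-by-descent sharing is exactly 0.5. Twin pairs are simulated
same-sex (sex assigned at the family level); real twin samples also
contain opposite-sex DZ pairs, a structure the generator omits so that
the sex main effect cancels exactly in MZ/DZ covariance comparisons.

### Phenotypes

A liability

L = G + b_sex·(sex − ½) + Σ_e s_e·E_e + Σ_e γ_e·(G·E_e) + ε

with:

* `G` — additive genetic value over `n_causal` SNPs with N(0,1) raw
  effects on standardized dosages, rescaled to variance `h2_additive`
  (default 0.34, the Falconer-type estimate for this outcome). The causal
  model is shared between discovery and target cohorts.
* `E_e` — standardized environment latents with corr(E, G) = `rge_corr`
  (defaults 0.05 and 0.08 for parental knowledge and peer deviance — the
  magnitudes reported for score-environment correlations; note the score
  is a noisy proxy of G, so the *observed* score-level rGE is smaller
  than the liability-level parameter). A family-level component gives
  co-twins a within-pair environmental correlation `env_twin_corr`
  (default 0.4), equal for MZ and DZ so it cancels in the Falconer
  difference.
* `s_e` — environment main effects (defaults 0.30 / 0.35, sized to give
  environment-outcome correlations near 0.3).
* `γ_e` — liability-scale G×E slope (default 0.3; with h² = 0.34 this
  puts the score-level interaction ΔR² in the few-tenths-of-a-percent
  range typical of such studies).
* ε — Gaussian noise topping total variance up to ≈1 (floor 0.05).

The discovery cohort observes L directly (a factor-score-like continuous
phenotype). The target cohort observes discretized variables:
environments are `clip(round(μ_e + σ_e·E), 4, 16)` with Table-2-style
locations (6.6 ± 2.1 and 7.9 ± 3.1) — a rank-preserving map, with the
achieved liability-environment correlation logged since clipping and
rounding attenuate the nominal value; alcohol problems are a zero-inflated
count: standardized liability below its 80th percentile maps to 0
(`zero_fraction = 0.8`), and the exceedance is converted to counts at
`count_scale = 0.45` SD per point, capped at 30. This reproduces the
heavy-zero character of the real outcome (mean ≈ 0.3, SD ≈ 1, observed
maxima ≈ 8 of a possible 30).

All randomness flows from one seed through named substreams
(`config.substream`), so regenerating any cohort is byte-identical and
adding stages never perturbs earlier draws.

### What the generator does **not** emulate

No mutation/recombination realism, no ancestry structure or stratification,
no X chromosome, no genotyping error, no imputation uncertainty (dosages
are integer counts unless an MCAR mask is requested), no opposite-sex DZ
pairs, no missing phenotypes. Passing tests therefore demonstrate the
statistical machinery is correct under the assumed structure — not that
real-data complications (stratification, batch effects, informative
missingness) are handled.

## Analysis stages

**GWAS.** Per-SNP OLS of phenotype on [1, dosage, covariates] via the
Frisch–Waugh–Lovell decomposition (covariates projected out once with a
QR basis, then a vectorized one-regressor solve per SNP). Two-sided p
from the t distribution with n − k residual df. Missing dosages:
per-SNP listwise deletion with per-SNP `n_used`. Monomorphic SNPs are
excluded with a logged reason. p-values are floored at the smallest
positive normal double so −log10 p stays finite. The scan is verified
against an explicit pseudo-inverse oracle and against centering/allele-flip
invariances.

**Scoring.** Weight = sign(β)·(−log10 p); sign(0) ≔ 0; p must lie in
(0, 1]. Allele alignment keeps SNPs present in both tables, reflecting
dosage (2 − d) where the target's effect allele is the discovery's other
allele and dropping irreconcilable pairs with a logged count; when a bare
`.raw` provides no other-allele metadata, matching falls back to the
effect-allele column. Scores default to average-per-allele normalization
(divide by 2 × non-missing scored SNPs) — consistent with the small
score magnitudes typical of the standard `--score` procedure — with a
`sum` mode behind a flag. Missing dosages leave both numerator and
denominator. Thresholds are inclusive (p ≤ t), so SNP sets are nested.
Strand-ambiguous (A/T, C/G) SNPs are retained, assuming both cohorts share
the post-imputation reference strand. No LD pruning is applied to scores.

**Association.** Partial correlation by double residualization (numerically
identical to the recursive formula, but valid for any covariate count);
p from t = r√((n−k−2)/(1−r²)). The implementation is exactly symmetric in
x and y and invariant to affine recodings of covariates (so the 0/1 sex
coding is immaterial). rGE is the plain Pearson correlation of score with
each environment. `falconer_h2` returns 2(r_MZ − r_DZ) clipped to [0, 1]
with a warning; `twin_correlations` uses double-entry (intraclass)
correlations over complete pairs. `drop_one_per_family` supports the
non-independence sensitivity re-run.

**Moderation.** OLS of the outcome on [1, sex, score_c, env_c,
score_c·env_c] via statsmodels, with score and environment centered on
the listwise-complete analysis sample before the product is formed
(centering reduces collinearity and cannot change the interaction
estimate — asserted in tests). Sex stays on its raw 0/1 coding. ΔR² comes
from explicitly refit nested models in the fixed entry order
sex → score → environment → interaction; the listwise n of each
environment's model is carried through, never pooled. Standard errors are
conventional (non-robust); twin non-independence is addressed only by the
drop-one re-run, matching the design this pipeline reproduces. The rGE
control mutually residualizes score and environment ([1, other] OLS
residuals) before refitting; the scale control refits on log₁₀(y + 1).
Predicted values are evaluated at ±1 SD of score and environment with sex
at its mean; negative predictions clamp to 0 (the outcome floor) and the
error bar is SD(residuals)/√n.

**Enrichment.** Top discovery SNPs at p ≤ cutoff (default 10⁻⁴; demo
configs use more liberal cutoffs so a 10³-SNP panel yields a workable
set), greedily LD-pruned in ascending discovery-p order (most significant
kept first — the traversal order is a documented choice, not forced) using
squared dosage correlations on one randomly chosen member per family.
Per-SNP interaction model [1, sex, dosage_c, env_c, dosage_c·env_c];
statistic = Σ|t| over SNPs with interaction p < 0.05. The null applies one
shared row permutation to the [outcome, sex, environment] block per
iteration, leaving genotype rows fixed: all SNP–SNP LD is preserved
bit-identically and phenotype-covariate relationships survive inside each
permuted dataset, so the test conditions on both and breaks only
genotype–phenotype links. Exceedance is strict (ties count as
non-exceeding), and empirical p = (R+1)/(N+1) is conservative and never
zero. Default N = 100,000; the test suite and demo configs use N = 999 and
N = 9,999 respectively.

## Calibration studies and their problem sizes

The `calibration` module repeats miniature end-to-end studies (hundreds of
discovery individuals, hundreds of SNPs, 550–634 target families per
replicate) — sizes chosen so the full-replication suites (1,000 null
cohorts, 500 power replicates, 200 permutation-calibration datasets)
preserve the pipeline's structure at desk scale; the package defaults
remain full-size.

One calibration finding deserves emphasis. The score×environment
interaction t-test is exactly calibrated under the *complete* sharp null
(no genotype or environment signal in the outcome; measured rejection
0.046 at α = 0.05 over 1,000 cohorts of n = 1,100, with uniform p-values).
But when the environment has a main effect on the zero-inflated count
outcome — with the genotype still completely null — the test over-rejects
at ≈0.09: residual variance rises with the environment while the product
regressor's scale rises with it too, so conventional OLS standard errors
understate the interaction's sampling variance. The log₁₀(y+1) refit does
not remove the distortion here (≈0.09) because the outcome is mostly 0/1.
This is precisely the scale-artifact class that motivates the
residualization and log-scale sensitivity analyses, and it is a property
any user applying this model to skewed count outcomes should know:
nominally significant interactions on such outcomes deserve robust or
permutation confirmation.

## Numerical conventions

* QR-based projections throughout; SNP-scan normal equations use relative
  thresholds (residual dosage sum-of-squares ≤ 1e-10·n → monomorphic;
  RSS < 1e-12 of total → exact fit, p at the floor sentinel).
* p-values are never 0: floored at the smallest positive normal double.
* Writers emit `%.17g` floats and readers parse with round-trip precision,
  so write→read is bit-exact and run manifests (SHA-256 digests per output)
  are reproducible for a given seed.
* `drop_one_per_family` and all permutations use seeded generators;
  permutation indices can be streamed to disk for exact replay.

## Known limitations

* OLS on a zero-inflated count outcome: see the calibration finding above;
  count-model alternatives (Poisson/negative-binomial) and clustered or
  robust standard errors are deliberately out of scope.
* The Falconer heuristic is a correlation-difference summary, not a
  variance-component model; on the discretized 0–30 outcome it is
  attenuated relative to the latent-liability value (the simulated
  recovery study therefore targets the latent scale and the attenuation
  is reported, not asserted).
* The generator's nominal liability-level rGE is attenuated by environment
  discretization and further by score noise; achieved values are logged.
* LD pruning is greedy and order-dependent; enough is logged (input order,
  survivors, r² cutoff) to audit any alternative order.
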