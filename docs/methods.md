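# Methods

## The generative model

The simulator emulates a biobank in which everyone carries cheap proxy
phenotypes and only a small subset carries the expensive imaging target.
All phenotypes share a latent adiposity factor `A`:

    A_i   = Σ_k δ_k b_k (g_ik − 2p_k) + c_i'w + ε_A,   ε_A ~ N(0, σ_A²)
    x_ij  = λ_j A_i + ε_x,                             ε_x ~ N(0, σ_x²)
    y_it  = a_t A_i + Σ_k (1−δ_k) b_k (g_ik − 2p_k) + ε_t

* `g_ik ~ Binomial(2, p_k)`: allele dosages, Hardy–Weinberg, no LD between
  cohort variants (LD exists only in the summary-region simulator, below).
  Allele frequencies are drawn from `maf_range` (default 0.05–0.5).
* `b_k` (default 0.15 factor-SD per allele) is the per-allele effect of
  causal variant k; the **mediation fraction** `δ_k ∈ [0,1]` splits it into a
  share transmitted through the proxy-visible factor (`δ_k b_k`) and a share
  acting directly on the target only (`(1−δ_k) b_k`). δ controls how much of
  a variant's effect the imputed phenotype can see: at δ=1 imputation loses
  nothing, at δ=0 the imputed scan is blind to the variant.
* `λ_j` are the proxy loadings (default 1.0, 0.8, 0.6, 0.4 over four
  proxies named height/weight/whr/bia_fat), scaled per sex (default F 1.0,
  M 0.9) so the two strata have genuinely different model parameters.
* Covariates: age ~ Uniform(40, 70), a deprivation-like score ~ N(0,1),
  batch ∈ {1..5} with additive shifts, and two PC-like standard normals;
  their weights on `A` are small (`Var(c'w) ≈ 0.02`).
* Phenotypes flagged positive-scale are exponentiated, `Y = exp(μ + s·y)`
  with μ=3, s=0.25, so the analysis pipeline's natural-log step recovers the
  latent linear scale exactly and the 6 SD trim rarely fires under the null.
* Randomness: a single integer seed drives a PCG64 generator; discovery,
  replication and summary-region draws use disjoint fixed streams, so every
  output is bit-reproducible.

Default noise levels (σ_A = 0.6, σ_x = 0.3, σ_y = 0.4) were set so the
theoretical imputation accuracy sits near two thirds of the target variance,
the regime the method is designed for; the default cohort (20,000 total,
1,000 measured, 500 variants, 5 causal variants at δ=1, replication cohort
1,000) is a desk-scale rendering of a biobank whose measured subset is one
to two orders of magnitude smaller than the full cohort.

### Analytic ground truth

Because the model is linear-Gaussian on the latent scale, the `TruthRecord`
carries closed forms, per target t and sex stratum:

* factor variance `v_A = Σ(δ_k b_k)² 2p_k(1−p_k) + σ_A²`, direct-effect
  variance `v_D`, and their covariance `c_GD`;
* imputation R² of the best linear predictor from proxies + covariates,
  using `λ'S⁻¹λ = u/(1 + v_A u)` with `u = Σλ_j²/σ_x²` (Sherman–Morrison);
* the per-allele marginal effect on the target, `b_k(a_t δ_k + 1 − δ_k)`,
  and on the *imputed* target, `δ_k b_k κ_t` with transmission coefficient
  `κ_t = (a_t v_A + c_GD)·u/(1 + v_A u)` — zero at δ=0, which is the
  attenuation property the scan-power tests exercise.

Standardised versions divide by the residual (covariate-adjusted) SD, which
is what a scan of an inverse-normal-transformed phenotype estimates.

### What the simulator does not emulate

Realistic LD panels in cohort mode, genotype-imputation uncertainty (the
info score is an independent Beta(20,1) used only by the filter),
relatedness or population structure beyond PC-like covariates,
ascertainment, and non-Gaussian phenotype tails. Tests passing on this
generator show the pipeline's statistics behave as designed under their own
assumptions; they do not certify behaviour under confounding the model
excludes.

## Pipeline conventions and numerical choices

* **Imputation fits on the natural-log scale** of proxies and targets. On
  the generative model the log scale is exactly linear, so fitted R² is
  comparable with the analytic truth; with real measurements this is simply
  a monotone variance-stabilising choice. Accuracy is reported on the
  training data (an optional held-out assessment is available through
  `assess_accuracy` on any prediction/observation pair); rows with missing
  proxies are excluded from fitting and flagged NaN at prediction.
  Composite indices (fat/lean ratio, fat/height²) are derived from simulated
  components before imputation.
* **Preprocessing** is single-pass per sex: log → 6 SD trim → OLS
  residualisation (categoricals one-hot) → inverse-normal transform with
  Blom offset `(rank − 3/8)/(n + 1/4)`, averaged ranks on ties → 4 SD trim →
  merge strata. Trims use the mean/SD of currently included values and are
  not iterated. Non-positive raw values are excluded with a reason code, not
  an error; constant input within a stratum is an error at the rank step.
* **Association** is simple regression of the analysis phenotype on dosage;
  P from the t distribution with n−2 df, floored at 10⁻³⁰⁰. Missing dosages
  are mean-substituted per variant so n stays constant.
* **Effective tests**: both Li–Ji and Nyholt estimates are always reported;
  the threshold divides α by the *ceiling* of the Li–Ji estimate
  (conservative integer count of independent traits).
* **Loci** use chain linkage (single linkage by position, 1 Mb gap) rather
  than lead-centred windows, so a locus can span more than 1 Mb end to end —
  the most direct reading of "signals more than 1 Mb apart are independent",
  documented here because it changes locus counts. Coordinates are 1-based
  inclusive; BED input is converted on read. Novelty screening replaces
  manual curation with a deterministic rule: any member within 1 Mb of a
  catalogue entry, or with reference-scan P < 10⁻¹², marks the locus known.
  The self-contained pipeline default runs with no catalogue and no
  reference tables (simulated loci are novel by construction); both are
  file inputs.
* **Replication**: the power screen's expected-P cutoff (`replicable_p_max`)
  has no privileged value; the shipped default config uses 0.05. The
  expected replication P is the one-sided upper normal tail at
  |β/se_pred| — the tail-probability reading of the power formula, chosen
  over the density reading because only the tail yields a probability.
  FDR control is Benjamini–Hochberg step-up (the standard default when a
  procedure is unnamed). Zero replication effects count as
  direction-inconsistent (strict sign rule), and the sign test is the
  one-sided exact binomial tail P(X ≥ k | n, ½).
* **Colocalisation**: Wakefield prior SD 0.15 (quantitative-trait
  convention) with priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵; posteriors are
  computed in log space with log-sum-exp. SMR uses the top-eQTL Wald ratio;
  HEIDI takes SNPs with r² to the top eQTL in [0.05, 0.9] (up to 20, ranked
  by eQTL strength, minimum 3 or the result is "not tested"), delta-method
  covariance of the Wald-ratio differences, and an eigenvalue-weighted
  chi-square null evaluated by Imhof integration — an adaptive head plus a
  QUADPACK Fourier tail, accurate to ~10⁻⁹ against the equal-weight
  chi-square closed form.
* **Summary regions** use an exponential-decay (AR-1) correlation
  `r_ij = exp(−|i−j|/ℓ)`, positive definite for any ℓ > 0; observed z-scores
  are MVN(Rγ, R) with γ a point mass (default 9) at the scenario's causal
  SNP(s). Note a HEIDI subtlety the distinct-causal tests respect: if the
  two causal variants are in negligible LD, no eligible instrument near the
  top eQTL carries the discordant signal and HEIDI is correctly null — the
  statistic rejects when the distinct variants are in modest LD (the
  linkage case it was designed to catch), so that configuration is what the
  heterogeneity tests simulate.

## Problem sizes used in the test suite

Property suites run at sizes where the checked bands are tight but the
suite stays quick: type-I error on a null scan of 2,000 × 2,000; parameter
recovery over 200 seeds of 1,000 individuals; the power-transfer contrast
at an 18,000 : 200 cohort ratio; attenuation at 20,000 individuals per
mediation fraction; colocalisation and HEIDI rates over 20-seed batches.
All seeds are fixed in the tests, so every reported rate is reproducible.

## Known limitations

* Accuracy on training data overstates out-of-sample accuracy; the package
  reports it this way by design (matching the study design it implements)
  and leaves held-out evaluation to the caller.
* The scan is plain OLS: no mixed models, relatedness correction, or
  X-chromosome dosage conventions.
* Single-causal-variant colocalisation only; multi-causal regions violate
  the enumeration's assumption.
* The clumping rule is positional, not LD-aware; with real dense data it
  merges signals a conditional analysis would separate.

## Run configuration schema (YAML)

```yaml
simulation:            # SimulationConfig fields
  n_total: 20000
  n_measured: 1000
  m_variants: 500
  n_causal: 5
  n_replication: 1000
  seed: 5
thresholds:            # Thresholds fields, all optional
  alpha_gw: 5.0e-8
  maf_min: 0.001
  info_min: 0.4
  locus_gap: 1.0e+6
  gene_flank: 5.0e+5
  p_exclude: 1.0e-12
  fdr: 0.1
  pp_h4: 0.75
replicable_p_max: 0.05
catalogue_path: null   # optional known-association TSV (chrom, pos, ...)
gene_table_path: null  # optional gene TSV (chrom, start, end, name)
```
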