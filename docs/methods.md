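# Methods

This note documents the statistical models implemented in `noisecorr`,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## Measurement model and attenuation corrections

Every log-scale measurement is treated as latent signal plus zero-mean
noise, X = φ + ε_X. The reliability α_X = Var(φ)/Var(X) is the fraction of
a measurement's variance that is signal; the Pearson correlation between
two independent replicates equals √(α₁α₂), so replicate correlations are
reliability estimates. Noise attenuates cross-correlations,
E[r_XY] ≈ ρ_φψ·√(α_X α_Y), which motivates the disattenuation estimator:
the geometric mean of the observed cross-correlations divided by the
square root of the product of the reliability correlations. The
four-measurement form uses all four cross-correlations so the estimate
does not depend on replicate labeling; the N×M form generalizes this with
geometric means over all pairs (within-set exponents 1/(N(N−1)), so each
unordered pair counts once per ordering).

Numerical conventions:

- All correlations are computed pairwise-complete (per pair of vectors,
  genes observed in both), because coverage varies strongly between
  studies. A pair with fewer than 3 shared genes has an undefined
  correlation, reported as missing in descriptive tables and raised as an
  error inside the estimators.
- A non-positive correlation makes the geometric mean undefined; the
  estimator raises with guidance rather than silently taking absolute
  values. The simulation-study driver records such simulations as missing
  (this only arises when the true correlation is near zero, where the
  corrected estimator carries no information anyway).
- The corrected estimate is not a correlation coefficient: it can exceed 1
  by sampling error, and no p-value is attached to it. Significance
  testing should use the uncorrected correlations.
- Natural log is the canonical scale everywhere; raw linear-scale input is
  converted by `log_prepare`, with zeros and negative values becoming
  missing (a value of zero in a linear-scale table is a non-detection, not
  a measurement of zero).

## Structured covariance model

Each measurement decomposes as

    X_ij = L_{i,l[j]}·G_{l[j]} + T_{i,t[j]} + E_{i,k[j]} + R_ij + ν_j

with L_i ~ N₂(0, Ψ) the latent (protein, mRNA) levels, T technology
effects (variance τ_t), E experiment/batch effects (variance ξ_k), R
replicate noise (variance θ_j), and ν_j per-replicate offsets (log-scale
normalization constants). Identifiability is resolved by giving L unit
marginal variances — Ψ is a correlation matrix with one free entry Ψ₁₂ —
and letting G_l > 0 carry the scale of true biological variation per
molecule type. The amplification exponent A = G_protein/G_mRNA is then the
log-log slope of protein on mRNA: both latent levels are the same
standardized variable up to correlation, and the measurement scales differ
by the factor A, so P ≈ M^A at steady state.

Missingness is non-ignorable: a cell is detected with probability
expit(η⁰_k + η¹_k·x) depending on the (possibly unobserved) value itself,
with per-experiment parameters. Detection probability is 0.5 at
x = −η⁰/η¹. Low-abundance molecules are therefore preferentially missing,
and ignoring this mechanism attenuates the inferred correlation (shown
directly in the tests by refitting with the missingness model disabled).

Priors: Ψ₁₂ marginally uniform on (−1, 1) — for the 2×2 case the
marginally-uniform correlation-matrix prior reduces to exactly this;
Inv-Gamma(3/2, 3/10) on each of τ_t, ξ_k, θ_j (weak: three
pseudo-observations at scale 1/5, mainly preventing degenerate early
draws; the same prior is used for all three strata since they play the
same role); flat priors on G (constrained positive) and ν; independent
Cauchy(0, 2.5) on η⁰ and η¹, which regularizes the logistic slope when an
experiment's detection boundary is sharp.

### Gibbs sampler

One sweep performs eight conditional updates:

1. Per gene, (L_i, T_i,·, E_i,·) are drawn jointly from their conditional
   multivariate normal given the current parameters and the completed data
   (observed plus imputed). The conditional covariance is shared across
   genes, so a single Cholesky factorization serves all genes per sweep.
2. Ψ₁₂ by random-walk Metropolis on atanh(Ψ₁₂) (boundary-safe; the
   transform's Jacobian is included in the acceptance ratio).
3. G_l by conjugate weighted regression of the residualized data on L_·l,
   truncated to G_l > 0 (the sign constraint that anchors the latent
   orientation).
4.–6. τ_t, ξ_k, θ_j from conjugate inverse-gamma conditionals; ν_j from
   its normal conditional under a flat prior.
7. Each unobserved X_ij by a Metropolis–Hastings independence sampler:
   propose from the model-implied Gaussian N(fitted_ij, θ_j); the model
   terms cancel and the acceptance ratio is the ratio of missingness
   likelihoods P(I=0 | x*)/P(I=0 | x). With the missingness model
   disabled, this reduces to a direct draw (ignorable imputation).
8. (η⁰_k, η¹_k) by a joint normal-proposal Metropolis step targeting the
   Bayesian logistic-regression posterior over all of the experiment's
   cells (observed indicator against completed values); the proposal scale
   adapts toward a 15–35% acceptance rate during burn-in only.

Defaults are 2 chains × 4,000 sweeps with 2,000 burn-in and thinning 2,
with convergence screened by split-R̂ on Ψ₁₂ (flag if above ~1.05); all
settings are config-overridable, and the validation studies below use
shorter chains sized to their smaller datasets. Genes with no observation
in any replicate are excluded with a warning (no data reaches their
posterior beyond the prior). Genes observed for only one molecule type
still contribute: the other type's latent is drawn from its conditional
given Ψ, which is how undetected proteins acquire predicted levels.

### Sampler validation

Two complementary checks are implemented in the test suite:

- **Geweke joint-distribution test.** Alternating Gibbs transitions with
  regeneration of the data from the current state must leave the parameter
  marginals exactly at their priors. Run on a 15-gene, 4-replicate layout
  with G and ν held fixed (their flat priors are improper, so no prior
  marginal exists to compare against), 2,000 draws thinned 15×, KS test at
  1% against Uniform(−1,1) for Ψ₁₂ and Inv-Gamma(3/2, 3/10) for the
  variance components.
- **Parameter recovery.** Twenty datasets (500 genes, 16 replicates in 8
  experiments over 4 technologies, detection-biased missingness in the
  protein studies) are generated from the model and refit. For Ψ₁₂, A,
  and every variance component the posterior mean must fall within two
  posterior SDs of the generating value in ≥90% of checks. Coverage is
  evaluated per component: aggregate functionals such as the mean of all
  θ_j have posterior SDs so small that the ordinary finite-sample pull of
  the variance priors (a few percent at 500 genes) dominates them, so a
  joint or aggregated criterion would fail for a provably correct sampler
  (the Geweke test above is the correctness arbiter).

Chain lengths in the recovery study (2 × 2,200 sweeps, 900 burn-in) were
set so that the slow-mixing amplification ratio (lag-1 autocorrelation
≈ 0.94) accumulates enough effective samples for stable posterior-SD
estimates; the problem sizes keep the full study at roughly ten minutes on
one core.

## Model-II regression

OLS assumes error-free predictors; noise in x shrinks its slope by the
reliability factor (regression dilution). The symmetric alternatives:
MA takes the first principal axis of the covariance; SMA uses
sign(r)·sd(y)/sd(x); RMA standardizes each axis by its observed min–max
range, takes the major axis, and back-transforms by range(y)/range(x)
("interval ranges", i.e. ranges on the log scale on which all analyses
run). All three satisfy fit(y~x)·fit(x~y) = 1 and dominate OLS in
magnitude for noisy positively correlated data. MA alone is not
scale-equivariant — rescaling an axis changes its principal axis — which
is precisely why the standardized and ranged variants exist; the
equivariance property test covers OLS/SMA/RMA only. Confidence intervals,
when requested, come from a nonparametric bootstrap over genes (default
1,000 resamples) since no analytic form is assumed.

## Synthetic data: what it emulates and what it does not

- `simulate_noisy_replicates` draws latent (mRNA, protein) pairs from a
  bivariate standard normal with correlation ρ and adds independent
  N(0, (1−α)/α) noise per replicate, so reliability is exactly α by
  construction. Defaults (5,000 genes, ρ = 0.9, α = 0.7, two replicates
  per side, 50 simulations per study cell) match the validation-study
  conditions. The "observed" estimator in the simulation study correlates
  a single replicate pair; the corrected estimator uses all four.
- NMAR masking drops whole genes with detection probability
  expit(η₀ + 2z) on the standardized mean log level, with η₀ solved
  numerically for a target detected count. The slope of 2 per standard
  deviation produces the marked detection bias seen in real protein data;
  the functional form matches the SCM's observation model. Whole-row
  masking reflects the "gene detected or not" framing of the validation
  study; per-cell masking is used in the SCM generator.
- The toy model draws ln M ~ N(1.09, 1.25²) (molecules/cell, matching
  integrated genome-scale estimates for budding yeast), translation rate
  τ = 0.1·exp(ln M + N(0, 1.1²))^0.56, and protein
  P = (τ/δ)·exp(ln M + N(0, 0.55²)) with δ = 0.001. Variance propagation
  gives corr(ln M, ln P) = (1+γ)·sd_lnM / sd_lnP ≈ 0.921 and
  sd-ratio slope ≈ 1.694; the generator is checked against these closed
  forms. The seed field is honored, but published values produced by a
  different RNG engine are matched in distribution (tolerances are
  three Monte-Carlo SDs measured over 100 seeds), not bit-for-bit.
- `simulate_scm_dataset` draws from the SCM equations exactly; its default
  layout (technologies shared by multiple experiments, two replicates per
  experiment, mostly-complete mRNA studies and 60–75%-detected protein
  studies) keeps every variance stratum identifiable.

None of the generators model gene-gene correlation, per-gene error
variances, or dynamic-range compression by measurement saturation. Passing
tests therefore certify the estimators under the stated noise model, not
robustness to those further real-data features (the model's robustness to
several of them is a property argued elsewhere, not established by this
test suite).

## Other numerical choices

- Molecules-per-cell scaling normalizes exponentiated log estimates to a
  configured cellular total: 36,169 mRNA molecules per haploid cell by
  default; protein totals may be given as molecule counts or as total
  protein mass with per-gene molecular weights. Ribosome counts multiply
  median density (per-nucleotide) by coding length and normalize to
  200,000 ribosomes/cell × 85% active = 170,000 engaged ribosomes. All
  scalings preserve ratios and rank order.
- Ribosome-density summaries follow the three-step median-normalization:
  log-transform all measurements, subtract the grand median, exponentiate
  the per-gene median; no variance rescaling, so each study's dynamic
  range is preserved.
- Dynamic-range comparisons use ratios of log ranges, with a central-95%
  variant to mute the extreme-value sensitivity of ranges.
- Simulation grid cells derive per-cell seeds deterministically from the
  study seed, so cells are independent and results identical regardless of
  execution order.
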