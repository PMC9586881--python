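# Methods

## Prevalence posterior

A within-participant test with false-positive rate α is applied
independently to each of N participants. The model assumes a participant
either carries an effect detectable by this test (population fraction γ)
or does not; a carrier is significant with probability 1, a non-carrier
with probability α. Hence each participant is significant with
probability θ = α + γ(1 − α) and k ~ Binomial(N, θ).

Two assumptions matter for interpretation. First, *perfect sensitivity
within class*: "detectable effect" is defined relative to the test
actually used, so γ is the prevalence of effects this experiment can
detect, not of effects in any absolute sense; test power is not modelled
separately. Second, a *uniform prior* on γ. Under it the θ-posterior is
Beta(k+1, N−k+1) truncated to [α, 1], and the γ-posterior follows by the
linear change of variables (Jacobian 1 − α).

Numerics: all cumulative quantities go through the regularized
incomplete beta function (`scipy.special.betainc` / `betaincinv`) with
log-space densities, rather than quadrature, so they remain stable for
large N and extreme k. The normalizer is 1 − I_α(k+1, N−k+1); it
underflows only as α → 1, which is rejected.

- **MAP**: clamp((k/N − α)/(1 − α), 0, 1). k/N ≤ α yields 0 — reported
  as a valid estimate (evidence of low prevalence), not an error.
- **HPDI**: the shortest interval with the requested mass. It is found
  by parameterizing the lower endpoint by its cdf value t ∈ [0, 1−mass]
  and minimizing quantile(t+mass) − quantile(t) with bounded scalar
  optimization (tolerance 1e-10 on t). For a unimodal density this is
  the HPD interval; endpoints of interior-mode intervals agree in
  density to ~1e-4 relative. Boundary modes are handled explicitly:
  k = N gives [quantile(1−mass), 1]; k/N ≤ α gives [0, quantile(mass)].
- **Reporting**: MAP and endpoints to 4 decimals; percentage rendering
  rounds to the nearest integer (the 96% HPDI for 10/20 at α = 0.05
  renders as 25–70%).

Calibration: the 96% HPDI's frequentist coverage is not exactly 0.96
because k is discrete. Exact enumeration at N = 20, α = 0.05 gives
coverage 0.9378, 0.9294 and 0.9611 at γ = 0.2, 0.5 and 0.8; the test
suite checks Monte-Carlo coverage against these enumerated values.

## Prevalence null tests

The null γ ≤ γ0 is tested by the exact upper binomial tail
P(X ≥ k | N, θ(γ0)), accumulated by log-sum-exp over binomial log-pmf
terms so p-values far below machine-printable sizes keep accurate
−log10 p. γ0 = 0 is the global null and γ0 = 0.5 the majority null; the
"at least k" tail convention asks how surprising k or more significant
participants would be. `contour_grid` tabulates −log10 p (global and
majority), MAP, and the HPDI lower edge over all (N, k) as a TSV with
fixed header `n, k, neglog10p_global, neglog10p_majority, map,
hpdi_lower`.

## Difference posteriors

**Between groups**: the two posteriors are independent, so δ = γ_a − γ_b
is sampled by pushing uniform variates through each quantile function
and subtracting. One root seed spawns per-group sub-streams
(`numpy.random.SeedSequence`), making outputs bit-reproducible.

**Paired tests**: participants fall in four latent classes — effect
detectable by both tests, only A, only B, neither — with probabilities
ρ = (ρ11, ρ10, ρ01, ρ00) on the simplex and uniform Dirichlet prior.
With per-test false-positive rates α1, α2 and perfect within-class
sensitivity (the same reading of "detectable" as above), the observed
significance pattern is multinomial with cells

    P11 = ρ11 + ρ10α2 + ρ01α1 + ρ00α1α2
    P10 = ρ10(1−α2) + ρ00α1(1−α2)
    P01 = ρ01(1−α1) + ρ00(1−α1)α2
    P00 = ρ00(1−α1)(1−α2)

and the quantity of interest is δ = γ_A − γ_B = ρ10 − ρ01. The posterior
is approximated by sampling-importance-resampling: proposals come from
the Dirichlet(counts + 1) posterior of the error-free model, weights are
the likelihood ratio Π(P_c/ρ_c)^{k_c}, and n_samples draws are
resampled. This proposal tracks the target closely for small α (weights
→ 1 as α → 0), so the importance effective sample size stays high where
a uniform-prior proposal collapses; ESS is reported with every summary
and a diagnostic warning is logged below 1% of the proposal count
(default proposal pool: 50 × n_samples). δ is summarized by the median,
a central equal-tail interval, and P(δ > 0) — sample-based HPD intervals
are noisy for skewed bounded distributions, so equal-tail is used. The
implementation is validated against a brute-force posterior on a
3-simplex grid (step 0.02, tie mass at δ = 0 split evenly).

## Simulator

Each participant contributes n_trials × n_timepoints of Gaussian noise
(SD noise_sd); carriers add to every trial a unit-peak Gaussian bump of
width effect_width with per-participant amplitude
A_p ~ Normal(amplitude_mean, amplitude_sd) and latency
L_p ~ Normal(latency_mean, latency_sd), rounded to a sample and clipped
to range (clipping logs a warning). The carrier count is
round(effect_fraction × n_participants).

Within-participant inference is a two-sided one-sample t-test per
timepoint at threshold family_alpha/n_timepoints (Bonferroni); a
participant is significant overall if any timepoint passes, so the
overall test's false-positive rate is the familywise rate (≈ 0.049 at
family_alpha = 0.05 with 60 independent timepoints) and the overall
prevalence posterior uses α = family_alpha. The per-timepoint prevalence
time course instead uses α = family_alpha/n_timepoints — the rate
actually controlled at a single timepoint. Population-mean inference
applies the same per-timepoint t-test across participants' trial means.
Zero-variance cells get p = 1 with a warning. Trial noise is Gaussian by
construction, so the t-test's normality assumption holds exactly in
simulation — passing tests say nothing about its robustness on real,
possibly heavy-tailed or autocorrelated data, nor do the simulations
model trial-to-trial latency jitter, spatial channels, or artifacts.

### Scenario presets

All presets use 100 trials, 60 timepoints, noise SD 1, bump width 3,
central latency 30; the numbers are this package's defaults, chosen so
the scenarios exhibit the qualitative regimes they illustrate (strong
individual effects, no population-mean significance at any timepoint in
a typical run).

| preset | N | amplitude (mean ± SD) | latency SD | carriers |
|---|---|---|---|---|
| A | 20 | 0 ± 1.5 | 1 | all |
| B | 20 | 1.0 fixed | 15 | all |
| C | 5 | 1.0 ± 0.5 | 1 | all |
| D | 20 | 1.2 fixed | 8 | half |

Design notes, in the package's own words:

- A uses amplitude mean 0 so signed effects cancel in the mean — the
  strongest form of "variable effect size" with no mean effect.
- B and D's latency SDs were set analytically before Monte-Carlo
  validation. With aligned same-sign effects the across-participant t at
  the peak is nearly invariant to amplitude (mean and SD both scale with
  it), ≈ 4.3 for N = 20 — above the Bonferroni threshold ≈ 3.9. Timing
  variability is the lever that lowers it: the expected bump value at
  the center is w/√(w²+s²) while its spread shrinks more slowly, giving
  worst-timepoint expected t ≈ 2.75 at s = 15 (B) and ≈ 2.5 at s = 8
  for D's half-carrier design. Monte-Carlo over 200 seeds confirms no
  population-mean significance in ~76% (B) and ~94% (D) of runs, with
  every carrier still detected individually.
- D's carrier count of 10/20 reproduces the 10-of-20 worked example in
  the seeds (≈ 60%) where none of the ten non-carriers triggers a
  familywise false positive; (1 − 0.0488)¹⁰ ≈ 0.61 is the ceiling on
  that frequency, so k = 10 is the modal but not near-certain outcome.

## Problem sizes in the test suite

Monte-Carlo checks use 2000 simulated participants for familywise-error
control, 2000 replicate experiments per γ for coverage, 200 seeds per
scenario preset, and 20k–100k posterior draws for difference summaries —
sizes at which the binomial error bands used in the assertions are a few
tenths of a percent.

## Known limitations

- No hierarchical pooling across participants; each participant is
  reduced to one bit (significant or not), so information in effect
  sizes is discarded.
- The uniform prior is fixed; no sensitivity parameter; prevalence is
  test-relative.
- The paired-difference model assumes the two tests err independently
  given class; correlated false positives would need a richer model.
- HPD search assumes a unimodal posterior (always true here).
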