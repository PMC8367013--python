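# Methods

## Model and assumptions

All estimators assume that, after variance stabilization, the response to
stimulus *i* on repeat *j* is

    Y_ij ~ Normal(mu_i, sigma^2),   independent across i and j,

with a common trial-to-trial variance sigma^2.  The estimand is r^2_ER, the
squared correlation between fixed model predictions nu and the expected
responses mu.  Two nuisance parameters control everything: sigma^2 and the
dynamic range d^2 = (1/m) sum (mu_i - mu_bar)^2; their ratio SNR = d^2/sigma^2
determines how hard the problem is.  The m stimuli are treated as fixed: the
estimator quantifies fit on the stimuli actually shown, not generalization to
a stimulus population, and it assumes independent responses (no shared slow
drift, no adjacent-time-bin correlation).

Variance stabilization (`ervar.stabilize`) covers the mean-variance family
Var = a * mean^b with b < 2 via f(x) = x^(1-b/2) / (a (1-b/2)); the plain
square root (the a=1, b=1 case up to a factor 2) brings Poisson counts to a
trial variance of ~1/4 for rates above ~5.  The slope/exponent are user
inputs; the package does not fit them.

## Point estimators

`r2_er` subtracts the noise terms (sigma^2/n, scaled by the model sum of
squares and by m-1 respectively) from the numerator and denominator of the
naive squared correlation.  Properties worth knowing when reading output:

* The estimate is not truncated to [0, 1]; with a perfect model roughly half
  of the estimates exceed 1.  Truncation would bias the mean downward, and
  group averages would inherit that bias.
* The ratio of two unbiased quantities is itself only approximately
  unbiased; the residual (Jensen-gap plus numerator/denominator covariance)
  upward bias is visible only at very low SNR and shrinks as m grows.  The
  test suite measures both component unbiasedness and the consistency-in-m
  behaviour.
* A denominator <= 0 (weak tuning, high noise) sets `unstable=True`; the raw
  ratio is still reported and the interval machinery, not the point
  estimate, carries the uncertainty.
* Predictions are internally rescaled to unit centred sum of squares; results
  are invariant to affine transformations of nu, and the reported
  numerator/denominator are mapped back to the caller's scale so the
  closed-form toy values hold as printed.
* `pooled_sample_variance` is the default sigma^2 (mean of per-stimulus
  unbiased variances).  Single-repeat designs must supply an assumed value
  (0.25 for sqrt-Poisson) via `NoiseEstimate(..., source="assumed")`.
* `r2_er_linear` generalizes the correction to least-squares fitted values
  with d parameters (subtract (m-d) and (m-1) noise terms from SS_res and
  SS_tot); at d=2 it is algebraically identical to `r2_er`, which the suite
  asserts to 1e-12.  Effective degrees of freedom of regularized fits are
  whatever the caller asserts — nothing in the theory defines them here.

## Simulation engine

`simulate` draws tuning curves mu_i = a + b sin((i-1) 2 pi/m + theta) against
the model nu_i = sin((i-1) 2 pi/m).  For equally spaced full-cycle phases the
discrete trig identities are exact, so theta = arccos(sqrt(r2)) gives the
target correlation to machine precision, and b is solved from the realized
discrete sum so the d^2 constraint is exact for any m (not the continuum
b = sqrt(2 d^2) approximation).  Gaussian mode draws Y directly;
`poisson_sqrt` mode draws counts from Poisson(mu_i^2) and square-roots them,
with the baseline a defaulting to b + 0.5 so rates stay positive.  What the
generator deliberately omits — correlated trial noise, stimulus-dependent
variance, temporal structure, non-Poisson dispersion — bounds what passing
benchmarks say about real recordings: they validate the estimator under the
model's own assumptions, not robustness to their violation.

Benchmark problem sizes used by the tests and the acceptance script (chosen
as the standard conditions of the simulation study, scaled where noted):
m=362, n=4, sigma2=0.25 with 500-1000 replicates for the estimator
benchmarks; m=40, n=4 with 2000-iteration chains and 200 interval
constructions per true value for the coverage experiments.

## Confidence intervals (ECCI)

The estimate-centred credible interval treats the estimator's sampling
distribution F(r_hat | r) as a function of the candidate truth r.  The upper
endpoint is the r at which the observed estimate sits at the lower
(1-alpha)/2 tail; the lower endpoint mirrors it.  `alpha` throughout is the
coverage level (0.8 by default).  Since F depends on (sigma^2, d^2), these
are drawn from their posterior given the recording's sufficient statistics
(pooled within-stimulus variance; raw between-stimulus variance of the trial
averages, whose expectation is inflated by sigma^2/n — distinct from the
corrected d^2_ER) under flat nonnegative priors.

Numerical choices:

* Endpoint search: the candidate CDF value is estimated from 2500 simulated
  estimates; a two-sided z-test at significance 0.01 decides whether the
  candidate is accepted; otherwise the root is bracketed and the next
  candidate drawn uniformly from the bracket (up to `max_splits`, default
  100).  Both unit-interval boundaries are evaluated first, which implements
  the clamping rules directly: an upper endpoint forced to 1 (or a lower
  endpoint forced to 0) is reported with a clamp flag; an upper endpoint
  forced to 0 (or lower to 1) yields the empty interval, per the
  non-inclusive boundary convention.
* Sampler: chains start at the estimates (near the mode; no burn-in) and use
  an independence proposal — a zero-truncated normal centred at the
  estimates with variances matched to the two statistics' sampling
  distributions, truncation by redraw.  The default acceptance rule is the
  plain likelihood ratio.  That rule does not satisfy detailed balance for
  the posterior (its stationary law is posterior x proposal, measurably
  narrower: total-variation distance ~0.2 from a grid-evaluated posterior at
  m=40, n=4); `hastings_correction=True` adds the proposal-density terms and
  matches the grid oracle to TV < 0.1.  The plain rule is kept as the
  default because the interval procedure built on it still attains nominal
  coverage (0.83 vs 0.81 for the corrected rule at alpha=0.8 in our
  validation runs) and it is the documented recipe this implementation
  follows; both rules are exercised in the tests.
* The stochastic-ordering assumption behind the construction (F
  non-increasing in the candidate) is asserted empirically over a candidate
  grid, not proven.
* Degenerate zero-variance data yields a zero-width interval at the clipped
  point estimate (there is no sampling variability to integrate over).

Bootstrap baselines: `npboot` resamples trials within stimulus; `pboot`
simulates from the fitted (sigma^2, d^2_ER, clipped point estimate); `bca`
adds bias-correction and jackknife-over-stimuli acceleration to the
parametric bootstrap.  Endpoints are clipped to [0, 1].  The coverage
harness reproduces the known failure of the non-parametric bootstrap at high
correlation (intervals almost entirely below the truth) and the near-nominal
behaviour of ECCI.

## SNR and power

SNR_hat = d^2_ER_hat / s^2 is unbiased up to the ratio approximation and can
be negative for untuned neurons (clipping would bias population summaries).
The one-way F statistic for stimulus modulation follows a noncentral
F(m-1, m(n-1)) with noncentrality m*n*SNR, so the power of the tuning test
is an upper-tail probability and `min_snr_for_power` inverts it by bracketed
root-finding (bracket [1e-6, 1e3] with expansion, tolerance 1e-8 on power;
power is strictly increasing in SNR so the root is unique).  Defaults
alpha=0.01, beta=0.99 — a deliberately strict "is there tuning at all" bar.
`snr_time_normalize` rescales SNR proportionally to the counting-window
duration; this is exact only if the firing rate is constant within the
window, an optimistic assumption that is surfaced rather than hidden.

## Prior noise-ceiling estimators

Interpretation choices where the published recipes are underspecified:

* Upsilon divides the residual and total sums of squares by the estimated
  variance of the *sample mean* (s^2/n) — the scaling under which its
  noncentral-F derivation is dimensionally consistent; at
  noise_mean_variance=0 the noise-free limit (plain 1 - SS_res/SS_tot) is
  returned.
* Split-half ceilings use two disjoint halves of floor(n/2) trials, a random
  odd trial dropped per resample, Spearman-Brown correction 2r/(1+r), and
  100 resamples by default.  `cc_norm_split2` takes CC_max = sqrt(SB) as the
  correlation-scale ceiling (so the squared ceiling is SB itself), which is
  approximately unbiased; `r2_norm_split_sb` treats the SB-corrected
  correlation directly as the r-scale ceiling and therefore double-counts
  the attenuation — reproducing the known over-estimation of that recipe.
* `cc_norm_pb` simulates 100 Gaussian surrogates from the per-stimulus
  sample means and pooled variance; its ceiling is too low because the
  sample means it conditions on are themselves noisy, hence the documented
  under-estimation.
* `pc_ratio` uses SE^2 = s^2/n and SS_total = variance of trial averages
  (m-1 denominator).  With these constants the estimator always exceeds the
  naive r^2 but its bias is mild; the original's stronger over-estimation
  presumably reflects different constants, which its description does not
  pin down.  Only the direction is asserted.
* FEVE is computed at trial level: MSE and total variance both over all m*n
  responses, each reduced by sigma^2_hat.
* Nonpositive ceilings/normalizers are flagged (RuntimeWarning) and the
  value returned as-is, never silently clipped.

## Known limitations

Correlated responses (time bins, shared noise), stimulus-dependent variance,
neuron-to-neuron signal correlation, Jensen-gap correction at very low SNR,
and mean-variance-relation fitting are out of scope.  The low-SNR regime can
produce wild point estimates, empty intervals, or full-range intervals; these
are faithful reports of uninformative data, and the SNR power analysis is the
tool for deciding whether a recording can support model evaluation at all.
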