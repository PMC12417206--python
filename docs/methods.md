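# Methods

## Model

The framework answers: *given one validation study of a blood-pressure
measurement device, how probable is it that the device would satisfy
ISO 81060-2-style accuracy criteria?* Two models are combined.

**Sampling model of the proportion.** Let μ_p be the probability that a
single measurement error is tolerable (|error| < Δ). Over repetitions of an
n-sample experiment the observed proportion P is modelled as a Beta random
variable whose mean is μ_p and whose SD is the binomial standard error
σ_p = √(μ_p(1−μ_p)/n). Moment matching gives shape parameters that simplify
exactly to α = (n−1)μ_p, β = (n−1)(1−μ_p) (the package computes the full
moment-matching closed form and a property test asserts the simplification to
1e−12). The Beta is a smooth stand-in for the scaled binomial: it has the
right first two moments, full support on (0, 1), and closed-form tails.
It is an approximation — the true proportion is discrete — and it degenerates
at μ_p ∈ {0, 1}, where the package switches to the point-mass limit
(credence 1 or 0 by comparison with the threshold) rather than evaluating an
undefined Beta.

**Error model.** Within a study, the error Y given blood pressure x is
normal about the fitted regression line ŷ(x) = ȳ + β₁(x − x̄) with
individual-prediction standard error

    SE[x] = sqrt( (ȳ² + s_y²) (1 + 1/n + (x − x̄)² / ((n−1) s_x²)) ).

Two remarks. First, the variance factor is ȳ² + s_y², not the conventional
OLS residual variance s_y²(1 − r²)-style quantity: the squared mean error
inflates the predictive spread. This is a deliberate, non-standard choice —
it reproduces the published evaluation results exactly, and it acts as a
conservative penalty on biased devices — but it means the conditional law is
*not* the classical prediction interval; no "corrected" variant is offered.
Second, when β₁ is unreported (the common case) it defaults to 0, in which
case s_y absorbs all error variability.

**Probability of tolerable error.** With X the reference BP distribution of
the standard (Normal(130, 20²) systolic, Normal(80, 13²) diastolic),

    μ_p = ∫ f_X(x) [ F_{Y|X=x}(Δ) − F_{Y|X=x}(−Δ) ] dx.

The inner integral over the error is collapsed analytically to a normal CDF
difference (identical to the double integral over the joint density by
Fubini); one adaptive quadrature (`scipy.integrate.quad`, absolute tolerance
1e−10) runs over x on ref_mean ± 10 SD, where the omitted tail mass is below
1e−23.

**Threshold and credence.** μ_pmin solves
C_pmin = 1 − I_{p_test}((n−1)m, (n−1)(1−m)) by bracketed Brent iteration on
(p_test, 1) with xtol 1e−10 (the left side is monotone in m, so the bracket
is guaranteed; the calibration identity is asserted to 1e−8 in tests). The
credence is cr_A = 1 − I_{μ_pmin}((n−1)μ_p, (n−1)(1−μ_p)).

## Parameters

| Parameter | Meaning | Default | Why |
|---|---|---|---|
| Δ | tolerable error, mmHg | 10 | the error magnitude standards treat as clinically acceptable |
| C_pmin | required confidence | 0.95 | standards' confidence level for acceptance |
| p_test | test proportion | 0.78 | at n = 85, a device with 85% tolerable errors shows ≥78% with 95% confidence |
| p̂ | headline proportion | 0.85 | used only by the mean-error-dependent SD limit |
| reference BP | X ~ Normal | 130±20 (SBP), 80±13 (DBP) | meets the standard's tail requirements on sampled BP by construction |

All probabilities are carried as floats in [0, 1]; percent strings (with the
"<0.1%" floor convention used in published tables) exist only in the
reporting layer and never feed back into computation. Presets are JSON data
files (`src/bpcredence/presets/`), so variants for other standards can be
added without code changes; user files with the same schema load via
`load_preset`.

The shipped demo table (`iso_demo_studies.csv`) transcribes the input
summary statistics of ten published validation studies covering cuff
oscillometric, volume-clamp, pulse-transit-time and PPG/ML methods. One row
has a diastolic BP mean of 97.7 mmHg — unusually high, but transcribed as
published, without correction. All slopes are 0 because none of the studies
reported an error-BP correlation.

## Synthetic data

`SimulationDesign` draws BPs Normal(bp_mean, bp_sd²) and errors
Normal(intercept + slope·(bp − bp_mean), error_sd²). This is exactly the
linear-normal structure the analytic pipeline assumes, so Monte-Carlo /
quadrature agreement tests the numerics, not model adequacy: passing tests
say nothing about heteroscedastic, heavy-tailed, or non-linear real device
errors. One subtlety: the generator's conditional error SD is `error_sd`,
while the analytic SE[x] adds the ȳ² term; the two laws coincide only at
zero mean error (or when the oracle draws with SE[x] itself, as the
quadrature-equivalence tests do). Replicate streams derive from the master
seed via `SeedSequence(seed, spawn_key=(replicate,))` — deterministic,
order-independent, no global state.

Default design values (n = 85, BP 130 ± 20 mmHg, error SD 5 mmHg, slope
0.05) mirror a standards-sized cuff study with a mid-range device; the
repeatability helper shows how strongly cr_A fluctuates across replicates at
small n.

The slope-recovery check runs 5000 replicates at n = 200: with nominal
two-sided 2·SE coverage of 95.3%, the Monte-Carlo error on the coverage rate
(≈0.3 pp at 5000 replicates) must be small relative to the 0.3 pp margin over
the 95% bound for the check to be informative rather than a coin flip.

## Numerical choices and conventions

- Sample SDs use the n−1 denominator throughout (the convention of reported
  summary statistics).
- n ≥ 2 for the Beta construction, n ≥ 3 for anything regression-based;
  smaller samples raise a `ValueError` naming the study where possible.
- The SD-limit solve brackets σ between ~0 and a doubling upper bound and
  uses Brent to 1e−10; at zero mean error it agrees with the closed form
  Δ/Φ⁻¹((1+p̂)/2) = 6.95 mmHg.
- Tail-requirement comparisons are weak inequalities ("at least 5%").
- Batch CSV output writes raw floats with round-trip precision alongside
  percent-formatted display columns; a bad row is reported and skipped, not
  fatal.

## Known limitations

- Normal BP and normal errors only; t-distributed or skewed error laws are
  out of scope.
- The ȳ² term in SE[x] (above) makes the error law non-standard; users
  expecting classical prediction intervals should note the difference.
- Published evaluation tables occasionally disagree with their own prose
  (one source describes a wrist-device credence as "exceeding 99%" where its
  table prints 96.80%/94.10%); this package reproduces the tabulated values
  and treats the table as authoritative.
- Demographic requirements of validation standards (sex balance, cuff
  sizes, age) are not modelled; only the BP-distribution tail requirements
  are checked.
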