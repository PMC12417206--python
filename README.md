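# bpcredence

Statistical evaluation of blood-pressure measurement (BPM) device accuracy:
given a validation study's sample size, sampled BP range, and measurement
error statistics, `bpcredence` computes the **credence of device
acceptability** — the probability that the device would meet
ISO 81060-2-style accuracy criteria — so that studies with different sample
sizes and BP ranges can be compared on a common footing.

It is aimed at BPM device developers and researchers who validate devices
(cuff oscillometric, volume-clamp, pulse-transit-time, PPG/ML methods) on
samples smaller or narrower than the standard's 85-subject, wide-BP-range
design, and want to know how much evidence of standards-level accuracy those
studies actually provide.

## The statistic

An error is *tolerable* when it lies within ±Δ (10 mmHg). The observed
proportion of tolerable errors over hypothetical repetitions of an n-sample
experiment is modelled as

P ~ Beta(α, β),  α = (n−1)μ_p,  β = (n−1)(1−μ_p),

the moment-matched Beta whose mean is the proportion μ_p and whose SD is the
binomial standard error √(μ_p(1−μ_p)/n). Tail probabilities of P are
regularized incomplete beta functions I_p(α, β). Three quantities follow:

1. **Acceptance threshold μ_pmin** — solves
   C_pmin = 1 − I_{p_test}((n−1)μ_pmin, (n−1)(1−μ_pmin)) at the study's n,
   with C_pmin = 0.95 and p_test = 0.78: the observed proportion a
   standards-compliant device must reach at that sample size.
2. **Probability of tolerable error μ_p** — the device error Y is modelled
   as normal about a regression line on BP, with individual-prediction
   standard error SE[x] = √((ȳ² + s_y²)(1 + 1/n + (x−x̄)²/((n−1)s_x²))), and
   μ_p = ∫ f_X(x)[F_{Y|X=x}(Δ) − F_{Y|X=x}(−Δ)]dx under the standard's
   reference BP distribution X ~ N(130, 20²) for systolic or N(80, 13²) for
   diastolic pressure.
3. **Credence cr_A = 1 − I_{μ_pmin}((n−1)μ_p, (n−1)(1−μ_p))** — the
   probability that the true proportion of tolerable errors is at least
   μ_pmin, given the study's evidence.

The package also checks BP distributions against the standard's tail
requirements (e.g. ≥5% of systolic readings below 100 mmHg) and computes the
classical mean-error-dependent SD limit (6.95 mmHg at zero mean error).

## Worked example

A pulse-transit-time study with 33 participants, systolic BPs
121.4 ± 17.6 mmHg and errors −0.06 ± 6.63 mmHg:

```sh
credence single --n 33 --bp-mean 121.4 --bp-sd 17.6 \
    --err-mean -0.06 --err-sd 6.63 --preset iso81060_2_sbp
```

```
Credence of Device Acceptability
====================================================
Sample size (n)                                   33
Sampled BP mean / SD (mmHg)           121.40   17.60
Error mean / SD (mmHg)                 -0.06    6.63
Error-BP slope                                0.0000
Reference BP (mmHg)                    130.0    20.0
Tolerable error Δ (mmHg)                        10.0
----------------------------------------------------
Acceptance threshold μ_pmin                   88.37%
P(tolerable error) μ_p                        85.38%
Credence cr_A                                 34.98%
SE of proportion σ_p                          0.0615
====================================================
```

The device's errors look acceptable at face value (mean near zero, SD under
8 mmHg) and indeed 85.4% of errors are expected to be tolerable over the
standard's BP range — but at n = 33 a compliant device would need an
observed proportion of 88.4%, so the study provides only a 35% credence that
the device meets the standard. The same computation from Python:

```python
from bpcredence import CredenceModel

res = CredenceModel.from_summary_stats(
    n=33, bp_mean=121.4, bp_sd=17.6, err_mean=-0.06, err_sd=6.63,
    preset="iso81060_2_sbp",
).fit()
print(res.summary())        # the table above
res.plot_confidence("confidence.png")
```

Batch evaluation of a study table (the packaged demo table holds ten
published validation studies):

```sh
credence evaluate --input studies.csv --output results.csv
credence threshold-curve --n-min 10 --n-max 1000 --out curve.png
```

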