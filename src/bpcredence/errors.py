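"""Study-specific error model and the probability of tolerable error.

The measurement error ``Y`` of a device is modelled as normally distributed
about a linear regression on blood pressure ``X``:

    (Y | X = x) ~ Normal(yhat(x), SE[x]^2),   yhat(x) = ybar + beta1 (x - xbar)

with an individual-prediction standard error

    SE[x] = sqrt( (ybar^2 + s_y^2) (1 + 1/n + (x - xbar)^2 / ((n-1) s_x^2)) ).

Note the variance factor is ``ybar^2 + s_y^2`` — the mean error contributes to
the spread used for individual predictions. This is deliberate and matches how
the published credence values were produced; see docs/methods.md for
discussion of how it differs from the conventional OLS residual variance.

The probability of a tolerable error under a reference BP distribution
``X ~ Normal(ref_mean, ref_sd^2)`` is

    mu_p = ∫ f_X(x) [ F_{Y|X=x}(Δ) − F_{Y|X=x}(−Δ) ] dx,

evaluated with the inner integral in closed form (normal CDF difference) and
one adaptive quadrature over x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import integrate
from scipy.stats import norm

if TYPE_CHECKING:  # pragma: no cover
    from .standards import StandardParams

__all__ = [
    "ErrorModel",
    "PairedSample",
    "fit_error_model",
    "prediction_se",
    "conditional_error_cdf",
    "probability_tolerable",
]

_QUAD_EPSABS = 1e-10
_TAIL_SDS = 10.0  # integration range ref_mean ± 10 SD; omitted tail mass < 1e-23


@dataclass(frozen=True)
class ErrorModel:
    """Summary statistics of a device validation study's error-vs-BP relation.

    Attributes
    ----------
    n : int
        Number of paired (BP, error) observations, >= 3.
    x_bar, s_x : float
        Mean and SD (n-1 denominator) of the sampled blood pressures, mmHg.
    y_bar, s_y : float
        Mean and SD of the measurement errors, mmHg.
    beta1 : float
        Slope of error on BP; 0 when a study does not report the
        error-BP correlation.
    """

    n: int
    x_bar: float
    s_x: float
    y_bar: float
    s_y: float
    beta1: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"error model requires n >= 3; got n={self.n}")
        if self.s_x <= 0:
            raise ValueError(f"BP standard deviation must be positive; got {self.s_x!r}")
        if self.s_y < 0:
            raise ValueError(f"error standard deviation must be >= 0; got {self.s_y!r}")

    def predict(self, x: float) -> float:
        """Mean predicted error at blood pressure ``x`` (mmHg)."""
        return self.y_bar + self.beta1 * (x - self.x_bar)


@dataclass(frozen=True)
class PairedSample:
    """Raw paired (blood pressure, error) observations from one study."""

    records: Sequence[tuple[float, float]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.records) < 3:
            raise ValueError("need at least 3 paired observations")

    @property
    def bp(self) -> np.ndarray:
        return np.asarray([r[0] for r in self.records], dtype=float)

    @property
    def error(self) -> np.ndarray:
        return np.asarray([r[1] for r in self.records], dtype=float)


def fit_error_model(sample: PairedSample) -> ErrorModel:
    """Fit the linear error model to raw paired observations.

    Means and SDs use the n-1 denominator; the slope is the ordinary
    least-squares estimate cov(x, y) / var(x).
    """
    x, y = sample.bp, sample.error
    sx = float(np.std(x, ddof=1))
    if sx == 0.0:
        raise ValueError("all blood pressures identical: regression slope undefined")
    cov = float(np.cov(x, y, ddof=1)[0, 1])
    return ErrorModel(
        n=len(x),
        x_bar=float(np.mean(x)),
        s_x=sx,
        y_bar=float(np.mean(y)),
        s_y=float(np.std(y, ddof=1)),
        beta1=cov / sx**2,
    )


def prediction_se(model: ErrorModel, x: float) -> float:
    """Individual-prediction standard error of the error at BP ``x`` (mmHg)."""
    lever = 1.0 + 1.0 / model.n + (x - model.x_bar) ** 2 / ((model.n - 1) * model.s_x**2)
    return math.sqrt((model.y_bar**2 + model.s_y**2) * lever)


def conditional_error_cdf(model: ErrorModel, x: float, y: float) -> float:
    """CDF of the error at BP ``x`` evaluated at ``y``: Normal(yhat(x), SE[x]^2)."""
    se = prediction_se(model, x)
    if se == 0.0:
        return float(y >= model.predict(x))
    return float(norm.cdf(y, loc=model.predict(x), scale=se))


def probability_tolerable(model: ErrorModel, params: "StandardParams") -> float:
    """Probability mu_p that a single error is within ±Δ under the reference BP law.

    Integrates the conditional tolerable-error probability against the
    reference Normal(ref_mean, ref_sd^2) density. The inner integral over the
    error is a normal CDF difference, mathematically identical to the double
    integral over the joint density.
    """
    delta = params.delta
    mu, sd = params.ref_mean, params.ref_sd

    def integrand(x: float) -> float:
        yhat = model.predict(x)
        se = prediction_se(model, x)
        if se == 0.0:
            band = float(abs(yhat) < delta)
        else:
            band = norm.cdf((delta - yhat) / se) - norm.cdf((-delta - yhat) / se)
        return norm.pdf(x, loc=mu, scale=sd) * band

    lo, hi = mu - _TAIL_SDS * sd, mu + _TAIL_SDS * sd
    value, _ = integrate.quad(integrand, lo, hi, epsabs=_QUAD_EPSABS, limit=200)
    return float(min(max(value, 0.0), 1.0))
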