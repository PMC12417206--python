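"""Sampling model of the proportion of tolerable errors.

A device validation experiment with ``n`` paired readings yields an observed
proportion of tolerable errors. Over hypothetical repetitions of the same
experiment that proportion is a random variable ``P``, modelled here as
Beta(alpha, beta) with alpha and beta chosen by moment matching so that the
mean equals the observed proportion ``mu_p`` and the standard deviation
equals the binomial standard error ``sqrt(mu_p (1 - mu_p) / n)``. The
moment-matching solution simplifies to

    alpha = (n - 1) mu_p,    beta = (n - 1) (1 - mu_p),

which makes every tail probability of ``P`` a regularized incomplete beta
function. Two quantities are built on this model:

* the acceptance threshold ``mu_pmin`` — the observed proportion a
  standards-compliant device must reach, at the study's sample size, for the
  required confidence ``C_pmin`` that the true proportion exceeds the test
  proportion ``p_test``;
* the credence of device acceptability ``cr_A`` — the probability, given the
  study's evidence, that the true proportion of tolerable errors is at least
  ``mu_pmin``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

from scipy import optimize, special

if TYPE_CHECKING:  # pragma: no cover
    from .standards import StandardParams

__all__ = [
    "BetaProportion",
    "proportion_standard_error",
    "beta_parameters",
    "confidence_at",
    "solve_acceptance_threshold",
    "credence",
]

_BRACKET_EPS = 1e-12
_ROOT_XTOL = 1e-10  # below the 1e-9 threshold tolerance documented for the solve


@dataclass(frozen=True)
class BetaProportion:
    """Beta sampling distribution of an observed proportion.

    Attributes
    ----------
    alpha, beta : float
        Shape parameters, equal to ``(n-1)*mu_p`` and ``(n-1)*(1-mu_p)``.
    mu_p : float
        Mean of the distribution: the observed proportion of tolerable errors.
    sigma_p : float
        Standard deviation: the binomial standard error of the proportion.
    n : int
        Sample size of the experiment the proportion came from.
    """

    alpha: float
    beta: float
    mu_p: float
    sigma_p: float
    n: int

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


def _check_proportion(mu_p: float, n: int) -> None:
    if not 0.0 < mu_p < 1.0:
        raise ValueError(
            f"mu_p must lie strictly inside (0, 1); got {mu_p!r} "
            "(the sampling distribution of the proportion is degenerate at the boundary)"
        )
    if n < 2:
        raise ValueError(f"sample size must be >= 2; got {n}")


def proportion_standard_error(mu_p: float, n: int) -> float:
    """Binomial standard error of a sample proportion, sqrt(mu_p(1-mu_p)/n)."""
    _check_proportion(mu_p, n)
    return math.sqrt(mu_p * (1.0 - mu_p) / n)


def beta_parameters(mu_p: float, n: int) -> BetaProportion:
    """Moment-matched Beta sampling distribution of the proportion.

    Solves for (alpha, beta) so the Beta mean is ``mu_p`` and the Beta SD is
    the binomial standard error at sample size ``n``. The closed form reduces
    to ``alpha = (n-1)*mu_p``, ``beta = (n-1)*(1-mu_p)``.
    """
    sigma_p = proportion_standard_error(mu_p, n)
    # Full moment-matching closed form; algebraically (n-1)*mu_p / (n-1)*(1-mu_p).
    var = sigma_p * sigma_p
    alpha = (mu_p * mu_p - mu_p**3 - mu_p * var) / var
    beta = (mu_p - 1.0) * (mu_p * mu_p - mu_p + var) / var
    return BetaProportion(alpha=alpha, beta=beta, mu_p=mu_p, sigma_p=sigma_p, n=n)


def confidence_at(p: float, bp: BetaProportion) -> float:
    """Confidence that the true proportion of tolerable errors exceeds ``p``.

    This is the survival function of the Beta sampling distribution,
    ``1 - I_p(alpha, beta)`` with ``I`` the regularized incomplete beta
    function. It equals 1 at p=0, 0 at p=1, and is non-increasing in p.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1]; got {p!r}")
    return float(1.0 - special.betainc(bp.alpha, bp.beta, p))


def solve_acceptance_threshold(n: int, params: "StandardParams") -> float:
    """Observed proportion of tolerable errors required for acceptability.

    Solves ``C_pmin = 1 - I_{p_test}((n-1) m, (n-1)(1-m))`` for ``m`` on
    (p_test, 1). The left-hand side is monotone in ``m``, so a bracketed
    Brent solve is guaranteed to converge.

    Raises
    ------
    ValueError
        If the required confidence cannot be attained at this sample size
        (the threshold would have to exceed 1).
    """
    if n < 2:
        raise ValueError(f"sample size must be >= 2; got {n}")
    p_test, c_pmin = params.p_test, params.c_pmin

    def gap(m: float) -> float:
        return 1.0 - float(special.betainc((n - 1) * m, (n - 1) * (1.0 - m), p_test)) - c_pmin

    lo, hi = p_test + _BRACKET_EPS, 1.0 - _BRACKET_EPS
    if gap(hi) < 0.0:
        raise ValueError(
            f"required confidence {c_pmin} is unattainable at n={n}: "
            "even an observed proportion of ~1 does not reach it"
        )
    return float(optimize.brentq(gap, lo, hi, xtol=_ROOT_XTOL))


def credence(mu_p: float, mu_pmin: float, n: int) -> float:
    """Credence of device acceptability: Pr[P >= mu_pmin] under the Beta model.

    ``1 - I_{mu_pmin}((n-1) mu_p, (n-1)(1-mu_p))``. Degenerate observed
    proportions (exactly 0 or 1, possible with a zero error SD or a huge
    tolerable error) bypass the Beta model: the sampling distribution
    collapses to a point mass, so the credence is 1 if mu_p >= mu_pmin
    else 0.
    """
    if not 0.0 <= mu_pmin <= 1.0:
        raise ValueError(f"mu_pmin must lie in [0, 1]; got {mu_pmin!r}")
    if n < 2:
        raise ValueError(f"sample size must be >= 2; got {n}")
    if mu_p in (0.0, 1.0):
        return 1.0 if mu_p >= mu_pmin else 0.0
    if not 0.0 < mu_p < 1.0:
        raise ValueError(f"mu_p must lie in [0, 1]; got {mu_p!r}")
    return float(1.0 - special.betainc((n - 1) * mu_p, (n - 1) * (1.0 - mu_p), mu_pmin))
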