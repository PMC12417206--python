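"""Model/Results interface for the credence-of-acceptability computation.

`CredenceModel` bundles a study's error model with the acceptance parameters
of a standard; `fit()` runs the pipeline — solve the acceptance threshold at
the study's sample size, integrate the probability of tolerable error under
the reference BP distribution, and evaluate the credence — and returns a
`CredenceResults` carrying all intermediate quantities with a `summary()`
table, in the style of statsmodels.

Example
-------
>>> from bpcredence import CredenceModel
>>> res = CredenceModel.from_summary_stats(
...     n=85, bp_mean=131.4, bp_sd=21.35, err_mean=0.89, err_sd=5.65,
...     preset="iso81060_2_sbp",
... ).fit()
>>> round(res.cr_a, 4)
0.9682
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import core, errors
from .errors import ErrorModel, PairedSample
from .standards import StandardParams, preset as _load_preset

__all__ = ["CredenceModel", "CredenceResults"]


class CredenceModel:
    """Credence of device acceptability for one study and one pressure type.

    Parameters
    ----------
    error_model : ErrorModel
        The study's error-vs-BP model (summary statistics).
    params : StandardParams
        Acceptance constants and reference BP distribution.
    """

    def __init__(self, error_model: ErrorModel, params: StandardParams):
        self.error_model = error_model
        self.params = params

    @classmethod
    def from_summary_stats(
        cls,
        n: int,
        bp_mean: float,
        bp_sd: float,
        err_mean: float,
        err_sd: float,
        slope: float = 0.0,
        *,
        preset: str | StandardParams = "iso81060_2_sbp",
    ) -> "CredenceModel":
        """Build from the summary statistics studies typically report.

        ``slope`` defaults to 0 because the error-BP correlation is rarely
        reported; set it when a study provides one.
        """
        params = preset if isinstance(preset, StandardParams) else _load_preset(preset)[0]
        em = ErrorModel(n=n, x_bar=bp_mean, s_x=bp_sd, y_bar=err_mean, s_y=err_sd, beta1=slope)
        return cls(em, params)

    @classmethod
    def from_pairs(
        cls,
        pairs: PairedSample | Sequence[tuple[float, float]],
        *,
        preset: str | StandardParams = "iso81060_2_sbp",
    ) -> "CredenceModel":
        """Build by fitting the error model to raw paired (BP, error) data."""
        if not isinstance(pairs, PairedSample):
            pairs = PairedSample(tuple(map(tuple, pairs)))
        params = preset if isinstance(preset, StandardParams) else _load_preset(preset)[0]
        return cls(errors.fit_error_model(pairs), params)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        bp_col: str = "bp",
        error_col: str = "error",
        *,
        preset: str | StandardParams = "iso81060_2_sbp",
    ) -> "CredenceModel":
        """Build from a DataFrame of raw paired observations."""
        pairs = list(zip(data[bp_col].astype(float), data[error_col].astype(float)))
        return cls.from_pairs(pairs, preset=preset)

    def fit(self) -> "CredenceResults":
        """Run the full pipeline and return the results object."""
        em, params = self.error_model, self.params
        mu_pmin = core.solve_acceptance_threshold(em.n, params)
        mu_p = errors.probability_tolerable(em, params)
        cr_a = core.credence(mu_p, mu_pmin, em.n)
        if 0.0 < mu_p < 1.0:
            bp = core.beta_parameters(mu_p, em.n)
            sigma_p, alpha, beta = bp.sigma_p, bp.alpha, bp.beta
        else:  # degenerate point-mass limit
            sigma_p, alpha, beta = 0.0, np.nan, np.nan
        return CredenceResults(
            model=self,
            mu_pmin=mu_pmin,
            mu_p=mu_p,
            cr_a=cr_a,
            sigma_p=sigma_p,
            alpha=alpha,
            beta=beta,
        )


@dataclass(frozen=True)
class CredenceResults:
    """Fitted credence pipeline outputs for one study/pressure type.

    Attributes
    ----------
    mu_pmin : float
        Acceptance threshold: observed proportion of tolerable errors a
        compliant device must reach at this sample size.
    mu_p : float
        Probability of a tolerable error under the reference BP distribution.
    cr_a : float
        Credence of device acceptability, Pr[P >= mu_pmin].
    sigma_p : float
        Standard error of the proportion at the study's sample size.
    alpha, beta : float
        Shape parameters of the Beta sampling distribution of the proportion
        (NaN in the degenerate mu_p ∈ {0, 1} limit).
    """

    model: CredenceModel
    mu_pmin: float
    mu_p: float
    cr_a: float
    sigma_p: float
    alpha: float
    beta: float

    def confidence_curve(self, p: np.ndarray | float) -> np.ndarray | float:
        """Confidence Pr[P >= p] as a function of the test proportion p."""
        n, mu_p = self.model.error_model.n, self.mu_p
        bp = core.beta_parameters(mu_p, n)
        p_arr = np.atleast_1d(np.asarray(p, dtype=float))
        out = np.array([core.confidence_at(v, bp) for v in p_arr])
        return out if np.ndim(p) else float(out[0])

    def to_dict(self) -> dict[str, float]:
        return {
            "mu_pmin": self.mu_pmin,
            "mu_p": self.mu_p,
            "cr_a": self.cr_a,
            "sigma_p": self.sigma_p,
            "alpha": self.alpha,
            "beta": self.beta,
        }

    def plot_joint(self, path):
        """Joint BP-error density panel; writes a figure to ``path``."""
        from .plots import plot_joint_density

        return plot_joint_density(self.model.error_model, self.model.params, path)

    def plot_confidence(self, path):
        """Confidence-curve panel; writes a figure to ``path``."""
        from .plots import plot_confidence_curve

        return plot_confidence_curve(self, path)

    def summary(self) -> str:
        """Human-readable summary table, percent-formatted where conventional."""
        em, params = self.model.error_model, self.model.params
        lines = [
            "Credence of Device Acceptability",
            "=" * 52,
            f"{'Sample size (n)':<36}{em.n:>16d}",
            f"{'Sampled BP mean / SD (mmHg)':<36}{em.x_bar:>8.2f}{em.s_x:>8.2f}",
            f"{'Error mean / SD (mmHg)':<36}{em.y_bar:>8.2f}{em.s_y:>8.2f}",
            f"{'Error-BP slope':<36}{em.beta1:>16.4f}",
            f"{'Reference BP (mmHg)':<36}{params.ref_mean:>8.1f}{params.ref_sd:>8.1f}",
            f"{'Tolerable error Δ (mmHg)':<36}{params.delta:>16.1f}",
            "-" * 52,
            f"{'Acceptance threshold μ_pmin':<36}{format_percent(self.mu_pmin):>16}",
            f"{'P(tolerable error) μ_p':<36}{format_percent(self.mu_p):>16}",
            f"{'Credence cr_A':<36}{format_percent(self.cr_a):>16}",
            f"{'SE of proportion σ_p':<36}{self.sigma_p:>16.4f}",
            "=" * 52,
        ]
        return "\n".join(lines)


def format_percent(value: float, decimals: int = 2) -> str:
    """Percent formatting with the '<0.1%' convention for tiny values."""
    if value < 0.001:
        return "<0.1%"
    return f"{100.0 * value:.{decimals}f}%"
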