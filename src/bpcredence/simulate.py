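"""Seeded synthetic validation experiments and Monte-Carlo twins.

The generator draws paired (BP, error) data from exactly the model the
analytic pipeline assumes — BPs normal, errors normal about a line in BP — so
agreement between analytic quantities and their simulated counterparts tests
the numerics (quadrature, root solves, Beta tail probabilities), not model
adequacy. All randomness flows through numpy Generators spawned
deterministically from the design seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core, errors
from .errors import ErrorModel, PairedSample
from .standards import StandardParams

__all__ = [
    "SimulationDesign",
    "generate_paired_sample",
    "simulate_proportion_distribution",
    "credence_repeatability",
    "RepeatabilitySummary",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Design of a simulated device validation experiment.

    ``error_intercept`` is the mean error at the BP mean; ``error_slope``
    tilts the error in BP; ``error_sd`` is the SD about the line (all mmHg
    except the dimensionless slope).
    """

    n: int
    bp_mean: float
    bp_sd: float
    error_intercept: float
    error_slope: float
    error_sd: float
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"n must be >= 3; got {self.n}")
        if self.bp_sd <= 0:
            raise ValueError(f"bp_sd must be positive; got {self.bp_sd!r}")
        if self.error_sd < 0:
            raise ValueError(f"error_sd must be >= 0; got {self.error_sd!r}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1; got {self.n_replicates}")

    def rng(self, replicate: int = 0) -> np.random.Generator:
        """Deterministic per-replicate generator from the master seed.

        Each replicate gets the stream of the ``replicate``-th spawned child
        of the master seed sequence, addressed directly by spawn key so
        replicates can be generated independently and in any order.
        """
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(replicate,)))


def _draw(design: SimulationDesign, rng: np.random.Generator,
          bp_mean: float | None = None, bp_sd: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    mu = design.bp_mean if bp_mean is None else bp_mean
    sd = design.bp_sd if bp_sd is None else bp_sd
    x = rng.normal(mu, sd, size=design.n)
    y = design.error_intercept + design.error_slope * (x - mu) + rng.normal(0.0, design.error_sd, size=design.n)
    return x, y


def generate_paired_sample(design: SimulationDesign, replicate: int = 0) -> PairedSample:
    """One synthetic paired (BP, error) sample, reproducible from the seed."""
    x, y = _draw(design, design.rng(replicate))
    return PairedSample(tuple(zip(x.tolist(), y.tolist())))


def simulate_proportion_distribution(
    design: SimulationDesign, params: StandardParams
) -> np.ndarray:
    """Per-replicate observed proportions of tolerable errors.

    BPs are drawn from the REFERENCE distribution in ``params`` (this emulates
    a standards-compliant experimental design); each replicate's proportion is
    the fraction of errors with |error| < Δ.
    """
    out = np.empty(design.n_replicates)
    for r in range(design.n_replicates):
        _, y = _draw(design, design.rng(r), bp_mean=params.ref_mean, bp_sd=params.ref_sd)
        out[r] = np.mean(np.abs(y) < params.delta)
    return out


@dataclass(frozen=True)
class RepeatabilitySummary:
    """Distribution of the credence metric over replicated experiments."""

    mean: float
    sd: float  # NaN when a single replicate gives no spread estimate
    quantiles: dict[float, float]
    credences: np.ndarray

    def __str__(self) -> str:
        qs = ", ".join(f"q{int(100 * q)}={v:.4f}" for q, v in self.quantiles.items())
        sd = "n/a" if np.isnan(self.sd) else f"{self.sd:.4f}"
        return f"cr_A over {len(self.credences)} replicates: mean={self.mean:.4f}, sd={sd}, {qs}"


def credence_repeatability(
    design: SimulationDesign,
    params: StandardParams,
    quantiles: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> RepeatabilitySummary:
    """Full pipeline (fit -> mu_p -> cr_A) on each replicate; summarise cr_A.

    Exposes how much the credence itself varies over repeated experiments of
    the same design — small studies can produce very different credences from
    run to run even when the device is unchanged.
    """
    mu_pmin = core.solve_acceptance_threshold(design.n, params)
    crs = np.empty(design.n_replicates)
    for r in range(design.n_replicates):
        sample = generate_paired_sample(design, replicate=r)
        em = errors.fit_error_model(sample)
        mu_p = errors.probability_tolerable(em, params)
        crs[r] = core.credence(mu_p, mu_pmin, em.n)
    sd = float(np.std(crs, ddof=1)) if design.n_replicates > 1 else float("nan")
    return RepeatabilitySummary(
        mean=float(np.mean(crs)),
        sd=sd,
        quantiles={q: float(np.quantile(crs, q)) for q in quantiles},
        credences=crs,
    )
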