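"""Standard acceptance parameters, BP-distribution compliance, and the SD limit.

Presets ship as JSON data files so that variants (other standards, other
reference populations) can be defined without code changes. The two built-in
presets mirror the ISO 81060-2 auscultatory-reference design: confidence
``C_pmin = 0.95`` at test proportion ``p_test = 0.78``, tolerable error
``Δ = 10`` mmHg, headline proportion ``p_hat = 0.85``, and reference BP
distributions Normal(130, 20²) for systolic and Normal(80, 13²) for diastolic
pressure — chosen so the standard's tail requirements on the sampled BP range
are met by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

from scipy import optimize
from scipy.stats import norm

__all__ = [
    "StandardParams",
    "TailRequirement",
    "RequirementCheck",
    "ComplianceReport",
    "preset",
    "load_preset",
    "available_presets",
    "check_distribution",
    "iso_sd_limit",
]


@dataclass(frozen=True)
class StandardParams:
    """Acceptance-criteria constants and reference BP distribution.

    Attributes
    ----------
    c_pmin : float
        Required confidence that the true proportion of tolerable errors
        exceeds ``p_test``.
    p_test : float
        Test proportion of tolerable errors.
    delta : float
        Tolerable error Δ, mmHg.
    p_hat : float
        The standard's headline proportion (0.85); used only by the
        mean-error-dependent SD limit.
    ref_mean, ref_sd : float
        Mean and SD of the reference blood pressure distribution, mmHg.
    """

    c_pmin: float
    p_test: float
    delta: float
    p_hat: float
    ref_mean: float
    ref_sd: float

    def __post_init__(self) -> None:
        for name in ("c_pmin", "p_test", "p_hat"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1); got {v!r}")
        if self.delta <= 0:
            raise ValueError(f"delta must be positive; got {self.delta!r}")
        if self.ref_sd <= 0:
            raise ValueError(f"ref_sd must be positive; got {self.ref_sd!r}")


@dataclass(frozen=True)
class TailRequirement:
    """Minimum mass of the sampled BP distribution beyond a threshold."""

    threshold: float
    side: Literal["below", "above"]
    min_fraction: float

    def __post_init__(self) -> None:
        if self.side not in ("below", "above"):
            raise ValueError(f"side must be 'below' or 'above'; got {self.side!r}")
        if not 0.0 < self.min_fraction < 1.0:
            raise ValueError(f"min_fraction must lie in (0, 1); got {self.min_fraction!r}")


@dataclass(frozen=True)
class RequirementCheck:
    requirement: TailRequirement
    achieved_fraction: float
    passes: bool


@dataclass(frozen=True)
class ComplianceReport:
    """Pass/fail of a BP distribution against a set of tail requirements."""

    checks: tuple[RequirementCheck, ...]

    @property
    def overall(self) -> bool:
        return all(c.passes for c in self.checks)


def _parse_preset(payload: dict) -> tuple[StandardParams, list[TailRequirement]]:
    try:
        params = StandardParams(**payload["params"])
        reqs = [TailRequirement(**r) for r in payload["tail_requirements"]]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed preset file: {exc}") from exc
    return params, reqs


def available_presets() -> list[str]:
    """Names of the presets shipped with the package."""
    pkg = resources.files("bpcredence") / "presets"
    return sorted(p.name.removesuffix(".json") for p in pkg.iterdir() if p.name.endswith(".json"))


def preset(name: str) -> tuple[StandardParams, list[TailRequirement]]:
    """Load a shipped preset by name (e.g. ``iso81060_2_sbp``)."""
    ref = resources.files("bpcredence") / "presets" / f"{name}.json"
    if not ref.is_file():
        raise KeyError(f"unknown preset {name!r}; available: {available_presets()}")
    return _parse_preset(json.loads(ref.read_text()))


def load_preset(path: str | Path) -> tuple[StandardParams, list[TailRequirement]]:
    """Load a user-supplied preset JSON file (same schema as the shipped ones)."""
    return _parse_preset(json.loads(Path(path).read_text()))


def check_distribution(
    ref_mean: float, ref_sd: float, requirements: Sequence[TailRequirement]
) -> ComplianceReport:
    """Check a normal BP distribution against tail requirements.

    Achieved fractions come from the normal CDF; a requirement passes when
    the achieved fraction is at least the required one (the standards say
    "at least", so the comparison is weak).
    """
    if ref_sd <= 0:
        raise ValueError(f"ref_sd must be positive; got {ref_sd!r}")
    checks = []
    for req in requirements:
        below = float(norm.cdf(req.threshold, loc=ref_mean, scale=ref_sd))
        achieved = below if req.side == "below" else 1.0 - below
        checks.append(RequirementCheck(req, achieved, achieved >= req.min_fraction))
    return ComplianceReport(tuple(checks))


def iso_sd_limit(mean_error: float, params: StandardParams) -> float:
    """Largest error SD admissible at a given mean error.

    Returns the largest σ with ``P(|Normal(mean_error, σ²)| <= Δ) >= p_hat``.
    Coverage is strictly decreasing in σ, so this is a monotone root solve;
    for mean 0 it reduces to ``Δ / Φ⁻¹((1 + p_hat) / 2)``.

    Raises
    ------
    ValueError
        When no positive σ achieves the coverage (|mean_error| too close
        to Δ: even a point mass at the mean would fail).
    """
    delta, p_hat = params.delta, params.p_hat
    if abs(mean_error) >= delta:
        raise ValueError(
            f"|mean_error| = {abs(mean_error)} >= delta = {delta}: coverage {p_hat} unattainable"
        )

    def coverage(sd: float) -> float:
        return float(norm.cdf(delta, mean_error, sd) - norm.cdf(-delta, mean_error, sd))

    # As sd -> 0 coverage -> 1 (mean strictly inside the band); find where it crosses p_hat.
    lo, hi = 1e-12, delta
    while coverage(hi) > p_hat:
        hi *= 2.0
        if hi > 1e6 * delta:  # pragma: no cover - p_hat < 1 guarantees a crossing
            raise RuntimeError("failed to bracket the SD limit")
    if coverage(lo) < p_hat:
        raise ValueError(
            f"coverage {p_hat} unattainable at mean error {mean_error} with delta {delta}"
        )
    return float(optimize.brentq(lambda s: coverage(s) - p_hat, lo, hi, xtol=1e-10))
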