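"""Diagnostic plots: joint BP-error density and the confidence curve.

The joint-density panel shows where (BP, error) pairs are likely under the
study's fitted error model and the reference BP distribution, with the
intolerable-error bands, the reference BP bell curve, and the mean and
68%/95% individual-prediction bands. The confidence panel shows how the
confidence that the true proportion of tolerable errors exceeds p falls with
p, the unacceptable region bounded by the acceptance threshold and required
confidence, the credence point, the observed proportion, and the Beta
sampling density of the proportion.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from . import core
from .errors import ErrorModel, prediction_se
from .standards import StandardParams

if TYPE_CHECKING:  # pragma: no cover
    from .batch import StudyRecord
    from .model import CredenceResults

__all__ = ["plot_joint_density", "plot_confidence_curve", "plot_study", "plot_threshold_curve"]


def plot_joint_density(
    model: ErrorModel, params: StandardParams, path: str | Path, n_grid: int = 200
) -> Path:
    """Contours of the joint density with prediction bands; writes ``path``."""
    xs = np.linspace(params.ref_mean - 3.5 * params.ref_sd, params.ref_mean + 3.5 * params.ref_sd, n_grid)
    y_span = max(3.5 * model.s_y + abs(model.y_bar), 2.0 * params.delta)
    ys = np.linspace(-y_span, y_span, n_grid)
    se = np.array([prediction_se(model, x) for x in xs])
    yhat = np.array([model.predict(x) for x in xs])
    fx = norm.pdf(xs, params.ref_mean, params.ref_sd)
    joint = fx[None, :] * norm.pdf(ys[:, None], loc=yhat[None, :], scale=se[None, :])

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.contour(xs, ys, joint, levels=8, cmap="viridis")
    for lo, hi in ((params.delta, y_span), (-y_span, -params.delta)):
        ax.axhspan(lo, hi, color="0.85", zorder=0)
    # reference BP density, arbitrary vertical scaling anchored at the bottom
    ax.plot(xs, -y_span + fx / fx.max() * 0.5 * y_span, "k-", lw=1.2, label="reference BP density")
    ax.plot(xs, yhat, "k--", lw=1.0, label="mean prediction")
    for z, lab in ((1.0, "68% individual prediction"), (1.96, "95% individual prediction")):
        ax.plot(xs, yhat + z * se, "--", color="0.4", lw=0.8, label=lab)
        ax.plot(xs, yhat - z * se, "--", color="0.4", lw=0.8)
    ax.set_xlabel("Blood pressure (mmHg)")
    ax.set_ylabel("Measurement error (mmHg)")
    ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_confidence_curve(results: "CredenceResults", path: str | Path) -> Path:
    """Confidence vs test proportion with the unacceptable region; writes ``path``."""
    params = results.model.params
    n = results.model.error_model.n
    ps = np.linspace(0.0, 1.0, 801)
    conf = results.confidence_curve(ps)

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.plot(ps, conf, "b-", lw=1.5, label="confidence Pr[P ≥ p]")
    # unacceptable region: right of mu_pmin, above C_pmin
    ax.fill_betweenx([params.c_pmin, 1.0], results.mu_pmin, 1.0, color="0.8", zorder=0,
                     label="unacceptable region")
    ax.plot([results.mu_pmin], [results.cr_a], "ko", ms=6, label=f"credence = {results.cr_a:.4f}")
    ax.annotate("", xy=(results.mu_p, 0.0), xytext=(results.mu_p, 0.08),
                arrowprops=dict(arrowstyle="-|>", color="k"))
    bp = core.beta_parameters(results.mu_p, n)
    dens = beta_dist.pdf(ps, bp.alpha, bp.beta)
    if np.isfinite(dens).any() and np.nanmax(dens) > 0:
        ax.plot(ps, 0.9 * dens / np.nanmax(dens), "r--", lw=1.0, label="sampling density of P")
    ax.set_xlabel("Proportion of tolerable errors, p")
    ax.set_ylabel("Confidence")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left", fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_study(
    record: "StudyRecord",
    params: StandardParams,
    pressure_type: str,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Both diagnostic plots for one study/pressure type; returns the two paths."""
    from .model import CredenceModel  # local import avoids a cycle

    block = getattr(record, pressure_type)
    results = CredenceModel(
        ErrorModel(n=record.n, x_bar=block.bp_mean, s_x=block.bp_sd,
                   y_bar=block.err_mean, s_y=block.err_sd, beta1=block.slope),
        params,
    ).fit()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{record.study_id}_{pressure_type}"
    left = plot_joint_density(results.model.error_model, params, out_dir / f"{stem}_joint.png")
    right = plot_confidence_curve(results, out_dir / f"{stem}_confidence.png")
    return left, right


def plot_threshold_curve(
    n_range: tuple[int, int], params: StandardParams, path: str | Path, n_points: int = 60
) -> Path:
    """Acceptance threshold vs sample size on a log-spaced grid; writes ``path``."""
    n_min, n_max = n_range
    if not 3 <= n_min < n_max <= 10**6:
        raise ValueError(f"n_range must satisfy 3 <= n_min < n_max <= 1e6; got {n_range}")
    ns = np.unique(np.geomspace(n_min, n_max, n_points).astype(int))
    thresholds = [core.solve_acceptance_threshold(int(n), params) for n in ns]

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ns, thresholds, "b-")
    ax.axhline(params.p_test, color="0.5", ls="--")
    ax.annotate(f"p_test = {params.p_test}", xy=(ns[-1], params.p_test),
                xytext=(-5, 5), textcoords="offset points", ha="right", fontsize=8)
    ax.set_xscale("log")
    ax.set_xlabel("Sample size n")
    ax.set_ylabel("Acceptance threshold μ_pmin")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
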