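"""Bootstrap inference and model validation for fitted release curves.

Nonparametric case resampling of (time, release) pairs quantifies the
sampling variability of the fitted parameters (mean, SD, and a two-sided
proportion-based p-value against zero per parameter).  An extra-sum-of-
squares F-test compares the nonlinear release model against a straight line,
and a lag-1 Durbin-Watson statistic screens the residuals for the
independence the bootstrap assumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import f as f_dist
from statsmodels.stats.stattools import durbin_watson

from .estimation import (
    FULL,
    SINGLE_EXPONENTIAL,
    FitResult,
    ReleaseCurve,
    _fit_theta,
)
from .kinetics import thermal_energy

__all__ = [
    "ParameterSummary",
    "BootstrapSummary",
    "ModelComparison",
    "AutocorrelationResult",
    "bootstrap_parameters",
    "f_test_vs_linear",
    "autocorrelation_check",
]

logger = logging.getLogger(__name__)

_MIN_POINTS = 6  # small-sample cases are excluded from bootstrap analysis


@dataclass(frozen=True)
class ParameterSummary:
    """Bootstrap mean, standard deviation and p-value for one parameter."""

    mean: float
    sd: float
    p_value: float


@dataclass(frozen=True)
class BootstrapSummary:
    """Per-parameter bootstrap distributions for one fitted curve.

    k_on is reported alongside (k_S, k_off, delta_G) for completeness even
    though only three of the four are independent.  ``valid`` is False when
    half or more of the replicates failed to converge.
    """

    k_s: ParameterSummary
    k_off: ParameterSummary | None
    k_on: ParameterSummary | None
    delta_g: ParameterSummary | None
    n_replicates: int
    n_failed: int
    seed: int
    method: str
    valid: bool
    durbin_watson: float
    residuals_independent: bool


class AutocorrelationResult(NamedTuple):
    statistic: float
    independent: bool


@dataclass(frozen=True)
class ModelComparison:
    """Extra-sum-of-squares F-test of the release model vs a straight line."""

    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    sse_linear: float
    sse_nonlinear: float


def _p_two_sided(samples: np.ndarray) -> float:
    """Two-sided bootstrap proportion test of H0: parameter = 0.

    Continuity-corrected (+1) so the p-value is never exactly zero; with no
    exceedances it reports 2/(B+1), i.e. "< 1/B".
    """
    b = samples.size
    n_le = int(np.sum(samples <= 0.0))
    n_ge = int(np.sum(samples >= 0.0))
    return min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (b + 1))


def _summary(samples: np.ndarray) -> ParameterSummary:
    return ParameterSummary(
        mean=float(np.mean(samples)),
        sd=float(np.std(samples, ddof=1)) if samples.size > 1 else 0.0,
        p_value=_p_two_sided(samples),
    )


def bootstrap_parameters(
    curve: ReleaseCurve,
    fit: FitResult,
    n_replicates: int = 1000,
    seed: int = 0,
    method: str = "cases",
) -> BootstrapSummary:
    """Bootstrap the fitted parameters of one release curve.

    ``method="cases"`` resamples (t, y) pairs with replacement — the natural
    scheme when observations are independent; ``method="residuals"`` keeps
    the design fixed and resamples fitted residuals instead.  Each replicate
    is refit starting from the original fit.  Non-converged replicates are
    dropped and counted, never imputed.  The same seed gives a bitwise-
    identical summary.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    if method not in ("cases", "residuals"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    if curve.n < _MIN_POINTS:
        raise ValueError(
            f"sample size {curve.n} is too small for bootstrap analysis "
            f"(at least {_MIN_POINTS} points required); small-sample cases "
            "are excluded rather than summarised"
        )
    if n_replicates < 2:
        raise ValueError("n_replicates must be at least 2")

    t, y = curve.times, curve.released
    kbt = thermal_energy(fit.temperature)
    if fit.variant == SINGLE_EXPONENTIAL:
        theta_hat = np.array([math.log(fit.k_s)])
    else:
        theta_hat = np.array(
            [fit.delta_g, math.log(fit.k_s), math.log(max(fit.k_off, 1e-10))]
        )
    fitted = y + fit.residuals  # model values at the original design points

    rng = np.random.default_rng(seed)
    thetas: list[np.ndarray] = []
    n_failed = 0
    for _ in range(n_replicates):
        if method == "cases":
            idx = np.sort(rng.integers(0, curve.n, curve.n))
            tb, yb = t[idx], y[idx]
        else:
            resampled = rng.choice(fit.residuals, size=curve.n, replace=True)
            tb, yb = t, np.clip(fitted - resampled, 0.0, None)
        theta, _, ok, _ = _fit_theta(
            tb, yb, theta_hat, fit.variant, kbt, max_starts=2
        )
        if ok:
            thetas.append(theta)
        else:
            n_failed += 1

    n_ok = len(thetas)
    valid = n_failed < n_replicates / 2
    if not valid:
        logger.warning(
            "bootstrap summary invalid: %d of %d replicates failed to converge",
            n_failed,
            n_replicates,
        )
    if n_ok == 0:
        raise RuntimeError("no bootstrap replicate converged")
    arr = np.vstack(thetas)

    dw, independent = autocorrelation_check(fit.residuals)

    if fit.variant == SINGLE_EXPONENTIAL:
        k_s_samples = np.exp(arr[:, 0])
        return BootstrapSummary(
            k_s=_summary(k_s_samples),
            k_off=None,
            k_on=None,
            delta_g=None,
            n_replicates=n_replicates,
            n_failed=n_failed,
            seed=seed,
            method=method,
            valid=valid,
            durbin_watson=dw,
            residuals_independent=independent,
        )

    dg_samples = arr[:, 0]
    k_s_samples = np.exp(arr[:, 1])
    k_off_samples = np.exp(arr[:, 2])
    k_on_samples = k_off_samples * np.exp(-dg_samples / kbt)
    return BootstrapSummary(
        k_s=_summary(k_s_samples),
        k_off=_summary(k_off_samples),
        k_on=_summary(k_on_samples),
        delta_g=_summary(dg_samples),
        n_replicates=n_replicates,
        n_failed=n_failed,
        seed=seed,
        method=method,
        valid=valid,
        durbin_watson=dw,
        residuals_independent=independent,
    )


def f_test_vs_linear(curve: ReleaseCurve, fit: FitResult) -> ModelComparison:
    """Compare the nonlinear release model against a straight line y = a + b t.

    F = ((SSE_linear - SSE_nonlinear)/1) / (SSE_nonlinear/(n-3)); small
    p-values mean the release model explains the curve significantly better
    than a trend line.  A perfect nonlinear fit yields an infinite F.
    """
    if not fit.converged:
        raise ValueError("F-test requires a converged fit")
    n = curve.n
    if n < 5:
        raise ValueError(f"F-test needs at least 5 points, got {n}")
    t, y = curve.times, curve.released
    coeffs = np.polyfit(t, y, 1)
    sse_linear = float(np.sum((np.polyval(coeffs, t) - y) ** 2))
    sse_nl = fit.sse
    df_num, df_den = 1, n - 3
    if sse_nl <= 0.0:
        logger.info("perfect nonlinear fit: F-statistic is infinite")
        return ModelComparison(math.inf, 0.0, df_num, df_den, sse_linear, sse_nl)
    f_stat = ((sse_linear - sse_nl) / df_num) / (sse_nl / df_den)
    p = float(f_dist.sf(f_stat, df_num, df_den)) if f_stat > 0 else 1.0
    return ModelComparison(float(f_stat), p, df_num, df_den, sse_linear, sse_nl)


def autocorrelation_check(residuals) -> AutocorrelationResult:
    """Lag-1 Durbin-Watson screen for residual independence.

    Values near 2 indicate no lag-1 autocorrelation; the conservative
    acceptance band is [1, 3].  Advisory only — it flags, not proves,
    dependence.  Degenerate (zero-variance) residuals are reported as
    dependent with a warning.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < _MIN_POINTS:
        raise ValueError(f"need at least {_MIN_POINTS} residuals, got {e.size}")
    if float(np.sum(e * e)) == 0.0:
        logger.warning("zero-variance residuals: autocorrelation undefined")
        return AutocorrelationResult(0.0, False)
    dw = float(durbin_watson(e))
    return AutocorrelationResult(dw, 1.0 <= dw <= 3.0)
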