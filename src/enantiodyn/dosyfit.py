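"""Stejskal-Tanner fitting of DOSY peak attenuations and enantiodiscrimination
statistics.

The pulsed-field-gradient signal decays as I(g) = I0 * exp(-b(g) * D).  For
the convection-compensating Oneshot sequence with unbalancing factor alpha and
gradient-pair spacing tau the decay constant is

    b(g) = gamma^2 * delta^2 * g^2 * [Delta + delta*(alpha^2 - 2)/6
                                      + tau*(alpha^2 - 1)/2]

which reduces to the classical gamma^2 delta^2 g^2 (Delta - delta/3) at
alpha = 0, tau = 0 (the default when a sequence's alpha is not known).

Enantiodiscrimination statistics follow the convention
Delta_D = D_R - D_S (R-analyte minus S-analyte) with errors propagated in
quadrature, and the between-agent selectivity ratio
|Delta_D(S-agent)| / |Delta_D(R-agent)| with first-order error propagation.
Comparisons against printed table values use round-half-even at the printed
number of decimals (see :func:`round_printed`); full precision is retained
internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from enantiodyn.core_io import AttenuationSeries, GradientSchedule

__all__ = [
    "FitResult",
    "b_factor",
    "fit_attenuation",
    "delta_D",
    "discrimination_ratio",
    "round_printed",
]


@dataclass
class FitResult:
    """Fitted diffusion coefficient for one peak; D, D_err in 1e-10 m^2/s."""

    D: float
    D_err: float
    I0: float
    residual_norm: float
    n_points: int

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("fitted D must be positive")
        if self.D_err < 0:
            raise ValueError("D_err must be non-negative")


def b_factor(schedule: GradientSchedule, g) -> np.ndarray | float:
    """Decay constant b (s/m^2) of the Oneshot-modified Stejskal-Tanner
    equation at gradient strength(s) ``g`` (T/m)."""
    a2 = schedule.alpha**2
    timing = (
        schedule.big_delta
        + schedule.little_delta * (a2 - 2.0) / 6.0
        + schedule.tau * (a2 - 1.0) / 2.0
    )
    return schedule.gamma**2 * schedule.little_delta**2 * np.asarray(g) ** 2 * timing


def fit_attenuation(series: AttenuationSeries, weighted: bool = False) -> FitResult:
    """Nonlinear least squares of I = I0 * exp(-b(g) * D) over (I0, D).

    Initial guesses come from the log-linear regression of ln I on b; D_err is
    the square root of the fit-covariance diagonal.  ``weighted`` applies
    inverse-intensity weights (Poisson-like); the default is unweighted.
    Raises on fewer than 3 increments, on non-convergence, and when the data
    carry no decay (fitted D at or below zero).
    """
    g = series.schedule.g_values
    intensities = series.intensities
    if len(g) < 3:
        raise ValueError("need at least 3 gradient increments")
    b = np.asarray(b_factor(series.schedule, g), dtype=float)

    # log-linear initialization: ln I = ln I0 - b * D
    slope, intercept = np.polyfit(b, np.log(intensities), 1)
    d0 = max(-slope, 1e-14)
    i0 = float(np.exp(intercept))

    def model(bb, log_i0, d_si):
        return np.exp(log_i0) * np.exp(-bb * d_si)

    sigma = np.sqrt(intensities) if weighted else None
    try:
        with warnings.catch_warnings():
            # a numerically perfect (noiseless) fit has no estimable covariance
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, pcov = curve_fit(
                model,
                b,
                intensities,
                p0=[np.log(i0), d0],
                sigma=sigma,
                absolute_sigma=False,
                maxfev=10000,
            )
    except RuntimeError as exc:
        raise RuntimeError(f"attenuation fit did not converge: {exc}") from exc
    d_si = popt[1]
    if d_si <= 0:
        raise ValueError("fitted D <= 0: data inconsistent with diffusive decay")
    if float(b.max()) * d_si < 1e-3:
        raise ValueError(
            "no measurable decay over the gradient range (relative attenuation "
            f"{float(b.max()) * d_si:.2e}); D is not determined by these data"
        )
    resid = intensities - model(b, *popt)
    if np.all(np.isfinite(pcov)):
        d_err_si = float(np.sqrt(pcov[1, 1]))
    elif np.linalg.norm(resid) < 1e-9 * intensities[0]:
        d_err_si = 0.0  # exact inversion of noiseless data
    else:
        d_err_si = float("inf")
    return FitResult(
        D=float(d_si / 1e-10),
        D_err=d_err_si / 1e-10,
        I0=float(np.exp(popt[0])),
        residual_norm=float(np.linalg.norm(resid)),
        n_points=len(g),
    )


def _d_and_err(x) -> tuple[float, float]:
    if isinstance(x, FitResult):
        return x.D, x.D_err
    d, e = x
    return float(d), float(e)


def delta_D(d_r, d_s) -> tuple[float, float]:
    """Enantiodifference Delta_D = D_R - D_S with quadrature error.

    Arguments are FitResults or (D, err) tuples in the same units."""
    dr, er = _d_and_err(d_r)
    ds, es = _d_and_err(d_s)
    return dr - ds, float(np.hypot(er, es))


def discrimination_ratio(dd_s: tuple[float, float], dd_r: tuple[float, float]) -> tuple[float, float]:
    """Between-agent selectivity: ratio = |Delta_D(S-agent) / Delta_D(R-agent)|
    with first-order propagated error
    ratio * sqrt((err_s/Delta_D_s)^2 + (err_r/Delta_D_r)^2)."""
    (vs, es), (vr, er) = dd_s, dd_r
    if vr == 0:
        raise ZeroDivisionError("reference enantiodifference is zero")
    ratio = abs(vs / vr)
    if vs == 0:
        return 0.0, abs(es / vr)
    err = ratio * float(np.sqrt((es / vs) ** 2 + (er / vr) ** 2))
    return ratio, err


def round_printed(value: float, decimals: int) -> float:
    """Round-half-even at the printed number of decimals (for comparison with
    published table values; raw precision is kept everywhere else)."""
    return round(value, decimals)
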