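"""Degradation-rate estimation from inhibitor decay experiments.

Protein degradation (delta_P) comes from a translation-block
(cycloheximide) trace, where P decays as a single exponential.  mRNA
degradation (delta_M) comes from a transcription-block (actinomycin D)
trace, where P follows the double-exponential solution of
dP/dt = alpha*M - delta_P*P with M = M0*exp(-delta_M*t).  Both are fitted
by nonlinear least squares; downstream stages treat the point rates as
known parameters, so only point estimates and standard errors are needed.
The translation rate alpha is not identifiable from decay data and is
fixed to 1 throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import CellTrace, DataError

__all__ = ["DecayFit", "fit_delta_p", "fit_delta_m", "average_traces"]

# below this rate (per hour) a fitted decay is reported as degenerate
_DEGENERATE_RATE = 1e-6
# relative rate gap below which the two exponents are not separately
# identifiable and the confluent (t * exp) model is used
_EQUAL_RATE_RTOL = 1e-3


@dataclass
class DecayFit:
    """Result of a decay-rate fit (rates per hour)."""

    rate: float
    rate_se: float
    model: str  # 'single-exponential' | 'double-exponential' | 'degenerate-double-exponential'
    residual_sd: float
    degenerate: bool = False
    params: dict | None = None


def average_traces(traces: list[CellTrace]) -> CellTrace:
    """Average several decay traces over their common time grid.

    Population-average decay curves are much smoother than single cells and
    are the default input to the rate fits.
    """
    if not traces:
        raise DataError("no traces to average")
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise DataError("traces must share a common time grid to be averaged")
    values = np.mean([tr.values for tr in traces], axis=0)
    return CellTrace(
        cell_id="average",
        reporter=traces[0].reporter,
        times=t0,
        values=values,
        treatment=traces[0].treatment,
    )


def fit_delta_p(trace: CellTrace) -> DecayFit:
    """Fit P(t) = P0 * exp(-delta_P * t) to a translation-block trace."""
    t, y = trace.times, trace.values
    if np.any(y <= 0):
        raise DataError("translation-block trace must have positive values")
    # log-linear regression gives the starting values
    slope, intercept = np.polyfit(t, np.log(y), 1)
    rate0 = max(-slope, _DEGENERATE_RATE)
    p00 = float(np.exp(intercept))

    def model(tt, p0, rate):
        return p0 * np.exp(-rate * tt)

    popt, pcov = curve_fit(
        model, t, y, p0=[p00, rate0], bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=20000,
    )
    resid = y - model(t, *popt)
    dof = max(len(y) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    rate = float(popt[1])
    rate_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
    return DecayFit(
        rate=rate,
        rate_se=rate_se,
        model="single-exponential",
        residual_sd=residual_sd,
        degenerate=rate < _DEGENERATE_RATE * 10,
        params={"P0": float(popt[0])},
    )


def _double_exp(t, c1, c2, dm, dp):
    return c1 * np.exp(-dm * t) + c2 * np.exp(-dp * t)


def _confluent(t, a, b, d):
    return (a + b * t) * np.exp(-d * t)


def fit_delta_m(trace: CellTrace, delta_p: float) -> DecayFit:
    """Fit the transcription-block protein decay and return delta_M.

    The model is P(t) = c1*exp(-delta_M*t) + c2*exp(-delta_P*t) with
    delta_P supplied from :func:`fit_delta_p`; c1, c2 are nuisance
    amplitudes.  When the fitted exponent approaches delta_P the confluent
    model (a + b*t)*exp(-d*t) is refitted and the result flagged as
    degenerate, since the two rates are then not separately identifiable.
    The returned rate is always the exponent distinct from delta_P.
    """
    t, y = trace.times, trace.values
    if not delta_p > 0:
        raise DataError("delta_p must be positive")
    scale = float(np.max(np.abs(y)))
    if scale == 0:
        raise DataError("all-zero trace")

    # multi-start over delta_M to dodge local minima of the bi-exponential fit
    best = None
    for dm0 in np.geomspace(0.05, 5.0, 8):
        try:
            popt, pcov = curve_fit(
                lambda tt, c1, c2, dm: _double_exp(tt, c1, c2, dm, delta_p),
                t, y, p0=[scale, scale, dm0],
                bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((y - _double_exp(t, popt[0], popt[1], popt[2], delta_p)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise DataError("double-exponential fit failed to converge")
    rss, popt, pcov = best
    dm = float(popt[2])
    dof = max(len(y) - 3, 1)
    residual_sd = float(np.sqrt(rss / dof))

    if abs(dm - delta_p) <= _EQUAL_RATE_RTOL * max(dm, delta_p):
        # rates coincide: refit the confluent form; delta_M = delta_P = d
        popt2, pcov2 = curve_fit(
            _confluent, t, y, p0=[scale, scale, delta_p], maxfev=20000
        )
        rss2 = float(np.sum((y - _confluent(t, *popt2)) ** 2))
        return DecayFit(
            rate=float(popt2[2]),
            rate_se=float(np.sqrt(pcov2[2, 2])) if np.isfinite(pcov2[2, 2]) else np.inf,
            model="degenerate-double-exponential",
            residual_sd=float(np.sqrt(rss2 / max(len(y) - 3, 1))),
            degenerate=True,
            params={"a": float(popt2[0]), "b": float(popt2[1])},
        )

    rate_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.inf
    return DecayFit(
        rate=dm,
        rate_se=rate_se,
        model="double-exponential",
        residual_sd=residual_sd,
        degenerate=False,
        params={
            "c1": float(popt[0]),
            "c2": float(popt[1]),
            "assigned": "exponent distinct from supplied delta_P",
        },
    )
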