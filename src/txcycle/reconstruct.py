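"""Reconstruction of mRNA and transcription-rate profiles from protein traces.

The observed protein path P(t) is approximated by a penalized cubic
smoothing spline (smoothing chosen by generalized cross-validation).  The
unobserved mRNA profile follows from inverting the protein equation,

    alpha * M(t) = dP/dt + delta_P * P(t),

and the transcription rate from the forward-Euler inversion of the mRNA
equation on a fine uniform grid (default 0.1 h),

    tau(t_i) = (M(t_{i+1}) - M(t_i)) / dt + delta_M * M(t_i).

Because alpha is not identifiable, profiles are reported as alpha*M and
alpha*tau.  The first and last hour of each reconstruction are flagged as
low-confidence (spline boundary behaviour) and excluded from correlation
windows by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline

from .datatypes import CellTrace, DataError, KineticParams, TranscriptionProfile

__all__ = [
    "SplineFit",
    "fit_protein_spline",
    "reconstruct_mrna",
    "reconstruct_transcription",
    "reconstruct_cell",
    "FINE_STEP",
    "BOUNDARY_MARGIN",
]

FINE_STEP = 0.1  # hours; reconstruction grid resolution
BOUNDARY_MARGIN = 1.0  # hours flagged low-confidence at each end
_MIN_POINTS = 8


@dataclass
class SplineFit:
    """A fitted smoothing spline with its first derivative."""

    spline: BSpline
    t_min: float
    t_max: float
    smoothing: float | None
    residual_sd: float

    def _check(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t_min - 1e-9) or np.any(t > self.t_max + 1e-9):
            raise DataError("evaluation outside the spline support")
        return t

    def fitted(self, t: np.ndarray | float) -> np.ndarray:
        return self.spline(self._check(t))

    def derivative(self, t: np.ndarray | float) -> np.ndarray:
        return self.spline.derivative()(self._check(t))


def fit_protein_spline(
    trace: CellTrace, smoothing: float | str = "auto"
) -> SplineFit:
    """Fit a cubic smoothing spline to a protein trace.

    ``smoothing='auto'`` selects the penalty by generalized cross-validation;
    a float fixes the penalty (0 interpolates).
    """
    t, y = trace.times, trace.values
    if len(trace) < _MIN_POINTS:
        raise DataError(f"need at least {_MIN_POINTS} observations, got {len(trace)}")
    if np.any(np.diff(t) <= 0):
        raise DataError("duplicate or unsorted observation times")
    lam = None if smoothing == "auto" else float(smoothing)
    spl = make_smoothing_spline(t, y, lam=lam)
    resid = y - spl(t)
    residual_sd = float(np.std(resid, ddof=1)) if len(y) > 1 else 0.0
    return SplineFit(
        spline=spl,
        t_min=float(t[0]),
        t_max=float(t[-1]),
        smoothing=lam,
        residual_sd=residual_sd,
    )


def fine_grid(t_min: float, t_max: float, step: float = FINE_STEP) -> np.ndarray:
    n = int(np.floor((t_max - t_min) / step + 1e-9)) + 1
    return t_min + step * np.arange(n)


def reconstruct_mrna(
    spline: SplineFit, delta_p: float, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate alpha*M = dP/dt + delta_P * P on the fine grid.

    Returns ``(grid, alpha_m)``.  ``delta_p = 0`` degenerates to the pure
    derivative of the spline.
    """
    if delta_p < 0:
        raise DataError("delta_p must be non-negative")
    if grid is None:
        grid = fine_grid(spline.t_min, spline.t_max)
    grid = np.asarray(grid, dtype=float)
    alpha_m = spline.derivative(grid) + delta_p * spline.fitted(grid)
    return grid, alpha_m


def reconstruct_transcription(
    grid: np.ndarray,
    alpha_m: np.ndarray,
    delta_m: float,
    cell_id: str = "",
    reporter: str = "",
) -> TranscriptionProfile:
    """Forward-Euler inversion of the mRNA equation on a uniform grid.

    tau(t_i) = (M(t_{i+1}) - M(t_i)) / dt + delta_M * M(t_i); the last grid
    point is dropped.  Values are alpha*tau since the input is alpha*M.
    """
    grid = np.asarray(grid, dtype=float)
    alpha_m = np.asarray(alpha_m, dtype=float)
    steps = np.diff(grid)
    if steps.size == 0:
        raise DataError("grid too short")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise DataError("reconstruction requires a uniform grid")
    dt = steps[0]
    tau = np.diff(alpha_m) / dt + delta_m * alpha_m[:-1]
    return TranscriptionProfile(
        grid=grid[:-1], tau=tau, mrna=alpha_m[:-1], cell_id=cell_id, reporter=reporter
    )


def reconstruct_cell(
    trace: CellTrace,
    kin: KineticParams,
    smoothing: float | str = "auto",
    step: float = FINE_STEP,
    clip_negative: bool = False,
) -> TranscriptionProfile:
    """Full per-cell reconstruction: spline -> alpha*M -> alpha*tau.

    Negative tau values are retained by default: clipping would create ties
    that distort downstream rank correlations.  The profile's time axis is
    shifted by the reporter's maturation delay so that tau is indexed by
    synthesis time rather than signal time.
    """
    spline = fit_protein_spline(trace, smoothing=smoothing)
    grid = fine_grid(spline.t_min, spline.t_max, step)
    grid, alpha_m = reconstruct_mrna(spline, kin.delta_P, grid)
    profile = reconstruct_transcription(
        grid, alpha_m, kin.delta_M, cell_id=trace.cell_id, reporter=trace.reporter
    )
    if kin.maturation_delay:
        profile.grid = profile.grid - kin.maturation_delay
    if clip_negative:
        profile.tau = np.clip(profile.tau, 0.0, None)
    return profile


def trim_boundary(
    profile: TranscriptionProfile, margin: float = BOUNDARY_MARGIN
) -> TranscriptionProfile:
    """Drop the low-confidence boundary margin at each end of a profile."""
    keep = (profile.grid >= profile.grid[0] + margin) & (
        profile.grid <= profile.grid[-1] - margin
    )
    return TranscriptionProfile(
        grid=profile.grid[keep],
        tau=profile.tau[keep],
        mrna=profile.mrna[keep],
        cell_id=profile.cell_id,
        reporter=profile.reporter,
    )
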