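"""Exact solutions of the linear reporter-gene ODE system.

The two-stage model is

    dM/dt = tau(t) - delta_M * M        (reporter mRNA)
    dP/dt = alpha * M - delta_P * P     (reporter protein)

with ``tau`` piecewise constant along a binary switch path.  On every
segment where ``tau`` is constant the system is linear with constant
coefficients and has a closed-form solution, so trajectories can be
propagated segment by segment without numerical integration error.
"""

from __future__ import annotations

import numpy as np

__all__ = ["segment_solution", "propagate_path", "mrna_segment_solution"]

# relative gap below which delta_M ~ delta_P triggers the confluent
# (t * exp(-delta * t)) branch of the protein solution
_DEGENERATE_RTOL = 1e-9


def segment_solution(
    t: np.ndarray | float,
    tau: float,
    m0: float,
    p0: float,
    delta_m: float,
    delta_p: float,
    alpha: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate M(t), P(t) on a constant-``tau`` segment.

    ``t`` is time since the segment start; ``m0``, ``p0`` are the state at
    the segment start.  Handles the degenerate case ``delta_m == delta_p``
    with the confluent ``t * exp(-delta * t)`` term.
    """
    t = np.asarray(t, dtype=float)
    m_ss = tau / delta_m
    em = np.exp(-delta_m * t)
    m = m_ss + (m0 - m_ss) * em
    p_ss = alpha * tau / (delta_m * delta_p)
    if abs(delta_p - delta_m) > _DEGENERATE_RTOL * max(delta_m, delta_p):
        a = alpha * (m0 - m_ss) / (delta_p - delta_m)
        c = p0 - p_ss - a
        p = p_ss + a * em + c * np.exp(-delta_p * t)
    else:
        d = 0.5 * (delta_m + delta_p)
        e = np.exp(-d * t)
        p = p_ss + (alpha * (m0 - m_ss) * t + (p0 - p_ss)) * e
    return m, p


def mrna_segment_solution(
    t: np.ndarray | float, tau: float, m0: float, delta_m: float
) -> np.ndarray:
    """M(t) alone on a constant-``tau`` segment (used when protein is not needed)."""
    t = np.asarray(t, dtype=float)
    m_ss = tau / delta_m
    return m_ss + (m0 - m_ss) * np.exp(-delta_m * t)


def propagate_path(
    obs_times: np.ndarray,
    boundaries: np.ndarray,
    rates: np.ndarray,
    m0: float,
    p0: float,
    delta_m: float,
    delta_p: float,
    alpha: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate M and P at ``obs_times`` along a piecewise-constant rate path.

    Parameters
    ----------
    obs_times
        Sorted observation times, all within ``[boundaries[0], boundaries[-1]]``.
    boundaries
        Segment boundaries ``b_0 < b_1 < ... < b_S`` (length S+1).
    rates
        Transcription rate on each of the S segments.
    m0, p0
        State at ``boundaries[0]``.

    Returns ``(M, P)`` arrays aligned with ``obs_times``.
    """
    obs_times = np.asarray(obs_times, dtype=float)
    boundaries = np.asarray(boundaries, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if obs_times.size and (
        obs_times[0] < boundaries[0] - 1e-9 or obs_times[-1] > boundaries[-1] + 1e-9
    ):
        raise ValueError("observation times extend beyond the path support")
    m_out = np.empty_like(obs_times)
    p_out = np.empty_like(obs_times)
    # obs index where each internal boundary cuts the observation vector
    cut = np.searchsorted(obs_times, boundaries[1:-1], side="right")
    starts = np.concatenate(([0], cut))
    stops = np.concatenate((cut, [obs_times.size]))
    m, p = float(m0), float(p0)
    for j in range(rates.size):
        lo, hi = starts[j], stops[j]
        if hi > lo:
            t_loc = obs_times[lo:hi] - boundaries[j]
            m_out[lo:hi], p_out[lo:hi] = segment_solution(
                t_loc, rates[j], m, p, delta_m, delta_p, alpha
            )
        h = boundaries[j + 1] - boundaries[j]
        m, p = segment_solution(h, rates[j], m, p, delta_m, delta_p, alpha)
        m, p = float(m), float(p)
    return m_out, p_out
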