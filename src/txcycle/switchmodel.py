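"""Bayesian inference of binary transcription switching from protein traces.

The transcription rate is modeled as a binary path: ``beta_on`` in the
active state, ``beta_off`` in the inactive state, switching at unknown
times.  Given known reporter kinetics (delta_M, delta_P), the protein path
is the deterministic piecewise-ODE solution along the switch path, and
observations carry heteroscedastic Gaussian measurement error (additive SD
plus a multiplicative CV, matching the imaging noise structure).  A
reversible-jump MCMC explores the joint posterior over the number of
switches, their times, the two rate levels, the noise parameters and the
initial mRNA/protein amounts.

Moves: birth/death of a switch pair inside one interval, birth/death of a
single switch (mixes switch-count parity), a Gaussian shift of one switch
time, an initial-state flip, and random-walk updates of the scalar
parameters.  Priors are weakly informative: truncated Poisson on the number
of switch pairs, uniform order statistics for the times, half-normal levels
scaled from the trace, half-Cauchy noise SD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import poisson, spearmanr

from .datatypes import CellTrace, DataError, DurationSet, KineticParams
from .reconstruct import fit_protein_spline, reconstruct_cell

__all__ = [
    "SwitchModelConfig",
    "SwitchPosterior",
    "run_switch_mcmc",
    "remove_weak_switches",
    "extract_durations",
    "duration_association",
]


@dataclass(frozen=True)
class SwitchModelConfig:
    """MCMC controls for the binary switch model."""

    iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    max_switches: int = 20
    prior_mean_switches: float = 4.0  # Poisson mean of the number of switch PAIRS
    shift_sd: float = 0.3  # h, switch-time shift proposal
    level_step_frac: float = 0.015  # RW scale as fraction of the level prior scale
    sigma_log_sd: float = 0.15
    init_step_frac: float = 0.08
    weak_switch_threshold: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.iterations > self.burn_in >= 0):
            raise DataError("require iterations > burn_in >= 0")
        if self.max_switches < 1:
            raise DataError("max_switches must be >= 1")


@dataclass
class SwitchPosterior:
    """Thinned posterior samples of the switch model for one cell."""

    cell_id: str
    record_length: float
    kin: KineticParams
    k: np.ndarray  # number of switches per sample
    switch_times: list[np.ndarray]
    initial_state: list[str]
    beta_off: np.ndarray
    beta_on: np.ndarray
    sigma: np.ndarray
    cv: np.ndarray
    m0: np.ndarray
    p0: np.ndarray
    loglik: np.ndarray
    acceptance: dict = field(default_factory=dict)
    warning: str | None = None

    @property
    def n_samples(self) -> int:
        return int(self.k.size)

    def modal_k(self) -> int:
        vals, counts = np.unique(self.k, return_counts=True)
        return int(vals[np.argmax(counts)])

    def modal_subset(self) -> tuple[np.ndarray, str]:
        """Indices of samples with the modal (k, initial_state) and that state."""
        km = self.modal_k()
        idx = np.nonzero(self.k == km)[0]
        states = np.array([self.initial_state[i] for i in idx])
        vals, counts = np.unique(states, return_counts=True)
        zm = str(vals[np.argmax(counts)])
        return idx[states == zm], zm

    def switch_time_matrix(self) -> tuple[np.ndarray, str]:
        """Per-switch marginal samples, conditional on the modal (k, state)."""
        idx, zm = self.modal_subset()
        km = self.modal_k()
        if km == 0 or idx.size == 0:
            return np.empty((0, km)), zm
        return np.vstack([self.switch_times[i] for i in idx]), zm


# half-normal prior scale for the multiplicative-noise CV (weakly
# informative: CVs beyond ~40% are implausible for extracted intensities)
_CV_SCALE = 0.2

# ---------------------------------------------------------------------------
# likelihood machinery

class _Model:
    """Scalar-arithmetic likelihood evaluator (fast inner loop)."""

    def __init__(self, trace: CellTrace, kin: KineticParams):
        d = kin.maturation_delay
        obs = trace.times - d
        if obs[0] < -1e-9:
            raise DataError(
                "maturation delay pushes observations before the record start"
            )
        self.obs = np.clip(obs, 0.0, None)
        self.y = trace.values.astype(float)
        self.n = self.y.size
        self.T = float(self.obs[-1])
        dm, dp, alpha = kin.delta_M, kin.delta_P, kin.alpha
        if abs(dm - dp) < 1e-8 * max(dm, dp):
            dp = dp * (1.0 + 1e-6)  # avoid the confluent branch in the inner loop
        self.dm, self.dp, self.alpha = dm, dp, alpha
        self.inv_dm = 1.0 / dm
        self.inv_gap = 1.0 / (dp - dm)

    def protein(self, times: np.ndarray, z0_on: bool, b_off: float, b_on: float,
                m0: float, p0: float) -> np.ndarray:
        dm, dp, alpha = self.dm, self.dp, self.alpha
        inv_dm, inv_gap = self.inv_dm, self.inv_gap
        obs = self.obs
        out = np.empty(self.n)
        k = times.size
        m, p = m0, p0
        t_cur = 0.0
        j = 0
        on = z0_on
        exp = math.exp
        for i in range(self.n):
            t = obs[i]
            while j < k and times[j] <= t:
                tau = b_on if on else b_off
                h = times[j] - t_cur
                mss = tau * inv_dm
                em = exp(-dm * h)
                a = alpha * (m - mss) * inv_gap
                pss = alpha * tau * inv_dm / dp
                p = pss + a * em + (p - pss - a) * exp(-dp * h)
                m = mss + (m - mss) * em
                t_cur = times[j]
                j += 1
                on = not on
            tau = b_on if on else b_off
            h = t - t_cur
            mss = tau * inv_dm
            em = exp(-dm * h)
            a = alpha * (m - mss) * inv_gap
            pss = alpha * tau * inv_dm / dp
            p = pss + a * em + (p - pss - a) * exp(-dp * h)
            m = mss + (m - mss) * em
            t_cur = t
            out[i] = p
        return out

    def loglik(self, pred: np.ndarray, sigma: float, cv: float) -> float:
        """Gaussian observation noise with additive SD ``sigma`` and
        multiplicative CV ``cv``: sd_i^2 = sigma^2 + (cv * pred_i)^2."""
        r = self.y - pred
        var = sigma * sigma + (cv * cv) * pred * pred
        return -0.5 * float(np.sum(r * r / var) + np.sum(np.log(var)))


def _initialize(trace: CellTrace, kin: KineticParams, model: _Model, max_switches: int):
    """Initialize the chain from the spline/Euler reconstruction."""
    try:
        prof = reconstruct_cell(trace, kin)
        spline = fit_protein_spline(trace)
        tau = prof.tau
        grid = prof.grid + kin.maturation_delay  # back to observation time
        lo, hi = np.quantile(tau, [0.2, 0.8])
        thr = 0.5 * (lo + hi)
        binary = tau > thr
        flips = np.nonzero(np.diff(binary.astype(int)))[0]
        times = (grid[flips] + grid[flips + 1]) / 2.0 - kin.maturation_delay
        times = times[(times > 1e-3) & (times < model.T - 1e-3)]
        # merge blips shorter than 0.5 h
        while times.size >= 2:
            gaps = np.diff(times)
            if gaps.size and gaps.min() < 0.5:
                i = int(np.argmin(gaps))
                times = np.delete(times, [i, i + 1])
            else:
                break
        if times.size > max_switches:
            times = times[:max_switches]
        z0_on = bool(binary[0])
        b_on = float(np.mean(tau[binary])) if binary.any() else float(np.max(tau))
        b_off = float(np.mean(tau[~binary])) if (~binary).any() else 0.0
        b_off = max(b_off, 0.0)
        if not b_on > b_off:
            b_on = b_off + max(1e-3, 0.1 * abs(b_on) + 1e-3)
        sigma = max(spline.residual_sd, 1e-3 * max(np.max(model.y), 1.0))
        m0 = max(float(prof.mrna[0]) / kin.alpha, 1e-6)
        p0 = max(float(model.y[0]), 1e-6)
    except DataError:
        scale = kin.delta_M * kin.delta_P * float(np.mean(model.y)) / kin.alpha
        times = np.empty(0)
        z0_on, b_on, b_off = True, max(scale, 1e-3), 0.0
        sigma = max(0.1 * float(np.std(model.y)), 1e-3)
        m0 = max(scale / kin.delta_M, 1e-6)
        p0 = max(float(model.y[0]), 1e-6)
    return times, z0_on, b_off, b_on, sigma, m0, p0


def run_switch_mcmc(
    trace: CellTrace, kin: KineticParams, cfg: SwitchModelConfig | None = None
) -> SwitchPosterior:
    """Sample the binary switch-model posterior for one protein trace.

    Deterministic under a fixed ``cfg.seed``.  A non-convergence heuristic
    (structural acceptance below 1%, or the switch count pinned at the
    maximum) sets a warning flag on the returned posterior.
    """
    if cfg is None:
        cfg = SwitchModelConfig()
    if len(trace) < 10:
        raise DataError("switch model needs at least 10 observations")
    model = _Model(trace, kin)
    rng = np.random.default_rng(cfg.seed)
    T = model.T

    # prior scales derived from the trace
    y = model.y
    tau_scale = kin.delta_M * kin.delta_P * float(np.max(np.abs(y))) / kin.alpha
    level_scale = 5.0 * max(tau_scale, 1e-6)  # half-normal scale for levels
    sigma_scale = max(0.2 * float(np.std(y)), 1e-6)  # half-Cauchy scale
    m_scale = 5.0 * max(tau_scale / kin.delta_M, 1e-6)
    p_scale = 3.0 * max(float(np.max(np.abs(y))), 1e-6)

    # truncated Poisson prior on the number of switch pairs
    kmax = cfg.max_switches
    log_pk = np.array(
        [poisson.logpmf(math.ceil(k / 2), cfg.prior_mean_switches) for k in range(kmax + 1)]
    )

    times, z0_on, b_off, b_on, sigma, m0, p0 = _initialize(
        trace, kin, model, kmax
    )
    cv = 0.05  # multiplicative-noise CV start; sampled below
    pred = model.protein(times, z0_on, b_off, b_on, m0, p0)
    ll = model.loglik(pred, sigma, cv)

    n_keep = (cfg.iterations - cfg.burn_in) // cfg.thin
    S_k = np.empty(n_keep, dtype=int)
    S_times: list[np.ndarray] = []
    S_state: list[str] = []
    S_boff = np.empty(n_keep)
    S_bon = np.empty(n_keep)
    S_sigma = np.empty(n_keep)
    S_cv = np.empty(n_keep)
    S_m0 = np.empty(n_keep)
    S_p0 = np.empty(n_keep)
    S_ll = np.empty(n_keep)
    accept = {m: 0 for m in
              ("birth_pair", "death_pair", "birth1", "death1", "shift",
               "flip", "levels", "sigma", "init")}
    attempt = {m: 0 for m in accept}
    kept = 0

    level_step = cfg.level_step_frac * level_scale
    init_step_m = cfg.init_step_frac * m_scale
    init_step_p = cfg.init_step_frac * p_scale

    for it in range(cfg.iterations):
        k = times.size
        # --- structural move -------------------------------------------------
        move = ("birth_pair", "death_pair", "birth1", "death1", "shift")[
            rng.integers(5)
        ]
        attempt[move] += 1
        if move == "shift" and k > 0:
            i = int(rng.integers(k))
            new_t = times[i] + rng.normal(0.0, cfg.shift_sd)
            lo = times[i - 1] if i > 0 else 0.0
            hi = times[i + 1] if i < k - 1 else T
            if lo < new_t < hi:
                cand = times.copy()
                cand[i] = new_t
                pred_c = model.protein(cand, z0_on, b_off, b_on, m0, p0)
                ll_c = model.loglik(pred_c, sigma, cv)
                if math.log(rng.random()) < ll_c - ll:
                    times, pred, ll = cand, pred_c, ll_c
                    accept["shift"] += 1
        elif move == "birth1" and k + 1 <= kmax:
            u = rng.uniform(0.0, T)
            cand = np.sort(np.append(times, u))
            pred_c = model.protein(cand, z0_on, b_off, b_on, m0, p0)
            ll_c = model.loglik(pred_c, sigma, cv)
            log_a = ll_c - ll + log_pk[k + 1] - log_pk[k]
            if math.log(rng.random()) < log_a:
                times, pred, ll = cand, pred_c, ll_c
                accept["birth1"] += 1
        elif move == "death1" and k >= 1:
            i = int(rng.integers(k))
            cand = np.delete(times, i)
            pred_c = model.protein(cand, z0_on, b_off, b_on, m0, p0)
            ll_c = model.loglik(pred_c, sigma, cv)
            log_a = ll_c - ll + log_pk[k - 1] - log_pk[k]
            if math.log(rng.random()) < log_a:
                times, pred, ll = cand, pred_c, ll_c
                accept["death1"] += 1
        elif move == "birth_pair" and k + 2 <= kmax:
            bounds = np.concatenate(([0.0], times, [T]))
            j = int(rng.integers(k + 1))
            L = bounds[j + 1] - bounds[j]
            u = np.sort(rng.uniform(bounds[j], bounds[j + 1], size=2))
            cand = np.sort(np.concatenate((times, u)))
            pred_c = model.protein(cand, z0_on, b_off, b_on, m0, p0)
            ll_c = model.loglik(pred_c, sigma, cv)
            log_a = (
                ll_c - ll
                + log_pk[k + 2] - log_pk[k]
                + math.log((k + 1) * (k + 2) * L * L / (2.0 * T * T))
            )
            if math.log(rng.random()) < log_a:
                times, pred, ll = cand, pred_c, ll_c
                accept["birth_pair"] += 1
        elif move == "death_pair" and k >= 2:
            i = int(rng.integers(k - 1))  # remove (times[i], times[i+1])
            lo = times[i - 1] if i > 0 else 0.0
            hi = times[i + 2] if i + 2 < k else T
            L = hi - lo
            cand = np.delete(times, [i, i + 1])
            pred_c = model.protein(cand, z0_on, b_off, b_on, m0, p0)
            ll_c = model.loglik(pred_c, sigma, cv)
            log_a = (
                ll_c - ll
                + log_pk[k - 2] - log_pk[k]
                + math.log(2.0 * T * T / ((k - 1) * k * L * L))
            )
            if math.log(rng.random()) < log_a:
                times, pred, ll = cand, pred_c, ll_c
                accept["death_pair"] += 1

        # --- initial-state flip ---------------------------------------------
        attempt["flip"] += 1
        pred_c = model.protein(times, not z0_on, b_off, b_on, m0, p0)
        ll_c = model.loglik(pred_c, sigma, cv)
        if math.log(rng.random()) < ll_c - ll:
            z0_on, pred, ll = not z0_on, pred_c, ll_c
            accept["flip"] += 1

        # --- level updates (separate RW on beta_on, beta_off) -----------------
        attempt["levels"] += 1
        step = level_step * (10.0 if rng.random() < 0.1 else 1.0)  # occasional big step
        bon_c = b_on + rng.normal(0.0, step)
        if bon_c > b_off:
            pred_c = model.protein(times, z0_on, b_off, bon_c, m0, p0)
            ll_c = model.loglik(pred_c, sigma, cv)
            dlp = -0.5 * ((bon_c / level_scale) ** 2 - (b_on / level_scale) ** 2)
            if math.log(rng.random()) < ll_c - ll + dlp:
                b_on, pred, ll = bon_c, pred_c, ll_c
                accept["levels"] += 1
        boff_c = b_off + rng.normal(0.0, step)
        if 0.0 <= boff_c < b_on:
            pred_c = model.protein(times, z0_on, boff_c, b_on, m0, p0)
            ll_c = model.loglik(pred_c, sigma, cv)
            dlp = -0.5 * ((boff_c / level_scale) ** 2 - (b_off / level_scale) ** 2)
            if math.log(rng.random()) < ll_c - ll + dlp:
                b_off, pred, ll = boff_c, pred_c, ll_c

        # --- noise updates (log random walks on sigma and cv) -----------------
        attempt["sigma"] += 1
        sigma_c = sigma * math.exp(rng.normal(0.0, cfg.sigma_log_sd))
        ll_c = model.loglik(pred, sigma_c, cv)
        dlp = (
            -math.log(1.0 + (sigma_c / sigma_scale) ** 2)
            + math.log(1.0 + (sigma / sigma_scale) ** 2)
            + math.log(sigma_c / sigma)  # Jacobian of the log walk
        )
        if math.log(rng.random()) < ll_c - ll + dlp:
            sigma, ll = sigma_c, ll_c
            accept["sigma"] += 1
        cv_c = cv * math.exp(rng.normal(0.0, cfg.sigma_log_sd))
        ll_c = model.loglik(pred, sigma, cv_c)
        dlp = (
            -0.5 * ((cv_c / _CV_SCALE) ** 2 - (cv / _CV_SCALE) ** 2)
            + math.log(cv_c / cv)
        )
        if math.log(rng.random()) < ll_c - ll + dlp:
            cv, ll = cv_c, ll_c

        # --- initial conditions ----------------------------------------------
        attempt["init"] += 1
        m0_c = m0 + rng.normal(0.0, init_step_m)
        p0_c = p0 + rng.normal(0.0, init_step_p)
        if m0_c >= 0.0 and p0_c >= 0.0:
            pred_c = model.protein(times, z0_on, b_off, b_on, m0_c, p0_c)
            ll_c = model.loglik(pred_c, sigma, cv)
            dlp = (
                -0.5 * ((m0_c / m_scale) ** 2 - (m0 / m_scale) ** 2)
                - 0.5 * ((p0_c / p_scale) ** 2 - (p0 / p_scale) ** 2)
            )
            if math.log(rng.random()) < ll_c - ll + dlp:
                m0, p0, pred, ll = m0_c, p0_c, pred_c, ll_c
                accept["init"] += 1

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_keep:
            S_k[kept] = times.size
            S_times.append(times.copy())
            S_state.append("on" if z0_on else "off")
            S_boff[kept] = b_off
            S_bon[kept] = b_on
            S_sigma[kept] = sigma
            S_cv[kept] = cv
            S_m0[kept] = m0
            S_p0[kept] = p0
            S_ll[kept] = ll
            kept += 1

    rates = {
        m: (accept[m] / attempt[m] if attempt[m] else 0.0) for m in accept
    }
    warning = None
    structural = sum(accept[m] for m in ("birth_pair", "death_pair", "birth1", "death1", "shift"))
    structural_att = sum(attempt[m] for m in ("birth_pair", "death_pair", "birth1", "death1", "shift"))
    if structural_att and structural / structural_att < 0.01:
        warning = "structural acceptance below 1%"
    if np.mean(S_k[:kept] == cfg.max_switches) > 0.5:
        warning = (warning + "; " if warning else "") + "switch count pinned at max_switches"
    if warning:
        warnings.warn(f"{trace.cell_id}: {warning}", stacklevel=2)

    return SwitchPosterior(
        cell_id=trace.cell_id,
        record_length=T,
        kin=kin,
        k=S_k[:kept],
        switch_times=S_times,
        initial_state=S_state,
        beta_off=S_boff[:kept],
        beta_on=S_bon[:kept],
        sigma=S_sigma[:kept],
        cv=S_cv[:kept],
        m0=S_m0[:kept],
        p0=S_p0[:kept],
        loglik=S_ll[:kept],
        acceptance=rates,
        warning=warning,
    )


def remove_weak_switches(
    post: SwitchPosterior, threshold: float | None = None
) -> SwitchPosterior:
    """Drop switch pairs whose implied transcription excursion is negligible.

    A brief opposite-state excursion of duration ``d`` only moves the mRNA by
    a fraction ``1 - exp(-delta_M * d)`` of the full on/off contrast; pairs
    with that fraction below ``threshold`` are deleted sample by sample and
    the flanking same-state intervals re-merged.  ``threshold = 0`` is the
    identity.
    """
    if threshold is None:
        threshold = SwitchModelConfig().weak_switch_threshold
    if threshold <= 0:
        return post
    dm = post.kin.delta_M
    min_dur = -math.log(max(1.0 - threshold, 1e-12)) / dm
    trimmed: list[np.ndarray] = []
    for t in post.switch_times:
        t = t.copy()
        while t.size >= 2:
            gaps = np.diff(t)
            i = int(np.argmin(gaps))
            if gaps[i] < min_dur:
                t = np.delete(t, [i, i + 1])
            else:
                break
        trimmed.append(t)
    # posterior inclusion: a switch is supported when at least half the
    # samples place a switch within +-0.5 h of it; diffuse, prior-driven
    # switch times (e.g. on a steady trace, where the levels can collapse
    # and make switching invisible) fail this and are dropped
    n = max(len(trimmed), 1)
    pooled = np.sort(np.concatenate(trimmed)) if trimmed else np.empty(0)
    new_times: list[np.ndarray] = []
    new_k = np.empty(post.n_samples, dtype=int)
    for s, t in enumerate(trimmed):
        if t.size:
            counts = np.searchsorted(pooled, t + 0.5, side="right") - np.searchsorted(
                pooled, t - 0.5, side="left"
            )
            t = t[counts / n >= 0.5]
        new_times.append(t)
        new_k[s] = t.size
    return SwitchPosterior(
        cell_id=post.cell_id,
        record_length=post.record_length,
        kin=post.kin,
        k=new_k,
        switch_times=new_times,
        initial_state=list(post.initial_state),
        beta_off=post.beta_off,
        beta_on=post.beta_on,
        sigma=post.sigma,
        cv=post.cv,
        m0=post.m0,
        p0=post.p0,
        loglik=post.loglik,
        acceptance=post.acceptance,
        warning=post.warning,
    )


def extract_durations(
    post: SwitchPosterior, estimator: str = "posterior-mean"
) -> DurationSet:
    """On/off durations and on-to-on periods from a point estimate of the path.

    The point estimate is taken conditional on the modal (switch count,
    initial state): either the per-switch marginal posterior means or the
    maximum-posterior sample.  Boundary intervals cut by the record are
    censored and excluded; with fewer than two switches the set is empty.
    """
    mat, z0 = post.switch_time_matrix()
    km = post.modal_k()
    if km < 2 or mat.shape[0] == 0:
        return DurationSet(cell_id=post.cell_id)
    if estimator == "posterior-mean":
        times = np.sort(mat.mean(axis=0))
    elif estimator == "MAP":
        idx, _ = post.modal_subset()
        best = idx[np.argmax(post.loglik[idx])]
        times = post.switch_times[best]
    else:
        raise DataError(f"unknown estimator '{estimator}'")
    # interior segment durations: segment i runs times[i-1] .. times[i]
    durs = np.diff(times)
    states = []
    s = z0
    # segment after the i-th switch flips each time; interior segments start at switch 1
    seg_states = [z0]
    for _ in range(km):
        s = "off" if s == "on" else "on"
        seg_states.append(s)
    interior_states = seg_states[1:-1]  # aligned with durs
    on_d = durs[[st == "on" for st in interior_states]]
    off_d = durs[[st == "off" for st in interior_states]]
    onsets = times[[st == "on" for st in seg_states[1:]]]  # switch into "on"
    periods = np.diff(onsets)
    return DurationSet(
        on_durations=on_d,
        off_durations=off_d,
        periods=periods,
        cell_id=post.cell_id,
        first_interior_state=interior_states[0] if interior_states else "",
    )


def duration_association(
    durations: list[DurationSet] | DurationSet,
    pairing: str = "on-then-off",
    n_perm: int = 1000,
    seed=None,
) -> dict:
    """Rank correlation between paired on/off phase durations across cells.

    ``pairing='on-then-off'`` pairs each on-phase with the subsequent
    off-phase; ``'off-then-on'`` with the preceding off-phase.  Significance
    is a permutation p-value (default 1000 shuffles, seeded).
    """
    sets = [durations] if isinstance(durations, DurationSet) else list(durations)
    xs, ys = [], []
    for ds in sets:
        x, y = _paired_durations(ds, pairing)
        xs.append(x)
        ys.append(y)
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    if x.size < 2:
        return {"rho": np.nan, "p_value": np.nan, "pairs": (x, y), "n": int(x.size)}
    rho = float(spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r = spearmanr(x, rng.permutation(y)).statistic
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return {"rho": rho, "p_value": float(p), "pairs": (x, y), "n": int(x.size)}


def _paired_durations(ds: DurationSet, pairing: str) -> tuple[np.ndarray, np.ndarray]:
    """Pair phases of one cell using the temporal interleaving.

    Interior segments alternate; ``first_interior_state`` says whether the
    sequence opens with an on- or an off-phase.  For ``'on-then-off'`` the
    i-th on-phase is paired with the off-phase immediately after it; for
    ``'off-then-on'`` with the off-phase immediately before it.
    """
    on, off = ds.on_durations, ds.off_durations
    if on.size == 0 or off.size == 0:
        return np.empty(0), np.empty(0)
    opens_on = ds.first_interior_state != "off"  # default to on-first when unknown
    if pairing == "on-then-off":
        # on_i is followed by off_i when the sequence opens with on,
        # and by off_{i+1} when it opens with off
        o = off if opens_on else off[1:]
    elif pairing == "off-then-on":
        # off preceding on_i: off_{i-1} (opens on) or off_i (opens off)
        on = on[1:] if opens_on else on
        o = off
    else:
        raise DataError(f"unknown pairing '{pairing}'")
    n = min(on.size, o.size)
    return on[:n], o[:n]
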