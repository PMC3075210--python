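"""Core value types shared across the pipeline.

Times are in hours everywhere; intensities and transcription rates are in
arbitrary units (transcription is only identified up to the translation
rate alpha, so profiles are reported as alpha*M and alpha*tau throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SwitchParams",
    "KineticParams",
    "NoiseParams",
    "SwitchPath",
    "CellTrace",
    "TranscriptionProfile",
    "DurationSet",
    "ParameterError",
    "DataError",
]


class ParameterError(ValueError):
    """Invalid model or generator parameters."""


class DataError(ValueError):
    """Input data violate a precondition (ordering, positivity, length...)."""


@dataclass(frozen=True)
class SwitchParams:
    """Residence-time and level parameters of the binary switch process.

    On-durations are Exponential(``mean_on``).  Off-durations are a hard
    ``refractory`` minimum plus an Exponential(``mean_excess_off``) excess;
    ``refractory = 0`` recovers the memoryless telegraph process.
    Transcription runs at ``rate_on`` in the active state and at the basal
    ``rate_off`` otherwise.
    """

    mean_on: float
    refractory: float
    mean_excess_off: float
    rate_on: float
    rate_off: float = 0.0

    def __post_init__(self) -> None:
        if not self.mean_on > 0:
            raise ParameterError("mean_on must be positive")
        if self.refractory < 0:
            raise ParameterError("refractory must be non-negative")
        if not self.mean_excess_off > 0:
            raise ParameterError("mean_excess_off must be positive")
        if not self.rate_on > self.rate_off or self.rate_off < 0:
            raise ParameterError("require rate_on > rate_off >= 0")

    @property
    def mean_off(self) -> float:
        return self.refractory + self.mean_excess_off

    @property
    def mean_period(self) -> float:
        return self.mean_on + self.mean_off

    @property
    def stationary_on_fraction(self) -> float:
        return self.mean_on / self.mean_period

    @property
    def mean_rate(self) -> float:
        """Long-run average transcription rate of the switch process."""
        f = self.stationary_on_fraction
        return f * self.rate_on + (1.0 - f) * self.rate_off


@dataclass(frozen=True)
class KineticParams:
    """Linear mRNA -> protein kinetics of one reporter.

    ``alpha`` is the translation/signal-formation rate, ``delta_M`` and
    ``delta_P`` the mRNA and protein degradation rates (per hour), and
    ``maturation_delay`` the constant lag between synthesis and detectable
    signal (only the between-reporter difference matters downstream).
    """

    delta_M: float
    delta_P: float
    alpha: float = 1.0
    maturation_delay: float = 0.0

    def __post_init__(self) -> None:
        if not (self.delta_M > 0 and self.delta_P > 0 and self.alpha > 0):
            raise ParameterError("alpha, delta_M, delta_P must be positive")
        if self.maturation_delay < 0:
            raise ParameterError("maturation_delay must be non-negative")


@dataclass(frozen=True)
class NoiseParams:
    """Heteroscedastic measurement-error model.

    Observed intensity = P * (1 + eps_m) + eps_a with
    eps_m ~ N(0, cv_multiplicative^2), eps_a ~ N(0, sd_additive^2).
    """

    sd_additive: float = 0.0
    cv_multiplicative: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_additive < 0 or self.cv_multiplicative < 0:
            raise ParameterError("noise scales must be non-negative")

    @property
    def is_noiseless(self) -> bool:
        return self.sd_additive == 0.0 and self.cv_multiplicative == 0.0


@dataclass
class SwitchPath:
    """Piecewise-binary transcription state over ``[0, duration]``.

    ``switch_times`` are the strictly increasing times at which the state
    flips; the state alternates starting from ``initial_state``.  ``levels``
    holds ``(rate_off, rate_on)``.
    """

    switch_times: np.ndarray
    initial_state: str
    levels: tuple[float, float]
    duration: float

    def __post_init__(self) -> None:
        self.switch_times = np.asarray(self.switch_times, dtype=float)
        if self.initial_state not in ("on", "off"):
            raise ParameterError("initial_state must be 'on' or 'off'")
        if self.switch_times.size and (
            np.any(np.diff(self.switch_times) <= 0)
            or self.switch_times[0] <= 0
            or self.switch_times[-1] >= self.duration
        ):
            raise ParameterError(
                "switch_times must be strictly increasing inside (0, duration)"
            )

    @property
    def n_switches(self) -> int:
        return int(self.switch_times.size)

    def states(self) -> list[str]:
        """State of each of the ``n_switches + 1`` segments."""
        first = self.initial_state
        other = "off" if first == "on" else "on"
        return [first if i % 2 == 0 else other for i in range(self.n_switches + 1)]

    def segment_rates(self) -> np.ndarray:
        rate_off, rate_on = self.levels
        return np.array(
            [rate_on if s == "on" else rate_off for s in self.states()], dtype=float
        )

    def boundaries(self) -> np.ndarray:
        return np.concatenate(([0.0], self.switch_times, [self.duration]))

    def rate_at(self, t: np.ndarray | float) -> np.ndarray:
        """Instantaneous transcription rate tau(t)."""
        t = np.asarray(t, dtype=float)
        seg = np.searchsorted(self.switch_times, t, side="right")
        return self.segment_rates()[seg]

    def intervals(self) -> list[tuple[float, float, str]]:
        """(start, end, state) for every segment, boundary segments included."""
        b = self.boundaries()
        return [
            (float(b[i]), float(b[i + 1]), s) for i, s in enumerate(self.states())
        ]


@dataclass
class CellTrace:
    """Observed intensity time-series for one cell and one reporter."""

    cell_id: str
    reporter: str
    times: np.ndarray
    values: np.ndarray
    treatment: str = "unstimulated"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise DataError("times and values must have identical shape")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise DataError("values must be finite")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class TranscriptionProfile:
    """Reconstructed transcription rate (alpha*tau) and mRNA (alpha*M) on a
    uniform fine grid."""

    grid: np.ndarray
    tau: np.ndarray
    mrna: np.ndarray
    cell_id: str = ""
    reporter: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.mrna = np.asarray(self.mrna, dtype=float)
        if not (self.grid.size == self.tau.size == self.mrna.size):
            raise DataError("grid, tau and mrna must have equal length")
        if self.grid.size >= 2:
            steps = np.diff(self.grid)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise DataError("profile grid must be uniform")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])


@dataclass
class DurationSet:
    """Complete (uncensored) on/off durations and on-to-on periods of a cell."""

    on_durations: np.ndarray = field(default_factory=lambda: np.empty(0))
    off_durations: np.ndarray = field(default_factory=lambda: np.empty(0))
    periods: np.ndarray = field(default_factory=lambda: np.empty(0))
    cell_id: str = ""
    # state of the first interior (uncensored) segment, "" when unknown;
    # lets consumers reconstruct the temporal interleaving of on/off phases
    first_interior_state: str = ""

    def __post_init__(self) -> None:
        self.on_durations = np.asarray(self.on_durations, dtype=float)
        self.off_durations = np.asarray(self.off_durations, dtype=float)
        self.periods = np.asarray(self.periods, dtype=float)

    @staticmethod
    def pooled(sets: Sequence["DurationSet"]) -> "DurationSet":
        return DurationSet(
            on_durations=np.concatenate([s.on_durations for s in sets])
            if sets
            else np.empty(0),
            off_durations=np.concatenate([s.off_durations for s in sets])
            if sets
            else np.empty(0),
            periods=np.concatenate([s.periods for s in sets]) if sets else np.empty(0),
            cell_id="pooled",
        )


def shift_path(path: SwitchPath, offset: float, duration: float) -> SwitchPath:
    """Restrict a path to a window ``[offset, offset + duration]`` and re-zero it."""
    times = path.switch_times - offset
    keep = (times > 0) & (times < duration)
    n_before = int(np.sum(path.switch_times <= offset))
    states = path.states()
    initial = states[n_before]
    return SwitchPath(
        switch_times=times[keep],
        initial_state=initial,
        levels=path.levels,
        duration=duration,
    )
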