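"""Uniformly sampled time-series containers used throughout the package.

A :class:`Trace` stores one recording channel (membrane potential in mV,
synaptic current in pA, or relative fluorescence dF/F) on a uniform time
base together with the stimulus times that structure the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AlignmentError, ConfigurationError

__all__ = ["Trace", "CaTrialSet"]


@dataclass
class Trace:
    """Uniformly sampled signal.

    Parameters
    ----------
    t0 : float
        Time of the first sample, ms.
    dt : float
        Sampling interval, ms.
    values : ndarray
        Sample values; unit given by ``unit``.
    stim_times : tuple of float
        Stimulus onset times, ms.
    unit : str
        One of ``"mV"``, ``"pA"``, ``"dff"`` (free-form accepted).
    """

    t0: float
    dt: float
    values: np.ndarray
    stim_times: tuple = ()
    unit: str = "mV"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.values.ndim != 1:
            raise ConfigurationError("trace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("trace contains non-finite values")
        self.stim_times = tuple(float(s) for s in self.stim_times)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    def time(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(self.n)

    def index_of(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (clipped to range)."""
        return int(np.clip(round((t - self.t0) / self.dt), 0, self.n - 1))

    def same_timebase(self, other: "Trace", rtol: float = 1e-9) -> bool:
        return (
            self.n == other.n
            and abs(self.t0 - other.t0) <= rtol * max(1.0, abs(self.t0))
            and abs(self.dt - other.dt) <= rtol * self.dt
        )

    def require_aligned(self, other: "Trace"):
        if not self.same_timebase(other):
            raise AlignmentError(
                f"time bases differ: (t0={self.t0}, dt={self.dt}, n={self.n}) "
                f"vs (t0={other.t0}, dt={other.dt}, n={other.n})"
            )

    def with_values(self, values: np.ndarray) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class CaTrialSet:
    """Trial-structured calcium recordings from one cell.

    All trials share a time base; ``stim_time`` is the stimulus onset in ms
    relative to each trial's own clock.
    """

    trials: list = field(default_factory=list)
    stim_time: float = 0.0

    def __post_init__(self):
        if len(self.trials) < 1:
            raise ConfigurationError("a trial set needs at least one trial")
        first = self.trials[0]
        for tr in self.trials[1:]:
            first.require_aligned(tr)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def average(self) -> Trace:
        """Trial-averaged trace (the basis of responsiveness calls)."""
        stacked = np.stack([tr.values for tr in self.trials])
        avg = self.trials[0].with_values(stacked.mean(axis=0))
        avg.stim_times = (self.stim_time,)
        return avg
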