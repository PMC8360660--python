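"""dF/F computation and stimulus-responsiveness classification.

``delta_f_over_f`` converts raw fluorescence to relative change using a
running-percentile baseline, R(t) = (F(t) - F0(t)) / F0(t); a cell is
called responsive when the trial-averaged dF/F shows a post-stimulus peak
exceeding three times the SD of its pre-stimulus noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import percentile_filter

from .errors import ConfigurationError, NgfcError
from .trace import CaTrialSet, Trace

__all__ = [
    "delta_f_over_f",
    "classify_responsive",
    "classify_population",
    "ResponsivenessResult",
    "CellCall",
]

#: responsiveness threshold in units of pre-stimulus noise SD
SD_FACTOR = 3.0


def delta_f_over_f(
    f: Trace,
    window_ms: float = 3000.0,
    percentile: float = 20.0,
) -> Trace:
    """Relative fluorescence change with a running-percentile baseline.

    F0(t) is the ``percentile``-th percentile of F in a sliding window of
    ``window_ms``; the result is (F - F0) / F0. Raises on a non-positive
    baseline anywhere.
    """
    if window_ms <= 0:
        raise ConfigurationError("window_ms must be positive")
    if not (0 < percentile < 100):
        raise ConfigurationError("percentile must be in (0, 100)")
    size = max(1, int(round(window_ms / f.dt)))
    f0 = percentile_filter(f.values, percentile=percentile, size=size, mode="nearest")
    if np.any(f0 <= 0):
        raise NgfcError("baseline F0 is non-positive; dF/F undefined")
    out = f.with_values((f.values - f0) / f0)
    out.unit = "dff"
    return out


@dataclass
class CellCall:
    """Responsiveness call for a single cell."""

    responsive: bool
    amplitude: float     # post-stimulus peak of the averaged dF/F
    noise_sd: float      # SD of the averaged trace before the stimulus


@dataclass
class ResponsivenessResult:
    """Population summary of per-cell responsiveness calls."""

    calls: list
    fraction_responsive_percent: float

    def __post_init__(self):
        if not (0.0 <= self.fraction_responsive_percent <= 100.0):
            raise ConfigurationError("fraction must be a percentage in [0, 100]")


def classify_responsive(
    trials: CaTrialSet,
    pre_window_ms: float = 1000.0,
    post_window_ms: float = 500.0,
    sd_factor: float = SD_FACTOR,
) -> CellCall:
    """Call one cell responsive from its trial-averaged dF/F.

    The trials are averaged; the noise SD is taken over the
    ``pre_window_ms`` span before the stimulus of the averaged trace, and
    the cell is responsive iff the peak within ``post_window_ms`` after
    the stimulus exceeds ``sd_factor`` times that SD (``post_window_ms
    = None`` searches to the end of the trace). A zero-noise,
    zero-response set is non-responsive.
    """
    if trials.n_trials < 2:
        raise ConfigurationError("need >= 2 trials to average")
    avg = trials.average()
    if not avg.stim_times:
        raise ConfigurationError("trial set has no stimulus time")
    stim = avg.stim_times[0]
    i_stim = avg.index_of(stim)
    i_pre = avg.index_of(stim - pre_window_ms)
    if i_stim <= i_pre:
        raise ConfigurationError("pre-stimulus window empty")
    pre = avg.values[i_pre:i_stim]
    noise_sd = float(np.std(pre))
    baseline = float(np.mean(pre))

    if post_window_ms is None:
        i_end = avg.n
    else:
        i_end = min(avg.n, avg.index_of(stim + post_window_ms) + 1)
    post = avg.values[i_stim:i_end] - baseline
    amplitude = float(post.max()) if post.size else 0.0
    responsive = amplitude > sd_factor * noise_sd
    return CellCall(responsive=bool(responsive), amplitude=amplitude, noise_sd=noise_sd)


def classify_population(cell_sets, **kwargs) -> ResponsivenessResult:
    """Classify many cells and report the responsive fraction in percent."""
    if not cell_sets:
        raise ConfigurationError("need at least one cell")
    calls = [classify_responsive(ts, **kwargs) for ts in cell_sets]
    frac = 100.0 * sum(c.responsive for c in calls) / len(calls)
    return ResponsivenessResult(calls=calls, fraction_responsive_percent=frac)
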