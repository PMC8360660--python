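"""IPSP/IPSC kinetics and summation arithmetic.

Convergent inhibitory inputs are compared against their arithmetic sum:
the *calculated* sum is the pointwise sum of the unitary responses, the
*measured* trace is the compound response, and the nonlinearity is the
difference at the peak expressed in percent of the calculated peak.
Negative nonlinearity means sublinear summation.

Kinetic conventions (shared with the generators):

* rise time: interval between the 10% and 90% crossings before the peak;
* half-width: width of the response at 50% of peak;
* decay time: interval from the peak to the point where the response has
  decayed to 32.7% of peak, i.e. by 67.3%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, KineticsError
from .trace import Trace

__all__ = [
    "Kinetics",
    "measure_kinetics",
    "SummationResult",
    "summation_nonlinearity",
    "normalize_burst",
    "conductance_response",
]

#: fraction of the peak that remains at the conventional decay read-out
DECAY_FRACTION = 0.327


class Kinetics(NamedTuple):
    peak: float                # signed extremum relative to baseline
    onset_latency: float       # stimulus -> 10% crossing, ms
    rise_10_90: float          # ms
    half_width: float          # ms; nan when the trace never re-crosses 50%
    decay_time: float          # ms; nan when decay is not reached in-window


def _cross_time(t, y, level, start, stop, rising):
    """Linearly interpolated first crossing of `level` in [start, stop)."""
    a = y[start:stop]
    b = y[start + 1 : stop + 1]
    hits = (a < level) & (level <= b) if rising else (a >= level) & (level > b)
    idx = np.flatnonzero(hits)
    if idx.size == 0:
        return np.nan
    i = start + int(idx[0])
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return t[i] + frac * (t[i + 1] - t[i])


def measure_kinetics(
    trace: Trace,
    peak_window: float = 50.0,
    stim_time: float | None = None,
    baseline_window: float = 50.0,
) -> Kinetics:
    """Measure peak and kinetics of a stimulus-locked response.

    Parameters
    ----------
    trace : Trace
        Signal with at least one stimulus time.
    peak_window : float
        Window after the stimulus in which the extremum is searched, ms.
        Use ~50 ms for fast (ionotropic) responses, ~400 ms for slow
        (metabotropic) ones.
    stim_time : float, optional
        Override the stimulus time; defaults to the first stimulus of the
        trace.
    baseline_window : float
        Pre-stimulus span averaged to define the baseline, ms.
    """
    if stim_time is None:
        if not trace.stim_times:
            raise ConfigurationError("trace has no stimulus time")
        stim_time = trace.stim_times[0]
    if peak_window <= 0:
        raise ConfigurationError("peak_window must be positive")

    t = trace.time()
    i_stim = trace.index_of(stim_time)
    i_base0 = trace.index_of(stim_time - baseline_window)
    baseline = float(np.mean(trace.values[i_base0 : max(i_stim, i_base0 + 1)]))
    y = trace.values - baseline

    i_end = min(trace.n - 1, trace.index_of(stim_time + peak_window))
    seg = y[i_stim : i_end + 1]
    if seg.size < 2 or np.allclose(seg, 0.0):
        raise KineticsError("flat trace: no measurable response in window")
    i_peak = i_stim + int(np.argmax(np.abs(seg)))
    peak = float(y[i_peak])

    sign = 1.0 if peak >= 0 else -1.0
    ys = sign * y  # peak now positive
    pk = sign * peak

    t10 = _cross_time(t, ys, 0.1 * pk, i_stim, i_peak, rising=True)
    t90 = _cross_time(t, ys, 0.9 * pk, i_stim, i_peak, rising=True)
    rise = t90 - t10 if np.isfinite(t10) and np.isfinite(t90) else np.nan
    onset = t10 - stim_time if np.isfinite(t10) else np.nan

    t50a = _cross_time(t, ys, 0.5 * pk, i_stim, i_peak, rising=True)
    t50b = _cross_time(t, ys, 0.5 * pk, i_peak, trace.n - 1, rising=False)
    half_width = t50b - t50a if np.isfinite(t50a) and np.isfinite(t50b) else np.nan

    t_dec = _cross_time(t, ys, DECAY_FRACTION * pk, i_peak, trace.n - 1, rising=False)
    decay = t_dec - t[i_peak] if np.isfinite(t_dec) else np.nan

    return Kinetics(peak=peak, onset_latency=onset, rise_10_90=rise,
                    half_width=half_width, decay_time=decay)


@dataclass
class SummationResult:
    """Measured vs. calculated sum of convergent unitary responses."""

    calculated: Trace
    measured: Trace
    difference: Trace            # measured - calculated
    nonlinearity_trace: Trace    # 100 * difference / |calculated peak|, %
    nonlinearity_percent: float  # at the peaks
    measured_peak: float
    calculated_peak: float


def summation_nonlinearity(
    unitaries: Sequence[Trace],
    measured: Trace,
    peak_window: float = 50.0,
) -> SummationResult:
    """Compare a compound response against the sum of its unitary inputs.

    Traces must be baseline-subtracted and share the same time base. The
    scalar nonlinearity is ``100 * (measured_peak - calculated_peak) /
    |calculated_peak|``; the time-resolved version normalizes the full
    difference trace by the calculated-sum peak so the trace reads in
    percent of the expected compound amplitude.
    """
    if not unitaries:
        raise ConfigurationError("need at least one unitary trace")
    for u in unitaries:
        measured.require_aligned(u)
    calc_values = np.sum([u.values for u in unitaries], axis=0)
    calculated = measured.with_values(calc_values)
    calculated.stim_times = measured.stim_times or unitaries[0].stim_times

    kin_c = measure_kinetics(calculated, peak_window=peak_window)
    kin_m = measure_kinetics(measured, peak_window=peak_window) if np.any(measured.values) else None
    measured_peak = kin_m.peak if kin_m is not None else 0.0
    calc_peak = kin_c.peak
    if calc_peak == 0:
        raise KineticsError("calculated sum has zero peak")

    diff = measured.with_values(measured.values - calc_values)
    nl_trace = measured.with_values(100.0 * diff.values / abs(calc_peak))
    nl_trace.unit = "%"
    nonlin = 100.0 * (abs(measured_peak) - abs(calc_peak)) / abs(calc_peak)
    return SummationResult(
        calculated=calculated,
        measured=measured,
        difference=diff,
        nonlinearity_trace=nl_trace,
        nonlinearity_percent=float(nonlin),
        measured_peak=float(measured_peak),
        calculated_peak=float(calc_peak),
    )


def normalize_burst(peaks: Sequence[float]) -> np.ndarray:
    """Normalize burst-evoked peak amplitudes to the single-AP response.

    ``peaks[0]`` is the 1-AP peak of the set; every entry is divided by it,
    so a perfectly linear burst of k APs reads ``[1, 2, ..., k]``.
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 1:
        raise ConfigurationError("empty peak list")
    if peaks[0] == 0:
        raise ConfigurationError("1-AP peak is zero; cannot normalize")
    return peaks / peaks[0]


def conductance_response(
    g_traces: Sequence[Trace],
    e_syn: float = -90.0,
    e_leak: float = -50.0,
    g_leak: float = 10.0,
    c_m: float = 200.0,
    method: str = "exact",
) -> Trace:
    """Membrane-potential response of a passive compartment to conductances.

    Integrates ``C dV/dt = -g_L (V - E_L) - sum_i g_i(t) (V - E_syn)`` with
    the synaptic conductances given as traces (nS). This is the minimal
    driving-force model in which summation of hyperpolarizing inputs is
    sublinear: simultaneous conductances see a smaller driving force than
    each alone.

    Units: nS, pF, mV, ms. ``method="exact"`` uses per-step exponential
    integration (exact for piecewise-constant g); ``method="ivp"`` uses an
    adaptive Runge-Kutta integration as an independent route.
    """
    if not g_traces:
        raise ConfigurationError("need at least one conductance trace")
    base = g_traces[0]
    for g in g_traces[1:]:
        base.require_aligned(g)
    g_tot = np.sum([g.values for g in g_traces], axis=0)
    if np.any(g_tot < 0):
        raise ConfigurationError("conductances must be nonnegative")
    t = base.time()
    dt = base.dt

    if method == "ivp":
        def rhs(ti, v):
            gi = np.interp(ti, t, g_tot)
            return (-g_leak * (v - e_leak) - gi * (v - e_syn)) / c_m

        sol = solve_ivp(rhs, (t[0], t[-1]), [e_leak], t_eval=t,
                        rtol=1e-8, atol=1e-10, max_step=dt)
        v = sol.y[0]
    elif method == "exact":
        v = np.empty_like(g_tot)
        v[0] = e_leak
        for i in range(1, v.size):
            g = g_tot[i - 1]
            g_sum = g_leak + g
            v_inf = (g_leak * e_leak + g * e_syn) / g_sum
            tau = c_m / g_sum
            v[i] = v_inf + (v[i - 1] - v_inf) * np.exp(-dt / tau)
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    out = base.with_values(v - e_leak)  # baseline-subtracted response
    out.unit = "mV"
    return out
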