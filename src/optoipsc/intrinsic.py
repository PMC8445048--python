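"""Intrinsic-property extraction from current-clamp step families.

Spike detection by dV/dt threshold crossing, spike threshold at the foot of
the fast rise, AP half-width at half of (peak - threshold), f-I curves with
rheobase, and passive properties (steady-state I-V points and input
resistance) from subthreshold steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import ParameterError, StepRecording


@dataclass
class FICurve:
    currents: np.ndarray    # pA
    rates: np.ndarray       # Hz
    rheobase: float | None  # pA, smallest current with >= 1 spike


@dataclass
class PassiveProps:
    input_resistance: float            # MOhm
    iv_points: list[tuple[float, float]]  # (pA, mV) steady-state pairs


def detect_spikes(trace: np.ndarray, sample_rate: float,
                  dvdt_thresh: float = 10.0) -> np.ndarray:
    """Spike times (s) from upward dV/dt threshold crossings.

    One spike per suprathreshold excursion: after a crossing, the detector
    re-arms only once dV/dt has crossed zero downward. Forward differences
    keep the reported time at the first sample of the fast rise.
    """
    v = np.asarray(trace, dtype=float)
    if v.size < 2:
        return np.array([])
    dv = np.diff(v) * sample_rate / 1000.0  # mV/ms
    above = dv >= dvdt_thresh
    starts = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    if starts.size == 0:
        return np.array([])
    # re-arm rule: a new spike requires a downward dV/dt zero crossing since
    # the previous accepted spike
    cneg = np.cumsum(dv < 0.0)
    times = [starts[0]]
    for s in starts[1:]:
        if cneg[s] > cneg[times[-1]]:
            times.append(s)
    return np.asarray(times) / sample_rate


def spike_threshold(trace: np.ndarray, spike_time: float, sample_rate: float,
                    dvdt_thresh: float = 10.0) -> float:
    """Membrane potential at the first pre-peak point where dV/dt exceeds
    the criterion (default 10 mV/ms). Returns NaN if no crossing exists."""
    v = np.asarray(trace, dtype=float)
    k = int(round(spike_time * sample_rate))
    dv = np.diff(v) * sample_rate / 1000.0
    # peak of this excursion: first local max after the spike time
    peak = k
    while peak + 1 < v.size and v[peak + 1] >= v[peak]:
        peak += 1
    # walk back to the start of the contiguous suprathreshold-dV/dt run
    i = min(peak - 1, dv.size - 1)
    while i > 0 and dv[i] < dvdt_thresh:
        i -= 1
    if dv[i] < dvdt_thresh:
        return np.nan
    while i > 0 and dv[i - 1] >= dvdt_thresh:
        i -= 1
    return float(v[i])


def ap_half_width(trace: np.ndarray, spike_time: float, sample_rate: float,
                  dvdt_thresh: float = 10.0) -> float:
    """AP width (ms) at half of (peak - threshold), linearly interpolated."""
    v = np.asarray(trace, dtype=float)
    k = int(round(spike_time * sample_rate))
    peak = k
    while peak + 1 < v.size and v[peak + 1] >= v[peak]:
        peak += 1
    thr = spike_threshold(trace, spike_time, sample_rate, dvdt_thresh)
    if not np.isfinite(thr) or v[peak] <= thr:
        return np.nan
    half = thr + 0.5 * (v[peak] - thr)

    def cross(idx_from: int, step: int) -> float:
        i = idx_from
        while 0 < i < v.size - 1:
            j = i + step
            if (v[i] - half) * (v[j] - half) <= 0 and v[i] != v[j]:
                frac = (half - v[i]) / (v[j] - v[i])
                return i + step * abs(frac)
            i = j
        return np.nan

    left = cross(peak, -1)
    right = cross(peak, +1)
    if not (np.isfinite(left) and np.isfinite(right)):
        return np.nan
    return float((right - left) / sample_rate * 1000.0)


def fi_curve(rec: StepRecording, dvdt_thresh: float = 10.0) -> FICurve:
    """Firing rate per current step; rheobase = first current with a spike."""
    lo, hi = rec.step_window
    step_len = hi - lo
    rates = np.empty(len(rec.currents))
    rheobase = None
    for j, trace in enumerate(rec.traces):
        times = detect_spikes(trace, rec.sample_rate, dvdt_thresh)
        times = times[(times >= lo) & (times < hi)]
        rates[j] = times.size / step_len
        if rheobase is None and times.size:
            rheobase = float(rec.currents[j])
    return FICurve(currents=np.asarray(rec.currents, float), rates=rates,
                   rheobase=rheobase)


def passive_props(rec: StepRecording, dvdt_thresh: float = 10.0,
                  steady_frac: float = 0.2) -> PassiveProps:
    """Steady-state I-V points and input resistance near rest.

    Steady state is the mean of the last ``steady_frac`` of the step window;
    input resistance is the slope (MOhm) through the two subthreshold steps
    with currents nearest zero.
    """
    lo, hi = rec.step_window
    fs = rec.sample_rate
    i1 = int(round(hi * fs))
    i0 = int(round((hi - steady_frac * (hi - lo)) * fs))
    iv = []
    for j, trace in enumerate(rec.traces):
        times = detect_spikes(trace, fs, dvdt_thresh)
        if times[(times >= lo) & (times < hi)].size:
            continue  # suprathreshold: no steady-state point
        iv.append((float(rec.currents[j]), float(np.mean(trace[i0:i1]))))
    if len(iv) < 2:
        raise ParameterError("need at least 2 subthreshold steps")
    order = np.argsort([abs(c) for c, _ in iv])
    (c1, v1), (c2, v2) = iv[order[0]], iv[order[1]]
    if c1 == c2:
        raise ParameterError("degenerate step pair: identical currents")
    rin = (v2 - v1) / (c2 - c1) * 1000.0  # mV/pA -> MOhm
    return PassiveProps(input_resistance=float(rin), iv_points=sorted(iv))


def property_table(recs: dict[str, StepRecording]) -> "pd.DataFrame":
    """Per-cell intrinsic-property table (one row per cell) for CSV export."""
    import pandas as pd

    rows = []
    for cell, rec in recs.items():
        fi = fi_curve(rec)
        pp = passive_props(rec)
        thr = np.nan
        hw = np.nan
        if fi.rheobase is not None:
            j = int(np.argmax(rec.currents >= fi.rheobase))
            times = detect_spikes(rec.traces[j], rec.sample_rate)
            if times.size:
                thr = spike_threshold(rec.traces[j], times[0], rec.sample_rate)
                hw = ap_half_width(rec.traces[j], times[0], rec.sample_rate)
        rows.append({"cell": cell, "input_resistance_mohm": pp.input_resistance,
                     "rheobase_pA": fi.rheobase, "spike_threshold_mV": thr,
                     "ap_half_width_ms": hw})
    return pd.DataFrame(rows)
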