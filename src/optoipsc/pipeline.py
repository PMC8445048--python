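"""Per-cell session analysis: QC, success rates, normalized amplitude
time courses, latency bins, episode-latency maps and phase summaries.

The quantities mirror the standard presentation of an optogenetic
lateral-inhibition experiment: a per-minute synaptic success rate (fraction
of stimuli followed by at least one detected evoked IPSC), an amplitude
time course normalised to the last five minutes of baseline with each point
an average of six consecutive IPSCs, a three-way latency split
(0-10 / 10-30 / 30-100 ms) separating evoked, secondary and spontaneous
event classes, and per-phase means over fixed five-minute windows
(baseline 10-15, drug 25-30, washout 40-45 min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import EventTable
from .synth import ParameterError, Session


class MissingMetadataError(RuntimeError):
    """Session lacks a QC channel the criteria require."""


class NormalizationError(RuntimeError):
    """No baseline events to normalise against."""


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------

@dataclass
class QCCriteria:
    """Cell-level inclusion rules.

    Reject if access resistance exceeds ``max_access_resistance`` at start or
    end, the input resistance changes by more than ``max_rin_change`` over
    the recording or within any rolling 2-min span (sudden step), or the
    recording is shorter than ``required_minutes``.
    """

    max_access_resistance: float = 22.0   # MOhm
    max_rin_change: float = 0.20          # fraction
    required_minutes: float = 45.0        # min
    sudden_span_minutes: float = 2.0

    def __post_init__(self) -> None:
        if min(self.max_access_resistance, self.max_rin_change,
               self.required_minutes) <= 0:
            raise ParameterError("QC criteria must all be positive")


@dataclass
class PhaseWindows:
    """Five-minute comparison windows, in session minutes."""

    baseline: tuple[float, float] = (10.0, 15.0)
    drug: tuple[float, float] = (25.0, 30.0)
    washout: tuple[float, float] = (40.0, 45.0)

    def __post_init__(self) -> None:
        spans = [self.baseline, self.drug, self.washout]
        for lo, hi in spans:
            if hi <= lo:
                raise ParameterError("phase windows must have positive length")
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ParameterError("phase windows must not overlap")

    def items(self):
        return [("baseline", self.baseline), ("drug", self.drug),
                ("washout", self.washout)]


@dataclass
class LatencyBins:
    """Half-open latency intervals [e0, e1), [e1, e2), ... in ms."""

    edges: tuple[float, ...] = (0.0, 10.0, 30.0, 100.0)

    def __post_init__(self) -> None:
        if self.edges[0] != 0.0 or np.any(np.diff(self.edges) <= 0):
            raise ParameterError("edges must start at 0 and increase strictly")


@dataclass
class QCVerdict:
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class PhaseSummary:
    """Per-cell phase means feeding the statistics layer."""

    cell_id: str
    norm_amplitude: dict[str, float]   # phase -> mean normalized amplitude
    success_rate: dict[str, float]     # phase -> mean success rate
    n_events: dict[str, int]           # phase -> evoked event count
    missing_phases: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_cell(session: Session, criteria: QCCriteria | None = None) -> QCVerdict:
    """Apply the inclusion rules to a session's QC channels."""
    criteria = criteria or QCCriteria()
    qc = session.qc or {}
    for key in ("ra_start_mohm", "ra_end_mohm", "rin_mohm"):
        if key not in qc:
            raise MissingMetadataError(f"session QC lacks {key!r}")
    reasons = []
    ra_s, ra_e = qc["ra_start_mohm"], qc["ra_end_mohm"]
    if ra_s > criteria.max_access_resistance or ra_e > criteria.max_access_resistance:
        reasons.append(
            f"access resistance {max(ra_s, ra_e):.1f} MOhm exceeds "
            f"{criteria.max_access_resistance:.0f} MOhm")
    rin = np.asarray(qc["rin_mohm"], dtype=float)
    if rin.size >= 2 and rin[0] > 0:
        change = abs(rin[-1] - rin[0]) / rin[0]
        if change > criteria.max_rin_change:
            reasons.append(
                f"input resistance changed {change:.0%} over the recording")
        span = max(1, int(round(criteria.sudden_span_minutes)))
        for i in range(rin.size):
            for j in range(i + 1, min(i + span + 1, rin.size)):
                if rin[i] > 0 and abs(rin[j] - rin[i]) / rin[i] > criteria.max_rin_change:
                    reasons.append(
                        f"sudden input-resistance step ({rin[i]:.0f} -> {rin[j]:.0f} "
                        f"MOhm within {span} min)")
                    break
            else:
                continue
            break
    if session.duration_min < criteria.required_minutes:
        reasons.append(
            f"recording lasted {session.duration_min:.0f} min "
            f"(< {criteria.required_minutes:.0f} min)")
    return QCVerdict(passed=not reasons, reasons=reasons)


# ---------------------------------------------------------------------------
# success rate and amplitude time course
# ---------------------------------------------------------------------------

def _event_frame(table: EventTable | pd.DataFrame) -> pd.DataFrame:
    return table.events if isinstance(table, EventTable) else table


def success_rate_per_minute(table: EventTable | pd.DataFrame, session: Session,
                            evoked_window: float = 10.0) -> pd.DataFrame:
    """Fraction of stimuli per minute followed by >= 1 evoked detection.

    A stimulus counts as a success when at least one pass-2 event falls in
    [0, ``evoked_window``) ms after it; at most one success per stimulus.
    Returns a frame with columns minute, n_stimuli, n_success, rate.
    """
    ev = _event_frame(table)
    stims_per_min = 60.0 / session.sweep_len
    n_minutes = int(round(session.duration_min))
    succ = np.zeros(n_minutes)
    nstim = np.zeros(n_minutes)
    for minute in range(n_minutes):
        first = int(round(minute * stims_per_min))
        last = min(int(round((minute + 1) * stims_per_min)), session.n_sweeps)
        nstim[minute] = last - first
        if not ev.empty:
            sel = ev[(ev.sweep >= first) & (ev.sweep < last)
                     & (ev.latency_ms >= 0) & (ev.latency_ms < evoked_window)]
            succ[minute] = sel.sweep.nunique()
    with np.errstate(invalid="ignore"):
        rate = np.where(nstim > 0, succ / np.maximum(nstim, 1), np.nan)
    return pd.DataFrame({"minute": np.arange(n_minutes), "n_stimuli": nstim,
                         "n_success": succ, "rate": rate})


def normalize_amplitude_series(table: EventTable | pd.DataFrame,
                               session: Session,
                               windows: PhaseWindows | None = None,
                               bin_events: int = 6,
                               evoked_window: float = 10.0) -> pd.DataFrame:
    """Amplitude time course in bins of ``bin_events`` consecutive IPSCs,
    normalised against the mean amplitude over the baseline window.

    Only detected evoked events (latency in [0, ``evoked_window``) ms) enter
    the series; failures never contribute zeros. Bins are chronological over
    detected events, so bins with no events simply do not exist. Returns a
    frame with columns time_min (mean event time of the bin), norm_amp, n.
    """
    windows = windows or PhaseWindows()
    ev = _event_frame(table)
    ev = ev[(ev.latency_ms >= 0) & (ev.latency_ms < evoked_window)].copy()
    ev["t_min"] = (ev.sweep * session.sweep_len + ev.onset_s) / 60.0
    ev = ev.sort_values("t_min").reset_index(drop=True)
    b0, b1 = windows.baseline
    base = ev[(ev.t_min >= b0) & (ev.t_min < b1)]
    if base.empty:
        raise NormalizationError("no evoked events in the baseline window")
    base_mean = base.amplitude_pA.mean()
    groups = np.arange(len(ev)) // bin_events
    out = ev.groupby(groups).agg(
        time_min=("t_min", "mean"),
        norm_amp=("amplitude_pA", "mean"),
        n=("amplitude_pA", "size"),
    )
    out["norm_amp"] /= base_mean
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# latency analysis
# ---------------------------------------------------------------------------

def bin_by_latency(table: EventTable | pd.DataFrame,
                   bins: LatencyBins | None = None) -> list[pd.DataFrame]:
    """Split events into half-open latency intervals; >= last edge discarded."""
    bins = bins or LatencyBins()
    ev = _event_frame(table)
    out = []
    for lo, hi in zip(bins.edges, bins.edges[1:]):
        out.append(ev[(ev.latency_ms >= lo) & (ev.latency_ms < hi)].copy())
    return out


def episode_latency_map(table: EventTable | pd.DataFrame, session: Session,
                        latency_interval: tuple[float, float] = (0.0, 10.0)
                        ) -> np.ndarray:
    """Amplitude accumulated at each (episode, latency sample) cell.

    One row per 5-s episode (sweep), one column per acquisition sample of
    the latency interval; zero where no event occurred. Averaging such maps
    across cells makes recurring-latency (time-locked) events dominate,
    while spontaneous events rarely recur at the same latency and average
    toward zero.
    """
    lo, hi = latency_interval
    ev = _event_frame(table)
    fs = session.sample_rate
    n_cols = int(round((hi - lo) * fs / 1000.0))
    out = np.zeros((session.n_sweeps, n_cols))
    sel = ev[(ev.latency_ms >= lo) & (ev.latency_ms < hi)]
    for _, r in sel.iterrows():
        col = int(round((r.latency_ms - lo) * fs / 1000.0))
        if 0 <= col < n_cols:
            out[int(r.sweep), col] += r.amplitude_pA
    return out


# ---------------------------------------------------------------------------
# phase summaries
# ---------------------------------------------------------------------------

def phase_summaries(norm_series: pd.DataFrame, success_series: pd.DataFrame,
                    windows: PhaseWindows | None = None,
                    cell_id: str = "cell") -> PhaseSummary:
    """Per-window means of the normalized amplitude and success-rate series."""
    windows = windows or PhaseWindows()
    norm_amp, success, n_events, missing = {}, {}, {}, []
    for name, (lo, hi) in windows.items():
        nb = norm_series[(norm_series.time_min >= lo) & (norm_series.time_min < hi)]
        sb = success_series[(success_series.minute >= lo) & (success_series.minute < hi)]
        n_events[name] = int(nb["n"].sum()) if not nb.empty else 0
        if nb.empty and sb.empty:
            missing.append(name)
            norm_amp[name] = np.nan
            success[name] = np.nan
            continue
        norm_amp[name] = float(nb.norm_amp.mean()) if not nb.empty else np.nan
        success[name] = float(sb.rate.mean()) if not sb.empty else np.nan
        if nb.empty:
            missing.append(name)
    return PhaseSummary(cell_id=cell_id, norm_amplitude=norm_amp,
                        success_rate=success, n_events=n_events,
                        missing_phases=missing)


def summaries_to_frame(summaries: list[PhaseSummary]) -> pd.DataFrame:
    """Tidy one-row-per-cell-and-phase frame for export and statistics."""
    rows = []
    for s in summaries:
        for phase in s.norm_amplitude:
            rows.append({"cell": s.cell_id, "phase": phase,
                         "norm_amplitude": s.norm_amplitude[phase],
                         "success_rate": s.success_rate[phase],
                         "n_events": s.n_events[phase]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ground-truth matching and release-probability inversion
# ---------------------------------------------------------------------------

def match_events_to_truth(table: EventTable | pd.DataFrame, truth: pd.DataFrame,
                          session: Session, tol_ms: float = 1.0) -> pd.DataFrame:
    """Flag each detection as matched (a truth event within ``tol_ms``) or not."""
    det = _event_frame(table).copy()
    det["matched"] = False
    if det.empty or truth.empty:
        return det
    by_sweep = dict(tuple(truth.groupby("sweep")))
    stim = session.stim_time
    matched = np.zeros(len(det), dtype=bool)
    for i, r in enumerate(det.itertuples()):
        tt = by_sweep.get(int(r.sweep))
        if tt is None:
            continue
        t_det = stim + r.latency_ms / 1000.0
        matched[i] = bool((np.abs(tt["t_sweep_s"].values - t_det) <= tol_ms / 1000.0).any())
    det["matched"] = matched
    return det


def false_positive_rate(table: EventTable | pd.DataFrame, truth: pd.DataFrame,
                        session: Session, tol_ms: float = 1.0) -> tuple[int, int]:
    """(n_false_positive, n_detections) under +/- ``tol_ms`` truth matching."""
    det = match_events_to_truth(table, truth, session, tol_ms)
    return int((~det["matched"]).sum()), len(det)


def release_prob_from_success(success_rate: float, n_connections: int) -> float:
    """Invert S = 1 - (1 - p)^N for the per-connection release probability."""
    if n_connections <= 0:
        raise ParameterError("n_connections must be positive")
    s = min(max(success_rate, 0.0), 1.0 - 1e-12)
    return 1.0 - (1.0 - s) ** (1.0 / n_connections)
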