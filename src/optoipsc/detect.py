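"""Two-pass template-matching detection of IPSCs.

The detector slides a scaled-and-offset prototype waveform (5-ms body
preceded by a 5-ms baseline) along the post-stimulus window of each sweep,
solving the least-squares fit y = s*T + c in closed form at every offset.
Candidate events are local maxima of the fitted-peak amplitude series that
exceed 2.5 times the robust SD of the pre-stimulus noise; events whose
re-measured raw amplitude is below 20 pA are discarded, since such events
cannot be distinguished from noise.

Pass 1 uses a template seeded from the highest signal-to-noise candidates of
the baseline period (an automated stand-in for manual event picking); the
detected events are captured, aligned on their steepest rise, and averaged
into a second template, which is used for the definitive second pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import KernelParams, ParameterError, Session, ipsc_kernel


class DetectionError(RuntimeError):
    """Detection could not proceed (degenerate template, missing seeds...)."""


class InsufficientSeedError(DetectionError):
    """Fewer candidate events than required to seed the first template."""


# ---------------------------------------------------------------------------
# configuration and result containers
# ---------------------------------------------------------------------------

@dataclass
class DetectionConfig:
    """Thresholds and windows of the two-pass detector.

    ``threshold_mult`` scales the robust noise SD into the acceptance
    threshold on the fitted-peak amplitude; ``min_amplitude`` is the raw
    amplitude floor below which events are indistinguishable from noise.
    ``search_window`` is the post-stimulus scan window of the second pass
    (10 ms for the evoked analysis, 100 ms for the latency analysis); the
    first pass always scans the 10-ms evoked window. ``statistic`` selects
    the thresholded quantity: ``"amplitude"`` (fitted peak vs noise SD,
    default) or ``"scale_se"`` (the classical fitted-scale over its standard
    error criterion).
    """

    threshold_mult: float = 2.5
    search_window: float = 10.0        # ms post-stimulus, pass 2
    min_amplitude: float = 20.0        # pA
    noise_window: tuple[float, float] | None = None  # s; default set from stim
    refractory: float = 5.0            # ms
    body_len: float = 5.0              # ms
    baseline_len: float = 5.0          # ms
    n_seed: int = 12
    statistic: str = "amplitude"

    def __post_init__(self) -> None:
        if self.threshold_mult <= 0 or self.search_window <= 0:
            raise ParameterError("threshold_mult and search_window must be positive")
        if self.min_amplitude < 0:
            raise ParameterError("min_amplitude must be >= 0")
        if self.statistic not in ("amplitude", "scale_se"):
            raise ParameterError(f"unknown statistic {self.statistic!r}")

    def noise_interval(self, stim_time: float) -> tuple[float, float]:
        """Noise-estimation window: 0.5 s ending 50 ms before the stimulus."""
        if self.noise_window is not None:
            return self.noise_window
        stop = stim_time - 0.05
        return (max(0.0, stop - 0.5), stop)


@dataclass
class Template:
    """Prototype IPSC waveform: flat baseline segment followed by the body."""

    waveform: np.ndarray
    sample_rate: float
    body_len: float = 5.0       # ms
    baseline_len: float = 5.0   # ms
    source: str = "seeded"

    def __post_init__(self) -> None:
        if self.waveform.size != self.n_baseline + self.n_body:
            raise ParameterError("template length must equal baseline_len + body_len")

    @property
    def n_body(self) -> int:
        return int(round(self.body_len * self.sample_rate / 1000.0))

    @property
    def n_baseline(self) -> int:
        return int(round(self.baseline_len * self.sample_rate / 1000.0))

    @property
    def peak(self) -> float:
        return float(np.max(self.waveform))


@dataclass
class DetectedEvent:
    sweep_index: int
    onset_time: float    # s within sweep, start of the event body
    latency: float       # ms from stimulus onset
    amplitude: float     # pA, raw peak minus local pre-event baseline mean
    fit_scale: float
    pass_id: int


@dataclass
class EventTable:
    """Detected events with the configuration snapshot that produced them."""

    events: pd.DataFrame
    config: DetectionConfig | None = None
    meta: dict = field(default_factory=dict)

    COLUMNS = ["sweep", "onset_s", "latency_ms", "amplitude_pA", "fit_scale", "pass_id"]

    def __post_init__(self) -> None:
        if self.events.empty:
            self.events = pd.DataFrame(columns=self.COLUMNS)
        missing = set(self.COLUMNS) - set(self.events.columns)
        if missing:
            raise ParameterError(f"event table missing columns {sorted(missing)}")
        self.events = self.events.sort_values(["sweep", "onset_s"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.events)


def kernel_template(kernel: KernelParams, sample_rate: float,
                    cfg: DetectionConfig | None = None) -> Template:
    """Canonical unit-peak template built from biexponential kinetics."""
    cfg = cfg or DetectionConfig()
    nb = int(round(cfg.baseline_len * sample_rate / 1000.0))
    nk = int(round(cfg.body_len * sample_rate / 1000.0))
    t = np.arange(nk) / sample_rate * 1000.0
    body = ipsc_kernel(t, kernel, 1.0)
    wav = np.concatenate([np.zeros(nb), body])
    return Template(wav, sample_rate, cfg.body_len, cfg.baseline_len, source="seeded")


# ---------------------------------------------------------------------------
# noise estimation
# ---------------------------------------------------------------------------

def estimate_noise_sd(data: np.ndarray, window: tuple[float, float],
                      sample_rate: float, stim_time: float | None = None) -> float:
    """Robust SD (MAD * 1.4826) of the linearly detrended window.

    The window must precede the stimulus and contain at least 100 samples;
    the median absolute deviation makes the estimate insensitive to the
    occasional spontaneous event inside the window.
    """
    lo, hi = window
    if stim_time is not None and hi > stim_time:
        raise ParameterError("noise window must precede the stimulus")
    i0, i1 = int(round(lo * sample_rate)), int(round(hi * sample_rate))
    seg = np.asarray(data[i0:i1], dtype=float)
    if seg.size < 100:
        raise ParameterError("noise window must contain at least 100 samples")
    x = np.arange(seg.size)
    slope, icept = np.polyfit(x, seg, 1)
    resid = seg - (slope * x + icept)
    return float(np.median(np.abs(resid - np.median(resid))) * 1.4826)


# ---------------------------------------------------------------------------
# sliding least-squares template fit
# ---------------------------------------------------------------------------

def template_fit_scan(data: np.ndarray, template: Template,
                      window: tuple[int, int]) -> dict[str, np.ndarray]:
    """Closed-form fit of y = s*T + c at every sample offset in ``window``.

    ``window`` is the (start, stop) sample range of allowed template offsets
    (offset = first sample of the full template, baseline included). Returns
    the scale, offset, fitted-peak amplitude (scale * template peak) and
    residual-based scale standard error series, each of length stop - start.
    """
    T = np.asarray(template.waveform, dtype=float)
    L = T.size
    k0, k1 = window
    data = np.asarray(data, dtype=float)
    if k1 + L - 1 > data.size or k0 < 0 or k1 <= k0:
        raise ParameterError("scan window (plus template length) must fit in the sweep")

    sT = T.sum()
    sTT = float(T @ T)
    denom = L * sTT - sT * sT
    if denom <= 1e-12 * max(1.0, sTT) * L:
        raise DetectionError("degenerate template (constant or zero waveform)")

    seg = data[k0: k1 + L - 1]
    # sliding sums via correlation / cumulative sum
    sTy = np.correlate(seg, T, mode="valid")
    csum = np.concatenate([[0.0], np.cumsum(seg)])
    sy = csum[L:] - csum[:-L]
    csum2 = np.concatenate([[0.0], np.cumsum(seg * seg)])
    syy = csum2[L:] - csum2[:-L]

    scale = (L * sTy - sT * sy) / denom
    offset = (sy - scale * sT) / L
    # SSE = yy - s*Ty - c*y (normal-equation identity)
    sse = np.maximum(syy - scale * sTy - offset * sy, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale_se = np.sqrt(sse / max(L - 2, 1) * L / denom)
    return {
        "scale": scale,
        "offset": offset,
        "amp": scale * template.peak,
        "scale_se": scale_se,
        "start": k0,
    }


def detect_events(sweep_data: np.ndarray, template: Template, cfg: DetectionConfig,
                  sample_rate: float, stim_time: float, sweep_index: int = 0,
                  pass_id: int = 1, search_window: float | None = None,
                  noise_sd: float | None = None) -> list[DetectedEvent]:
    """Single-pass detection in the post-stimulus window of one sweep.

    Accepts offsets where the fitted-peak amplitude is a local maximum of
    the fit series and exceeds ``threshold_mult`` times the noise SD,
    enforces the refractory spacing (greedy, largest first), re-measures the
    amplitude as the raw-data peak over the event body relative to the mean
    of the 5-ms pre-event baseline, and applies the ``min_amplitude`` floor.
    """
    win_ms = search_window if search_window is not None else cfg.search_window
    nb, nk = template.n_baseline, template.n_body
    stim_idx = int(round(stim_time * sample_rate))
    # allow the event body to start anywhere in [stim, stim + window)
    k0 = stim_idx - nb
    k1 = stim_idx - nb + int(round(win_ms * sample_rate / 1000.0))
    k1 = min(k1, sweep_data.size - (nb + nk) + 1)
    if k1 <= k0:
        return []

    if noise_sd is None:
        noise_sd = estimate_noise_sd(sweep_data, cfg.noise_interval(stim_time),
                                     sample_rate, stim_time)
    fit = template_fit_scan(sweep_data, template, (k0, k1))
    amp = fit["amp"]

    if cfg.statistic == "amplitude":
        stat, thresh = amp, cfg.threshold_mult * noise_sd
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(fit["scale_se"] > 0, fit["scale"] / fit["scale_se"], 0.0)
        thresh = cfg.threshold_mult

    # strict local maxima of the thresholded statistic
    cand = np.flatnonzero(
        (stat >= thresh)
        & (stat > np.roll(stat, 1)) & (stat >= np.roll(stat, -1))
    )
    cand = cand[(cand > 0) & (cand < stat.size - 1)]
    if cand.size == 0:
        return []

    # refractory suppression, largest statistic first
    refr = int(round(cfg.refractory * sample_rate / 1000.0))
    order = cand[np.argsort(stat[cand])[::-1]]
    kept: list[int] = []
    for k in order:
        if all(abs(k - j) >= refr for j in kept):
            kept.append(int(k))

    body = template.waveform[nb:]
    pk_off = int(np.argmax(body)) if body.size else 0
    events = []
    for k in sorted(kept):
        onset = k0 + k + nb                       # body start, samples
        base_lo = max(0, onset - nb)
        baseline = float(np.mean(sweep_data[base_lo:onset])) if onset > base_lo else 0.0
        # raw peak read at the fitted peak position (3-sample mean) so the
        # measurement is not biased upward by the max of the noise
        j = min(onset + pk_off, sweep_data.size - 2)
        peak = float(np.mean(sweep_data[max(j - 1, 0): j + 2]))
        amplitude = peak - baseline
        if amplitude < cfg.min_amplitude:
            continue
        events.append(DetectedEvent(
            sweep_index=sweep_index,
            onset_time=onset / sample_rate,
            latency=(onset - stim_idx) / sample_rate * 1000.0,
            amplitude=amplitude,
            fit_scale=float(fit["scale"][k]),
            pass_id=pass_id,
        ))
    return events


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _extract_segment(data: np.ndarray, onset: int, nb: int, nk: int) -> np.ndarray | None:
    lo, hi = onset - nb, onset + nk
    if lo < 0 or hi > data.size:
        return None
    return np.asarray(data[lo:hi], dtype=float)


def _align_and_average(segments: list[np.ndarray], nb: int, nk: int) -> np.ndarray:
    """Align segments on the steepest rise within the body and average.

    The first difference is lightly smoothed (11-sample boxcar) before the
    argmax so alignment jitter stays within about a sample on noisy events.
    """
    win = 11
    box = np.ones(win) / win
    rises = []
    for seg in segments:
        d = np.diff(seg[nb: nb + nk])
        if d.size >= win:
            d = np.convolve(d, box, mode="same")
        rises.append(int(np.argmax(d)) if d.size else 0)
    ref = int(np.median(rises))
    acc = np.zeros(nb + nk)
    cnt = np.zeros(nb + nk)
    for seg, r in zip(segments, rises):
        shift = ref - r
        lo_dst, hi_dst = max(0, shift), min(seg.size, seg.size + shift)
        lo_src, hi_src = max(0, -shift), min(seg.size, seg.size - shift)
        acc[lo_dst:hi_dst] += seg[lo_src:hi_src]
        cnt[lo_dst:hi_dst] += 1
    cnt[cnt == 0] = 1
    return acc / cnt


def build_initial_template(session: Session, cfg: DetectionConfig | None = None,
                           canon: KernelParams | None = None,
                           n_seed: int | None = None,
                           baseline_sweeps: int | None = None) -> Template:
    """Seed template from the strongest baseline-period candidates.

    Automated stand-in for manual event identification: the evoked window of
    each baseline sweep is scanned with a canonical biexponential matched
    template, candidates are ranked by fitted amplitude over noise SD, the
    top ``n_seed`` are aligned and averaged, and the baseline segment is
    zeroed (mean removal).
    """
    cfg = cfg or DetectionConfig()
    canon = canon or KernelParams()
    n_seed = n_seed if n_seed is not None else cfg.n_seed
    seed_tpl = kernel_template(canon, session.sample_rate, cfg)
    nb, nk = seed_tpl.n_baseline, seed_tpl.n_body

    n_base = baseline_sweeps if baseline_sweeps is not None else session.n_sweeps
    candidates: list[tuple[float, int, int]] = []  # (snr, sweep, onset)
    for sw in range(min(n_base, session.n_sweeps)):
        data = session.sweeps[sw]
        noise_sd = estimate_noise_sd(data, cfg.noise_interval(session.stim_time),
                                     session.sample_rate, session.stim_time)
        if noise_sd <= 0:
            noise_sd = np.inf
        for ev in detect_events(data, seed_tpl, cfg, session.sample_rate,
                                session.stim_time, sw, pass_id=1,
                                search_window=10.0, noise_sd=noise_sd):
            onset = int(round(ev.onset_time * session.sample_rate))
            candidates.append((ev.amplitude / noise_sd, sw, onset))

    if len(candidates) < n_seed:
        raise InsufficientSeedError(
            f"found {len(candidates)} seed candidates, need {n_seed}")
    candidates.sort(reverse=True)
    segments = []
    for _, sw, onset in candidates[:n_seed]:
        seg = _extract_segment(session.sweeps[sw], onset, nb, nk)
        if seg is not None:
            segments.append(seg)
    wav = _align_and_average(segments, nb, nk)
    wav -= wav[:nb].mean()
    wav[:nb] = 0.0
    return Template(wav, session.sample_rate, cfg.body_len, cfg.baseline_len,
                    source="seeded")


def refine_template(events: list[DetectedEvent] | pd.DataFrame, session: Session,
                    cfg: DetectionConfig | None = None) -> Template:
    """Second template: time-course average of captured, aligned events."""
    cfg = cfg or DetectionConfig()
    fs = session.sample_rate
    nb = int(round(cfg.baseline_len * fs / 1000.0))
    nk = int(round(cfg.body_len * fs / 1000.0))
    if isinstance(events, pd.DataFrame):
        pairs = list(zip(events["sweep"].astype(int), events["onset_s"]))
    else:
        pairs = [(ev.sweep_index, ev.onset_time) for ev in events]
    if not pairs:
        raise DetectionError("cannot refine template from an empty event list")
    segments = []
    for sw, onset_s in pairs:
        seg = _extract_segment(session.sweeps[sw], int(round(onset_s * fs)), nb, nk)
        if seg is not None:
            segments.append(seg)
    if not segments:
        raise DetectionError("no extractable event segments")
    wav = _align_and_average(segments, nb, nk)
    wav -= wav[:nb].mean()
    wav[:nb] = 0.0
    return Template(wav, fs, cfg.body_len, cfg.baseline_len,
                    source="first_pass_average")


# ---------------------------------------------------------------------------
# two-pass orchestration
# ---------------------------------------------------------------------------

def two_pass_detect(session: Session, cfg: DetectionConfig | None = None,
                    canon: KernelParams | None = None,
                    baseline_sweeps: int | None = None) -> EventTable:
    """Full two-pass detection over a session; pass-2 events are returned.

    Pass 1 scans the 10-ms evoked window with the seeded template; the
    aligned average of its detections forms the second template, which is
    scanned over ``cfg.search_window`` in every sweep (pass 2).
    """
    cfg = cfg or DetectionConfig()
    tpl1 = build_initial_template(session, cfg, canon,
                                  baseline_sweeps=baseline_sweeps)
    pass1: list[DetectedEvent] = []
    fs, stim = session.sample_rate, session.stim_time
    noise_cache = np.empty(session.n_sweeps)
    for sw in range(session.n_sweeps):
        noise_cache[sw] = estimate_noise_sd(
            session.sweeps[sw], cfg.noise_interval(stim), fs, stim)
        pass1.extend(detect_events(session.sweeps[sw], tpl1, cfg, fs, stim, sw,
                                   pass_id=1, search_window=10.0,
                                   noise_sd=noise_cache[sw]))
    if not pass1:
        return EventTable(pd.DataFrame(columns=EventTable.COLUMNS), cfg,
                          meta={"template_source": tpl1.source, "n_pass1": 0})
    tpl2 = refine_template(pass1, session, cfg)
    rows = []
    for sw in range(session.n_sweeps):
        for ev in detect_events(session.sweeps[sw], tpl2, cfg, fs, stim, sw,
                                pass_id=2, noise_sd=noise_cache[sw]):
            rows.append((ev.sweep_index, ev.onset_time, ev.latency,
                         ev.amplitude, ev.fit_scale, ev.pass_id))
    table = pd.DataFrame(rows, columns=EventTable.COLUMNS)
    return EventTable(table, cfg, meta={"template_source": tpl2.source,
                                        "n_pass1": len(pass1)})
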