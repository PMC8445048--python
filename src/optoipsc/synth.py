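"""Synthetic voltage-clamp sessions and current-clamp step families.

The generator emulates an optogenetic lateral-inhibition experiment in
striatal spiny projection neurons: repeated 5-s voltage-clamp sweeps with a
single light stimulus 1 s into each sweep, compound IPSCs built from a small
number of presynaptic connections that each release a quantum with some
probability per stimulus, delayed "secondary" release, spontaneous Poisson
events, and Gaussian recording noise shaped by a 4-pole Bessel low-pass.
A session-long drug protocol (5-HT1B agonist, agonist+antagonist, TTX, or
no drug) modulates release probability with exponential onset and washout.

Ground truth for every inserted event is recorded, so the downstream
detector and statistics layers can be validated without recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal


class ParameterError(ValueError):
    """Invalid generator or analysis parameter."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class KernelParams:
    """Biexponential IPSC kinetics.

    The field default (0.5 ms rise, 8 ms decay) mimics a sharp, short-latency
    IPSC with a prolonged decay, as produced by a high-chloride internal
    solution. ``sign`` is a session-level polarity flag; amplitudes are
    handled as positive magnitudes throughout.
    """

    tau_rise: float = 0.5    # ms
    tau_decay: float = 8.0   # ms
    sign: str = "outward"

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ParameterError(
                f"require 0 < tau_rise < tau_decay, got {self.tau_rise}, {self.tau_decay}"
            )
        if self.sign not in ("inward", "outward"):
            raise ParameterError(f"unknown sign {self.sign!r}")

    @property
    def peak_time(self) -> float:
        """Closed-form time of the biexponential peak, in ms."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * np.log(td / tr)


@dataclass
class ConnectionParams:
    """Presynaptic connection ensemble releasing onto the recorded cell.

    ``n_connections`` presynaptic neurons each release one quantum with
    probability ``release_prob`` per light stimulus. Quantal amplitudes are
    lognormal (positive by construction) with the stated mean and CV;
    ``quantal_amp_min`` optionally truncates the draw from below. Each
    connection draws a fixed latency mean (normal around ``latency_mean``
    with SD ``latency_spread_sd``) and jitters it sweep-to-sweep by
    ``latency_jitter_sd``. ``secondary_prob`` governs delayed release in the
    ``secondary_latency_range`` window (attributed to secondary presynaptic
    spikes), scaled by the drug multiplier exactly as evoked release is.
    """

    n_connections: int = 4
    release_prob: float = 0.3
    quantal_amp_mean: float = 60.0   # pA
    quantal_amp_cv: float = 0.4
    quantal_amp_min: float = 0.0     # pA, lower truncation of the draw
    latency_mean: float = 4.0        # ms
    latency_spread_sd: float = 1.0   # ms, per-connection draw
    latency_jitter_sd: float = 0.3   # ms, per-sweep
    secondary_prob: float = 0.1
    secondary_latency_range: tuple[float, float] = (10.0, 30.0)

    def __post_init__(self) -> None:
        if self.n_connections < 0:
            raise ParameterError("n_connections must be >= 0")
        if not 0.0 <= self.release_prob <= 1.0:
            raise ParameterError("release_prob must lie in [0, 1]")
        if self.quantal_amp_mean <= 0:
            raise ParameterError("quantal_amp_mean must be positive")
        if not 0.0 < self.latency_mean < 10.0:
            raise ParameterError("latency_mean must lie in the evoked window (0, 10) ms")
        lo, hi = self.secondary_latency_range
        if not (10.0 <= lo < hi <= 30.0):
            raise ParameterError("secondary_latency_range must lie within (10, 30) ms")


@dataclass
class DrugProtocol:
    """Bath-application schedule and its effect on release probability.

    The drug effect e(t) rises from 0 toward 1 with time constant
    ``onset_tau`` after ``t_on`` and relaxes back with ``washout_tau`` after
    ``t_off``. The release multiplier is m(t) = 1 - (1 - residual) * e(t).
    ``agonist_plus_antagonist`` and ``none`` force m == 1. For ``ttx`` the
    block is treated as all-or-none axonal AP failure: once e(t) comes
    within exp(-5) of complete effect the multiplier snaps to exactly 0, and
    the spontaneous (AP-dependent) rate is scaled by the same multiplier.

    ``quantal_scale_fraction`` optionally co-modulates quantal size with the
    same time course (default 1: release probability only).
    """

    drug_kind: str = "agonist"
    t_on: float = 15.0        # min
    t_off: float = 30.0       # min
    residual_release_fraction: float = 0.1
    onset_tau: float = 1.25   # min; visible effect at 2-3 min
    washout_tau: float = 5.0  # min
    quantal_scale_fraction: float = 1.0

    KINDS = ("agonist", "agonist_plus_antagonist", "ttx", "none")

    def __post_init__(self) -> None:
        if self.drug_kind not in self.KINDS:
            raise ParameterError(f"unknown drug_kind {self.drug_kind!r}")
        if not 0.0 <= self.t_on < self.t_off:
            raise ParameterError("require 0 <= t_on < t_off")
        if not 0.0 <= self.residual_release_fraction <= 1.0:
            raise ParameterError("residual_release_fraction must lie in [0, 1]")
        if self.onset_tau <= 0 or self.washout_tau <= 0:
            raise ParameterError("onset_tau and washout_tau must be positive")

    def effect(self, t_min: float) -> float:
        """Drug effect e(t) in [0, 1] at session time ``t_min`` minutes."""
        if self.drug_kind in ("none", "agonist_plus_antagonist"):
            return 0.0
        if t_min < self.t_on:
            return 0.0
        if t_min < self.t_off:
            e = 1.0 - np.exp(-(t_min - self.t_on) / self.onset_tau)
        else:
            e_off = 1.0 - np.exp(-(self.t_off - self.t_on) / self.onset_tau)
            e = e_off * np.exp(-(t_min - self.t_off) / self.washout_tau)
        if self.drug_kind == "ttx" and e > 1.0 - np.exp(-5.0):
            # all-or-none AP block: complete at depths beyond 5 onset taus
            e = 1.0
        return float(e)

    def release_multiplier(self, t_min: float) -> float:
        r = 0.0 if self.drug_kind == "ttx" else self.residual_release_fraction
        return 1.0 - (1.0 - r) * self.effect(t_min)

    def quantal_multiplier(self, t_min: float) -> float:
        return 1.0 - (1.0 - self.quantal_scale_fraction) * self.effect(t_min)


@dataclass
class SessionConfig:
    """Acquisition settings for one simulated voltage-clamp session."""

    duration: float = 60.0          # min
    sweep_len: float = 5.0          # s
    stim_time: float = 1.0          # s within sweep
    stim_duration: float = 2.0      # ms (2 or 5)
    sample_rate: float = 20000.0    # Hz
    lowpass_cutoff: float = 4000.0  # Hz
    noise_sd: float = 5.0           # pA, SD of the filtered noise
    spont_rate: float = 1.0         # Hz, Poisson over the whole sweep
    seed: int = 0
    render: bool = True             # False: ground truth only, no traces
    # QC channel emulation (access/input resistance readings)
    ra_start_mohm: float = 15.0
    ra_end_mohm: float = 16.0
    rin_start_mohm: float = 100.0
    rin_drift_frac: float = 0.05    # total fractional Rin drift over the session

    def __post_init__(self) -> None:
        if self.sample_rate <= 2 * self.lowpass_cutoff:
            raise ParameterError("sample_rate must exceed twice lowpass_cutoff")
        if self.stim_time + 0.1 >= self.sweep_len:
            raise ParameterError("stimulus must fall at least 0.1 s before the sweep end")

    @property
    def n_sweeps(self) -> int:
        return int(round(self.duration * 60.0 / self.sweep_len))

    @property
    def n_samples(self) -> int:
        return int(round(self.sweep_len * self.sample_rate))


# ---------------------------------------------------------------------------
# session containers
# ---------------------------------------------------------------------------

@dataclass
class Sweep:
    """One acquisition sweep: current (pA) on a uniform time grid."""

    data: np.ndarray
    sample_rate: float
    stim_time: float
    index: int = 0


@dataclass
class Session:
    """Ordered sweeps from one cell plus acquisition and QC metadata.

    ``sweeps`` is an (n_sweeps, n_samples) array of membrane current in pA,
    stored with positive-going IPSC deflections; ``polarity`` records the
    original recorded sign. ``qc`` holds the access-resistance readings at
    start/end and the per-minute input-resistance series the QC rules need.
    """

    sweeps: np.ndarray | None
    sample_rate: float
    sweep_len: float
    stim_time: float
    polarity: str = "outward"
    qc: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_sweeps(self) -> int:
        if self.sweeps is not None:
            return self.sweeps.shape[0]
        return int(self.meta.get("n_sweeps", 0))

    @property
    def duration_min(self) -> float:
        return self.n_sweeps * self.sweep_len / 60.0

    def sweep(self, i: int) -> Sweep:
        if self.sweeps is None:
            raise ValueError("session carries no rendered traces")
        return Sweep(self.sweeps[i], self.sample_rate, self.stim_time, i)


@dataclass
class SyntheticSession(Session):
    """Session with generator ground truth attached.

    ``truth`` has one row per inserted event: sweep index, time within the
    sweep (s), latency from the stimulus (ms; NaN for spontaneous events),
    amplitude (pA) and class (evoked / secondary / spontaneous).
    """

    truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    config: SessionConfig | None = None
    protocol: DrugProtocol | None = None
    connections: ConnectionParams | None = None
    kernel: KernelParams | None = None


TRUTH_COLUMNS = ["sweep", "t_sweep_s", "latency_ms", "amplitude_pA", "kind"]


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def ipsc_kernel(t: np.ndarray, params: KernelParams, amplitude: float) -> np.ndarray:
    """Biexponential IPSC waveform on time grid ``t`` (ms), peak = ``amplitude``.

    Shape is exp(-t/tau_decay) - exp(-t/tau_rise), zero at t = 0, normalised
    so the continuous-time peak equals ``amplitude`` exactly.
    """
    t = np.asarray(t, dtype=float)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
        raise ParameterError("time grid must be nonnegative and strictly increasing")
    tr, td = params.tau_rise, params.tau_decay
    raw = np.exp(-t / td) - np.exp(-t / tr)
    tpk = params.peak_time
    peak = np.exp(-tpk / td) - np.exp(-tpk / tr)
    return amplitude * raw / peak


def _bessel_sos(config: SessionConfig):
    return signal.bessel(4, config.lowpass_cutoff, fs=config.sample_rate, output="sos")


def _noise_gain(config: SessionConfig) -> float:
    """SD ratio (out/in) of white noise through the Bessel low-pass."""
    sos = _bessel_sos(config)
    w, h = signal.sosfreqz(sos, worN=8192, fs=config.sample_rate)
    return float(np.sqrt(np.mean(np.abs(h) ** 2)))


# ---------------------------------------------------------------------------
# voltage-clamp session generator
# ---------------------------------------------------------------------------

def _draw_amplitudes(rng: np.random.Generator, n: int, conn: ConnectionParams,
                     qmult: float) -> np.ndarray:
    """Lognormal quantal amplitudes with stated mean/CV, truncated from below."""
    cv = conn.quantal_amp_cv
    sigma2 = np.log(1.0 + cv * cv)
    mu = np.log(conn.quantal_amp_mean) - sigma2 / 2.0
    amps = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    if conn.quantal_amp_min > 0:
        amps = np.maximum(amps, conn.quantal_amp_min)
    return amps * qmult


def simulate_vc_session(config: SessionConfig,
                        conn: ConnectionParams | None = None,
                        protocol: DrugProtocol | None = None,
                        kernel: KernelParams | None = None) -> SyntheticSession:
    """Simulate one voltage-clamp session with ground truth.

    Per sweep, each connection releases with probability
    ``release_prob * m(t)`` where m(t) is the drug multiplier; secondary
    release is scaled identically; spontaneous events are homogeneous
    Poisson over the full sweep and unmodulated by the agonist (but
    abolished by TTX along with everything else). Recording noise is
    Gaussian, shaped by a 4-pole Bessel low-pass and scaled so the trace
    noise SD equals ``config.noise_sd`` after filtering.
    """
    conn = conn if conn is not None else ConnectionParams()
    protocol = protocol if protocol is not None else DrugProtocol(drug_kind="none")
    kernel = kernel if kernel is not None else KernelParams()
    rng = np.random.default_rng(config.seed)

    n_sweeps, n_samp, fs = config.n_sweeps, config.n_samples, config.sample_rate
    stim_idx = int(round(config.stim_time * fs))

    # fixed per-connection latency means, one draw per session
    conn_lat = rng.normal(conn.latency_mean, conn.latency_spread_sd, size=conn.n_connections)
    conn_lat = np.clip(conn_lat, 0.5, 9.0)

    # kernel lookup covering ~10 decay constants
    klen = int(round(10.0 * kernel.tau_decay * fs / 1000.0))
    kt = np.arange(klen) / fs * 1000.0
    kshape = ipsc_kernel(kt, kernel, 1.0).astype(np.float32)

    rows: list[tuple] = []
    sweeps = np.zeros((n_sweeps, n_samp), dtype=np.float32) if config.render else None

    def insert(sw: int, idx: int, amp: float) -> None:
        if sweeps is None:
            return
        stop = min(idx + klen, n_samp)
        if idx < n_samp:
            sweeps[sw, idx:stop] += amp * kshape[: stop - idx]

    for sw in range(n_sweeps):
        t_min = sw * config.sweep_len / 60.0
        m = protocol.release_multiplier(t_min)
        qmult = protocol.quantal_multiplier(t_min)

        if conn.n_connections:
            rel = rng.random(conn.n_connections) < conn.release_prob * m
            n_rel = int(rel.sum())
            if n_rel:
                lats = conn_lat[rel] + rng.normal(0.0, conn.latency_jitter_sd, size=n_rel)
                lats = np.clip(lats, 0.3, 9.99)
                amps = _draw_amplitudes(rng, n_rel, conn, qmult)
                for lat, amp in zip(lats, amps):
                    t_ev = config.stim_time + lat / 1000.0
                    insert(sw, int(round(t_ev * fs)), amp)
                    rows.append((sw, t_ev, lat, amp, "evoked"))
            sec = rng.random(conn.n_connections) < conn.secondary_prob * m
            n_sec = int(sec.sum())
            if n_sec:
                lo, hi = conn.secondary_latency_range
                lats = rng.uniform(lo, hi, size=n_sec)
                amps = _draw_amplitudes(rng, n_sec, conn, qmult)
                for lat, amp in zip(lats, amps):
                    t_ev = config.stim_time + lat / 1000.0
                    insert(sw, int(round(t_ev * fs)), amp)
                    rows.append((sw, t_ev, lat, amp, "secondary"))

        spont_rate = config.spont_rate * (m if protocol.drug_kind == "ttx" else 1.0)
        n_spont = rng.poisson(spont_rate * config.sweep_len)
        if n_spont:
            times = np.sort(rng.uniform(0.0, config.sweep_len, size=n_spont))
            amps = _draw_amplitudes(rng, n_spont, conn, 1.0)
            for t_ev, amp in zip(times, amps):
                lat = (t_ev - config.stim_time) * 1000.0
                insert(sw, int(round(t_ev * fs)), amp)
                rows.append((sw, t_ev, lat if lat >= 0 else np.nan, amp, "spontaneous"))

    if sweeps is not None and config.noise_sd > 0:
        sos = _bessel_sos(config).astype(np.float32)
        scale = np.float32(config.noise_sd / _noise_gain(config))
        zi = np.zeros((sos.shape[0], 2), dtype=np.float32)
        chunk = max(1, int(10_000_000 // n_samp))
        for lo in range(0, n_sweeps, chunk):
            hi = min(lo + chunk, n_sweeps)
            white = rng.standard_normal((hi - lo) * n_samp, dtype=np.float32) * scale
            filt, zi = signal.sosfilt(sos, white, zi=zi)
            sweeps[lo:hi] += filt.reshape(hi - lo, n_samp)

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    minutes = np.arange(int(np.ceil(config.duration)))
    rin = config.rin_start_mohm * (
        1.0 - config.rin_drift_frac * minutes / max(config.duration - 1.0, 1.0)
    )
    qc = {
        "ra_start_mohm": config.ra_start_mohm,
        "ra_end_mohm": config.ra_end_mohm,
        "rin_mohm": rin,
    }
    return SyntheticSession(
        sweeps=sweeps, sample_rate=fs, sweep_len=config.sweep_len,
        stim_time=config.stim_time, polarity=kernel.sign, qc=qc,
        meta={"n_sweeps": n_sweeps, "seed": config.seed},
        truth=truth, config=config, protocol=protocol, connections=conn,
        kernel=kernel,
    )


# ---------------------------------------------------------------------------
# current-clamp step generator
# ---------------------------------------------------------------------------

@dataclass
class NeuronStepConfig:
    """Phenomenological SPN model for current-clamp step families.

    Subthreshold voltage follows Ohm's law around rest, with the slope
    reduced by ``rectification_factor`` below -90 mV (inward rectification).
    Suprathreshold steps emit regular spikes at ``fi_slope * (I - rheobase)``
    rendered as stereotyped triangular action potentials: rise slope
    ``ap_rise_slope`` from ``spike_threshold`` to ``ap_peak``, with the fall
    slope chosen so the width at half of (peak - threshold) equals
    ``ap_half_width``. This is deliberately not a conductance-based model;
    it exists to give the extraction operations known ground truth.
    """

    membrane_resistance: float = 100.0   # MOhm
    resting_potential: float = -80.0     # mV
    rheobase: float = 200.0              # pA
    fi_slope: float = 0.05               # Hz/pA
    spike_threshold: float = -56.0       # mV
    rectification_factor: float = 0.6    # slope gain below -90 mV
    ap_peak: float = 30.0                # mV
    ap_rise_slope: float = 100.0         # mV/ms
    ap_half_width: float = 1.2           # ms
    membrane_tau: float = 10.0           # ms, charging time constant

    def __post_init__(self) -> None:
        if self.membrane_resistance <= 0:
            raise ParameterError("membrane_resistance must be positive")
        if self.rheobase < 0:
            raise ParameterError("rheobase must be >= 0")
        amp = self.ap_peak - self.spike_threshold
        if 2.0 * self.ap_half_width / amp <= 1.0 / self.ap_rise_slope:
            raise ParameterError("ap_half_width too small for the given rise slope")

    @property
    def ap_fall_slope(self) -> float:
        amp = self.ap_peak - self.spike_threshold
        return 1.0 / (2.0 * self.ap_half_width / amp - 1.0 / self.ap_rise_slope)


@dataclass
class StepRecording:
    """Family of current-clamp step responses, one voltage trace per current."""

    traces: np.ndarray          # (n_steps, n_samples) mV
    currents: np.ndarray        # pA, strictly increasing
    sample_rate: float
    step_window: tuple[float, float]   # s, (start, stop) of the step
    spike_times: list[np.ndarray] = field(default_factory=list)  # generator truth, s

    def __post_init__(self) -> None:
        if len(self.traces) != len(self.currents):
            raise ParameterError("one trace per current required")
        if np.any(np.diff(self.currents) <= 0):
            raise ParameterError("currents must be strictly increasing")


def _ap_waveform(neuron: NeuronStepConfig, base: float, fs: float) -> tuple[np.ndarray, int]:
    """Stereotyped AP starting at ``base`` mV: slow foot to threshold, fast
    triangular spike, return to base. Returns (waveform, fast-rise onset
    sample), the onset being what a dV/dt spike detector reports."""
    dt = 1000.0 / fs  # ms per sample
    thr, peak = neuron.spike_threshold, neuron.ap_peak
    foot = np.arange(base, thr, 4.0 * dt) if thr > base else np.array([])
    rise = np.arange(thr, peak, neuron.ap_rise_slope * dt)
    fall = np.arange(peak, base, -neuron.ap_fall_slope * dt)
    return np.concatenate([foot, rise, fall, [base]]), foot.size


def subthreshold_voltage(neuron: NeuronStepConfig, current_pa: float) -> float:
    """Steady-state voltage for a subthreshold step (piecewise-linear I-V)."""
    r_gohm = neuron.membrane_resistance / 1000.0  # mV/pA
    v = neuron.resting_potential + current_pa * r_gohm
    if v < -90.0:
        i_break = (-90.0 - neuron.resting_potential) / r_gohm
        v = -90.0 + (current_pa - i_break) * r_gohm * neuron.rectification_factor
    return v


def simulate_cc_steps(neuron: NeuronStepConfig, steps: list[float],
                      step_len: float = 1.0, sample_rate: float = 20000.0,
                      pre_len: float = 0.2, post_len: float = 0.2) -> StepRecording:
    """Current-clamp step family with known passive and firing properties."""
    steps = np.asarray(sorted(steps), dtype=float)
    if steps.size == 0:
        raise ParameterError("step list must be non-empty")
    fs = sample_rate
    n_total = int(round((pre_len + step_len + post_len) * fs))
    i0, i1 = int(round(pre_len * fs)), int(round((pre_len + step_len) * fs))
    t_rel = np.arange(i1 - i0) / fs * 1000.0  # ms within step

    traces = np.empty((steps.size, n_total))
    spike_times: list[np.ndarray] = []
    for j, cur in enumerate(steps):
        v = np.full(n_total, neuron.resting_potential)
        suprathreshold = cur >= neuron.rheobase and cur > 0
        if suprathreshold:
            v_ss = neuron.spike_threshold - 2.0  # depolarised plateau
        else:
            v_ss = subthreshold_voltage(neuron, cur)
        v[i0:i1] = v_ss + (neuron.resting_potential - v_ss) * np.exp(-t_rel / neuron.membrane_tau)
        t_post = np.arange(n_total - i1) / fs * 1000.0
        v[i1:] = neuron.resting_potential + (v_ss - neuron.resting_potential) * np.exp(
            -t_post / neuron.membrane_tau)

        times = np.array([])
        if suprathreshold:
            rate = neuron.fi_slope * (cur - neuron.rheobase)
            # at least one spike at or above rheobase, by definition
            n_spk = max(int(np.floor(rate * step_len + 1e-9)), 1)
            rate = max(rate, n_spk / step_len)
            if n_spk:
                nominal = pre_len + (np.arange(n_spk) + 0.5) / rate
                ap, onset = _ap_waveform(neuron, v_ss, fs)
                times = np.empty(n_spk)
                for m, ts in enumerate(nominal):
                    k = int(round(ts * fs))
                    stop = min(k + ap.size, i1)
                    v[k:stop] = ap[: stop - k]
                    times[m] = (k + onset) / fs
        spike_times.append(times)
        traces[j] = v
    return StepRecording(traces=traces, currents=steps, sample_rate=fs,
                         step_window=(pre_len, pre_len + step_len),
                         spike_times=spike_times)


# ---------------------------------------------------------------------------
# optical-protocol arithmetic
# ---------------------------------------------------------------------------

def compute_irradiance(power_w: float, area_mm2: float) -> float:
    """Irradiance in mW/mm^2 from light power (W) and illuminated area (mm^2),
    rounded to 2 decimals for reporting."""
    if power_w < 0:
        raise ParameterError("power must be >= 0")
    if area_mm2 <= 0:
        raise ParameterError("area must be positive")
    return round(power_w * 1000.0 / area_mm2, 2)


def apply_nd_filter(irradiance_mw_mm2: float, transmission: float) -> float:
    """Attenuate an irradiance by a neutral-density filter transmission."""
    if not 0.0 <= transmission <= 1.0:
        raise ParameterError("transmission must lie in [0, 1]")
    return round(irradiance_mw_mm2 * transmission, 2)
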