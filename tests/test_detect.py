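"""Detector checks: noise estimation, sliding least-squares fit against a
brute-force oracle, event detection round trips, template building and the
two-pass procedure's recall / false-positive behaviour."""

import numpy as np
import pytest

from optoipsc import (ConnectionParams, DetectionConfig, DetectionError,
                      InsufficientSeedError, KernelParams, ParameterError,
                      SessionConfig, Template, build_initial_template,
                      detect_events, estimate_noise_sd, false_positive_rate,
                      ipsc_kernel, kernel_template, refine_template,
                      simulate_vc_session, template_fit_scan, two_pass_detect)
from optoipsc.detect import _align_and_average

FS = 20000.0


class TestNoiseSd:
    def test_constant_trace_gives_zero(self):
        sd = estimate_noise_sd(np.full(20000, 3.0), (0.0, 0.5), FS)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_noise_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 5.0, 10000)
        assert estimate_noise_sd(x, (0.0, 0.5), FS) == pytest.approx(5.0, rel=0.05)

    def test_robust_to_injected_event(self, kernel):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 5.0, 10000)
        t = np.arange(80) / FS * 1000.0
        x[5000:5080] += ipsc_kernel(t, kernel, 100.0)
        assert estimate_noise_sd(x, (0.0, 0.5), FS) == pytest.approx(5.0, rel=0.10)

    def test_window_overlapping_stimulus_rejected(self):
        with pytest.raises(ParameterError):
            estimate_noise_sd(np.zeros(40000), (0.5, 1.5), FS, stim_time=1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            estimate_noise_sd(np.zeros(40000), (0.0, 0.001), FS)


def _minimize_sse(y, T):
    """Independent oracle: direct numerical minimisation of the two-parameter
    SSE(s, c) = sum (y - s*T - c)^2, no normal equations involved."""
    from scipy.optimize import minimize

    res = minimize(lambda p: ((y - p[0] * T - p[1]) ** 2).sum(), [0.0, 0.0],
                   method="Nelder-Mead",
                   options=dict(xatol=1e-10, fatol=1e-14, maxiter=20000))
    return res.x


class TestTemplateFitScan:
    def test_exact_fit_identity(self, kernel):
        tpl = kernel_template(kernel, FS)
        y = np.zeros(1000)
        y[100: 100 + tpl.waveform.size] = 3.0 * tpl.waveform + 10.0
        fit = template_fit_scan(y, tpl, (90, 120))
        assert fit["scale"][10] == pytest.approx(3.0, abs=1e-9)
        assert fit["offset"][10] == pytest.approx(10.0, abs=1e-9)

    def test_matches_brute_force_grid_oracle(self, kernel):
        # 50-ms toy trace; closed form vs iterative grid SSE minimiser
        rng = np.random.default_rng(2)
        tpl = kernel_template(kernel, FS)
        T = tpl.waveform
        y = rng.normal(0.0, 2.0, 1000)
        y[300: 300 + T.size] += 2.5 * T + 4.0
        fit = template_fit_scan(y, tpl, (280, 320))
        for k in (0, 10, 20, 30):
            seg = y[280 + k: 280 + k + T.size]
            s_bf, _ = _minimize_sse(seg, T)
            assert abs(fit["scale"][k] - s_bf) < 1e-6 * max(abs(s_bf), 1.0)

    from hypothesis import given, settings
    from hypothesis import strategies as hst

    @given(hst.floats(min_value=-5.0, max_value=5.0),
           hst.floats(min_value=-20.0, max_value=20.0))
    @settings(derandomize=True, max_examples=30)
    def test_fit_recovers_any_scale_and_offset(self, s_true, c_true):
        tpl = kernel_template(KernelParams(), FS)
        y = np.zeros(400)
        y[:] = c_true
        y[100: 100 + tpl.waveform.size] = s_true * tpl.waveform + c_true
        fit = template_fit_scan(y, tpl, (100, 101))
        assert fit["scale"][0] == pytest.approx(s_true, abs=1e-8)
        assert fit["offset"][0] == pytest.approx(c_true, abs=1e-8)

    def test_zero_template_degenerate(self):
        tpl = Template(np.zeros(200), FS)
        with pytest.raises(DetectionError):
            template_fit_scan(np.zeros(1000), tpl, (0, 100))

    def test_window_bounds_enforced(self, kernel):
        tpl = kernel_template(kernel, FS)
        with pytest.raises(ParameterError):
            template_fit_scan(np.zeros(100), tpl, (0, 50))


class TestDetectEvents:
    def test_single_event_round_trip(self, noisy_trace, kernel):
        data, inject = noisy_trace
        inject(3.0, 100.0)
        tpl = kernel_template(kernel, FS)
        evs = detect_events(data, tpl, DetectionConfig(), FS, 1.0)
        assert len(evs) == 1
        assert evs[0].latency == pytest.approx(3.0, abs=1000.0 / FS + 1e-9)
        assert evs[0].amplitude == pytest.approx(100.0, rel=0.05)

    def test_flat_trace_yields_nothing(self, kernel):
        tpl = kernel_template(kernel, FS)
        assert detect_events(np.zeros(100000), tpl, DetectionConfig(), FS, 1.0,
                             noise_sd=1.0) == []

    def test_amplitude_floor_excludes_small_events(self, noisy_trace, kernel):
        data, inject = noisy_trace
        inject(3.0, 15.0)
        tpl = kernel_template(kernel, FS)
        cfg = DetectionConfig(min_amplitude=20.0, threshold_mult=0.5)
        evs = detect_events(data, tpl, cfg, FS, 1.0)
        assert evs == []

    def test_raising_threshold_never_adds_detections(self, short_session, kernel):
        tpl = kernel_template(kernel, FS)
        counts = []
        for mult in (1.5, 2.5, 4.0, 6.0):
            cfg = DetectionConfig(threshold_mult=mult, min_amplitude=0.0)
            n = sum(len(detect_events(short_session.sweeps[i], tpl, cfg, FS, 1.0))
                    for i in range(20))
            counts.append(n)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_amplitude_consistency_noiseless(self, kernel):
        # isolated noiseless event: reported amplitude within sample curvature
        data = np.zeros(100000)
        t = np.arange(1600) / FS * 1000.0
        data[int(1.004 * FS):int(1.004 * FS) + 1600] = ipsc_kernel(t, kernel, 80.0)
        tpl = kernel_template(kernel, FS)
        evs = detect_events(data, tpl, DetectionConfig(), FS, 1.0, noise_sd=2.0)
        assert len(evs) == 1
        assert evs[0].amplitude == pytest.approx(80.0, rel=0.02)


class TestTemplates:
    def test_seed_template_tracks_truth_amplitude(self, short_session):
        tpl = build_initial_template(short_session)
        truth = short_session.truth
        ev = truth[(truth.kind == "evoked")]
        # template averages the top-SNR events; its peak must be in their range
        assert tpl.peak <= ev.amplitude_pA.max() * 1.3
        assert tpl.peak >= ev.amplitude_pA.quantile(0.5) * 0.5
        assert np.all(tpl.waveform[: tpl.n_baseline] == 0.0)

    def test_all_noise_session_raises_insufficient_seed(self):
        cfg = SessionConfig(duration=2.0, spont_rate=0.0, seed=9)
        s = simulate_vc_session(cfg, ConnectionParams(n_connections=0))
        with pytest.raises(InsufficientSeedError):
            build_initial_template(s)

    def test_single_clean_event_template_identity(self, kernel):
        # one-sweep session: the sole candidate must become the template
        cfg = SessionConfig(duration=5.0 / 60.0, spont_rate=0.0, noise_sd=0.5,
                            seed=1)
        s = simulate_vc_session(cfg, ConnectionParams(n_connections=1,
                                                      release_prob=1.0,
                                                      latency_jitter_sd=0.0))
        tpl = build_initial_template(s, n_seed=1)
        onset = int(round((1.0 + s.truth.latency_ms.iloc[0] / 1000.0) * FS))
        seg = s.sweeps[0][onset - tpl.n_baseline: onset + tpl.n_body].astype(float)
        seg -= seg[: tpl.n_baseline].mean()
        assert np.allclose(tpl.waveform[tpl.n_baseline:], seg[tpl.n_baseline:],
                           atol=2.0)

    def test_average_of_identical_segments_is_identity(self):
        seg = np.concatenate([np.zeros(100), np.linspace(0, 1, 100)])
        out = _align_and_average([seg.copy() for _ in range(5)], 100, 100)
        assert np.allclose(out, seg)

    def test_alignment_recovers_peak_from_jittered_copies(self, kernel):
        t = np.arange(100) / FS * 1000.0
        body = ipsc_kernel(t, kernel, 100.0)
        base = np.concatenate([np.zeros(100), body])
        segs = [np.roll(base, shift) for shift in (-2, -1, 0, 1, 2)]
        aligned = _align_and_average(segs, 100, 100)
        unaligned = np.mean(segs, axis=0)
        assert aligned.max() >= unaligned.max()

    def test_noise_averages_out_as_root_n(self, kernel):
        rng = np.random.default_rng(3)
        t = np.arange(100) / FS * 1000.0
        body = ipsc_kernel(t, kernel, 100.0)
        clean = np.concatenate([np.zeros(100), body])
        segs = [clean + rng.normal(0, 5.0, 200) for _ in range(100)]
        avg = _align_and_average(segs, 100, 100)
        rms = np.sqrt(np.mean((avg[100:] - body) ** 2))
        assert rms < 1.0

    def test_refine_empty_list_rejected(self, short_session):
        with pytest.raises(DetectionError):
            refine_template([], short_session)


class TestTwoPass:
    def test_standard_session_low_false_positive_rate(self, short_session):
        table = two_pass_detect(short_session, DetectionConfig(search_window=100.0))
        fp, n = false_positive_rate(table, short_session.truth, short_session)
        assert n > 100
        assert fp / n <= 0.03

    def test_refinement_does_not_lose_true_events(self, short_session):
        table = two_pass_detect(short_session, DetectionConfig(search_window=10.0))
        n_pass1 = table.meta["n_pass1"]
        assert len(table) >= 0.9 * n_pass1

    def test_empty_noiseless_session_gives_empty_table(self):
        cfg = SessionConfig(duration=2.0, spont_rate=0.0, noise_sd=0.0, seed=0)
        s = simulate_vc_session(cfg, ConnectionParams(n_connections=0))
        with pytest.raises(InsufficientSeedError):
            two_pass_detect(s)

    def test_recall_on_isolated_strong_events(self):
        # truth events >= 40 pA with no neighbour within the refractory must
        # be found at >= 95% (8:1 SNR regime); pooled over seeded sessions
        hits = total = 0
        for seed in range(6):
            s = simulate_vc_session(SessionConfig(duration=6.0, seed=100 + seed))
            table = two_pass_detect(s, DetectionConfig(search_window=100.0))
            det = table.events
            truth = s.truth
            for r in truth.itertuples():
                if r.amplitude_pA < 40 or not np.isfinite(r.latency_ms):
                    continue
                if not 0 <= r.latency_ms < 100:
                    continue
                d = np.abs(truth[truth.sweep == r.sweep].t_sweep_s - r.t_sweep_s)
                if ((d > 0) & (d < 0.005)).any():
                    continue
                total += 1
                dd = det[det.sweep == r.sweep]
                if not dd.empty and (np.abs(1.0 + dd.latency_ms / 1000.0
                                            - r.t_sweep_s) <= 0.001).any():
                    hits += 1
        assert total > 200
        assert hits / total >= 0.95
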