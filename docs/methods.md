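# Methods

`optoipsc` reimplements, as a tested pipeline, the analysis used in
optogenetic studies of lateral inhibition between striatal spiny projection
neurons (SPNs): light-evoked inhibitory postsynaptic currents (IPSCs) are
detected by two-pass template matching, summarised as per-phase success
rates and normalized amplitudes, split by latency class, and compared with
repeated-measures statistics. Because such studies deposit no raw
recordings, every stage is driven and validated by a synthetic
voltage-clamp generator built on a stochastic quantal-release model with
full ground truth.

## Synthetic voltage-clamp sessions

A session is 60 min of 5-s sweeps sampled at 20 kHz, one light stimulus 1 s
into each sweep (12 stimuli/min, 720 sweeps). Compound IPSCs arise from
`n_connections` presynaptic cells (default 4) that each release one quantum
per stimulus with probability `release_prob` (default 0.3), giving a
baseline success probability 1 − (1 − p)^N ≈ 0.76 per stimulus — in the
upper range of paired-recording reports for SPN collaterals. Quantal
amplitudes are lognormal (mean 60 pA, CV 0.4; lognormal guarantees
positivity), summed linearly when several connections release together.

Event kinetics are a biexponential exp(−t/τd) − exp(−t/τr), normalised to
unit peak, with τ_rise = 0.5 ms and τ_decay = 8 ms by default: a sharp
rising edge with the prolonged decay produced by high-chloride internal
solutions. Each connection draws a fixed latency mean (normal around 4 ms,
SD 1 ms, clipped into the 0–10 ms evoked window) and jitters it
sweep-to-sweep by 0.3 ms. "Secondary" release (delayed presynaptic spiking)
occurs per connection with probability 0.1, uniformly in 10–30 ms.
Spontaneous IPSCs are a homogeneous Poisson process over the whole sweep at
1 Hz — a middle-of-the-road slice rate for the mixed SPN/interneuron
sources that populate the 30–100 ms window — with single-quantum
amplitudes, unmodulated by the agonist.

Drug protocols modulate release probability through an effect variable
e(t) rising exponentially after `t_on` (onset τ = 1.25 min, so effects are
visible 2–3 min after application) and decaying after `t_off` with
`washout_tau`. The release multiplier is m(t) = 1 − (1 − r)·e(t) with r the
residual release fraction (default 0.1 for the agonist). The
`agonist_plus_antagonist` and `none` protocols force m ≡ 1. TTX is modelled
as all-or-none axonal spike failure: r = 0, the multiplier snaps to exactly
0 once e(t) is within exp(−5) of complete effect, and the spontaneous
(spike-dependent) rate is scaled by the same multiplier. An optional
quantal-scale multiplier (default 1) lets the agonist co-modulate quantal
size, since amplitude-based data cannot distinguish the two mechanisms;
the default attributes the whole effect to release probability. Subtype
asymmetries in recovery are expressed only through `washout_tau` presets
(slower for D1→D2 than D2→D1), not a mechanistic model.

Recording noise is Gaussian, shaped by a 4-pole Bessel low-pass at 4 kHz
and rescaled so the *filtered* trace SD equals `noise_sd` (default 5 pA).
Line noise and slow seal drift are not modelled; QC tests inject
resistance-step artifacts directly into the metadata instead. Sessions
also carry emulated QC channels (access resistance at start/end, an
input-resistance series with 5% linear drift).

What the generator does not emulate: overlapping-event waveform
nonlinearities (summation is linear), electrode/series-resistance
filtering of the synaptic current, temperature or rundown drifts in
kinetics, and bursting presynaptic activity. Passing tests therefore show
that the analysis recovers the statistical structure it assumes, not that
it is robust to every artifact of real recordings.

## Two-pass template-matching detection

The template is a 5-ms body preceded by a 5-ms flat baseline. At every
offset the data segment is fit to s·T + c in closed form (normal
equations); the fitted-peak amplitude is s times the template peak.
Candidates are strict local maxima of that series above 2.5× the noise SD,
thinned to one per 5-ms refractory period (largest first). The noise SD is
the MAD-based robust SD of a detrended 0.5-s window ending 50 ms before
the stimulus. Event amplitude is then re-measured from the raw trace: a
3-sample mean at the fitted peak position minus the mean of the 5-ms
pre-event baseline (reading the raw maximum over the body would be biased
upward by the noise). Events below the 20 pA floor are discarded as
indistinguishable from noise.

Pass 1 scans the 10-ms evoked window with a seed template: the evoked
windows of the session are scanned with a canonical biexponential matched
filter, candidates ranked by fitted amplitude over noise SD, and the top
12 aligned and averaged — an automated stand-in for manual event picking.
Detected events are aligned on the steepest rise (argmax of the first
difference, lightly smoothed with an 11-sample boxcar so alignment jitter
stays near one sample) and averaged into the second template, which is
scanned over the configured window (10 ms for evoked analyses, 100 ms for
latency analyses). Only pass-2 events are reported.

Two thresholding statistics are implemented because the convention is
ambiguous in the field: the default thresholds the fitted-peak amplitude
against 2.5× noise SD; the classical alternative (fitted scale over its
standard error) is available via `DetectionConfig(statistic="scale_se")`.

Detection semantics for overlapping release: two quanta closer than the
refractory period are reported as a single compound IPSC — the same
convention as the source instrumentation, where multiple contemporaneous
events count as one detected IPSC. Detector recall is therefore quantified
on *resolvable* truth events (no neighbour within 5 ms); under the default
conditions (events ≥ 40 pA, 5 pA noise) it exceeds 95%, with a pooled
false-positive rate (no truth event within ±1 ms) at or below 3%.

## Per-cell analysis

Cells are excluded when access resistance exceeds 22 MΩ at start or end,
input resistance changes by more than 20% over the recording or within any
rolling 2-min span (the operationalisation of a "sudden" step), or the
recording is shorter than 45 min. Success rate per minute is the fraction
of that minute's 12 stimuli followed by ≥ 1 pass-2 event within 10 ms (at
most one success per stimulus; amplitudes never enter). The amplitude time
course groups detected evoked events chronologically into bins of six and
divides each bin mean by the mean amplitude over minutes 10–15 (the last
5 min of baseline). Failures never contribute zeros to the amplitude
series — they appear only in the success rate; the alternative reading
(group averages including failure sweeps as zeros) is not used. Latency
bins are half-open lower-inclusive ([0,10), [10,30), [30,100) ms); events
at ≥ 100 ms are dropped from the latency analysis. Episode-latency maps
accumulate amplitude at (episode, latency-sample) resolution with no
smoothing. Phase summaries average the normalized-amplitude bins and
per-minute success rates over minutes 10–15 (baseline), 25–30 (drug) and
40–45 (washout).

## Intrinsic properties

Current-clamp step families use a phenomenological SPN model: Ohmic
subthreshold responses with the slope reduced below −90 mV (inward
rectification), membrane charging with a 10-ms time constant, and regular
spiking at `fi_slope`·(I − rheobase) rendered as stereotyped triangular
action potentials (rise 100 mV/ms from the configured threshold; fall
slope set so the width at half of peak-minus-threshold equals the
configured half-width). This is not a conductance-based model; it exists
to give the extraction operations exact ground truth.

Extraction conventions (the sources are silent on all of them): spikes are
upward crossings of dV/dt ≥ 10 mV/ms, one per excursion (re-armed at a
downward zero crossing); spike threshold is the voltage at the first
pre-peak sample of the suprathreshold-dV/dt run; half-width interpolates
linearly between samples; firing rates are counted over the full step;
steady state is the mean of the last 20% of the step; input resistance is
the I-V slope through the two subthreshold currents nearest zero.

## Statistics

One-way repeated-measures ANOVA is computed from sums of squares with
subject blocking; the Greenhouse–Geisser ε comes from Box's formula on the
condition covariance, clamped to [1/(k−1), 1], and scales both degrees of
freedom (producing the fractional df this literature reports). The mixed
two-way design tests the between factor against subjects-within-groups and
the within factor and interaction against the within-error term, with ε
from the pooled within-group covariance. Note the correction can only
*raise* p in the F ≥ 1 regime; below F = 1 the scaled tail probability may
decrease, which is immaterial since nothing there is significant.

Holm–Šídák adjustment is the step-down 1 − (1 − p₍ⱼ₎)^(m−j+1) with running
maximum; Tukey comparisons use the studentized-range distribution against
the RM error term; Bonferroni–Dunn is plain Bonferroni on the family.
Welch's t uses Satterthwaite degrees of freedom. The within-subject effect
size is ω² = df·(MS_effect − MS_error)/(SS_total + MS_subjects), clamped
at zero; other ω² variants exist in the literature, and this formula is
the one fixed and tested here. The choice between Holm–Šídák and Tukey per
analysis is configuration, not inference.

## Problem sizes and numerical choices

Acceptance-level runs use 20 seeded 60-min sessions for the
false-positive bound, 40 seeded 30-min (baseline + drug) sessions for the
latency-class dissociation, one 30-min session for the TTX limit, 4-cell
groups for the no-effect scenarios, and 20 meta-replicates of 6-cell
no-drug groups (45-min sessions sampled at 10 kHz — the per-minute
statistics do not depend on the sampling rate) for the pipeline-level
type-I error check. Sessions are generated in float32; the noise path is
filtered in chunks with carried filter state so results are independent of
chunking. Degenerate inputs (constant templates, zero-variance samples,
empty event lists, missing QC channels) raise explicit errors rather than
propagating NaNs, except where a flagged result is specified (degenerate
Welch t, missing phases).

## Known limitations

Real vendor recordings require an adapter (`read_abf` / `read_axograph`
are declared but unimplemented); the equilibrium-potential arithmetic for
the high-chloride internal solution is deliberately not an operation (the
ion inventory needed to reproduce the printed −3 mV is ambiguous); group
means from the original recordings are not reproducible and are not
targets — the statistical layer is validated by oracles and null
simulations instead.
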