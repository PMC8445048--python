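# optoipsc

Analysis pipeline for optogenetically evoked inhibitory postsynaptic
currents (IPSCs) in voltage clamp, aimed at slice electrophysiologists
studying lateral inhibition between striatal spiny projection neurons
(SPNs) and its presynaptic neuromodulation (e.g., 5-HT1B receptor
agonists). The package covers the full desk side of such an experiment:

- **Synthetic sessions with ground truth** — a stochastic quantal-release
  generator: N presynaptic connections each release a lognormal quantum
  with probability p per light stimulus, biexponential IPSC kinetics,
  latency jitter, secondary (10–30 ms) and spontaneous (Poisson) events,
  band-limited Gaussian noise, and session-long drug protocols (agonist,
  agonist + antagonist, TTX, none) with exponential onset/washout.
- **Two-pass template-matching detection** — sliding least-squares fit of
  a scaled-and-offset template (5-ms body, 5-ms baseline); threshold
  2.5× the robust pre-stimulus noise SD, 20 pA amplitude floor; a seeded
  first pass whose aligned event average becomes the second, definitive
  template.
- **Session analysis** — QC rules (access resistance ≤ 22 MΩ, ≤ 20% input
  resistance change, ≥ 45 min), per-minute synaptic success rate,
  amplitude time course normalized to the last 5 min of baseline in bins
  of six events, latency classes 0–10 / 10–30 / 30–100 ms, episode-latency
  maps, and phase means over minutes 10–15 / 25–30 / 40–45.
- **Intrinsic properties** — spike detection, spike threshold, AP
  half-width, f-I curve with rheobase, input resistance and I-V curves
  from current-clamp step families.
- **Statistics** — one-way repeated-measures ANOVA with Greenhouse–Geisser
  correction, mixed two-way ANOVA, Holm–Šídák / Tukey / Bonferroni–Dunn
  multiple comparisons, Welch's t, and within-subject ω².

The success model: a stimulus succeeds when at least one of N connections
releases, so the success rate is S = 1 − (1 − p)^N and drug action on
release probability (p → m·p) moves both S and the compound amplitude —
the dissociation the latency analysis tests is that events in the 30–100
ms window (spontaneous class) are *not* moved.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

```python
from optoipsc import RunConfig, SessionConfig, run_pipeline

cfg = RunConfig(scenario="agonist_d1_to_d2", n_cells=6, seed=42,
                session=SessionConfig(duration=60.0))
rep = run_pipeline(cfg)
print(rep.summaries.groupby("phase")[["norm_amplitude", "success_rate"]]
      .mean().round(3))
r = rep.anova_amplitude
print(f"RM-ANOVA (GG): F({r.df_num:.3f}, {r.df_den:.2f}) = {r.F:.1f}, "
      f"p = {r.p:.2e}")
```

prints

```
          norm_amplitude  success_rate
phase
baseline           1.003         0.764
drug               0.672         0.114
washout            0.897         0.644
RM-ANOVA (GG): F(1.253, 6.26) = 10.5, p = 1.42e-02
```

Six simulated cells receive the agonist protocol (15-min baseline, 15-min
drug, washout). The success rate collapses from 0.76 (the generator's
1 − 0.7⁴) to 0.11 during the drug phase and partially recovers, while the
mean amplitude of the *detected* events falls less steeply — the drug
mainly converts successes into failures, which never enter the amplitude
series. The repeated-measures ANOVA on the per-cell phase means, with
Greenhouse–Geisser-scaled fractional degrees of freedom, confirms a phase
effect; `rep.comparisons` carries the Holm–Šídák-adjusted pairwise tests.

The same stages are scriptable from the shell:

```sh
optoipsc simulate --seed 1 session.h5
optoipsc detect session.h5 events.csv
optoipsc run --scenario no_drug --seed 7
```

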