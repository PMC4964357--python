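# fernpipe

Simulation and analysis pipeline for studies of the **feedback Error-Related
Negativity** (fERN, also called FRN/MFN) — the negative frontocentral ERP
deflection 250–400 ms after outcome feedback that indexes how the brain's
value system evaluates monetary and social outcomes. The package is aimed at
cognitive-electrophysiology researchers who want a fully testable, end-to-end
reference chain: task simulation → synthetic high-density EEG → preprocessing
→ resampling waveform statistics → source analysis, with every stage
validated by construction and parameter recovery.

Two paradigms are simulated:

* a **children's gambling task** (two versions × 160 card choices between an
  advantageous and a disadvantageous deck, cumulative feedback every 20
  choices, $120 starting capital), analyzed as win-vs-loss contrasts for the
  disadvantageous and high-loss-frequency options;
* an **observed, rigged Prisoner's Dilemma** (160 trials; the fair player
  cooperates on exactly 72.5% of trials, the unfair player betrays on 67.5%;
  fair-player cooperation pays the participant 3 points, betrayal 6),
  analyzed as the betrayal-vs-cooperation contrast with a >70%
  omission-error exclusion rule.

Synthetic 128+2-channel EEG at 1024 Hz carries a feedback-locked negativity
generated by an anterior-cingulate-proxy dipole in an analytic three-shell
spherical head model, with group-dependent condition gains (control: loss >
win and betray > cooperate; ADHD: no modulation; ASD: loss > win but
cooperate > betray), 1/f background noise and blink artifacts.

The analysis chain implements the standard recipe: downsample to 256 Hz,
0.5–20 Hz zero-phase bandpass, averaged-mastoid reference, −200..800 ms
epochs, baseline correction, threshold artifact rejection; fERN scoring at Fz
in 250–400 ms; a **bootstrap Monte Carlo waveform test** (5000 resamples with
replacement from the pooled conditions, pointwise two-sample *t*, add-one
Monte Carlo *p*, temporal extents, max-|t| familywise correction, Cohen's
*d*); and a **depth-weighted L2 minimum-norm inverse** (depth exponent
γ = 0.8, SNR-parameterized Tikhonov regularization, orientation constrained
to the surface normal) with anterior-cingulate ROI scalars compared across
groups by Mann-Whitney *U* with effect size r = |Z|/√N.

## Worked example

```python
import fernpipe as fp

# one control participant, scaled-down session
cfg = fp.IGTConfig(n_trials_per_version=36, block_len=12, iti_range=(0.9, 1.2))
session = fp.simulate_igt_session(cfg, policy="uniform-random", seed=1)
montage = fp.default_montage()
raw = fp.synthesize_eeg(session, fp.ERPTemplate.for_profile("control"),
                        montage, fp.NoiseParams(rms_uv=10.0), seed=1)
epochs = fp.preprocess(raw)

loss = ["igt/v1-DD/loss", "igt/v2-AD/loss"]   # high-loss-frequency options
win = ["igt/v1-DD/win", "igt/v2-AD/win"]
res = fp.montecarlo_bootstrap_test(
    epochs.select(loss), epochs.select(win),
    fp.AnalysisConfig(n_resamples=5000, seed=1), times=epochs.times)
print(f"max diff at {res.max_diff_time_ms:.0f} ms: "
      f"t={res.t_at_max:.2f}, p={res.p_at_max:.4f}, d={res.d_at_max:.2f}")
print("significant extents (ms):", res.extents_ms)
```

Output:

```
max diff at 344 ms: t=-2.20, p=0.0342, d=-0.77
significant extents (ms): [(332.03125, 351.5625)]
```

The loss waveform is more negative than the win waveform at Fz (negative *t*
and *d*, a medium-to-large single-subject trial-level effect), the maximal
difference falls near the 330 ms template peak, and the significant extent
sits inside the 250–400 ms scoring window — the simulated control profile
recovered by the full chain from a single participant's trials. Cohort-level
tests on subject averages are far more sensitive (see below).

Whole-cohort studies run through one call (or `fernpipe run-all` on the
command line):

```python
report = fp.run_study(fp.StudyConfig(groups={"control": 20, "adhd": 20},
                                     tasks=("igt",), master_seed=7))
```

The JSON report contains per-group waveform statistics, per-subject
anterior-cingulate ROI scalars, between-group Mann-Whitney contrasts,
trial-retention tables and demographic covariate checks, all reproducible
from the master seed.

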