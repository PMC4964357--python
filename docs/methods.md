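# Methods

`fernpipe` is a simulation-plus-analysis pipeline for studies of the feedback
Error-Related Negativity (fERN, also called FRN or MFN): the negative
frontocentral deflection that follows outcome feedback at roughly 250–400 ms
and is larger for losses and other undesired outcomes. The package covers the
whole experimental chain — two reward paradigms, synthetic high-density EEG,
preprocessing, resampling waveform statistics, and a linear source analysis —
so that every analysis stage can be validated by construction and by
parameter recovery on synthetic cohorts.

## Task simulators

**Monetary task (children's gambling task).** Two versions of a two-deck
card-selection task, played back to back, 160 trials per version by default.
Each version pairs an advantageous deck (positive expected payoff) with a
disadvantageous one (negative expected payoff); the win schedule (5 units on
every card) is identical across decks and versions, while loss size and
frequency differ so that each version contains exactly one
high-loss-frequency deck (loss probability 0.5 versus 0.1). Published
descriptions of this family of tasks constrain the *structure* (profit signs,
frequency classes, constant wins) but not the exact magnitudes, so the
default magnitudes (losses of 25, 7.5 and 125 units) are package choices that
satisfy the constraints; they are fully configurable. Every drawn loss card
is a net loss (the loss always exceeds the concurrent win), so the feedback
label ("win"/"loss") and the payoff sign agree. Capital starts at 120 units;
cumulative feedback appears after every 20 choices (8 displays per version).
Two choice policies are provided: uniform-random and loss-frequency-avoidant
(children's dominant strategy — avoid the disadvantageous and
high-loss-frequency options). The analyses condition on the *chosen* option,
so the uniform policy is used in validation cohorts to balance cell counts.

**Social task (observed, rigged Prisoner's Dilemma).** The participant
watches two players cooperate or betray over 160 trials and is paid the fair
player's points. The rig is exact rather than stochastic: the fair player
cooperates on exactly round(0.725 × n) trials and the unfair player betrays
on exactly round(0.675 × n), orders permuted by the seed, so the printed
rates (72.5%/27.5% and 67.5%/32.5%) are reproduced identically for every
seed. Cooperation by the fair player pays the participant 3 points and
betrayal 6 — the payoff follows the fair player's action in this rigged
variant, which is what makes the prosocial fERN pattern dissociable from
monetary self-interest. The full 4-cell payoff matrix is configurable for
standard temptation/reward/punishment/sucker orderings. A comprehension
question follows every trial; wrong answers mark the trial unusable, and a
session whose omission-error rate strictly exceeds 70% is excluded.

## Group response profiles

Condition gains multiply a common negative template amplitude:

| profile | monetary | social | interpretation |
|---|---|---|---|
| control | loss 1.0 > win 0.35 | betray 1.0 > cooperate 0.35 | prosocial modulation |
| adhd | 0.55 = 0.55 | 0.55 = 0.55 | no modulation, reduced overall |
| asd | loss 1.0 > win 0.35 | cooperate 1.0 > betray 0.35 | inverted social pattern |

The base amplitude is −6 µV at Fz (mastoid-referenced), so the
strong-vs-weak condition difference is ≈3.9 µV at the peak — at the upper end
of the 2–5 µV range typical of feedback-negativity contrasts, chosen once as
the synthetic effect size.

## Synthetic EEG

130 channels (128 quasi-equidistant scalp sites with a named Fz at the
canonical frontal-midline position, plus left/right mastoids) at 1024 Hz. At
each feedback onset a Gaussian-envelope deflection (peak 330 ms, SD 45 ms) is
forward-projected from a dipole at the centroid of the anterior-cingulate
proxy region, oriented along the (inward) surface normal; the dipole moment
is normalized so that a gain-1.0 trial peaks at exactly the configured
microvolt value at mastoid-referenced Fz. Background noise is 1/f ("pink")
noise with a 20% white-variance floor, independent per channel, RMS 10 µV by
default; optional blink artifacts are frontally weighted Hanning transients
(~120 µV, 0.03/s). Inter-trial intervals are jittered uniformly (1.5–2.5 s by
default; the task literature rarely prints exact screen timings, so these are
declared defaults — only feedback-locking depends on them).

What the generator does *not* emulate: spatially correlated background
sources, alpha rhythms, muscle/line noise, latency or amplitude variability
across trials, habituation, or realistic anatomy. Passing recovery tests
therefore demonstrates the correctness and calibration of the analysis chain
under the stated model, not robustness to every artifact class of real
recordings.

## Preprocessing

Downsample 1024 → 256 Hz (zero-phase 8th-order Butterworth anti-alias low-pass
at 0.4 × target rate, then decimation; event indices remapped), 0.5–20 Hz
4th-order Butterworth bandpass applied forward-backward (zero phase, so
component latencies are not shifted), algebraic re-reference to averaged
mastoids, epochs of −200..800 ms around each usable feedback onset (half-open
window: exactly 256 samples at 256 Hz, with 0 ms exactly on the event
sample), baseline correction by the −200..0 ms mean, and threshold rejection:
an epoch is dropped if any channel exceeds 100 µV peak-to-peak or a
50 µV/sample gradient, with a manual-override list as the escape hatch of the
otherwise deterministic rule. Re-applying baseline correction to its own
output is the identity; the API flags accidental double application as an
error.

## Waveform statistics

Artifact-free epochs are averaged per condition; a condition may pool two
task options (e.g. the two disadvantageous decks), and subject-level
condition averages are the default statistical units for cohort inference
(a trial-level option exists; published reports are frequently ambiguous on
this point, so both are exposed). The fERN is scored at Fz as the mean over
the half-open 250–400 ms window.

The two-condition test follows the bootstrap Monte Carlo recipe used in
small-sample ERP work: pool both conditions, resample **with replacement**,
split into the original group sizes, and compute a pooled-variance two-sample
t per timepoint; 5000 resamples form the null. Pointwise two-sided p-values
use the add-one convention (1 + exceedances)/(1 + B), so p is never zero.
Contiguous runs of the uncorrected pointwise mask are the reported "temporal
extents" (the field's convention), and the result also carries a
max-|t|-corrected p per timepoint whose any-rejection decision controls the
familywise error over the scoring window — that corrected decision is what
the cohort recovery experiments count, because the uncorrected any-timepoint
rate is necessarily above alpha. The summary (t, p, Cohen's d with
(n−1)-pooled SD) is reported at the timepoint of maximal absolute condition
difference. A label-permutation null is available behind a flag for
sensitivity analysis; degenerate zero-variance comparisons define t = 0.

Group contrasts of scalar measures use the Mann-Whitney U test (exact for
combined n ≤ 20 without ties, tie-corrected normal approximation otherwise;
`scipy.stats.mannwhitneyu` under the surface) with effect size
r = |Z|/√(n₁+n₂) from the tie-corrected Z without continuity correction.
Demographic nuisance checks are Spearman correlations with age and
Mann-Whitney gender contrasts; constant measures are reported as undefined
rather than silently producing a correlation.

## Head model and source analysis

The forward model is an analytic three-shell concentric sphere (brain/skull/
scalp radii 80/85/92 mm, conductivities 0.33 S/m in the ratio 1 : 1/80 : 1).
For each spherical-harmonic order n the radial boundary problem (potential
and radial-current continuity at the interfaces, insulating outer boundary)
is solved exactly, giving the scalp potential of an arbitrary interior dipole
as a Legendre series (100 terms; the series is validated against the
free-space dipole closed form, the homogeneous-sphere (2n+1)/n factor, the
center-dipole factor 3, and mirror symmetry). This replaces a boundary-element
model on template anatomy while preserving the linear-inverse mathematics.

The cortical proxy is a set of three concentric upper-hemisphere caps at
0.55, 0.675 and 0.80 of the brain radius (260 sources each), with sources
oriented along the surface normal (the orthogonal-to-cortex constraint). The
normals point inward so that the generator of a frontocentral scalp
*negativity* carries positive source activation — the sign convention under
which a loss-minus-win contrast is a positive "activation" in controls. The
anterior-cingulate proxy ROI is the deep frontal-midline sector of the
deepest cap (anterior, within 40% of the cap radius of the midline; 40
sources with the default sampling), defined geometrically rather than by
visual identification so it is reproducible.

The inverse is the depth-weighted L2 minimum norm: source covariance
W = diag(‖gᵢ‖^(−2γ)) with γ = 0.8 by default, Tikhonov regularization
λ = trace(G W Gᵀ)/(trace(C)·SNR²) with assumed amplitude SNR 3 for data
analysis, and noise covariance C either identity or the baseline-sample
covariance shrunk 10% toward a scaled identity. ROI scalars are the mean of
the subject's condition-difference estimate over ROI sources and the
250–400 ms window.

**Resolution benchmarks and the role of regularization.** With 130 EEG
channels and a 1/80 skull, leadfield column norms vary by only ~15–30%
between the deepest and the most superficial cap, so in the λ → 0 limit the
peak of a minimum-norm map for a deep source sits one cap superficial
*regardless* of the depth exponent — depth weighting changes the estimate's
amplitude profile but not its argmax there. The depth prior becomes active
when λ is comparable to the leadfield Gram scale: in that regime (benchmarked
at assumed SNR 0.2) noiseless anterior-cingulate-proxy sources localize to
within 25 mm with γ = 0.8 while γ = 0 lands a cap superficial (~20 mm), and
γ = 0.8 error is ≤ the γ = 0 error for essentially all deep sources. The
resolution benchmarks therefore run at that strong-regularization operating
point, and this behavior — no peak improvement from depth weighting at weak
regularization — is documented here as a property of the estimator, not a
defect of the implementation. With matched sensor noise the localization
error decreases with actual SNR toward this benchmark floor.

## Cohort studies and reproducibility

`run_study` simulates per-group cohorts end to end (session → EEG →
preprocessing → subject condition averages → group statistics → ROI
contrasts → demographic checks) and writes a single JSON report. Per-subject
seeds derive from the master seed and the subject identifier (CRC32 into a
`SeedSequence`), so a fixed master seed reproduces the report bit-for-bit
while subjects are independent. Ages are drawn uniformly from 8–15 years and
genders at a 0.7 male fraction, matching the recruited-population shape; the
generator is age- and gender-independent by construction, which is what the
covariate null checks verify.

**Validation problem sizes.** The validation and benchmark experiments scale
the *number* of trials and subjects down while leaving every study condition
(rigged rates, deck structure, amplitudes, noise, thresholds) at its default:
recovery/separation cohorts use 20 control + 20 ADHD subjects with 36 trials
per task version, ASD social cohorts use 12 subjects with 40 trials, and
rates are estimated over 10 replicate cohorts (8 in the acceptance script).
Calibration uses 2000 null replicates of n = 20/20 with 500 resamples each;
power uses 200 replicates at a 3-pooled-SD separation with n = 30/30. These
sizes were fixed by a priori power analysis of the subjects-as-units test
(expected t ≈ 5–6 for the control contrast, ≈ 3.5 for the ROI separation).

## Numerical choices and edge cases

- Epoch grid: 0 ms sits exactly on the event sample; −200 ms is represented
  by the nearest grid sample (a 256 Hz grid cannot hold both).
- Half-open windows everywhere ([250, 400) ms, [−200, 0) ms) avoid duplicate
  endpoint ambiguity.
- Bootstrap p-values: add-one convention; max-|t| null shares the same
  resamples as the pointwise null.
- Zero pooled variance → t = 0; zero-variance Cohen's d → NaN with the
  degenerate case reported; all-tied Mann-Whitney input → U = n₁n₂/2, p = 1.
- The EDF exporter quantizes to 16 bits with per-channel symmetric physical
  ranges and 1-s records (final record zero-padded); round trips are verified
  against an independent reader. HDF5 containers are bit-exact.
- Deck schedules with all-zero payoffs are accepted as degenerate
  bookkeeping fixtures; otherwise profit-sign and frequency-class invariants
  are enforced at construction.

## Known limitations

- The spherical head model and geometric ROI are proxies; source results are
  about the *method*, not about anatomy.
- Depth weighting does not improve peak localization at weak regularization
  (see above); no noise-normalized variants (dSPM/sLORETA) are provided.
- No ocular ICA/regression, bad-channel interpolation, or alternative
  references; rejection is the deterministic threshold rule.
- Statistical units for published fERN tests are often ambiguous; both
  subject-level and trial-level units are exposed, with subject-level the
  default.
- Effect sizes r are capped at 1 by construction; impossible published
  values (e.g. r > 1) cannot be, and are not, reproduced.
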