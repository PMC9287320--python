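# Methods

`pdsense` converts raw smartphone/smartwatch sensor streams from a battery of
ten active tests plus daily passive monitoring into 17 pre-specified sensor
features for early Parkinson's disease, applies per-session quality control,
aggregates features over two contiguous 2-week windows anchored at the
baseline visit, and quantifies test–retest reliability and clinical validity
against MDS-UPDRS scores. A seeded simulator generates whole synthetic
cohorts — raw signals and clinical records with a shared latent severity —
so every stage is testable end to end without clinical data.

## Feature definitions

All inertial quantities are SI (m/s², rad/s); logs are natural.

| Test | Feature | Definition |
|---|---|---|
| Dexterity | tapping variability (ms) | sample SD (n−1) of consecutive inter-tap-down intervals; down events mark tapping intent, all downs count regardless of alternation |
| Draw A Shape | spiral celerity (1/s) | accuracy / completion time, accuracy = 1/(1 + d̄/w) with d̄ the mean orthogonal distance to the template polyline and w the tolerance radius (20 px) |
| Hand Turning | median turn speed (rad/s) | gyro projected on its first principal axis, 0.5 Hz high-passed, segmented at hysteresis-guarded (±0.1 rad/s) zero crossings; median of per-segment \|∫ω dt\|/duration over rotations ≥ π/4 |
| Rest / Postural Tremor | log median squared energy | 3–12 Hz band-passed acceleration (zero-phase, effective 4th order), ln of the median of ‖a‖² |
| Balance | log sway jerk | 3.5 Hz low-passed acceleration, jerk by central difference, ln of the time-averaged ‖jerk‖² |
| U-turn | median turn speed (rad/s) | yaw rate about the gravity axis (gravity from 0.25 Hz low-passed acceleration), turns = contiguous \|yaw rate\| > 0.2 rad/s accumulating ≥ 140°; median of \|Δyaw\|/duration |
| Phonation | voice jitter (%) | jitter:local — 100·mean\|p_{i+1}−p_i\|/mean(p) over cycle-level pitch periods from autocorrelation voicing (40 ms frames, 10 ms hop, 50–500 Hz) plus glottal-cycle peak picking |
| Speech | MFCC2 variability | per-frame MFCC coefficient 2 (25 ms/10 ms, Hamming, 26 mel filters to 8 kHz, DCT-II ortho, C0 excluded) averaged within each voiced segment > 200 ms; SD across segment means; three questions processed independently and averaged |
| eSDMT | number correct | responses matching the symbol→digit key within 90 s |
| Passive (phone) | daily median turn speed | the U-turn turn detector applied inside detected gait intervals |
| Passive (watch) | median arm-movement power (m²/s³) | ∫‖a_dyn‖² dt per discrete movement (gravity-removed ‖a‖ > 0.15 m/s² for 0.25–10 s) within non-gait time; daily median |

Lateralized tests (Draw A Shape, Dexterity, Hand Turning, both tremor tests)
are computed per hand, giving the 17 feature/side rows.

Where a feature returns no value (fewer than 3 taps, fewer than 2 pitch
cycles or voiced segments, no qualifying rotations/turns/movements), the
record is marked undefined with a reason rather than zero-filled; digitally
silent energy features clip at ln(10⁻¹²) and flag "floor".

Choices the methodology leaves open, fixed here: the tremor band 3–12 Hz
(parkinsonian rest tremor 3.5–7.5 Hz plus first harmonic); all filtering
zero-phase (forward–backward Butterworth; band-pass designed at order 2 so
the effective zero-phase response is 4th order with flat in-band gain); the
celerity accuracy definition (bounded, tolerance-scaled); the 140° turn
threshold (catches ~180° U-turns with undershoot margin); the π/4 qualifying
rotation angle (a π/2 threshold would reject legitimate moderate-amplitude
pronation/supination, e.g. a 4 rad/s, 1 Hz oscillation whose per-rotation
angle is 1.27 rad); the MFCC recipe pinned in `config.AudioConfig` for
cross-library reproducibility; "variability" operationalised as the sample
SD across segment means.

## Quality control

Each session yields a metric map: movement energy (mean per-axis-detrended
‖a‖², the "phone lying on a table" check), tap count, trace length, voiced
fraction, and a duration ratio for fixed-length tests (timeout-bounded tests
— Draw A Shape, Phonation, eSDMT — legitimately end early and skip it).
Thresholds are (low, high) bounds keyed by metric or `test:metric`; the
movement-energy gate applies to Hand Turning and U-turn only, because a
still phone is indistinguishable from correct execution of the tremor and
balance tests. A session is excluded on its first failing metric; the full
metric map is kept for audit. Only the movement-energy example mirrors a
published check; the remaining metrics are this package's design. Defaults
were calibrated once against the simulator so correctly executed sessions
pass at > 99%, and tightening any threshold can only shrink the retained
set (a tested invariant).

## Aggregation, side assignment, adherence

Features are summarised as the median over windows of days 1–14 and 15–28,
reported only when ≥ 3 QC-passed points fell in the window. The fortnightly
eSDMT can contribute at most one point per window, so it aggregates with
≥ 1 (the ≥ 3 rule cannot coexist with a fortnightly schedule).

The more-affected side is the side with the larger sum of lateralized
Part III items (3.4, 3.5, 3.6, 3.15, 3.17); ties fall back to the side
contralateral to reported onset, else the right side, and the mapping is
applied uniformly to all of a participant's lateralized features. The rule
is swappable — it reconstructs an unpublished definition.

Adherence treats day 1 as the in-clinic baseline, leaving 27 remote testing
days per 4-week span; both a day-level percentage (a day counts when every
scheduled session completed — 26/27 days ⇒ 96.296%) and a session-level
percentage are reported, with the cohort summarised by the median across
participants. Which motor tests form the alternating halves is arbitrary
and fixed in `config`.

## Validation statistics

Test–retest reliability is ICC(2,1) — two-way random effects, absolute
agreement, single measure — between the window-1 and window-2 values,
computed from the ANOVA mean squares with a 95% CI by the F-distribution
method; listwise deletion; a zero-variance table reports ICC 1 with a
degenerate CI. Validity is Spearman's ρ (average ranks; exact permutation
p for n ≤ 10, t-approximation above) between window-1 values and the
baseline comparator item, with the comparator map pinned per feature —
including the passive arm-movement-power ↔ left-hand pronation/supination
pairing, reproduced verbatim and flagged. Group contrasts (item 0 vs 1;
Hoehn & Yahr I vs II) use Mann–Whitney U (exact for min(n) ≤ 8 without
ties, tie-corrected normal approximation otherwise), reporting both U
statistics, group sizes and the percent difference of group medians
100·(med_b − med_a)/|med_a| (undefined at a zero reference median — an
invented but guarded formula). Raw p-values by default; Benjamini–Hochberg
optional. Subscale scores (bradykinesia, tremor, rigidity, PIGD, bulbar)
are sums over the collected item subset; a missing constituent item makes
the subscore missing, never imputed.

## Synthetic cohort

Each participant draws an overall latent severity ~ U(0.02, 0.98); domain
severities (bradykinesia, tremor, axial, speech, cognition) scatter around
it (SD 0.15); lateralized domains split by a per-participant asymmetry
(0.10–0.35) around a randomly chosen more-affected side. Hoehn & Yahr
stage II above overall severity 0.25 (≈ 75% stage II). Item scores
discretize severity + N(0, 0.12) through fixed cuts (0.45/0.70/0.88/0.97),
giving early-disease marginals with most items 0–2. Day-to-day wobble adds
N(0, 0.15) to the effective severity of every session, placing pipeline
test–retest ICCs in the good-to-excellent band (median ≈ 0.9 at study
scale). Two percent of hand-turning sessions are emitted as "phone on the
table" misexecutions, so the end-to-end QC exclusion rate sits at the
few-per-thousand scale.

Emission models are deliberately elementary so analytic targets exist: tap
trains with Gaussian intervals (SD 15 + 100·s ms); spiral traces as the
template plus i.i.d. positional noise (2 + 22·s px) drawn over 6 + 12·s s;
sinusoidal pronation/supination with amplitude 5 − 3.2·s rad/s and
frequency 1.8 − 1.2·s Hz (slower but still complete rotations); tremor
sinusoids at 4–6 Hz with amplitude 0.05 + 1.2·s m/s²; low-frequency sway
0.05 + 0.55·s m/s²; square-pulse turns at rate 2/(1 + 1.4·s) rad/s; glottal
pulse trains whose adjacent-period mean absolute difference is
(0.3 + 5.5·s)% of the 8.3 ms period; two-formant vowel pairs whose spectral
contrast shrinks with speech severity (monotone speech); eSDMT response
counts 44 − 18·s. Passive days interleave idle, 2 Hz walking bursts with
injected turns, non-gait movement blocks and discrete wrist movements with
amplitude 2.3 − 1.5·s m/s², plus an optional off-body tail. Ground truth
(latent severities, per-day turn and movement inventories, emitted jitter
targets) is returned alongside each bundle, sufficient to score detectors
exactly. Randomness is counter-based per (participant, day, test) from the
master seed: adding a test or day never perturbs other streams, and output
is bit-reproducible.

What the simulator does **not** emulate: real gait or voice spectra,
sensor drift and clock jitter, orientation changes of the watch, medication
cycles, progression, or missingness correlated with severity. Passing
tests therefore demonstrate the correctness of the algorithms and the
statistical machinery under known generating conditions, not clinical
performance on real recordings.

## Problem sizes

The study-scale configuration reproduces the protocol (28 days, 20 s
tapping, 10 s hand turning, 15 s tremor, 30 s balance, 60 s U-turn, three
20 s speech questions, daily passive monitoring). Tests and
`scripts/acceptance.py` run size-reduced profiles — the package's own
choice of desk-scale problem sizes: `desk_scale` keeps the 28-day
two-window schedule with shorter audio (2.5 s phonation, 3 × 2.2 s speech)
and minutes-long passive days at 20 Hz; `sign_recovery` is a 6-day
cross-sectional profile (exactly the 3 points per feature window 1
requires) used for the 100-replicate coupling-direction study. IMU streams
are 50 Hz, audio 16 kHz. Wear-time numbers under these profiles reflect the
shortened simulated days, not all-day wear.

## Known limitations

- The affected-side rule, celerity accuracy, QC metric list beyond movement
  energy, and the percent-median-difference formula reconstruct unpublished
  definitions; all are config-swappable.
- Turn detection assumes the phone is worn roughly upright at the waist;
  heavily tilted wear degrades the gravity-axis yaw estimate.
- The exact Spearman permutation path enumerates n! pairings and is slow at
  n = 9–10; cohort analyses should have n > 10 (the t-approximation regime).
- `ActivityMask` labels at 6 s window granularity; movements shorter than a
  window sitting across a boundary can be split.
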