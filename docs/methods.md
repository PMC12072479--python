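# Methods

This note documents the models, conventions and numerical choices behind
`icpwaves`, and what the synthetic-data tests do and do not establish about
real recordings.

## Signal model and clock conventions

A recording is a uniformly sampled pressure trace in mmHg
(`IcpSignal`), anchored to a naive local wall clock; clinical acquisitions
sample at 200 Hz, but every stage accepts any rate. Timestamps are stored
as offsets from the start clock; time zones are out of scope.

The diurnal stratum is the half-open clock window **[08:00:00, 22:01:00)**
and the night is its complement. The conventional endpoints ("day 08:00 to
22:00", "night 22:01 to 07:59") leave the minute 22:00:xx unassigned; the
half-open convention gives it to the day so that every sample carries
exactly one label — an exhaustive partition is required for the stratified
means and the burden denominators. The "10-h night" actually spans
9 h 58 min; wave percentages divide by the *actual* nocturnal window length
by default, and a `strict_10h` flag reproduces a fixed 600-min denominator
for comparability with reports that use the nominal figure. Recordings
spanning several nights average the per-night percentages; this equal
weighting of nights is a package choice.

## Smoothed slow-wave channel

The display channel on which slow waves are read is a triangular
(Bartlett) FIR filter, default window 255 samples (~1.3 s at 200 Hz),
weights normalized to unit DC gain. The kernel is centered and symmetric —
zero phase — so wave timing on the smoothed channel stays aligned with the
raw trace; a causal variant would lag the raw channel by half the window.
Edges use reflection padding, which preserves output length and DC gain up
to the boundary and avoids edge transients that could mimic slow waves.
The window is defined in samples at the clinical 200 Hz; at other sampling
rates the physically equivalent window is the same *duration* (e.g. 51
samples at 20 Hz), which matters because an over-long triangular window
attenuates the fastest in-band B-waves.

Artifact detection replaces manual "artifact-free period" selection with
explicit per-sample rules: pressures outside a physiological range
(default −10..80 mmHg), sample-to-sample jumps > 20 mmHg, near-zero
flat-line dropouts (rolling SD < 0.05 mmHg with |ICP| < 0.5 mmHg sustained
≥ 2 s), and non-finite samples. Flagged regions are dilated by 1 s on each
side. All thresholds are configuration-exposed; they are engineering
defaults, not published constants.

## B-wave train detection

B-waves: 0.5–3 waves/min sustained ≥ 10 min; high-amplitude at a median
per-wave amplitude ≥ 10 mmHg (boundary inclusive), low-amplitude below.
The detector:

1. block-averages the smoothed channel to a 1 Hz slow channel (a 1-s block
   is valid when ≥ 50 % of its raw samples are);
2. band-passes it to 0.5–3 cycles/min with a zero-phase order-2
   Butterworth filter;
3. takes alternating peak–trough extrema; a trough→peak excursion
   ≥ 2 mmHg whose rise time fits a half-cycle of the slowest in-band wave
   is a candidate wave (the rise-time bound prevents the last trough of
   one episode pairing with the first peak of the next across a quiet
   gap);
4. chains waves whose peak spacing lies in the 20–120 s period band into
   trains, refusing chains across artifact gaps > 30 s;
5. merges trains separated by < 2 min of sub-threshold oscillation when
   the merged episode still satisfies the frequency band;
6. keeps trains ≥ 10 min with mean frequency inside the band.

Per-wave amplitude is measured peak-to-trough on the band-passed channel —
the measurement convention is a package choice, as is the 2 mmHg candidate
floor and the < 2 min merge rule. Returned trains satisfy the definition
invariants (duration, frequency band, amplitude class rule) by
construction, and raising the amplitude floor can only reduce detected
wave time.

Plateau (A-) waves: an elevation ≥ 20 mmHg above a trailing 30-min rolling
median baseline, sustained 5–30 min with a flat top (CV < 0.15). Once an
onset is found, the pre-onset baseline is frozen while extending the
region, so a long plateau cannot absorb itself into its own baseline. The
20 mmHg default follows the phenomenology of published overnight traces in
this population; the classical adult definition is not numerically
pediatric, so every plateau parameter is configuration-exposed.

## Cardiac pulse analysis

Beat segmentation needs no ECG: the dominant cardiac frequency is found as
the spectral peak inside the heart-rate band (default 60–220 bpm,
pediatric), the signal is band-passed around it, and troughs of the
band-passed trace delimit beats. Within a beat, the diastolic minimum is
located in the first half-cycle and the systolic maximum after it, both on
a 15 Hz low-passed copy of the raw trace (cardiac energy in ICP lies well
below that; measuring extrema on the low-passed trace keeps broadband
noise from inflating amplitudes). Beats touching invalid samples are
discarded; a flat or aperiodic signal yields an empty beat list with a
warning rather than an exception.

`ICP_AMP` over a 10-min window is the **mean** of per-beat amplitudes of
beats fully inside the window (aggregation choice), indeterminate below 30
beats. The baseline window (`ICP_AMP1`) is the lowest-mean-ICP 10-min
window (1-min stride) that is wholly artifact-free and overlaps no
detected train; ties go to the earliest. The wave-top window (`ICP_AMP2`)
lies inside the train whose contained waves have the largest mean
amplitude, and its beats are restricted to wave crests — the top tertile
of the smoothed channel within the window (configurable) —
operationalizing "on top of the waves". Amplitudes ≥ 5 mmHg are flagged
abnormal.

P1/P2 morphology: sub-peaks are local maxima after the diastolic trough
with prominence ≥ 0.5 mmHg; the first two are P1 and P2. A window is
abnormal when the median P2 height exceeds the median P1 height among
beats with both sub-peaks resolved, and indeterminate when fewer than half
the beats resolve both — reporting indeterminate rather than guessing
mirrors how unanalyzable windows are handled clinically.

## Decision rule

Criterion A fires on any high-amplitude B-wave or plateau activity
(`pct_b_high > 0` or plateau present — "any frequency" read literally).
Criterion B fires when low-amplitude B-waves exceed 10 % of the recording
time *and* `ICP_AMP1 ≥ 5` mmHg or `ICP_AMP2 > 5` mmHg; the mixed
inclusive/exclusive bounds are kept exactly as printed. "Recording time"
is read as the nocturnal window by default (consistent with how the wave
percentages are defined); `criterion_b_basis: total` re-expresses the
burden over the full recording instead. When criterion B's wave condition
holds but both amplitudes are indeterminate, the decision is indeterminate
and flagged for review (CLI exit code 3). Criterion A wins the label when
both fire.

Evans' index (bifrontal width / inner skull diameter, abnormal ≥ 0.30) and
the developmental-delay flags (Bayley-III scaled < 7, composite < 85, both
strict) are small threshold classifiers with exactly those boundaries;
missing scores yield absent flags, not `False`.

## Cohort statistics

Normality is tested per group with Shapiro–Wilk at α = 0.05 (the α is a
package choice); both groups normal → mean ± SD and Student's t-test,
otherwise median (min–max) and Mann–Whitney. 2×2 tables use Pearson χ²
without continuity correction — the dialect that reproduces the worked
statistic in the source cohort — switching to Fisher's exact test when any
expected cell is < 5, with the selection recorded. All p-values are
two-sided, significance at p ≤ 0.05, no multiple-testing correction (none
is applied in the reporting style this mirrors).

When both samples have ≤ 8 observations the Mann–Whitney p-value is
computed by exhaustive enumeration of all label assignments over the
pooled midranks, which stays exact under ties (the standard exact method
refuses ties); `p = P(U ≤ min(u, n₁n₂−u)) + P(U ≥ max(u, n₁n₂−u))`,
matching the tie-free exact distribution. Larger samples use the
tie-corrected normal approximation. Groups with < 3 observations get
summaries but no test.

## Synthetic recordings

The generator composes: baseline + slow-wave trains + plateaus + cardiac
pulse + respiration + noise, artifacts last. Trains are sinusoids (or
ramp-like sawtooths, to stress detectors with the asymmetric shape real
B-waves have) riding *upward* from baseline with 30-s raised-cosine
on/off ramps, so wave episodes also raise mean ICP as they do in
patients. The cardiac beat is three Gaussian bumps (P1, P2, P3) at fixed
intra-beat phases with configurable P2/P1 ratio, normalized so the
peak-to-trough of the template equals the configured pulse amplitude;
cycle lengths jitter by 1 % SD. `amp_coupling` scales the pulse amplitude
with instantaneous wave height, reproducing the observed rise of
pulsatility on wave tops. Noise is Gaussian low-passed at 10 Hz —
sensor noise in ICP traces is band-limited, and the rescaled-after-filter
SD keeps per-beat extremes honest. Defaults describe a quiet overnight
pediatric recording: 200 Hz from 20:00, baseline 12 mmHg, 120 bpm,
4 mmHg pulse, P2/P1 = 0.8, 30 breaths/min at 1 mmHg, noise SD 0.2 mmHg.

Ground truth records the injected intervals, classes (by the 10 mmHg
rule; out-of-band or sub-10-min segments are marked `non_B` and excluded
from the true burden), configured pulse amplitudes, and clean-trace
stratum means. Overlapping plateau and train specifications are rejected
to keep the truth unambiguous.

The cohort generator draws per-patient records from distributions spanning
the ranges reported for this population (mean ICP ~6.7–29 mmHg, nocturnal
B-wave burden ~23–75 %, `ICP_AMP1` around 4 mmHg and `ICP_AMP2` around
11 mmHg log-normally, Evans' index 0.23–0.34) plus demographics, and one
matching recording spec per patient; signals are generated on demand
rather than materialized, since 36 full-night traces are large.

**What passing tests show — and don't.** Recovery tests demonstrate that
the detectors are correct against the stated definitions under realistic
amplitudes, frequencies and noise, and that boundary content (4 waves/min,
8-min episodes) is never misreported. They do not establish performance on
real recordings: the generator has stationary noise, no baroreflex or
sleep-stage structure, stylized artifacts, and wave shapes that are
smoother than real B-waves (the ramp option only partially addresses
this). Absolute-pressure offsets of epidural sensors, a known limitation
of the measurement itself, are likewise not modelled.

## Problem sizes and tolerances

Simulation-based tests use overnight (12-h) recordings at 20–60 Hz for
slow-wave content — slow-wave detection operates on a 1 Hz channel, so
nothing is lost — and short (1–11 min) segments at 100–200 Hz where beat
morphology matters; these sizes keep the full suite and the acceptance
script fast while exercising every code path at clinically realistic
durations. Recovery tolerances: train count ± 1, class exact, nocturnal
burden ± 5 points, pulse amplitude ± 0.5 mmHg; filter-vs-oracle agreement
is required to 1e-9 per interior sample, and small-sample p-values to
1e-9 of enumeration.

## Known limitations

* Beat sub-peak resolution degrades below ~100 Hz sampling; morphology is
  then reported indeterminate rather than guessed.
* The plateau detector's trailing-median baseline biases onset estimates
  slightly late (bounded by the 30-s ramp in simulations).
* EDF input is a thin optional path through `mne`; LabChart native files
  and digitized pen-recorder charts are out of scope.
* The exact Mann–Whitney enumerates up to C(16, 8) = 12 870 assignments;
  beyond n = 8 per group it hands over to the asymptotic approximation by
  design.
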