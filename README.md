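# icpwaves

Analysis of continuous intracranial-pressure (ICP) recordings in children
monitored for benign external hydrocephalus (BEH) — infants with
macrocephaly and enlarged frontal subarachnoid spaces in whom the decision
to place a CSF shunt hinges on what overnight ICP monitoring shows.

The package is for neuromonitoring labs and methods researchers who need
the visual, manual review workflow of such monitoring turned into explicit,
reproducible, testable code:

* **Slow (Lundberg) waves.** B-waves are oscillations at 0.5–3 waves/min
  sustained ≥ 10 min on a smoothed display channel, split into
  low-amplitude (< 10 mmHg) and high-amplitude (≥ 10 mmHg) classes;
  plateau (A-) waves are abrupt elevations ≥ 20 mmHg above baseline
  lasting 5–30 min. Nocturnal burden is the percentage of the night
  (22:01–07:59) occupied by wave trains.
* **Cardiac pulse amplitude.** Per beat,
  `ICP_AMP = systolic max − diastolic min` (mmHg), summarized over two
  10-min windows: `ICP_AMP1` on a quiet baseline stretch at the lowest
  mean ICP without slow waves, and `ICP_AMP2` on top of the
  largest-amplitude wave train. An amplitude ≥ 5 mmHg, or a pulse shape
  with P2 > P1, indicates reduced intracranial compliance.
* **Shunt criteria.** Criterion A: any high-amplitude B- or A-wave
  activity. Criterion B: low-amplitude B-waves in > 10 % of the recording
  time together with `ICP_AMP1 ≥ 5` mmHg or `ICP_AMP2 > 5` mmHg.
* **Cohort statistics.** Shapiro–Wilk-guided choice between t-test /
  mean ± SD and Mann–Whitney / median (min–max); χ² without continuity
  correction or Fisher's exact test for 2×2 tables; exact small-sample
  Mann–Whitney by enumeration.
* **Synthetic recordings.** A seeded generator produces overnight ICP
  traces with known trains, plateaus, P1/P2/P3 pulse morphology,
  respiratory modulation, artifacts and ground truth, so every stage is
  testable without clinical data.

## Worked example

```python
from datetime import datetime
from icpwaves import (RecordingAnalysis, SimulationSpec, BWaveTrainSpec,
                      simulate_icp_recording)

spec = SimulationSpec(
    duration_s=12 * 3600, sampling_rate=60, baseline_icp=12.0, noise_sd=0.2,
    amp_coupling=2.0,
    b_wave_trains=(
        BWaveTrainSpec(start_s=3 * 3600, duration_s=2 * 3600,
                       freq_per_min=1.0, amplitude=6.0),
        BWaveTrainSpec(start_s=6 * 3600, duration_s=1.5 * 3600,
                       freq_per_min=1.5, amplitude=14.0),
    ),
    seed=11, start_clock=datetime(2000, 1, 1, 20, 0, 0),
)
signal, truth = simulate_icp_recording(spec)
res = RecordingAnalysis(signal).fit()
print(res.summary())
```

prints

```
ICP recording analysis
======================================================
patient            sim
duration           12.0 h at 60 Hz
valid samples      100.0%
------------------------------------------------------
mean ICP           total 15.2 mmHg, day 13.6, night 15.6
B-wave trains      2 (low 1, high 1); plateau waves 0
nocturnal B-waves  low 20.0%, high 15.0%, total 35.0% of the night
ICP_AMP1           4.0 mmHg (normal, morphology normal)
ICP_AMP2           7.6 mmHg (abnormal, morphology normal)
------------------------------------------------------
shunt criteria     met=True (criterion A)
```

Reading the output: both injected trains were found and classified
correctly (configured 6 mmHg → low, 14 mmHg → high), and the recovered
nocturnal burden (20 % + 15 %) matches the simulated ground truth exactly.
The quiet-baseline pulse amplitude (4.0 mmHg, normal) doubles on wave tops
because the simulation coupled pulse amplitude to wave activity; the
wave-top value crosses the 5 mmHg compliance threshold, and the presence of
any high-amplitude train fires shunt criterion A.

The same pipeline runs from a shell:

```bash
icpwaves simulate spec.yaml --signal-out rec.csv --truth-out truth.json
icpwaves analyze rec.csv --sampling-rate 200 --json-out metrics.json
icpwaves cohort patients.csv --grouping preterm --csv-out table.csv
```

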