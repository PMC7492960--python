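# neoseize

Evaluation of clinical neonatal seizure recognition against a dual-expert
EEG gold standard.

Neonatal seizures are mostly electrographic-only and hard to recognise at
the cot side, even with continuous conventional EEG (cEEG) displayed.
Multicentre trials of bedside decision support therefore judge the clinical
team — their hourly seizure record forms and antiseizure-medication (ASM)
decisions — against post-hoc annotation of the full EEG by two independent
expert neurophysiologists. `neoseize` implements that entire evaluation
computation for biostatisticians and trialists:

* **Consensus annotation** — an electrographic seizure is confirmed iff the
  two expert annotations overlap by ≥ 30 s; confirmed events define the
  seizure neonates, the seizure hours (60-min bins from recording start),
  and the burden summaries (total min, max hourly min/h, median duration s).
* **Clinical scoring** — a gold seizure hour counts as identified if the
  form is marked or ASM given in that hour or the next; a marked hour with
  no seizure in it or the hour before is a false detection; an ASM dose
  with no seizure in its hour or the hour before is inappropriate.
* **Accuracy statistics** — sensitivity 100·tp/(tp+fn), specificity
  100·tn/(tn+fp), false detection rate 100·fp/(fp+tp) at neonate level;
  pooled-ratio sensitivity at hour level, overall and by weekday/weekend
  and day/night shift; between-group differences. Confidence intervals are
  bias-corrected (BC) percentile bootstrap intervals with neonates
  resampled with replacement within group × hospital clusters (sizes
  preserved): z₀ = Φ⁻¹(b/B), endpoints at bootstrap quantiles
  Φ(2z₀ + z_{α/2}) and Φ(2z₀ + z_{1−α/2}). Post-hoc contrasts use a
  logistic interaction model (Wald test for the group × period term), and
  the sample-size arithmetic (n = 2(z_{1−α/2}+z_{1−β})²σ²/δ² seizure
  neonates per group, inflated by expected prevalence) is included.
* **Synthetic cohorts** — clinical EEG datasets of this kind are not
  shareable, so a generator emulates the full trial structure (two arms of
  130 neonates over 8 hospitals, 25/29% seizure prevalence, bout-structured
  seizure trains, imperfect annotators, burden-dependent clinical
  detection) with ground truth emitted alongside, including a
  `plant_group_effect` calibrator for parameter-recovery studies.

## Worked example

`examples/` contains one short script per capability. The first one builds
two expert annotations and derives the gold standard:

```python
from neoseize import AnnotationSet, build_consensus, burden_summary, seizure_hours

expert1 = AnnotationSet("baby01", "E1", [(120, 300), (3550, 3720), (5000, 5020)])
expert2 = AnnotationSet("baby01", "E2", [(140, 290), (3540, 3700), (6000, 6015)])
consensus = build_consensus(expert1, expert2, recording_duration_h=2.0)
```

Running `python examples/01_consensus_and_burden.py` prints:

```
confirmed seizures (start_s, end_s):
  (  140.0,   290.0)  duration 150.0 s
  ( 3550.0,  3700.0)  duration 150.0 s
seizure hours: [0, 1]
total burden      5.00 min
max hourly burden 3.33 min/h
median duration   150 s over 2 events
```

The 150 s overlaps survive the 30 s rule; the two short events (20 s and
15 s, never co-annotated) are excluded from the gold standard. The second
seizure crosses the 3600 s boundary, so both hour 0 and hour 1 are seizure
hours, and the worst hour holds 200 s = 3.33 min/h.

`examples/05_full_pipeline.py` simulates a full trial and runs the whole
evaluation; its first table looks like

```
              metric         group  estimate  ci_low  ci_high  n_num  n_den
         sensitivity     algorithm      92.6    79.3    100.0   25.0   27.0
         specificity     algorithm      74.8    66.0     82.2   77.0  103.0
false_detection_rate     algorithm      51.0    36.8     64.0   26.0   51.0
```

i.e. 25 of the 27 seizure neonates in the simulated algorithm arm were
identified by the clinical team (sensitivity 92.6%, 95% BC bootstrap CI
79.3–100.0). A thin CLI mirrors the library
(`neoseize simulate|validate|consensus|score|ci|report`).

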