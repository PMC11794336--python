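# msrobust — EEG microstates vs. ICA artifact-removal intensity

Resting-state EEG microstates are the handful of quasi-stable scalp
topographies that dominate the signal for 40–120 ms at a time before
switching. Their maps and temporal features (duration, occurrence,
coverage, explained variance) are widely used as markers of large-scale
brain dynamics — but they are extracted *after* an artifact-removal step
that differs from lab to lab. `msrobust` is a tested, reproducible
pipeline for asking how much that step matters: it runs the same
microstate analysis at four increasing ICA cleaning intensities and
quantifies what changes.

It is written for EEG methodologists and pipeline builders. Everything is
exercised on synthetic eyes-open / eyes-closed (EO/EC) sessions with
complete ground truth (planted templates, state sequence, artifact
sources), so every stage is scored against known answers rather than
against convention.

## The model in brief

* Frames follow a semi-Markov switching model
  `x_t = a_t·T_{s_t} + noise` with dwell times uniform on 40–120 ms;
  polarity is ignored (`|r|` spatial correlation, dissimilarity
  `d = 1 − |r|`).
* Templates are extracted from GFP-peak maps by polarity-invariant
  modified k-means (200 restarts; best Global Explained Variance wins):

      GEV = Σ_t GFP_t² · r²(x_t, T_{a(t)}) / Σ_t GFP_t²

* The number of microstates k ∈ 2..8 is chosen by a meta-criterion: the
  median of the optima of six cluster-validity indices (gamma, silhouette,
  Davies–Bouldin, point-biserial, robust Dunn, Krzanowski–Lai).
* ICs are scored by *dipolarity* `dip = 100·(1 − resvar)` of an
  equivalent-dipole fit in a four-shell spherical head model (radii
  71/72/79/85 mm), classified by a deterministic rule-based classifier
  over {brain, muscle, eye, heart, line, channel, other}, and removed at
  four levels: **RAW** (nothing), **EYES** (ocular, p > 0.80 ∧ dip > 85%),
  **ART** (+ heart, + dipolar muscle), **HARD** (everything except
  reliable brain ICs).
* Cleaned recordings are backfit winner-takes-all (threshold 0.5, 24 ms
  temporal smoothing) and features compared by a 3-way ANOVA
  (condition × level × map) with Tukey contrasts.

See `docs/methods.md` for the full model, parameter table and limitations.

## Worked example

Simulate one blink-contaminated EO/EC session, clean it at the EYES level,
pick the model order, and fit:

```python
from msrobust import SimulationConfig, make_session, fit_ica, RemovalPolicy
from msrobust.preprocess import (apply_zero_phase_filter, HIGHPASS_1HZ,
                                 LOWPASS_45HZ, reject_extreme_epochs,
                                 average_reference)
from msrobust.ica_clean import build_ic_table, select_ics, remove_ics, pvaf_removed
from msrobust.evaluation import condition_peak_maps
from msrobust import microstates as ms
from msrobust.backfit import label_frames, temporal_smoothing, compute_features

rec, truth = make_session(SimulationConfig(seed=7))
r = apply_zero_phase_filter(rec, HIGHPASS_1HZ)
r = apply_zero_phase_filter(r, LOWPASS_45HZ)
keep = reject_extreme_epochs(r)
r = average_reference(r)

dec = fit_ica(r, seed=7, max_iter=200)
table = build_ic_table(dec, r.fs, r.montage)
removed = select_ics(table, RemovalPolicy("EYES"))
clean = remove_ics(r, dec, removed)
print(f"removed {sorted(removed)} of {dec.n_ic} ICs at EYES "
      f"(pvaf {pvaf_removed(r, clean):.1f}%)")

maps, w = condition_peak_maps(clean, keep, None, 1000, seed=7)
segs = {k: ms.modified_kmeans(maps, k, weights=w, n_restarts=100, seed=7)[1]
        for k in range(2, 9)}
meta_k, mean_k, cand = ms.meta_criterion(ms.validity_criteria(maps, segs))
print(f"meta-criterion: k = {meta_k} (mean {mean_k:.2f}, candidates {cand})")

tpl, _ = ms.modified_kmeans(maps, meta_k, weights=w, n_restarts=100, seed=7,
                            montage=r.montage)
seg = temporal_smoothing(label_frames(clean, tpl, 0.5), 6)
print(compute_features(seg, ms.gfp(clean).values).round(3))
```

Output:

```
removed [7, 10] of 18 ICs at EYES (pvaf 1.5%)
meta-criterion: k = 5 (mean 5.00, candidates [5])
 map  duration_ms  occurrence  coverage   gev
   0       66.816       3.125     0.209 0.191
   1       64.762       3.325     0.215 0.175
   2       64.751       3.158     0.204 0.166
   3       65.358       2.708     0.176 0.154
   4       59.544       2.850     0.170 0.105
```

Two ocular ICs were removed (1.5% of the variance — blinks are large but
brief); the six validity criteria unanimously recover the five planted
states; the five fitted maps correlate 0.985–0.992 with the planted
templates; durations land in the expected tens-of-milliseconds range
(somewhat below the planted 80 ms mean — threshold-based fitting splits
segments at noisy frames; `docs/methods.md` quantifies the bias).

The full four-level study — n subjects, all levels, two-level clustering,
pooled-template backfit, pairing matrices, ANOVA, ground-truth recovery
report — is one call (or `msrobust run --out studydir` on the command
line):

```python
from msrobust.evaluation import StudyConfig, run_full_study
report = run_full_study(StudyConfig(n_subjects=6, seed=1), out_dir="study")
```

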