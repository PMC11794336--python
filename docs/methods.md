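# Methods

`msrobust` implements, end to end, a resting-state EEG microstate pipeline
whose purpose is to measure how the *intensity* of ICA-based artifact
removal changes microstate topographies and features. Because no public
dataset ships with the package, every stage is exercised on synthetic
eyes-open / eyes-closed (EO/EC) sessions with full ground truth: the
quasi-stable scalp templates, the per-sample state sequence, and every
artifact source (pattern x time course) are known exactly, so each stage
can be scored rather than eyeballed.

## The microstate model

Spontaneous EEG topographies do not drift continuously; they linger in one
of a small number of quasi-stable scalp maps for tens of milliseconds and
then switch abruptly. The pipeline models this as a semi-Markov process:
`k` templates `T_1..T_k` (zero-mean, unit-norm maps over channels), a state
sequence with dwell times drawn i.i.d. uniform on [40, 120] ms (mean
80 ms), and no self-transitions. The observed frame at time `t` is

    x_t = a_t * T_{s_t} + noise,    a_t > 0,

with `a_t` a positive amplitude envelope. Polarity is ignored throughout
the analysis chain: spatial similarity between maps is `|r|`, the absolute
spatial Pearson correlation, and every dissimilarity used downstream is
`d = 1 - |r|`.

Global Field Power, `GFP(t)`, is the spatial standard deviation of the
scalp map at `t`. GFP maxima are moments of maximal topographic
signal-to-noise, so template extraction uses only GFP-peak maps.

The Global Explained Variance of a template set on maps with weights
`w_t = GFP(t)` is

    GEV = sum_t w_t^2 r^2(x_t, T_{a(t)}) / sum_t w_t^2,

with `a(t)` the winner-takes-all assignment.

## Synthetic sessions (the study conditions)

Defaults: 19-channel 10-10 montage (62- and 12-channel layouts available),
four alternating 30 s EC/EO blocks at 250 Hz, `k = 5` states, 10 dB
background SNR. The generator's layers:

* **Templates** are forward projections of one random intracranial dipole
  or a bilateral mirrored pair (independent moments) in the four-shell
  spherical head model, average-referenced and unit-normalised, drawn until
  every pairwise `|r| <= 0.5`. Canonical resting-state maps are clearly
  distinct from one another; 0.5 sits well inside the looser 0.7
  admissibility bound the generator enforces as a hard invariant.
* **Amplitude envelope**: rectified 12 Hz-low-passed noise, mean one.
  Scalp fields wax and wane at roughly alpha rate; an envelope that only
  drifted below ~4 Hz would make brain components spectrally
  indistinguishable from slow ocular components, which real data do not
  show.
* **Background noise**: 24 random-dipole patterns driven by 1/f time
  courses, scaled so that the channel-averaged state-signal/noise variance
  ratio equals the configured SNR in dB.
* **Artifacts** (pattern x time course, amplitudes as multiples of the
  clean recording's median GFP):
  - *eye blinks* (10x): biphasic 200-400 ms pulses at 10/min, EO blocks
    only, on the average-referenced forward field of a symmetric vertical
    eyeball dipole pair — frontal-maximal with the posterior negative
    offset that average reference imposes;
  - *lateral eye movements* (3x): square gaze steps, EO only, on the
    antisymmetric horizontal pair field;
  - *muscle* (0.5x): 20-45 Hz carriers modulated by slow positive
    envelopes (bursty, super-Gaussian — a stationary Gaussian EMG proxy
    would be unidentifiable by any plain ICA), on broad edge-localised
    patterns at T7/T8;
  - *heartbeat* (1.5x): a Mexican-hat QRS-like wavelet at ~1.1 Hz with 2%
    beat jitter on a diagonal-gradient map;
  - *line noise* (0.5x): 50 Hz sinusoid on a broad near-global map;
  - *electrode pops* (20x): rare (~2/min) one-channel bursts. Pops are
    deliberately in the few-hundred-microvolt class: they are exactly what
    extreme-epoch rejection exists to remove.

The contaminated recording minus the clean one equals the sum of the
stored artifact back-projections exactly (same accumulation order), so
artifact-level scoring is exact.

What the generator does **not** emulate: cortical geometry and realistic
source spectra, volume-conduction differences of a BEM head, vigilance
drift, eye-tracking-coupled gaze behaviour, inter-subject montage
variability. Passing tests therefore demonstrate that the *pipeline
machinery* is correct and that its comparative claims hold under the
modelled physics — not that any specific real dataset would produce the
same numbers.

## Signal conditioning

Zero-phase Chebyshev-II filtering (1 Hz high-pass, design order 24; 45 Hz
low-pass, design order 70; both applied forward-backward so the effective
order doubles and phase is exactly zero; stopband attenuation 40 dB,
cutoff = stopband edge in scipy's convention), polyphase resampling to
250 Hz, robust bad-channel detection (kurtosis or peak-to-peak range with
|robust z| > 6, median/MAD across channels — an outlying channel must not
corrupt the statistics it is tested against), order-4 spherical-spline
interpolation (regularisation 1e-5, 50 Legendre terms) of flagged
channels, and average re-referencing (which reduces the data rank by
exactly one). An extreme-amplitude epoch screen (1 s epochs, same robust
6 SD range rule, one padding epoch each side for filter ring-down) runs
before ICA; it belongs to *every* cleaning level, including RAW.

## ICA and the four cleaning levels

ICA runs on the rank-reduced (channels - 1) subspace left by average
referencing. The solver is pluggable: the default is FastICA (fast and
deterministic under a seed); extended infomax is available. What the
pipeline relies on — and what the tests enforce — is the contract, not the
solver: maximal temporal independence (cross-talk < 0.05 on planted
sources), determinism, and a likelihood-based sample-rejection analog
(samples whose logistic-model log-likelihood is > 5 SD from the mean are
dropped and the fit repeated, up to 3 passes; the final unmixing is
applied back to the full data). The nominal iteration cap is 2000; the
study pipeline passes 200 for FastICA, whose fixed-point updates plateau
far earlier (verified: identical recovery quality at 200 vs 2000).

Each IC topography gets an equivalent-dipole fit in the four-shell
concentric spherical head model (radii 71/72/79/85 mm, conductivities
0.33/0.0042/1/0.33): coarse 1 cm grid search inside the brain shell, then
Nelder-Mead refinement of the position with the moment solved linearly at
every step. Ocular ICs are refit with a mirrored symmetric pair (ocular
generators come in twos). Dipolarity is `dip = 100 * (1 - resvar)`.

The forward solution expands the dipole potential in spherical harmonics
and solves the per-order boundary conditions of the four shells as a 7x7
linear system (series truncated at order 60; terms decay like
`(b/R)^(n-1)`). With all conductivities equal it reproduces the
closed-form homogeneous-sphere surface potential (per-order factor
`(2n+1)/n`) to machine precision — the two derivations are independent, so
this is the standing oracle for the solver.

ICs are classified over {brain, muscle, eye, heart, line, channel, other}
by a deterministic rule-based scorer: products of sigmoid feature
detectors (frontal energy concentration and low-frequency dominance for
eye; >20 Hz power fraction on broad lateralised maps for muscle; a regular
~1 Hz train of sharp peaks for heart; the relative 50/60 Hz spectral peak
for line; single-channel energy dominance for channel noise; dipolarity
with a 1/f-falling spectrum for brain), passed through a temperature-1
softmax (gain 6) so scores sum to one. The detectors gate one another
(e.g. a dominant mains peak vetoes muscle; a one-channel map vetoes eye)
— the gates encode the same exclusions a human rater applies. The
classifier is scored against ground truth on well-isolated components;
when the ICA itself fails to isolate a weak source (short desk-scale
sessions make the 1.5x heart source genuinely marginal), the mixed
component's "true" class is undefined and no classifier can recover it.

Removal levels gate on class probability `p > 0.80` and dipolarity
`dip > 85%`:

| level | removed |
|---|---|
| RAW | nothing |
| EYES | eye ICs with `p > 0.80` and `dip > 85` |
| ART | EYES + heart (`p > 0.80`; no dipolarity gate by default, configurable) + muscle (`p > 0.80` and `dip > 85`) |
| HARD | everything except brain ICs with `p > 0.80` and `dip > 85` |

The HARD brain-dipolarity threshold is configurable (85 by default; 80 is
the other defensible reading of the source material). Removal sets nest
(RAW ⊆ EYES ⊆ ART ⊆ HARD) by construction. Removal is implemented as
subtraction of the removed ICs' back-projection (equivalent to zeroing
mixing columns, but the empty set reproduces the input exactly).
`pvaf_removed` uses the difference-variance form:
`100 * sum_ch var(original - cleaned) / sum_ch var(original)`.

## Template extraction and model order

Per subject and condition, GFP-peak maps (strict local maxima, thinned to
>= 3 samples apart, peaks inside rejected epochs excluded) are capped at
the 1000 *highest-GFP* peaks. The cap-by-GFP choice extends the rationale
for using GFP peaks in the first place — high GFP means high topographic
SNR — and measurably stabilises the model-order criteria relative to a
uniform random cap.

Modified k-means: templates initialised from random data maps, each map
assigned to the template with the highest `|r|` (ties: lowest index),
templates updated as the sign-aligned arithmetic mean of their members and
renormalised, iterated until the GEV stabilises (relative tolerance 1e-6)
or the assignment repeats; an emptied cluster is re-seeded from the
worst-fit map. 200 restarts by default; the best restart by GEV wins.
Returned templates are ordered by descending explained weight.

Model order is chosen over k = 2..8 by six cluster-validity indices on
`d = 1 - |r|`: Goodman-Kruskal gamma, silhouette, Davies-Bouldin (sign
flipped so higher is better), point-biserial, a robust Dunn ratio (10th
percentile of between-cluster over 90th percentile of within-cluster
distances — percentile aggregates because single outlier maps otherwise
own the classic min/max ratio), and Krzanowski-Lai (undefined at the
endpoints of the k range). The **meta-criterion** is the median of the
per-criterion optima (lower median on ties); the mean criterion and the
set of all per-criterion optima are reported alongside.

Two-level clustering: level 1 runs per subject at fixed k = 8 (the top of
the evaluated range; the level-2 criteria decide the final k), level 2
pools all subject templates and clusters them for each k with the same
algorithm. At desk scale the pooled-template criteria run on few, noisy
maps (8 per subject of which ~3 are not genuine states), so the
study-level meta-criteria are noticeably noisier than the single-session
path — a known desk-scale limitation; the calibrated model-order result is
the single-session EYES-level recovery.

## Backfitting and features

Every frame of the (cleaned, average-referenced) recording is labeled with
the template of highest `|r|`; frames below 0.5 stay unlabeled, as do
zero-variance frames. Labeling is per block, so segments never straddle an
EO/EC boundary. Temporal smoothing dissolves labeled segments shorter
than 6 samples (24 ms at 250 Hz), shortest first (ties: earliest), sample
by sample toward the adjacent label with the higher per-sample
correlation; unlabeled runs are never modified, and the pass repeats until
stable.

Features per map: *duration* (mean segment length in ms; segments touching
a block edge are censored dwell times and are excluded whenever interior
segments exist), *occurrence* (segments per second, edge segments
counted), *coverage* (labeled samples over all samples, unlabeled frames
included in the denominator), *GEV* (GFP^2-weighted squared correlation
over the map's samples). Unlabeled gaps split segments. The identity
`coverage ~= duration x occurrence` holds to ~1e-4 up to edge censoring.
Measured durations on artifact-free data run ~6-8% below the planted 80 ms
mean: noise-induced splits and sub-threshold frames shorten segments — a
bias inherent to threshold-based winner-takes-all fitting, not a bug.

The full study fits *one* pooled template set (all conditions and levels
merged, k = median of the per-(condition, level) meta-criteria) to avoid
per-level fitting bias, then compares features with a fixed-effects 3-way
ANOVA (condition x level x map) per feature, with Tukey-HSD pairwise
contrasts on each factor (statsmodels; an all-identical response is
reported as "no effect" rather than as numerical-noise F ratios).
Template sets are compared across conditions/levels by exhaustive-search
pairing maximising the summed `|r|` (k <= 8, so at most 8! permutations).

## Numerical and design notes

* All randomness flows from integer seeds through `numpy`'s SeedSequence;
  every stage is bit-reproducible under a fixed seed.
* Desk-scale sizes (19 channels, 4 x 30 s blocks, 6 subjects, 50 restarts
  in the study driver) were chosen so a full study runs in minutes on one
  CPU; the library defaults keep the reference values (200 restarts, 2000
  ICA iterations) where a published number exists.
* EDF is the canonical on-disk format (16-bit, 1 s records, EO/EC blocks
  as standard annotations); BrainVision is read-only. The EDF writer is
  in-repo because no installed library writes EDF.
* The optimal-pairing step, the IC classifier thresholds, and the
  validity-index battery are deterministic; the only stochastic stages are
  the simulator, FastICA, and the k-means restarts, all seeded.

## Known limitations

* Weak, temporally sparse sources (the realistic-amplitude heartbeat) are
  often not isolated by ICA in 2-minute sessions; their ICs then classify
  as brain/other. Longer sessions or stronger priors would be needed.
* The blink map's frontal/occipital variance ratio is ~3.4, not the order
  of magnitude seen against raw references: average reference spreads a
  common negative offset across posterior channels by construction.
* Study-level (two-level) meta-criteria overshoot at desk scale (see
  above).
* HARD cleaning can *lower* the cross-condition template correlation on
  some seeds: bilateral (two-dipole) state generators have modest
  single-dipole dipolarity, so the brain gate occasionally discards a
  genuine state — the aggressive end of the trade-off costs physiological
  signal by design.
* The simulator's artifact topographies are fixed per session; real
  muscle and movement artifacts drift spatially, which makes them *less*
  clusterable than our worst case — the "clustering naturally rejects
  non-ocular artifacts" behaviour should, if anything, be stronger on real
  data.
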