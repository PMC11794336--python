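"""Synthetic resting-state EO/EC sessions with known microstate dynamics.

A session is built in three layers, each with recoverable ground truth:

1. *Microstate dynamics* — ``k`` quasi-stable scalp templates (forward
   projections of one or two intracranial dipoles) switch according to a
   semi-Markov sequence with uniformly distributed dwell times (default
   40-120 ms, i.e. mean 80 ms), modulated by a positive amplitude envelope.
2. *Background noise* — spatially smooth 1/f sensor noise built from many
   weak random dipoles, scaled to a configured SNR.
3. *Artifacts* — six stereotyped families (eye blinks, lateral eye
   movements, muscle, heartbeat, line noise, single-channel pops), each a
   fixed topography times a time course.  Ocular artifacts occur only in
   eyes-open blocks, mirroring real blink behaviour.

The injected recording minus the clean recording equals the sum of the
stored artifact back-projections exactly, so every downstream stage can be
scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .data_model import Block, Montage, Recording, Topography, standard_1010_montage
from .headmodel import HeadModel, dipole_forward

__all__ = [
    "SimulationConfig",
    "ArtifactSource",
    "GroundTruth",
    "make_templates",
    "simulate_state_sequence",
    "synthesize_clean_eeg",
    "inject_artifacts",
    "make_session",
]

ARTIFACT_KINDS = ("eye_blink", "eye_lateral", "muscle", "heart", "line", "channel")

#: approximate eyeball centres, head-centred RAS, mm (inside the brain shell)
_EYE_L = np.array([-28.0, 58.0, -25.0])
_EYE_R = np.array([28.0, 58.0, -25.0])


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic session.

    Defaults are the desk-scale conditions: 19 channels, four alternating
    30 s EC/EO blocks at 250 Hz, five states with 40-120 ms dwell times,
    10 dB background SNR, 10 blinks per eyes-open minute with amplitude
    10x the median clean GFP.
    """

    n_channels: int = 19
    k_states: int = 5
    dwell_ms_range: Tuple[float, float] = (40.0, 120.0)
    block_len_s: float = 30.0
    n_blocks: int = 4
    fs: float = 250.0
    snr_db: float = 10.0
    #: maximum pairwise |spatial correlation| between planted templates;
    #: canonical resting-state maps are clearly distinct, so the default
    #: sits well inside the 0.7 admissibility bound.
    template_max_r: float = 0.5
    #: separate seed for the template draw, so a cohort of subjects can
    #: share one canonical template set while dynamics/artifacts differ;
    #: None means "use ``seed``"
    template_seed: Optional[int] = None
    blink_rate_EO: float = 10.0  # per minute
    #: per-kind amplitude as a multiple of the clean recording's median GFP
    artifact_amplitude: Dict[str, float] = field(
        default_factory=lambda: {
            "eye_blink": 10.0,
            "eye_lateral": 3.0,
            "muscle": 0.5,
            "heart": 1.5,
            "line": 0.5,
            "channel": 20.0,
        }
    )
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.dwell_ms_range
        if not (0 < lo <= hi):
            raise ValueError("dwell range must be positive")
        if self.blink_rate_EO < 0 or any(v < 0 for v in self.artifact_amplitude.values()):
            raise ValueError("rates and amplitudes must be nonnegative")
        unknown = set(self.artifact_amplitude) - set(ARTIFACT_KINDS)
        if unknown:
            raise ValueError(f"unknown artifact kind(s): {sorted(unknown)}")


@dataclass
class ArtifactSource:
    """One artifact generator: fixed scalp pattern x time course (microvolts)."""

    kind: str
    topography: np.ndarray  # (n_channels,), unit-norm pattern
    time_course: np.ndarray  # (n_samples,), carries the amplitude

    def back_projection(self) -> np.ndarray:
        return np.outer(self.topography, self.time_course)


@dataclass
class GroundTruth:
    true_templates: List[Topography]
    true_labels: np.ndarray
    artifact_sources: List[ArtifactSource]
    snr_db: float
    seed: int
    dwell_draws_ms: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        k = len(self.true_templates)
        if self.true_labels.size and not (
            self.true_labels.min() >= 0 and self.true_labels.max() < k
        ):
            raise ValueError("true_labels out of range")
        for s in self.artifact_sources:
            if s.kind not in ARTIFACT_KINDS:
                raise ValueError(f"unknown artifact kind {s.kind!r}")

    def artifact_matrix(self, n_samples: int, n_channels: int) -> np.ndarray:
        """Sum of all artifact back-projections."""
        out = np.zeros((n_channels, n_samples))
        for s in self.artifact_sources:
            out += s.back_projection()
        return out

    def to_json(self, path) -> None:
        """Sidecar serialization: templates, run-length-encoded labels,
        and an artifact inventory (kind, peak amplitude, active samples)."""
        runs = []
        lab = self.true_labels
        i = 0
        while i < len(lab):
            j = i
            while j < len(lab) and lab[j] == lab[i]:
                j += 1
            runs.append([int(lab[i]), j - i])
            i = j
        doc = {
            "seed": int(self.seed),
            "snr_db": float(self.snr_db),
            "templates": [t.values.tolist() for t in self.true_templates],
            "channel_labels": list(self.true_templates[0].montage.labels)
            if self.true_templates
            else [],
            "labels_rle": runs,
            "artifacts": [
                {
                    "kind": s.kind,
                    "peak_uv": float(np.abs(s.time_course).max()),
                    "active_samples": int(np.count_nonzero(s.time_course)),
                }
                for s in self.artifact_sources
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


# --------------------------------------------------------------------------
# templates
# --------------------------------------------------------------------------


def _random_dipole_topography(montage, head, rng, n_dipoles) -> np.ndarray:
    """Map of one random dipole, or of a bilateral (mirrored-position) pair
    with independent moments — the two source configurations the equivalent-
    dipole stage models."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    position = rng.uniform(20.0, 0.85 * head.brain_radius_mm) * direction
    moment = rng.normal(size=3)
    moment /= np.linalg.norm(moment)
    v = dipole_forward(position, moment, head, montage).values
    if n_dipoles == 2:
        mirrored = position * np.array([-1.0, 1.0, 1.0])
        moment2 = rng.normal(size=3)
        moment2 /= np.linalg.norm(moment2)
        v = v + dipole_forward(mirrored, moment2, head, montage).values
    v = v - v.mean()
    return v / np.linalg.norm(v)


def make_templates(
    montage: Montage,
    k: int,
    seed: int,
    head: Optional[HeadModel] = None,
    max_sep_r: float = 0.7,
    max_tries: int = 200,
) -> List[Topography]:
    """``k`` dipolar microstate templates with pairwise |r| <= ``max_sep_r``.

    Each template is the forward projection of 1-2 random intracranial
    dipoles, average-referenced and unit-normalised.
    """
    if k < 2:
        raise ValueError("need k >= 2 templates")
    head = head or HeadModel()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    accepted: List[np.ndarray] = []
    tries = 0
    while len(accepted) < k:
        if tries >= max_tries * k:
            raise RuntimeError(
                f"could not find {k} templates with pairwise |r| <= {max_sep_r}"
            )
        tries += 1
        v = _random_dipole_topography(montage, head, rng, int(rng.integers(1, 3)))
        if all(abs(float(v @ u)) <= max_sep_r for u in accepted):
            accepted.append(v)
    return [Topography(v, montage, normalized=True) for v in accepted]


# --------------------------------------------------------------------------
# state sequence
# --------------------------------------------------------------------------


def simulate_state_sequence(
    k: int,
    dwell_range_ms: Tuple[float, float],
    n_samples: int,
    fs: float,
    seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Semi-Markov state sequence: uniform dwell times, no self-transitions.

    Returns ``(labels, dwell_draws_ms)``; the continuous dwell draws are kept
    so the configured uniform law can be tested directly.
    """
    if k < 2:
        raise ValueError("need k >= 2 states")
    lo, hi = dwell_range_ms
    if int(round(lo * fs / 1000.0)) < 1:
        raise ValueError("dwell range must be at least one sample")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    labels = np.empty(n_samples, dtype=np.int64)
    draws = []
    t = 0
    state = int(rng.integers(k))
    while t < n_samples:
        dwell_ms = float(rng.uniform(lo, hi))
        draws.append(dwell_ms)
        n = max(1, int(round(dwell_ms * fs / 1000.0)))
        labels[t : t + n] = state
        t += n
        nxt = int(rng.integers(k - 1))
        state = nxt if nxt < state else nxt + 1
    return labels, np.array(draws)


# --------------------------------------------------------------------------
# clean EEG
# --------------------------------------------------------------------------


def _one_over_f_noise(n: int, rng, exponent: float = 1.0) -> np.ndarray:
    """Unit-variance noise with power spectral density ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    spec[0] = 0.0
    out = np.fft.irfft(spec, n)
    return out / out.std()


def _smooth_envelope(n: int, fs: float, rng, cutoff_hz: float = 4.0) -> np.ndarray:
    """Positive amplitude envelope: rectified low-passed noise, mean 1."""
    noise = rng.standard_normal(n)
    sos = sps.butter(4, cutoff_hz / (fs / 2.0), output="sos")
    env = np.abs(sps.sosfiltfilt(sos, noise)) + 0.05
    return env / env.mean()


def synthesize_clean_eeg(
    templates: Sequence[Topography],
    labels: np.ndarray,
    fs: float,
    seed: int,
    snr_db: Optional[float] = 10.0,
    base_gfp_uv: float = 10.0,
    head: Optional[HeadModel] = None,
) -> Recording:
    """State templates x positive envelope + spatially smooth 1/f noise.

    ``snr_db`` is the ratio of state-signal variance to noise variance
    averaged over channels, in dB; ``None`` means noiseless.
    """
    montage = templates[0].montage
    T = np.array([t.values for t in templates])  # (k, ch)
    if labels.max() >= len(templates):
        raise ValueError("labels reference a missing template")
    n = len(labels)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    # scalp fields wax and wane at roughly alpha rate, so the positive
    # amplitude envelope fluctuates up to ~12 Hz (not just slow drifts);
    # this keeps brain components spectrally distinct from slow ocular ICs
    env = _smooth_envelope(n, fs, rng, cutoff_hz=12.0)
    amp = base_gfp_uv * np.sqrt(montage.n_channels)  # unit-norm map -> GFP base_gfp
    data = (T[labels] * (amp * env)[:, None]).T  # (ch, n)

    if snr_db is not None and np.isfinite(snr_db):
        head = head or HeadModel()
        q = 24
        maps = np.array(
            [_random_dipole_topography(montage, head, rng, 1) for _ in range(q)]
        )
        courses = np.array([_one_over_f_noise(n, rng) for _ in range(q)])
        noise = maps.T @ courses
        sig_var = data.var(axis=1).mean()
        noise_var = noise.var(axis=1).mean()
        target = sig_var / (10.0 ** (snr_db / 10.0))
        noise *= np.sqrt(target / noise_var)
        data = data + noise
    return Recording(data=data, fs=fs, montage=montage, reference="common")


# --------------------------------------------------------------------------
# artifacts
# --------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    return v / np.linalg.norm(v)


def _blink_topography(montage, head) -> np.ndarray:
    """Frontal-maximal symmetric dual-dipole map (vertical eye dipoles)."""
    m = np.array([0.0, 0.4, 1.0])
    m /= np.linalg.norm(m)
    v = (
        dipole_forward(_EYE_L, m, head, montage).values
        + dipole_forward(_EYE_R, m, head, montage).values
    )
    return _unit(v)


def _lateral_eye_topography(montage, head) -> np.ndarray:
    """Left-right antisymmetric dual-dipole map (horizontal gaze)."""
    m = np.array([1.0, 0.0, 0.0])
    v = (
        dipole_forward(_EYE_L, m, head, montage).values
        + dipole_forward(_EYE_R, m, head, montage).values
    )
    return _unit(v)


def _edge_topography(montage, centre_label: str, sigma_mm: float = 40.0) -> np.ndarray:
    """Pattern concentrated around one (edge) electrode."""
    c = montage.positions[montage.index(centre_label)]
    d = np.linalg.norm(montage.positions - c, axis=1)
    return _unit(np.exp(-0.5 * (d / sigma_mm) ** 2))


def _gradient_topography(montage, direction: np.ndarray) -> np.ndarray:
    return _unit(montage.positions @ direction)


def _blink_pulse(fs: float, dur_s: float) -> np.ndarray:
    """Biphasic blink pulse: dominant positive lobe + small undershoot."""
    n = max(4, int(round(dur_s * fs)))
    n_pos = max(2, int(round(n * 0.7)))
    pulse = np.zeros(n)
    pulse[:n_pos] = np.hanning(n_pos + 2)[1:-1]
    tail = n - n_pos
    if tail > 1:
        pulse[n_pos:] = -0.2 * np.hanning(tail + 2)[1:-1]
    return pulse


def _ricker(n_points: int, width: float) -> np.ndarray:
    """Mexican-hat (second Gaussian derivative) wavelet, QRS-like."""
    t = np.arange(n_points) - (n_points - 1) / 2.0
    x = (t / width) ** 2
    return (1.0 - x) * np.exp(-x / 2.0)


def _poisson_times(rate_per_s: float, t0: float, t1: float, rng) -> np.ndarray:
    if rate_per_s <= 0:
        return np.array([])
    n = rng.poisson(rate_per_s * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def inject_artifacts(
    rec: Recording,
    config: SimulationConfig,
    seed: int,
    head: Optional[HeadModel] = None,
) -> Tuple[Recording, List[ArtifactSource]]:
    """Add the six artifact families; ocular ones in EO blocks only.

    Returns the contaminated recording and the list of planted sources;
    contaminated - clean == sum of source back-projections, exactly.
    """
    if not rec.blocks:
        raise ValueError("recording has no EO/EC block annotations")
    head = head or HeadModel()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))
    montage, fs, n = rec.montage, rec.fs, rec.n_samples
    gfp = rec.data.std(axis=0, ddof=0)
    med_gfp = float(np.median(gfp))
    amp = {k: config.artifact_amplitude.get(k, 0.0) * med_gfp for k in ARTIFACT_KINDS}
    sources: List[ArtifactSource] = []

    eo_blocks = [b for b in rec.blocks if b.condition == "EO"]

    # (a) blinks: biphasic 200-400 ms pulses at blink_rate_EO, EO only
    if amp["eye_blink"] > 0 and config.blink_rate_EO > 0:
        tc = np.zeros(n)
        for b in eo_blocks:
            for t in _poisson_times(
                config.blink_rate_EO / 60.0, b.start / fs, b.stop / fs, rng
            ):
                pulse = _blink_pulse(fs, rng.uniform(0.2, 0.4))
                i = int(round(t * fs))
                j = min(i + len(pulse), b.stop)
                tc[i:j] += pulse[: j - i]
        sources.append(
            ArtifactSource("eye_blink", _blink_topography(montage, head), amp["eye_blink"] * tc)
        )

    # (b) lateral eye movements: square gaze steps, EO only
    if amp["eye_lateral"] > 0:
        tc = np.zeros(n)
        for b in eo_blocks:
            for t in _poisson_times(8.0 / 60.0, b.start / fs, b.stop / fs, rng):
                i = int(round(t * fs))
                j = min(i + int(round(rng.uniform(0.5, 2.0) * fs)), b.stop)
                tc[i:j] += rng.choice([-1.0, 1.0])
        sources.append(
            ArtifactSource(
                "eye_lateral", _lateral_eye_topography(montage, head), amp["eye_lateral"] * tc
            )
        )

    # (c) muscle: tonic 20-45 Hz activity on edge-localised patterns.
    # EMG waxes and wanes, so the band-limited carrier is modulated by a
    # slow positive envelope (this also makes the source super-Gaussian,
    # as real EMG is, rather than an unidentifiable Gaussian process).
    if amp["muscle"] > 0:
        sos = sps.butter(4, [20.0 / (fs / 2), min(45.0, 0.45 * fs) / (fs / 2)], "bandpass", output="sos")
        for lab in ("T7", "T8"):
            if lab not in montage.labels:
                continue
            tc = sps.sosfiltfilt(sos, rng.standard_normal(n))
            env = _smooth_envelope(n, fs, rng, cutoff_hz=0.5) ** 2
            tc = tc * env
            tc /= tc.std()
            sources.append(
                ArtifactSource("muscle", _edge_topography(montage, lab), amp["muscle"] * tc)
            )

    # (d) heartbeat: QRS-like wavelet train at ~1.1 Hz, diagonal gradient map
    if amp["heart"] > 0:
        tc = np.zeros(n)
        beat = _ricker(int(round(0.08 * fs)) | 1, 0.012 * fs)
        beat /= np.abs(beat).max()
        t = rng.uniform(0, 0.9)
        while t * fs < n:
            i = int(round(t * fs))
            j = min(i + len(beat), n)
            tc[i:j] += beat[: j - i]
            t += 1.0 / 1.1 * rng.uniform(0.98, 1.02)
        topo = _gradient_topography(montage, np.array([0.7, 0.6, 0.4]))
        sources.append(ArtifactSource("heart", topo, amp["heart"] * tc))

    # (e) line noise: 50 Hz sinusoid on a broad topography
    if amp["line"] > 0 and fs > 110.0:
        t = np.arange(n) / fs
        tc = np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        # broad, near-global pattern with a mild vertical gradient
        topo = _unit(
            _edge_topography(montage, "Cz" if "Cz" in montage.labels else montage.labels[0], 90.0)
            + 0.3 * _gradient_topography(montage, np.array([0.2, 0.3, 1.0]))
        )
        sources.append(ArtifactSource("line", topo, amp["line"] * tc))

    # (f) single-channel pops: brief high-amplitude bursts on one channel
    # (kept off the temporal muscle sites so each planted source stays
    # attributable to exactly one artifact family)
    if amp["channel"] > 0:
        candidates = [
            i for i, l in enumerate(montage.labels) if l not in ("T7", "T8")
        ]
        ch = int(rng.choice(candidates))
        topo = np.zeros(montage.n_channels)
        topo[ch] = 1.0
        tc = np.zeros(n)
        for t in _poisson_times(2.0 / 60.0, 0.0, n / fs, rng):
            i = int(round(t * fs))
            j = min(i + int(round(rng.uniform(0.3, 1.0) * fs)), n)
            tc[i:j] += rng.standard_normal(j - i) + rng.choice([-2.0, 2.0])
        sources.append(ArtifactSource("channel", topo, amp["channel"] * tc))

    out = rec.copy()
    if sources:
        art = np.zeros_like(out.data)
        for s in sources:  # same accumulation order as GroundTruth.artifact_matrix
            art += s.back_projection()
        out.data = out.data + art
    return out, sources


# --------------------------------------------------------------------------
# session
# --------------------------------------------------------------------------


def make_session(
    config: SimulationConfig, head: Optional[HeadModel] = None
) -> Tuple[Recording, GroundTruth]:
    """Full synthetic session: alternating EC/EO blocks, planted dynamics,
    EO-dominant ocular contamination.  Deterministic under ``config.seed``."""
    head = head or HeadModel()
    montage = standard_1010_montage(config.n_channels)
    block_n = int(round(config.block_len_s * config.fs))
    n = block_n * config.n_blocks
    blocks = [
        Block(i * block_n, (i + 1) * block_n, "EC" if i % 2 == 0 else "EO")
        for i in range(config.n_blocks)
    ]
    tseed = config.seed if config.template_seed is None else config.template_seed
    templates = make_templates(
        montage, config.k_states, tseed, head, max_sep_r=config.template_max_r
    )
    labels, draws = simulate_state_sequence(
        config.k_states, config.dwell_ms_range, n, config.fs, config.seed
    )
    clean = synthesize_clean_eeg(
        templates, labels, config.fs, config.seed, config.snr_db, head=head
    )
    clean.blocks = blocks
    contaminated, sources = inject_artifacts(clean, config, config.seed, head)
    gt = GroundTruth(
        true_templates=templates,
        true_labels=labels,
        artifact_sources=sources,
        snr_db=config.snr_db,
        seed=config.seed,
        dwell_draws_ms=draws,
    )
    return contaminated, gt
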