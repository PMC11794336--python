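"""Deterministic signal conditioning before ICA and microstate extraction.

The chain is: zero-phase Chebyshev-II band limiting (1 Hz high-pass,
45 Hz low-pass), resampling to 250 Hz, robust bad-channel detection
(kurtosis / amplitude range beyond 6 SD in robust z-units), order-4
spherical-spline interpolation of flagged channels, and average
re-referencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import List, Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

from .data_model import Block, Recording

__all__ = [
    "FilterSpec",
    "ChannelQCReport",
    "apply_zero_phase_filter",
    "designed_response_db",
    "resample",
    "detect_bad_channels",
    "spherical_spline_interpolate",
    "average_reference",
    "reject_extreme_epochs",
]


@dataclass(frozen=True)
class FilterSpec:
    """Chebyshev type II filter design.

    ``cutoff_hz`` is the stopband edge (scipy's cheby2 convention);
    ``order`` is the one-pass design order, applied forward-backward so the
    effective order doubles and the phase response is zero.
    """

    kind: str  # "highpass" | "lowpass"
    cutoff_hz: float
    order: int
    stopband_attenuation_db: float = 40.0
    zero_phase: bool = True

    def __post_init__(self):
        if self.kind not in ("highpass", "lowpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.zero_phase and self.order % 2:
            raise ValueError("zero-phase application requires an even design order")

    def design_sos(self, fs: float) -> np.ndarray:
        if not self.cutoff_hz < fs / 2:
            raise ValueError(f"cutoff {self.cutoff_hz} Hz >= Nyquist ({fs / 2} Hz)")
        sos = sps.cheby2(
            self.order,
            self.stopband_attenuation_db,
            self.cutoff_hz / (fs / 2.0),
            btype=self.kind,
            output="sos",
        )
        # stability diagnostic: all section poles strictly inside unit circle
        for sec in sos:
            poles = np.roots(sec[3:])
            if np.any(np.abs(poles) >= 1.0 - 1e-12):
                raise ValueError(
                    f"unstable {self.kind} design (order {self.order}, "
                    f"{self.cutoff_hz} Hz at fs={fs}): pole modulus "
                    f"{np.abs(poles).max():.6f}"
                )
        return sos


HIGHPASS_1HZ = FilterSpec("highpass", 1.0, 24)
LOWPASS_45HZ = FilterSpec("lowpass", 45.0, 70)


def apply_zero_phase_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Forward-backward (zero-phase) filtering; preserves blocks and fs."""
    sos = spec.design_sos(rec.fs)
    if spec.zero_phase:
        data = sps.sosfiltfilt(sos, rec.data, axis=1)
    else:
        data = sps.sosfilt(sos, rec.data, axis=1)
    return rec.copy(data=np.ascontiguousarray(data))


def designed_response_db(spec: FilterSpec, fs: float, freqs_hz) -> np.ndarray:
    """Analytic magnitude response (dB) of the design at given frequencies,
    including the squaring from forward-backward application."""
    sos = spec.design_sos(fs)
    w = 2 * np.pi * np.atleast_1d(np.asarray(freqs_hz, float)) / fs
    _, h = sps.sosfreqz(sos, worN=w)
    mag = np.abs(h)
    if spec.zero_phase:
        mag = mag ** 2
    return 20.0 * np.log10(np.maximum(mag, 1e-300))


def resample(rec: Recording, target_fs: float = 250.0) -> Recording:
    """Polyphase downsampling; block boundaries are rescaled consistently."""
    if target_fs > rec.fs:
        raise ValueError("upsampling is not supported")
    if np.isclose(target_fs, rec.fs):
        return rec.copy()
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = sps.resample_poly(rec.data, up, down, axis=1)
    n_new = data.shape[1]
    ratio = target_fs / rec.fs
    blocks = [
        Block(int(round(b.start * ratio)), min(int(round(b.stop * ratio)), n_new), b.condition)
        for b in rec.blocks
    ]
    return rec.copy(data=data, fs=float(target_fs), blocks=blocks)


@dataclass
class ChannelQCReport:
    """Per-channel quality metrics and flags.

    Robust z-scores use the median/MAD across channels; a channel is
    flagged when either its kurtosis or its amplitude range deviates by
    more than ``threshold_sd`` robust standard deviations.
    """

    kurtosis: np.ndarray
    amplitude_range: np.ndarray
    z_kurtosis: np.ndarray
    z_range: np.ndarray
    flagged: List[int] = field(default_factory=list)
    threshold_sd: float = 6.0

    def to_dict(self) -> dict:
        return {
            "threshold_sd": self.threshold_sd,
            "kurtosis": self.kurtosis.tolist(),
            "amplitude_range": self.amplitude_range.tolist(),
            "z_kurtosis": self.z_kurtosis.tolist(),
            "z_range": self.z_range.tolist(),
            "flagged": list(map(int, self.flagged)),
        }


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        if iqr == 0:
            return np.zeros_like(x)
        return (x - med) / (iqr / 1.349)
    return (x - med) / (1.4826 * mad)


def detect_bad_channels(rec: Recording, threshold_sd: float = 6.0) -> ChannelQCReport:
    """Flag channels whose kurtosis OR amplitude range is an outlier."""
    if rec.n_channels < 8:
        raise ValueError("channel QC needs at least 8 channels")
    if threshold_sd <= 0:
        raise ValueError("threshold must be positive")
    if np.allclose(rec.data, rec.data[:, :1]):
        raise ValueError("constant data: channel statistics are undefined")
    kurt = stats.kurtosis(rec.data, axis=1, fisher=True, bias=True)
    rng = rec.data.max(axis=1) - rec.data.min(axis=1)
    zk, zr = _robust_z(kurt), _robust_z(rng)
    flagged = sorted(
        int(i)
        for i in np.nonzero((np.abs(zk) > threshold_sd) | (np.abs(zr) > threshold_sd))[0]
    )
    return ChannelQCReport(kurt, rng, zk, zr, flagged, threshold_sd)


# --------------------------------------------------------------------------
# spherical spline interpolation (Perrin et al. 1989 style)
# --------------------------------------------------------------------------


def _spline_g(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Spline basis g(cos) = 1/(4 pi) sum (2n+1)/(n(n+1))^m P_n(cos)."""
    x = np.clip(cosang, -1.0, 1.0)
    out = np.zeros_like(x, dtype=float)
    P_prev = np.ones_like(x)
    P = x.copy()
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / float(n * (n + 1)) ** m * P
        P_next = ((2 * n + 1) * x * P - n * P_prev) / (n + 1)
        P_prev, P = P, P_next
    return out / (4.0 * np.pi)


def spherical_spline_interpolate(
    rec: Recording,
    bad: Sequence[int],
    m: int = 4,
    regularization: float = 1e-5,
    n_terms: int = 50,
) -> Recording:
    """Replace ``bad`` channels with order-``m`` spherical-spline estimates
    computed from the remaining channels; good channels are untouched."""
    bad = sorted(set(int(i) for i in bad))
    if not bad:
        return rec.copy()
    if any(i < 0 or i >= rec.n_channels for i in bad):
        raise ValueError("bad channel index out of range")
    good = [i for i in range(rec.n_channels) if i not in bad]
    if len(good) < 4:
        raise ValueError("need at least 4 good channels for spline interpolation")
    pos = rec.montage.positions
    unit = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    cos_gg = unit[good] @ unit[good].T
    cos_bg = unit[bad] @ unit[good].T
    G = _spline_g(cos_gg, m, n_terms)
    Gt = _spline_g(cos_bg, m, n_terms)
    n_good = len(good)
    A = np.zeros((n_good + 1, n_good + 1))
    A[:n_good, :n_good] = G + regularization * np.eye(n_good)
    A[:n_good, n_good] = 1.0
    A[n_good, :n_good] = 1.0
    rhs = np.vstack([rec.data[good], np.zeros((1, rec.n_samples))])
    sol = np.linalg.solve(A, rhs)
    c, c0 = sol[:n_good], sol[n_good]
    est = Gt @ c + c0
    out = rec.copy()
    out.data[bad] = est
    return out


def average_reference(rec: Recording) -> Recording:
    """Subtract the per-sample channel mean; reduces data rank by one."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy(data=data, reference="average")


def reject_extreme_epochs(
    rec: Recording,
    epoch_s: float = 1.0,
    threshold_sd: float = 6.0,
    pad_epochs: int = 1,
) -> np.ndarray:
    """Extreme-amplitude epoch screen: boolean keep-mask over samples.

    Fixed-length epochs whose peak-to-peak range (max over channels) is a
    robust outlier (same +-threshold robust-z rule as the channel QC) are
    dropped, together with ``pad_epochs`` neighbours on each side to cover
    zero-phase filter ring-down around the artifact."""
    n_ep = int(rec.n_samples // int(epoch_s * rec.fs))
    keep = np.ones(rec.n_samples, dtype=bool)
    if n_ep < 4:
        return keep
    L = int(epoch_s * rec.fs)
    ranges = np.array(
        [np.ptp(rec.data[:, i * L : (i + 1) * L], axis=1).max() for i in range(n_ep)]
    )
    z = _robust_z(ranges)
    for i in np.nonzero(np.abs(z) > threshold_sd)[0]:
        lo = max(0, i - pad_epochs)
        hi = min(n_ep, i + pad_epochs + 1)
        keep[lo * L : hi * L] = False
    return keep
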