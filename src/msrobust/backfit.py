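"""Winner-takes-all labeling of EEG frames with microstate templates, the
minimum-duration temporal constraint, and the four microstate features
(duration, occurrence, coverage, GEV).

Frames are labeled with the template of highest |spatial correlation|;
frames whose best correlation is below 0.5 stay unlabeled.  Labeled
segments shorter than the temporal constraint (default 6 samples = 24 ms at
250 Hz) are dissolved into their neighbours, sample by sample, toward the
neighbour whose template correlates better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .data_model import Recording
from .microstates import MicrostateTemplates, gfp

__all__ = [
    "UNLABELED",
    "Segment",
    "Segmentation",
    "label_frames",
    "temporal_smoothing",
    "compute_features",
    "features_per_condition",
]

UNLABELED = -1


@dataclass(frozen=True)
class Segment:
    label: int
    start: int  # half-open [start, stop)
    stop: int

    @property
    def length(self) -> int:
        return self.stop - self.start


def _runs(labels: np.ndarray):
    """Vectorised run-length decomposition: (labels, starts, stops) arrays
    covering the whole sequence, unlabeled runs included."""
    n = len(labels)
    if n == 0:
        return labels[:0], np.array([], int), np.array([], int)
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.r_[0, change]
    stops = np.r_[change, n]
    return labels[starts], starts, stops


def _segments_from_labels(labels: np.ndarray) -> List[Segment]:
    labs, starts, stops = _runs(np.asarray(labels))
    return [
        Segment(int(l), int(s), int(e))
        for l, s, e in zip(labs, starts, stops)
        if l != UNLABELED
    ]


@dataclass
class Segmentation:
    """Per-sample labels (UNLABELED = -1), best |r|, and the correlation of
    every frame with every template (kept for the smoothing step)."""

    labels: np.ndarray
    best_r: np.ndarray
    corr: np.ndarray  # (k, n_samples) absolute correlations
    fs: float

    @property
    def segments(self) -> List[Segment]:
        return _segments_from_labels(self.labels)

    @property
    def k(self) -> int:
        return self.corr.shape[0]


def label_frames(
    rec: Recording, templates: MicrostateTemplates, r_threshold: float = 0.5
) -> Segmentation:
    """Winner-takes-all polarity-invariant frame labeling.

    Zero-variance frames and frames with max |r| below ``r_threshold``
    are left unlabeled.
    """
    X = rec.data - rec.data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(X, axis=0)
    safe = norms > 0
    Xn = np.where(safe, X / np.where(norms > 0, norms, 1.0), 0.0)
    corr = np.abs(templates.maps @ Xn)  # (k, n)
    labels = corr.argmax(axis=0).astype(np.int64)
    best = corr[labels, np.arange(corr.shape[1])]
    labels[(best < r_threshold) | ~safe] = UNLABELED
    return Segmentation(labels=labels, best_r=best, corr=corr, fs=rec.fs)


def temporal_smoothing(seg: Segmentation, min_samples: int = 6) -> Segmentation:
    """Dissolve labeled segments shorter than ``min_samples``.

    Segments are processed shortest first (ties: earliest).  Each sample of
    a dissolved segment is reassigned to the adjacent segment's label with
    the higher per-sample correlation; when only one labeled neighbour
    exists, it absorbs the whole segment.  Segments with no labeled
    neighbour (isolated between unlabeled gaps or recording edges) are left
    alone.  Repeats until stable; unlabeled runs are never touched.
    """
    labels = seg.labels.copy()
    n = len(labels)
    while True:
        labs, starts, stops = _runs(labels)
        lengths = stops - starts
        labeled = labs != UNLABELED
        left_ok = np.r_[False, labeled[:-1]]
        right_ok = np.r_[labeled[1:], False]
        short = labeled & (lengths < min_samples) & (left_ok | right_ok)
        if not short.any():
            break
        idx = np.flatnonzero(short)
        j = idx[np.lexsort((starts[idx], lengths[idx]))[0]]  # shortest, earliest
        a, b = int(starts[j]), int(stops[j])
        left = int(labels[a - 1]) if a > 0 else UNLABELED
        right = int(labels[b]) if b < n else UNLABELED
        if left == UNLABELED:
            labels[a:b] = right
        elif right == UNLABELED:
            labels[a:b] = left
        else:
            pick_left = seg.corr[left, a:b] >= seg.corr[right, a:b]
            labels[a:b] = np.where(pick_left, left, right)
    best = np.where(
        labels != UNLABELED, seg.corr[np.maximum(labels, 0), np.arange(n)], seg.best_r
    )
    return Segmentation(labels=labels, best_r=best, corr=seg.corr, fs=seg.fs)


def compute_features(
    seg: Segmentation,
    gfp_values: np.ndarray,
    k: Optional[int] = None,
) -> pd.DataFrame:
    """Per-map duration / occurrence / coverage / GEV from one segmentation.

    * duration: mean segment length in ms, edge segments (touching the
      start or end of the data) excluded as censored dwell times; NaN when
      a map has no interior segment;
    * occurrence: segments per second (edge segments counted);
    * coverage: labeled samples of the map over all samples (unlabeled
      frames stay in the denominator);
    * gev: GFP^2-weighted squared correlation, summed over the map's
      samples, relative to the total GFP^2 of all samples.
    """
    if k is None:
        k = seg.k
    n = len(seg.labels)
    total_s = n / seg.fs
    w2 = np.asarray(gfp_values, float) ** 2
    if len(w2) != n:
        raise ValueError("gfp length does not match segmentation")
    tot_w2 = w2.sum()
    segs = seg.segments
    rows = []
    for m in range(k):
        msegs = [s for s in segs if s.label == m]
        # edge segments are censored dwell times; fall back to them only
        # when a map has no interior segment at all
        interior = [s for s in msegs if s.start > 0 and s.stop < n] or msegs
        dur = (
            1000.0 * np.mean([s.length for s in interior]) / seg.fs
            if interior
            else float("nan")
        )
        sel = seg.labels == m
        gev = float((w2[sel] * seg.best_r[sel] ** 2).sum() / tot_w2) if tot_w2 > 0 else 0.0
        rows.append(
            {
                "map": m,
                "duration_ms": dur,
                "occurrence": len(msegs) / total_s,
                "coverage": float(sel.mean()),
                "gev": gev,
            }
        )
    return pd.DataFrame(rows)


def features_per_condition(
    rec: Recording,
    templates: MicrostateTemplates,
    r_threshold: float = 0.5,
    min_samples: int = 6,
) -> pd.DataFrame:
    """Label each EO/EC block separately (so segments never straddle a
    condition change), aggregate the four features per (condition, map)."""
    if not rec.blocks:
        raise ValueError("recording has no block annotations")
    g = gfp(rec)
    out = []
    for cond in ("EO", "EC"):
        blocks = [b for b in rec.blocks if b.condition == cond]
        if not blocks:
            continue
        seg_list = []
        for b in blocks:
            sub = rec.copy(data=rec.data[:, b.start : b.stop], blocks=[])
            seg = temporal_smoothing(label_frames(sub, templates, r_threshold), min_samples)
            seg_list.append((b, seg))
        k = templates.k
        n_tot = sum(b.stop - b.start for b, _ in seg_list)
        total_s = n_tot / rec.fs
        w2_tot = sum((g.values[b.start : b.stop] ** 2).sum() for b, _ in seg_list)
        for m in range(k):
            durs, edge_durs, n_segs, n_cov, gev = [], [], 0, 0, 0.0
            for b, seg in seg_list:
                nb = b.stop - b.start
                msegs = [s for s in seg.segments if s.label == m]
                durs += [s.length for s in msegs if s.start > 0 and s.stop < nb]
                edge_durs += [s.length for s in msegs]
                n_segs += len(msegs)
                sel = seg.labels == m
                n_cov += int(sel.sum())
                w2 = g.values[b.start : b.stop] ** 2
                gev += float((w2[sel] * seg.best_r[sel] ** 2).sum())
            out.append(
                {
                    "condition": cond,
                    "map": m,
                    "duration_ms": 1000.0 * np.mean(durs or edge_durs) / rec.fs
                    if (durs or edge_durs)
                    else float("nan"),
                    "occurrence": n_segs / total_s,
                    "coverage": n_cov / n_tot,
                    "gev": gev / w2_tot if w2_tot > 0 else 0.0,
                }
            )
    return pd.DataFrame(out)
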