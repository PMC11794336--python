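"""Microstate template extraction.

Pipeline: GFP peak topographies -> polarity-invariant modified k-means
(restarted, best run kept by Global Explained Variance) -> cluster-validity
battery over k = 2..8 -> mean/meta-criterion for the number of microstates
-> optional second clustering level that pools subject templates into group
templates.

Polarity is ignored throughout: the spatial correlation between maps is
|Pearson r| across channels, and the dissimilarity used by every validity
index is ``d = 1 - |r|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data_model import Montage, Recording, Topography

__all__ = [
    "GFPSeries",
    "MicrostateTemplates",
    "CriterionCurve",
    "CRITERION_NAMES",
    "gfp",
    "gfp_peaks",
    "peak_maps",
    "spatial_correlation",
    "modified_kmeans",
    "compute_gev",
    "validity_criteria",
    "meta_criterion",
    "two_level_cluster",
    "subsample_maps",
]

CRITERION_NAMES = (
    "gamma",
    "silhouette",
    "davies_bouldin",
    "point_biserial",
    "dunn_robust",
    "krzanowski_lai",
)

K_RANGE_DEFAULT = tuple(range(2, 9))


@dataclass
class GFPSeries:
    """Global Field Power: spatial SD of the scalp map at each sample."""

    values: np.ndarray
    fs: float

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0):
            raise ValueError("GFP is nonnegative by definition")


@dataclass
class MicrostateTemplates:
    """A set of k zero-mean unit-norm template topographies."""

    maps: np.ndarray  # (k, n_channels)
    montage: Montage
    level: str = "subject"  # "subject" | "group"
    gev: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.maps = np.atleast_2d(np.asarray(self.maps, float))
        norms = np.linalg.norm(self.maps, axis=1)
        means = np.abs(self.maps.mean(axis=1))
        if np.any(np.abs(norms - 1) > 1e-8) or np.any(means > 1e-8):
            raise ValueError("templates must be zero-mean and unit-norm")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def topographies(self) -> List[Topography]:
        return [Topography(m, self.montage, normalized=True) for m in self.maps]


@dataclass
class CriterionCurve:
    name: str
    ks: np.ndarray
    values: np.ndarray  # normalised so that higher = better
    optimal_k: int

    def __post_init__(self):
        if self.name not in CRITERION_NAMES:
            raise ValueError(f"unknown criterion {self.name!r}")
        if self.optimal_k not in self.ks:
            raise ValueError("optimal_k outside evaluated range")


# --------------------------------------------------------------------------
# GFP and peak maps
# --------------------------------------------------------------------------


def gfp(rec: Recording) -> GFPSeries:
    """Spatial standard deviation per sample (population SD)."""
    return GFPSeries(rec.data.std(axis=0, ddof=0), rec.fs)


def gfp_peaks(series: GFPSeries, min_distance_samples: int = 3) -> np.ndarray:
    """Strict local maxima of the GFP curve, greedily thinned so that
    surviving peaks are at least ``min_distance_samples`` apart (higher
    peaks win)."""
    v = series.values
    if len(v) < 3:
        return np.array([], dtype=int)
    cand = np.nonzero((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]))[0] + 1
    if min_distance_samples <= 1 or len(cand) == 0:
        return cand
    order = cand[np.argsort(-v[cand], kind="stable")]
    taken = np.zeros(len(v), bool)
    keep = []
    for i in order:
        lo, hi = max(0, i - min_distance_samples + 1), i + min_distance_samples
        if not taken[lo:hi].any():
            keep.append(i)
            taken[i] = True
    return np.array(sorted(keep), dtype=int)


def _normalize_maps(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=1, keepdims=True)
    n = np.linalg.norm(M, axis=1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("zero-variance map cannot be normalised")
    return M / n


def peak_maps(rec: Recording, min_distance_samples: int = 3) -> Tuple[np.ndarray, np.ndarray]:
    """GFP-peak topographies (rows zero-mean unit-norm) and their GFP weights."""
    g = gfp(rec)
    idx = gfp_peaks(g, min_distance_samples)
    M = rec.data[:, idx].T
    return _normalize_maps(M), g.values[idx]


def subsample_maps(
    maps: np.ndarray, weights: np.ndarray, max_maps: int, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform seeded subsample used to cap per-subject GFP peaks."""
    if len(maps) <= max_maps:
        return maps, weights
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 505]))
    idx = np.sort(rng.choice(len(maps), size=max_maps, replace=False))
    return maps[idx], weights[idx]


def spatial_correlation(a, b, ignore_polarity: bool = True) -> float:
    """Pearson correlation across channels of two scalp maps.

    Maps are average-referenced before correlating; with
    ``ignore_polarity`` the absolute value is returned.
    """
    va = a.values if isinstance(a, Topography) else np.asarray(a, float)
    vb = b.values if isinstance(b, Topography) else np.asarray(b, float)
    va = va - va.mean()
    vb = vb - vb.mean()
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance map has no defined spatial correlation")
    r = float(va @ vb / (na * nb))
    return abs(r) if ignore_polarity else r


# --------------------------------------------------------------------------
# modified k-means
# --------------------------------------------------------------------------


def compute_gev(
    maps: np.ndarray,
    weights: Optional[np.ndarray],
    templates: np.ndarray,
    assignment: np.ndarray,
) -> float:
    """GEV = sum_t GFP_t^2 r^2(map_t, template_a(t)) / sum_t GFP_t^2."""
    M = _normalize_maps(np.atleast_2d(maps))
    T = _normalize_maps(np.atleast_2d(templates))
    w = np.ones(len(M)) if weights is None else np.asarray(weights, float)
    w2 = w**2
    tot = w2.sum()
    if tot == 0:
        raise ValueError("total GFP weight is zero")
    r = np.einsum("nc,nc->n", M, T[assignment])
    return float((w2 * r**2).sum() / tot)


def _one_kmeans_run(
    M: np.ndarray, w2: np.ndarray, k: int, rng, tol: float, max_iter: int
) -> Tuple[np.ndarray, np.ndarray, float]:
    n = len(M)
    T = M[rng.choice(n, size=k, replace=False)].copy()
    prev_gev = -1.0
    prev_assign = None
    for _ in range(max_iter):
        C = T @ M.T  # (k, n) signed correlations
        assign = np.argmax(np.abs(C), axis=0)  # ties -> lowest template index
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            break
        prev_assign = assign.copy()
        r = C[assign, np.arange(n)]
        gev = float((w2 * r**2).sum() / w2.sum())
        for j in range(k):
            sel = assign == j
            if not sel.any():
                # re-seed an empty cluster from the worst-fit map
                worst = int(np.argmin(np.abs(r)))
                T[j] = M[worst]
                continue
            mean = (np.sign(C[j, sel])[:, None] * M[sel]).mean(axis=0)
            nrm = np.linalg.norm(mean)
            T[j] = mean / nrm if nrm > 0 else M[int(np.argmin(np.abs(r)))]
        if prev_gev >= 0 and abs(gev - prev_gev) <= tol * max(prev_gev, 1e-12):
            break
        prev_gev = gev
    C = T @ M.T
    assign = np.argmax(np.abs(C), axis=0)
    r = C[assign, np.arange(n)]
    gev = float((w2 * r**2).sum() / w2.sum())
    return T, assign, gev


def modified_kmeans(
    maps: np.ndarray,
    k: int,
    weights: Optional[np.ndarray] = None,
    n_restarts: int = 200,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 100,
    montage: Optional[Montage] = None,
) -> Tuple[MicrostateTemplates, np.ndarray]:
    """Polarity-invariant modified k-means on (GFP-peak) maps.

    Each restart initialises templates from random data maps, assigns every
    map to the template with the highest |spatial correlation|, updates each
    template as the sign-aligned mean of its members, and iterates until the
    GEV stabilises.  The restart with the highest GEV wins.  Returns
    ``(templates, assignment)``.
    """
    M = _normalize_maps(np.atleast_2d(np.asarray(maps, float)))
    n = len(M)
    if n < k:
        raise ValueError(f"need at least k={k} maps, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    w2 = w**2
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 606]))
    best = None
    for _ in range(max(1, n_restarts)):
        T, assign, gev = _one_kmeans_run(M, w2, k, rng, tol, max_iter)
        if best is None or gev > best[2]:
            best = (T, assign, gev)
    T, assign, gev = best
    # stable ordering: by descending explained weight
    share = np.array([(w2 * (assign == j)).sum() for j in range(k)])
    order = np.argsort(-share, kind="stable")
    T = T[order]
    remap = np.empty(k, int)
    remap[order] = np.arange(k)
    assign = remap[assign]
    tpl = MicrostateTemplates(
        maps=_normalize_maps(T),
        montage=montage if montage is not None else _DummyMontage(M.shape[1]),
        gev=gev,
        provenance={"k": k, "n_restarts": n_restarts, "seed": int(seed)},
    )
    return tpl, assign


class _DummyMontage(Montage):
    """Positional stand-in when clustering plain arrays without geometry
    (golden-spiral points on the upper scalp sphere)."""

    def __init__(self, n: int):
        from .data_model import SCALP_RADIUS_MM

        i = np.arange(n) + 0.5
        z = i / n  # upper hemisphere
        theta = np.pi * (1 + 5**0.5) * i
        s = np.sqrt(1 - z**2)
        pos = SCALP_RADIUS_MM * np.column_stack([s * np.cos(theta), s * np.sin(theta), z])
        super().__init__(tuple(f"ch{i}" for i in range(n)), pos)


# --------------------------------------------------------------------------
# validity criteria
# --------------------------------------------------------------------------


def _distance_matrix(M: np.ndarray) -> np.ndarray:
    C = np.abs(M @ M.T)
    np.fill_diagonal(C, 1.0)
    return 1.0 - np.clip(C, 0.0, 1.0)


def _centroids(M: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    T = np.empty((k, M.shape[1]))
    for j in range(k):
        sel = labels == j
        ref = M[sel][0]
        signs = np.sign(M[sel] @ ref)
        signs[signs == 0] = 1.0
        mean = (signs[:, None] * M[sel]).mean(axis=0)
        T[j] = mean / np.linalg.norm(mean)
    return T


def _gamma_index(D: np.ndarray, labels: np.ndarray) -> float:
    """Goodman-Kruskal gamma: concordance of within- vs between-cluster
    distances, counted over all (within, between) pairs by sorting."""
    iu = np.triu_indices(len(D), 1)
    same = labels[iu[0]] == labels[iu[1]]
    w = np.sort(D[iu][same])
    b = np.sort(D[iu][~same])
    if len(w) == 0 or len(b) == 0:
        raise ValueError("degenerate clustering for gamma")
    # concordant: w < b ; discordant: w > b
    conc = (len(b) - np.searchsorted(b, w, side="right")).sum()
    disc = np.searchsorted(b, w, side="left").sum()
    return float((conc - disc) / max(conc + disc, 1))


def _silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    n = len(D)
    uniq = np.unique(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        mask_own = (labels == own)
        n_own = mask_own.sum()
        if n_own <= 1:
            s[i] = 0.0
            continue
        a = D[i][mask_own].sum() / (n_own - 1)
        b = min(D[i][labels == c].mean() for c in uniq if c != own)
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


def _davies_bouldin(M: np.ndarray, D: np.ndarray, labels: np.ndarray, k: int) -> float:
    T = _centroids(M, labels, k)
    S = np.empty(k)
    for j in range(k):
        sel = labels == j
        S[j] = (1.0 - np.abs(M[sel] @ T[j])).mean()
    Md = 1.0 - np.abs(T @ T.T)
    db = 0.0
    for i in range(k):
        worst = max(
            (S[i] + S[j]) / max(Md[i, j], 1e-12) for j in range(k) if j != i
        )
        db += worst
    return db / k


def _point_biserial(D: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices(len(D), 1)
    d = D[iu]
    x = (labels[iu[0]] != labels[iu[1]]).astype(float)
    if x.std() == 0 or d.std() == 0:
        raise ValueError("degenerate clustering for point-biserial")
    return float(np.corrcoef(d, x)[0, 1])


def _dunn_robust(D: np.ndarray, labels: np.ndarray) -> float:
    """Dunn's separation ratio with percentile (robust) aggregates:
    10th percentile of between-cluster distances over 90th percentile of
    within-cluster distances."""
    iu = np.triu_indices(len(D), 1)
    same = labels[iu[0]] == labels[iu[1]]
    w = D[iu][same]
    b = D[iu][~same]
    if len(w) == 0 or len(b) == 0:
        raise ValueError("degenerate clustering for Dunn")
    return float(np.percentile(b, 10) / max(np.percentile(w, 90), 1e-12))


def _within_dispersion(M: np.ndarray, labels: np.ndarray, k: int) -> float:
    T = _centroids(M, labels, k)
    w = 0.0
    for j in range(k):
        sel = labels == j
        w += float(((1.0 - np.abs(M[sel] @ T[j])) ** 2).sum())
    return w


def validity_criteria(
    maps: np.ndarray,
    segmentations: Dict[int, np.ndarray],
    p_dim: Optional[int] = None,
) -> List[CriterionCurve]:
    """Six cluster-validity curves over the evaluated k values.

    ``segmentations`` maps k -> label array from :func:`modified_kmeans`.
    All indices use the polarity-invariant dissimilarity d = 1 - |r| and are
    orientation-normalised so that the optimum is the maximum.  The
    Krzanowski-Lai index needs both neighbouring k values, so the endpoints
    are not evaluated for it.
    """
    M = _normalize_maps(np.atleast_2d(np.asarray(maps, float)))
    D = _distance_matrix(M)
    p = p_dim if p_dim is not None else M.shape[1]
    ks = sorted(segmentations)
    valid: Dict[str, Dict[int, float]] = {name: {} for name in CRITERION_NAMES}
    W: Dict[int, float] = {}
    for k in ks:
        labels = np.asarray(segmentations[k])
        counts = np.bincount(labels, minlength=k)
        if len(np.unique(labels)) < k or counts.min() == 0 or k < 2:
            continue  # k invalid for all criteria
        try:
            valid["gamma"][k] = _gamma_index(D, labels)
            valid["silhouette"][k] = _silhouette(D, labels)
            valid["davies_bouldin"][k] = -_davies_bouldin(M, D, labels, k)
            valid["point_biserial"][k] = _point_biserial(D, labels)
            valid["dunn_robust"][k] = _dunn_robust(D, labels)
        except ValueError:
            continue
        W[k] = _within_dispersion(M, labels, k)
    for k in ks:
        if k - 1 in W and k in W and k + 1 in W:
            diff_k = (k - 1) ** (2.0 / p) * W[k - 1] - k ** (2.0 / p) * W[k]
            diff_k1 = k ** (2.0 / p) * W[k] - (k + 1) ** (2.0 / p) * W[k + 1]
            if abs(diff_k1) > 1e-300:
                valid["krzanowski_lai"][k] = abs(diff_k) / abs(diff_k1)
    curves = []
    for name in CRITERION_NAMES:
        vals = valid[name]
        if not vals:
            continue
        kk = np.array(sorted(vals))
        vv = np.array([vals[k] for k in kk])
        curves.append(CriterionCurve(name, kk, vv, int(kk[int(np.argmax(vv))])))
    return curves


def meta_criterion(curves: Sequence[CriterionCurve]) -> Tuple[int, float, List[int]]:
    """(meta_k, mean_k, candidates): median (lower on ties) and mean of the
    per-criterion optimal k, plus every k optimal for at least one
    criterion."""
    if len(curves) < 2:
        raise ValueError("need at least two valid criterion curves")
    opts = sorted(c.optimal_k for c in curves)
    n = len(opts)
    meta_k = opts[(n - 1) // 2]  # lower median on even counts
    mean_k = float(np.mean(opts))
    return int(meta_k), mean_k, sorted(set(opts))


# --------------------------------------------------------------------------
# two-level clustering
# --------------------------------------------------------------------------


def two_level_cluster(
    subject_maps: Sequence[Tuple[np.ndarray, Optional[np.ndarray]]],
    k_range: Sequence[int] = K_RANGE_DEFAULT,
    seed: int = 0,
    level1_k: int = 8,
    n_restarts: int = 200,
    montage: Optional[Montage] = None,
) -> Dict[str, object]:
    """Two-stage clustering: per-subject templates, then group templates.

    ``subject_maps`` is a list of (maps, gfp_weights) per subject.  Level 1
    runs modified k-means with a fixed k (default 8) on each subject's
    GFP-peak maps; level 2 pools the subject templates and clusters them
    again for every k in ``k_range``.  Returns the pooled maps, per-k group
    templates and segmentations, the validity curves and the
    mean/meta-criterion.
    """
    if len(subject_maps) < 2:
        raise ValueError("two-level clustering needs at least 2 subjects")
    pooled = []
    for s, (maps, w) in enumerate(subject_maps):
        k1 = min(level1_k, len(maps))
        tpl, _ = modified_kmeans(
            maps, k1, weights=w, n_restarts=n_restarts,
            seed=int(seed) * 1000 + s, montage=montage,
        )
        pooled.append(tpl.maps)
    pooled = np.vstack(pooled)
    per_k: Dict[int, MicrostateTemplates] = {}
    segs: Dict[int, np.ndarray] = {}
    for k in k_range:
        if len(pooled) < k:
            continue
        tpl, assign = modified_kmeans(
            pooled, k, n_restarts=n_restarts, seed=int(seed) * 1000 + 999 + k,
            montage=montage,
        )
        tpl.level = "group"
        per_k[k] = tpl
        segs[k] = assign
    curves = validity_criteria(pooled, segs)
    meta_k, mean_k, candidates = meta_criterion(curves)
    return {
        "pooled_maps": pooled,
        "templates_per_k": per_k,
        "segmentations": segs,
        "curves": curves,
        "meta_k": meta_k,
        "mean_k": mean_k,
        "candidates": candidates,
    }
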