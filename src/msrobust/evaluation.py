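"""Study-level comparison layer.

Orchestrates the whole experiment on synthetic sessions: simulate n
subjects -> condition the signal -> decompose with ICA and clean at each
removal level (RAW / EYES / ART / HARD) -> two-level microstate clustering
per condition -> validity criteria and meta-criterion -> pooled template
set -> backfit -> feature table -> template pairing matrices, 3-way ANOVA
(condition x level x map) with Tukey contrasts, and ground-truth recovery
metrics.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data_model import Recording
from . import preprocess as pp
from . import ica_clean as ic
from . import microstates as ms
from . import backfit as bf
from .synthetic import GroundTruth, SimulationConfig, make_session

__all__ = [
    "PairingResult",
    "StudyConfig",
    "pair_templates",
    "correlation_matrix",
    "feature_anova",
    "subject_pipeline",
    "condition_peak_maps",
    "run_full_study",
    "recovery_report",
    "write_report",
]


# --------------------------------------------------------------------------
# template pairing
# --------------------------------------------------------------------------


@dataclass
class PairingResult:
    """Bijection of set B's maps onto set A's, maximising total |r|."""

    permutation: Tuple[int, ...]  # permutation[i] = index in B paired with A's i-th
    pair_r: Tuple[float, ...]
    mean_r: float


def pair_templates(A: ms.MicrostateTemplates, B: ms.MicrostateTemplates) -> PairingResult:
    """Exhaustive search over assignments (k <= 8) for the pairing that
    maximises the summed |spatial correlation|."""
    if A.montage.labels != B.montage.labels:
        raise ValueError("template sets live on different montages")
    C = np.abs(A.maps @ B.maps.T)  # (kA, kB)
    kA, kB = C.shape
    small, big = min(kA, kB), max(kA, kB)
    best, best_perm = -1.0, None
    if kA <= kB:
        for perm in itertools.permutations(range(kB), kA):
            s = C[np.arange(kA), perm].sum()
            if s > best:
                best, best_perm = s, perm
        pair_r = tuple(float(C[i, j]) for i, j in enumerate(best_perm))
        perm = tuple(best_perm)
    else:
        for sel in itertools.permutations(range(kA), kB):
            s = C[sel, np.arange(kB)].sum()
            if s > best:
                best, best_perm = s, sel
        # report as: A-index -> B-index for the paired subset
        perm = tuple(best_perm)
        pair_r = tuple(float(C[i, j]) for j, i in enumerate(best_perm))
    return PairingResult(perm, pair_r, float(np.mean(pair_r)))


def correlation_matrix(
    sets: Dict[Tuple[str, str], ms.MicrostateTemplates]
) -> pd.DataFrame:
    """Mean paired |r| between every pair of (condition, level) template sets."""
    if len(sets) < 2:
        raise ValueError("need at least two template sets")
    keys = sorted(sets)
    names = ["/".join(k) for k in keys]
    M = pd.DataFrame(np.ones((len(keys), len(keys))), index=names, columns=names)
    for (i, ka), (j, kb) in itertools.combinations(enumerate(keys), 2):
        r = pair_templates(sets[ka], sets[kb]).mean_r
        M.iloc[i, j] = M.iloc[j, i] = r
    return M


# --------------------------------------------------------------------------
# ANOVA
# --------------------------------------------------------------------------


def feature_anova(table: pd.DataFrame, features: Sequence[str] = ("duration_ms", "occurrence", "coverage", "gev")) -> Dict[str, dict]:
    """Fixed-effects 3-way ANOVA (condition x level x map) per feature with
    Tukey HSD pairwise contrasts on each factor.

    ``table`` is the tidy feature table with columns subject, condition,
    level, map and the feature columns.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    for col in ("condition", "level", "map"):
        if table[col].nunique() < 2:
            raise ValueError(f"factor {col!r} is degenerate (needs >= 2 levels)")
    out: Dict[str, dict] = {}
    for feat in features:
        df = table.dropna(subset=[feat]).copy()
        df["y"] = df[feat]
        model = smf.ols("y ~ C(condition) * C(level) * C(map)", data=df).fit()
        an = anova_lm(model, typ=2)
        # constant response: any nonzero F is floating-point noise
        if np.isclose(df["y"].var(), 0.0, atol=1e-12 * max(1.0, df["y"].abs().max()) ** 2):
            an["F"] = np.nan
            an["PR(>F)"] = np.nan
        tukey = {}
        for factor in ("condition", "level", "map"):
            if df[factor].nunique() >= 2:
                res = pairwise_tukeyhsd(df["y"], df[factor].astype(str))
                tukey[factor] = pd.DataFrame(
                    res.summary().data[1:], columns=res.summary().data[0]
                )
        out[feat] = {"anova": an, "tukey": tukey}
    return out


# --------------------------------------------------------------------------
# pipeline pieces
# --------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Desk-scale study conditions: 6 subjects, 19 channels, 4 x 30 s
    blocks at 250 Hz, all four removal levels, k evaluated over 2..8."""

    n_subjects: int = 6
    session: SimulationConfig = field(default_factory=SimulationConfig)
    levels: Tuple[str, ...] = ("RAW", "EYES", "ART", "HARD")
    k_range: Tuple[int, ...] = tuple(range(2, 9))
    n_restarts: int = 50
    level1_k: int = 8
    max_peaks: int = 1000
    ica_max_iter: int = 200
    r_threshold: float = 0.5
    smooth_samples: int = 6
    #: one canonical template set for the whole cohort (subjects still get
    #: independent dynamics, noise and artifacts)
    shared_templates: bool = True
    seed: int = 0


@dataclass
class SubjectData:
    """One subject after conditioning, ICA and cleaning at every level."""

    recording: Recording  # conditioned, average-referenced (RAW)
    keep: np.ndarray  # extreme-epoch keep mask
    ground_truth: GroundTruth
    ic_table: List[ic.ICRecord]
    decomposition: ic.ICADecomposition
    cleaned: Dict[str, Recording]
    removed: Dict[str, set]


def subject_pipeline(cfg: StudyConfig, subject: int) -> SubjectData:
    """Simulate and preprocess one subject; clean at every removal level."""
    session_cfg = replace(
        cfg.session,
        seed=int(cfg.seed) * 101 + subject,
        template_seed=int(cfg.seed) * 101 + 1000 if cfg.shared_templates else None,
    )
    rec, gt = make_session(session_cfg)
    r = pp.apply_zero_phase_filter(rec, pp.HIGHPASS_1HZ)
    r = pp.apply_zero_phase_filter(r, pp.LOWPASS_45HZ)
    if r.fs != 250.0:
        r = pp.resample(r, 250.0)
    keep = pp.reject_extreme_epochs(r)
    r = pp.average_reference(r)
    dec = ic.fit_ica(r, seed=session_cfg.seed, max_iter=cfg.ica_max_iter)
    table = ic.build_ic_table(dec, r.fs, r.montage)
    cleaned, removed = {}, {}
    for level in cfg.levels:
        rem = ic.select_ics(table, ic.RemovalPolicy(level))
        removed[level] = rem
        cleaned[level] = ic.remove_ics(r, dec, rem)
    return SubjectData(r, keep, gt, table, dec, cleaned, removed)


def condition_peak_maps(
    rec: Recording,
    keep: np.ndarray,
    condition: Optional[str],
    max_peaks: int,
    seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """GFP-peak maps restricted to one condition's blocks and to samples
    kept by the epoch screen; capped at the ``max_peaks`` highest-GFP
    peaks."""
    g = ms.gfp(rec)
    idx = ms.gfp_peaks(g)
    idx = idx[keep[idx]]
    if condition is not None:
        in_cond = np.zeros(rec.n_samples, bool)
        for b in rec.blocks:
            if b.condition == condition:
                in_cond[b.start : b.stop] = True
        idx = idx[in_cond[idx]]
    if len(idx) == 0:
        raise ValueError("no usable GFP peaks")
    maps = ms._normalize_maps(rec.data[:, idx].T)
    w = g.values[idx]
    if len(idx) > max_peaks:
        sel = np.sort(np.argsort(-w)[:max_peaks])
        maps, w = maps[sel], w[sel]
    return maps, w


def run_full_study(cfg: StudyConfig, out_dir: Optional[str] = None) -> dict:
    """End-to-end study; deterministic under ``cfg.seed``.

    Returns a report dict with per-(condition, level) group templates and
    meta-criteria, the pooled final template set, the tidy feature table,
    the template pairing matrix, the ANOVA and the recovery metrics.
    """
    subjects = [subject_pipeline(cfg, s) for s in range(cfg.n_subjects)]
    montage = subjects[0].recording.montage

    sets: Dict[Tuple[str, str], ms.MicrostateTemplates] = {}
    meta: Dict[Tuple[str, str], dict] = {}
    all_subject_templates = []
    for level in cfg.levels:
        for cond in ("EO", "EC"):
            maps_per_subj = [
                condition_peak_maps(
                    sd.cleaned[level], sd.keep, cond, cfg.max_peaks, cfg.seed
                )
                for sd in subjects
            ]
            res = ms.two_level_cluster(
                maps_per_subj,
                k_range=cfg.k_range,
                seed=cfg.seed,
                level1_k=cfg.level1_k,
                n_restarts=cfg.n_restarts,
                montage=montage,
            )
            meta[(cond, level)] = {
                "meta_k": res["meta_k"],
                "mean_k": res["mean_k"],
                "candidates": res["candidates"],
                "curves": res["curves"],
            }
            sets[(cond, level)] = res["templates_per_k"][res["meta_k"]]
            all_subject_templates.append(res["pooled_maps"])

    # one pooled template set across all conditions and levels for fitting
    pooled = np.vstack(all_subject_templates)
    k_votes = [m["meta_k"] for m in meta.values()]
    k_final = int(np.median(k_votes))
    final_templates, _ = ms.modified_kmeans(
        pooled, k_final, n_restarts=cfg.n_restarts, seed=cfg.seed, montage=montage
    )
    final_templates.level = "group"

    rows = []
    for s, sd in enumerate(subjects):
        for level in cfg.levels:
            feats = bf.features_per_condition(
                sd.cleaned[level], final_templates, cfg.r_threshold, cfg.smooth_samples
            )
            feats.insert(0, "level", level)
            feats.insert(0, "subject", s)
            rows.append(feats)
    features = pd.concat(rows, ignore_index=True)

    pairings = correlation_matrix(sets)
    anova = feature_anova(features)
    recovery = recovery_report(subjects, sets, final_templates, cfg)

    report = {
        "config": cfg,
        "meta": {
            f"{c}/{l}": {
                "meta_k": m["meta_k"],
                "mean_k": m["mean_k"],
                "candidates": m["candidates"],
            }
            for (c, l), m in meta.items()
        },
        "templates": sets,
        "final_templates": final_templates,
        "k_final": k_final,
        "features": features,
        "pairings": pairings,
        "anova": anova,
        "recovery": recovery,
        "subjects": subjects,
    }
    if out_dir is not None:
        write_report(report, out_dir)
    return report


# --------------------------------------------------------------------------
# ground-truth recovery
# --------------------------------------------------------------------------


def recovery_report(
    subjects: Sequence[SubjectData],
    sets: Dict[Tuple[str, str], ms.MicrostateTemplates],
    final_templates: ms.MicrostateTemplates,
    cfg: StudyConfig,
) -> dict:
    """Score the study against the simulator's ground truth."""
    montage = subjects[0].recording.montage
    k_true = len(subjects[0].ground_truth.true_templates)

    # template recovery: pooled final set vs the planted maps (per subject)
    rec_r = []
    for sd in subjects:
        true_tpl = ms.MicrostateTemplates(
            np.array([t.values for t in sd.ground_truth.true_templates]), montage
        )
        rec_r.append(pair_templates(true_tpl, final_templates).mean_r)

    # label accuracy per level: backfit with the subject's true templates
    # would be circular; instead pair final templates onto the truth and
    # count matching samples
    label_acc: Dict[str, float] = {}
    pvaf_level: Dict[str, Dict[str, float]] = {}
    for level in cfg.levels:
        accs = []
        pv_eo, pv_ec = [], []
        for sd in subjects:
            gt = sd.ground_truth
            true_tpl = ms.MicrostateTemplates(
                np.array([t.values for t in gt.true_templates]), montage
            )
            pairing = pair_templates(final_templates, true_tpl)
            # map final-template labels onto true-state indices
            if final_templates.k <= true_tpl.k:
                back = {i: pairing.permutation[i] for i in range(final_templates.k)}
            else:
                back = {pairing.permutation[j]: j for j in range(true_tpl.k)}
            seg = bf.temporal_smoothing(
                bf.label_frames(sd.cleaned[level], final_templates, cfg.r_threshold),
                cfg.smooth_samples,
            )
            pred = np.array([back.get(l, -2) for l in seg.labels])
            ok = pred == gt.true_labels
            accs.append(float(ok[sd.keep].mean()))
            orig, clean = sd.recording, sd.cleaned[level]
            for cond, store in (("EO", pv_eo), ("EC", pv_ec)):
                sel = np.zeros(orig.n_samples, bool)
                for b in orig.blocks:
                    if b.condition == cond:
                        sel[b.start : b.stop] = True
                o = orig.copy(data=orig.data[:, sel], blocks=[])
                c = clean.copy(data=clean.data[:, sel], blocks=[])
                store.append(ic.pvaf_removed(o, c))
        label_acc[level] = float(np.mean(accs))
        pvaf_level[level] = {"EO": float(np.mean(pv_eo)), "EC": float(np.mean(pv_ec))}

    return {
        "template_recovery_mean_r": float(np.mean(rec_r)),
        "template_recovery_per_subject": [float(x) for x in rec_r],
        "label_accuracy": label_acc,
        "pvaf_removed": pvaf_level,
        "k_true": k_true,
    }


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def write_report(report: dict, out_dir: str) -> None:
    """Write the study report as a directory of open formats."""
    os.makedirs(out_dir, exist_ok=True)
    cfg = report["config"]
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(
            {
                "n_subjects": cfg.n_subjects,
                "levels": list(cfg.levels),
                "k_range": list(cfg.k_range),
                "n_restarts": cfg.n_restarts,
                "seed": cfg.seed,
                "session": {
                    "n_channels": cfg.session.n_channels,
                    "k_states": cfg.session.k_states,
                    "fs": cfg.session.fs,
                    "block_len_s": cfg.session.block_len_s,
                    "n_blocks": cfg.session.n_blocks,
                    "snr_db": cfg.session.snr_db,
                    "blink_rate_EO": cfg.session.blink_rate_EO,
                    "artifact_amplitude": cfg.session.artifact_amplitude,
                },
            },
            fh,
            indent=2,
        )
    with open(os.path.join(out_dir, "meta_criteria.json"), "w") as fh:
        json.dump(report["meta"], fh, indent=2)
    tpl_dir = os.path.join(out_dir, "templates")
    os.makedirs(tpl_dir, exist_ok=True)
    for (cond, level), tpl in report["templates"].items():
        with open(os.path.join(tpl_dir, f"{cond}_{level}.json"), "w") as fh:
            json.dump(
                {
                    "labels": list(tpl.montage.labels),
                    "maps": tpl.maps.tolist(),
                    "gev": tpl.gev,
                    "level": tpl.level,
                },
                fh,
            )
    ft = report["final_templates"]
    with open(os.path.join(tpl_dir, "final.json"), "w") as fh:
        json.dump(
            {"labels": list(ft.montage.labels), "maps": ft.maps.tolist(), "gev": ft.gev},
            fh,
        )
    report["features"].to_csv(os.path.join(out_dir, "features.csv"), index=False)
    report["pairings"].to_csv(os.path.join(out_dir, "pairings.csv"))
    anova_rows = []
    for feat, res in report["anova"].items():
        an = res["anova"].reset_index().rename(columns={"index": "term"})
        an.insert(0, "feature", feat)
        anova_rows.append(an)
    pd.concat(anova_rows, ignore_index=True).to_csv(
        os.path.join(out_dir, "anova.csv"), index=False
    )
    with open(os.path.join(out_dir, "recovery.json"), "w") as fh:
        json.dump(report["recovery"], fh, indent=2)
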