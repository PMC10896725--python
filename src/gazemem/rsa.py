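"""Single-trial representational similarity analysis of gaze positions.

For every trial and time point, the empirical representational dissimilarity
vector (RDV) holds the 16 Euclidean distances between the current trial's
gaze position and the leave-one-out trial-average gaze positions of the 16
orientations.  Correlating this RDV (Pearson) with the model RDV anchored at
the current trial's orientation yields a cross-validated encoding value per
trial and time point; averaging over trials reproduces the conventional
trial-averaged RSA time course while retaining single-trial variability.

The same machinery runs with averages formed separately per object (3 x 16
cells), yielding one within-object and two between-object RDVs per trial;
the two between-object correlations are averaged.

Missing cells: if an orientation average is undefined at a time point (no
valid sample left after hold-out), the correlation is computed over the
available entries when at least half (8) remain, otherwise it is NaN.  The
self-distance entry (model prediction 0) is always part of the RDV.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .dataset import GazeEpoch
from .geometry import BiasGeometry, blend_geometry

__all__ = [
    "loo_orientation_averages", "single_trial_encoding", "encoding_timecourse",
    "within_between_encoding", "bin_by_encoding_strength", "bias_model_contrast",
    "condition_timecourse", "mnemonic_distance_summary", "MIN_RDV_ENTRIES",
]

MIN_RDV_ENTRIES = 8


def nanmean(a, axis=None):
    """numpy nanmean returning NaN (silently) for all-NaN slices."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(a, axis=axis)


# -- reference-style (naive) path --------------------------------------------

def loo_orientation_averages(xy: np.ndarray, valid: np.ndarray, ori_idx: np.ndarray,
                             held_out: int, n_orient: int = 16,
                             objects: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-out orientation averages for one held-out trial.

    Returns (n_orient, T, 2), or (n_objects, n_orient, T, 2) when ``objects``
    (per-trial object ids, consecutive integers from 0) is given; cells with
    no remaining valid sample are NaN.  This is the direct, per-trial
    formulation; the pipeline uses an algebraically equivalent all-trials
    path (see tests for the equivalence check).
    """
    if objects is not None:
        n_obj = int(objects.max()) + 1
        return np.stack([
            loo_orientation_averages(xy[objects == g], valid[objects == g],
                                     ori_idx[objects == g],
                                     _held_index(objects, held_out, g), n_orient)
            for g in range(n_obj)
        ])
    keep = np.ones(len(ori_idx), bool)
    if 0 <= held_out < len(keep):
        keep[held_out] = False
    out = np.full((n_orient, xy.shape[1], 2), np.nan)
    for o in range(n_orient):
        sel = keep & (ori_idx == o)
        if not sel.any():
            continue
        v = valid[sel][:, :, None]
        cnt = v.sum(axis=0)
        s = np.where(v, xy[sel], 0.0).sum(axis=0)
        out[o] = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    return out


def _held_index(objects, held_out, g):
    """Index of the held-out trial within group g; out of range when the
    trial belongs to another group (no hold-out there)."""
    idx = np.flatnonzero(objects == g)
    pos = np.flatnonzero(idx == held_out)
    return int(pos[0]) if pos.size else len(idx) + 1


# -- fast vectorized path -----------------------------------------------------

def _loo_distances(xy, valid, ori_idx, member=None, n_orient=16):
    """All-trials leave-one-out RDV distances.

    Averages are formed from trials with ``member`` True (default: all);
    the hold-out correction applies only to member trials.  Returns
    D (n, T, n_orient) and an availability mask of the same shape.
    """
    n, T, _ = xy.shape
    member = np.ones(n, bool) if member is None else member
    v = (valid & member[:, None])[:, :, None].astype(float)
    xz = xy * v
    sums = np.zeros((n_orient, T, 2))
    cnts = np.zeros((n_orient, T, 1))
    np.add.at(sums, ori_idx, xz)
    np.add.at(cnts, ori_idx, v)
    own_sums = sums[ori_idx] - xz          # (n, T, 2): own-orientation cell minus self
    own_cnts = cnts[ori_idx] - v
    D = np.empty((n, T, n_orient))
    avail = np.empty((n, T, n_orient), bool)
    for o in range(n_orient):
        own = (ori_idx == o) & member
        s = np.where(own[:, None, None], own_sums, sums[o][None])
        c = np.where(own[:, None, None], own_cnts, cnts[o][None])
        mean = s / np.maximum(c, 1.0)
        D[:, :, o] = np.linalg.norm(xy - mean, axis=-1)
        avail[:, :, o] = (c[:, :, 0] > 0) & valid
    return D, avail


def _masked_pearson(D, avail, model_vec):
    """Pearson r between D[i, t, :] and model_vec[i, :] over available
    entries; NaN with < MIN_RDV_ENTRIES entries or zero variance."""
    m = avail.astype(float)
    cnt = m.sum(axis=-1)
    mv = model_vec[:, None, :]
    sx = (D * m).sum(-1)
    sy = (mv * m).sum(-1)
    sxx = (D * D * m).sum(-1)
    syy = (mv * mv * m).sum(-1)
    sxy = (D * mv * m).sum(-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / np.maximum(cnt, 1)
        vx = sxx - sx * sx / np.maximum(cnt, 1)
        vy = syy - sy * sy / np.maximum(cnt, 1)
        r = cov / np.sqrt(vx * vy)
    r[(cnt < MIN_RDV_ENTRIES) | (vx <= 0) | (vy <= 0)] = np.nan
    return r


def single_trial_encoding(epoch: GazeEpoch, ori_idx: np.ndarray,
                          model: BiasGeometry | None = None) -> np.ndarray:
    """Trial x time Pearson correlations between gaze RDVs and the model RDV
    anchored at each trial's orientation."""
    model = model or blend_geometry(0.0)
    ori_idx = np.asarray(ori_idx)
    D, avail = _loo_distances(epoch.xy, epoch.valid, ori_idx)
    return _masked_pearson(D, avail, model.rdm[ori_idx])


def encoding_timecourse(epoch: GazeEpoch, ori_idx, model=None) -> np.ndarray:
    """Trial-averaged encoding time course (the conventional RSA estimate)."""
    return nanmean(single_trial_encoding(epoch, ori_idx, model), axis=0)


def within_between_encoding(epoch: GazeEpoch, ori_idx: np.ndarray,
                            objects: np.ndarray,
                            model: BiasGeometry | None = None):
    """Within- and between-object encoding, each (trial x time).

    Orientation averages are formed separately per object; a trial's RDV
    against its own object's averages gives the within-object correlation,
    and the mean of its correlations against the other objects' averages the
    between-object correlation.
    """
    model = model or blend_geometry(0.0)
    objects = np.asarray(objects)
    ori_idx = np.asarray(ori_idx)
    n_obj = int(objects.max()) + 1
    n, T = epoch.valid.shape
    r_obj = np.full((n_obj, n, T), np.nan)
    for g in range(n_obj):
        D, avail = _loo_distances(epoch.xy, epoch.valid, ori_idx, member=(objects == g))
        r_obj[g] = _masked_pearson(D, avail, model.rdm[ori_idx])
    within = r_obj[objects, np.arange(n)]
    other = np.stack([objects != g for g in range(n_obj)])  # (n_obj, n)
    masked = np.where(other[:, :, None], r_obj, np.nan)
    cnt = (~np.isnan(masked)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        between = np.where(cnt > 0, np.nansum(np.nan_to_num(masked), axis=0)
                           / np.maximum(cnt, 1), np.nan)
    return within, between


# -- summaries over trials ----------------------------------------------------

def bin_by_encoding_strength(enc_sort: np.ndarray, enc_report: np.ndarray,
                             time_ms: np.ndarray, window: tuple = (250.0, 1000.0),
                             n_bins: int = 8) -> pd.DataFrame:
    """Bin trials by mean encoding of one item in a window; report the mean
    encoding of the other item per bin.

    ``enc_sort`` and ``enc_report`` are (trial x time) encoding arrays on the
    same time grid; ``window`` is in the same epoch-relative ms.  Trials are
    ranked by the windowed mean of ``enc_sort`` and split into ``n_bins``
    equal-count bins (sizes differing by at most 1).  Returns one row per bin
    with the windowed means of both encodings.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    sel = (time_ms >= window[0]) & (time_ms <= window[1])
    x = nanmean(enc_sort[:, sel], axis=1)
    y = nanmean(enc_report[:, sel], axis=1)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < n_bins:
        raise ValueError("fewer trials than bins")
    order = np.argsort(x, kind="stable")
    bins = np.array_split(order, n_bins)
    return pd.DataFrame({
        "bin": np.arange(1, n_bins + 1),
        "n_trials": [len(b) for b in bins],
        "mean_sort_encoding": [x[b].mean() for b in bins],
        "mean_report_encoding": [y[b].mean() for b in bins],
    })


def bin_profile_slope(profile: pd.DataFrame) -> float:
    """Least-squares slope of the reported encoding across bin indices."""
    return float(np.polyfit(profile["bin"], profile["mean_report_encoding"], 1)[0])


def bias_model_contrast(epoch: GazeEpoch, ori_idx: np.ndarray,
                        last_ms: tuple | None = None) -> dict[str, np.ndarray]:
    """Correlations with the repulsion (B=1), attraction (B=-1) and circle
    (B=0) model RDVs, plus the repulsion-minus-attraction contrast.

    Returns trial x time arrays under keys 'repulsion', 'attraction',
    'circle', 'contrast'; with ``last_ms = (t0, t1)`` adds 'contrast_mean',
    the per-trial contrast averaged over that window (e.g. the last second
    of the delay period).
    """
    ori_idx = np.asarray(ori_idx)
    D, avail = _loo_distances(epoch.xy, epoch.valid, ori_idx)
    out = {}
    for name, b in (("repulsion", 1.0), ("attraction", -1.0), ("circle", 0.0)):
        model = blend_geometry(b)
        out[name] = _masked_pearson(D, avail, model.rdm[ori_idx])
    out["contrast"] = out["repulsion"] - out["attraction"]
    if last_ms is not None:
        sel = (epoch.time_ms >= last_ms[0]) & (epoch.time_ms <= last_ms[1])
        out["contrast_mean"] = nanmean(out["contrast"][:, sel], axis=1)
    return out


def condition_timecourse(encoding: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Trial-mean encoding time course over the trials selected by ``mask``."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty condition")
    return nanmean(encoding[mask], axis=0)


def mnemonic_distance_summary(level_means: np.ndarray) -> np.ndarray:
    """Per-participant least-squares slope across the four mnemonic-distance
    levels (coded 1-4, shortest to longest unattended storage).

    ``level_means`` is (n_participants, 4); returns the slopes.  Group-level
    inference on the slopes is delegated to :mod:`gazemem.inference`.
    """
    level_means = np.asarray(level_means, float)
    if level_means.ndim == 1:
        level_means = level_means[None, :]
    if level_means.shape[1] != 4 or np.isnan(level_means).any():
        raise ValueError("need complete means for the 4 mnemonic-distance levels")
    x = np.arange(1, 5, dtype=float)
    xc = x - x.mean()
    return (level_means - level_means.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
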