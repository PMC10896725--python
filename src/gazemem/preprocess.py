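"""Minimal gaze preprocessing: centering, artifact rejection, epoching, QC.

The cleaning pipeline is deliberately light: per participant, gaze is
zero-centred on the grand mean over all trials, then samples farther than
100 px (2.17° visual angle) from the zero-centre are marked invalid.
Centering is computed once, before rejection, and not recomputed afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .dataset import EPOCH_WINDOWS, GazeDataset, GazeEpoch, ScreenGeometry

__all__ = [
    "zero_center", "reject_artifacts", "extract_epochs", "px_to_deg",
    "rotational_align", "participant_qc", "QCReport", "RejectionStats",
]

REJECT_THRESHOLD_PX = 100.0
MAX_REJECTED_FRACTION = 0.15


@dataclass(frozen=True)
class RejectionStats:
    threshold_px: float
    rejected_fraction: dict[int, float]  # per epoch, 0-1 of previously valid samples


@dataclass(frozen=True)
class QCReport:
    participant_id: str
    accuracy_test1: float   # percent
    accuracy_test2: float
    binomial_p_test1: float
    binomial_p_test2: float
    rejected_fraction_epoch1: float  # percent
    rejected_fraction_epoch2: float
    excluded: bool
    reason: str = ""


def zero_center(dataset: GazeDataset) -> GazeDataset:
    """Subtract the grand mean over all valid samples of all epochs."""
    num = np.zeros(2)
    cnt = 0
    for ep in dataset.epochs.values():
        m = ep.valid
        num += ep.xy[m].sum(axis=0)
        cnt += int(m.sum())
    if cnt == 0:
        raise ValueError("no valid samples to centre on")
    centre = num / cnt
    out = dataset.copy()
    for ep in out.epochs.values():
        ep.xy -= centre
    out.meta["zero_centre"] = centre
    return out


def reject_artifacts(dataset: GazeDataset,
                     threshold_px: float = REJECT_THRESHOLD_PX) -> tuple[GazeDataset, RejectionStats]:
    """Invalidate samples strictly farther than ``threshold_px`` from the
    zero-centre (Euclidean distance; a sample exactly at the threshold is
    kept)."""
    out = dataset.copy()
    fractions = {}
    for k, ep in out.epochs.items():
        dist = np.linalg.norm(ep.xy, axis=-1)
        bad = (dist > threshold_px) & ep.valid
        n_valid = int(ep.valid.sum())
        fractions[k] = float(bad.sum() / n_valid) if n_valid else 0.0
        ep.valid &= ~bad
    return out, RejectionStats(threshold_px=threshold_px, rejected_fraction=fractions)


def extract_epochs(dataset: GazeDataset,
                   windows: dict[int, tuple[float, float]] | None = None) -> GazeDataset:
    """Restrict each epoch to its canonical analysis window (both ends
    inclusive) and drop trials without a second test from epoch 2."""
    windows = windows or EPOCH_WINDOWS
    out = dataset.copy()
    for k, ep in list(out.epochs.items()):
        lo, hi = windows[k]
        sel = (ep.time_ms >= lo) & (ep.time_ms <= hi)
        xy, valid, ids = ep.xy[:, sel], ep.valid[:, sel], ep.trial_ids
        if k == 2 and "has_test2" in out.trials:
            keep_ids = set(out.trials.loc[out.trials["has_test2"].astype(bool), "trial_id"])
            row = np.array([tid in keep_ids for tid in ids])
            xy, valid, ids = xy[row], valid[row], ids[row]
        out.epochs[k] = GazeEpoch(ep.time_ms[sel], xy, valid, ids)
    return out


def px_to_deg(extent_px, geometry: ScreenGeometry | None = None):
    """Full visual angle (degrees) of a pixel extent; 8 px -> 0.17°,
    100 px -> 2.17° with the default geometry."""
    return (geometry or ScreenGeometry()).px_to_deg(extent_px)


def rotational_align(xy: np.ndarray, reference_orientation, target: float = 90.0) -> np.ndarray:
    """Rotate zero-centred samples about the origin by (target - reference),
    bringing each trial's orientation to the object-upright (90°) position.

    ``xy`` is (..., 2) with a leading trial axis matching ``reference_orientation``.
    """
    ref = np.atleast_1d(np.asarray(reference_orientation, float))
    phi = np.deg2rad(target - ref)
    c, s = np.cos(phi), np.sin(phi)
    rot = np.empty(ref.shape + (2, 2))
    rot[..., 0, 0] = c
    rot[..., 0, 1] = -s
    rot[..., 1, 0] = s
    rot[..., 1, 1] = c
    return np.einsum("i...j,ikj->i...k", np.asarray(xy, float), rot)


def participant_qc(trials: pd.DataFrame, rejection: RejectionStats,
                   participant_id: str = "sim",
                   alpha: float = 0.05,
                   max_rejected: float = MAX_REJECTED_FRACTION) -> QCReport:
    """Exclude participants at chance on either memory test (one-sided exact
    binomial vs 50%) or with more than 15% of samples rejected in any epoch."""
    reasons = []
    acc, pvals = {}, {}
    for test in (1, 2):
        col = f"correct_{test}"
        resp = trials[col].dropna() if col in trials else pd.Series(dtype=float)
        if test == 2 and "has_test2" in trials:
            resp = trials.loc[trials["has_test2"].astype(bool), col].dropna()
        n = len(resp)
        if n == 0:
            raise ValueError(f"no answered trials for test {test}")
        k = int(resp.sum())
        p = binomtest(k, n, 0.5, alternative="greater").pvalue
        acc[test] = 100.0 * k / n
        pvals[test] = p
        if p >= alpha:
            reasons.append(f"test{test} at chance (p={p:.3f})")
    rej = {k: rejection.rejected_fraction.get(k, 0.0) for k in (1, 2)}
    for k, frac in rej.items():
        if frac > max_rejected:
            reasons.append(f"epoch{k} rejection {100 * frac:.1f}% > {100 * max_rejected:.0f}%")
    return QCReport(participant_id=participant_id,
                    accuracy_test1=acc[1], accuracy_test2=acc[2],
                    binomial_p_test1=pvals[1], binomial_p_test2=pvals[2],
                    rejected_fraction_epoch1=100.0 * rej[1],
                    rejected_fraction_epoch2=100.0 * rej[2],
                    excluded=bool(reasons), reason="; ".join(reasons))
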