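"""Velocity-threshold microsaccade detection and direction analysis.

Gaze is transformed to a speed trace (Euclidean distance between consecutive
samples, smoothed with a 7 ms Gaussian kernel).  Events are maximal runs of
samples above a trial-specific threshold of 5 x the median speed; onset and
endpoint are the first and last suprathreshold samples, direction and
amplitude come from the gaze positions at onset vs endpoint, and detections
within a 100 ms refractory interval (onset-to-onset) of the previous
accepted event are discarded.  Thresholding uses raw pixel-per-sample units
(the 5 x median rule is unit-free); amplitudes are converted to degrees for
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import EVENTS, GazeDataset
from .inference import circular_correlation, gaussian_smooth, rayleigh_test

__all__ = ["Saccade", "velocity_trace", "detect_saccades", "detect_dataset",
           "direction_analysis", "ANALYSIS_WINDOWS"]

# analysis windows (epoch, start_ms, end_ms) during which the named
# stimulus orientation is considered relevant
ANALYSIS_WINDOWS = {
    "stimulus_1": (1, EVENTS["stim1_on"] + 300.0, EVENTS["stim1_on"] + 1000.0),
    "stimulus_2": (1, EVENTS["stim2_on"] + 300.0, EVENTS["stim2_on"] + 1000.0),
    "delay_1": (1, EVENTS["cue1_off"], EVENTS["test1_on"]),
    "delay_2": (2, EVENTS["cue2_on"] + 300.0, EVENTS["test2_on"]),
}


@dataclass(frozen=True)
class Saccade:
    trial_id: int
    onset_ms: float
    end_ms: float
    direction_deg: float
    amplitude_px: float
    peak_velocity: float  # px per sample, smoothed


def velocity_trace(xy: np.ndarray, valid: np.ndarray, dt_ms: float,
                   kernel_ms: float = 7.0) -> np.ndarray:
    """Per-step speed (px/sample), Gaussian-smoothed; NaN where either
    neighbouring sample is invalid (gaps break the trace)."""
    if len(xy) < 2:
        raise ValueError("need at least 2 samples")
    speed = np.linalg.norm(np.diff(xy, axis=0), axis=-1)
    gap = ~(valid[:-1] & valid[1:])
    speed[gap] = np.nan
    if np.isnan(speed).all():
        raise ValueError("all samples invalid")
    out = gaussian_smooth(speed, kernel_ms, dt_ms)
    out[gap] = np.nan  # gaps break the trace; do not interpolate across them
    return out


def detect_saccades(xy: np.ndarray, valid: np.ndarray, time_ms: np.ndarray,
                    k: float = 5.0, refractory_ms: float = 100.0,
                    kernel_ms: float = 7.0, min_samples: int = 2,
                    trial_id: int = 0) -> list[Saccade]:
    """Detect saccades in one trial's gaze.

    The threshold is k x the median of the smoothed speed trace (NaN
    excluded).  Runs shorter than ``min_samples`` are discarded as noise;
    zero-median (e.g. constant-position) trials yield no detections.
    """
    dt = float(time_ms[1] - time_ms[0])
    speed = velocity_trace(xy, valid, dt, kernel_ms)
    med = np.nanmedian(speed)
    if not np.isfinite(med) or med <= 0:
        return []
    thresh = k * med
    supra = np.where(np.isnan(speed), False, speed > thresh)
    if not supra.any():
        return []
    idx = np.flatnonzero(supra)
    splits = np.flatnonzero(np.diff(idx) > 1)
    events = []
    last_onset = -np.inf
    for seg in np.split(idx, splits + 1):
        if len(seg) < min_samples:
            continue
        onset_i, end_i = int(seg[0]), int(seg[-1]) + 1  # positions bracketing the run
        onset_t = float(time_ms[onset_i])
        if onset_t - last_onset < refractory_ms:
            continue
        last_onset = onset_t
        vec = xy[end_i] - xy[onset_i]
        events.append(Saccade(
            trial_id=trial_id, onset_ms=onset_t, end_ms=float(time_ms[end_i]),
            direction_deg=float(np.rad2deg(np.arctan2(vec[1], vec[0])) % 360.0),
            amplitude_px=float(np.linalg.norm(vec)),
            peak_velocity=float(np.nanmax(speed[seg])),
        ))
    return events


def detect_dataset(dataset: GazeDataset, **kwargs) -> pd.DataFrame:
    """Detect saccades in every trial of every epoch; returns a tidy table."""
    rows = []
    for epoch_id, ep in dataset.epochs.items():
        for i, tid in enumerate(ep.trial_ids):
            if ep.valid[i].sum() < 2:
                continue
            for s in detect_saccades(ep.xy[i], ep.valid[i], ep.time_ms,
                                     trial_id=int(tid), **kwargs):
                rows.append({"epoch": epoch_id, "trial_id": s.trial_id,
                             "onset_ms": s.onset_ms, "end_ms": s.end_ms,
                             "direction_deg": s.direction_deg,
                             "amplitude_px": s.amplitude_px,
                             "amplitude_deg": dataset.screen.px_to_deg(s.amplitude_px),
                             "peak_velocity": s.peak_velocity})
    return pd.DataFrame(rows, columns=["epoch", "trial_id", "onset_ms", "end_ms",
                                       "direction_deg", "amplitude_px",
                                       "amplitude_deg", "peak_velocity"])


def _relevant_orientation(trials: pd.DataFrame, window: str) -> pd.Series:
    """Orientation of the stimulus relevant in an analysis window, indexed
    by trial_id (NaN where undefined, e.g. no second test)."""
    t = trials.set_index("trial_id")
    if window == "stimulus_1":
        ori = t["orientation_1"]
    elif window == "stimulus_2":
        ori = t["orientation_2"]
    elif window == "delay_1":
        ori = t.apply(lambda r: r[f"orientation_{int(r['cued_first'])}"], axis=1)
    elif window == "delay_2":
        ori = t.apply(lambda r: r[f"orientation_{3 - int(r['cued_first'])}"], axis=1)
        ori[~t["has_test2"].astype(bool)] = np.nan
    else:
        raise KeyError(window)
    return ori


def direction_analysis(saccade_table: pd.DataFrame, trials: pd.DataFrame,
                       n_perm: int = 0, seed: int = 0) -> pd.DataFrame:
    """Per analysis window: circular correlation of saccade direction with
    the relevant orientation, plus the Rayleigh test on directions after
    aligning each saccade by (90° - orientation)."""
    rows = []
    for window, (epoch_id, t0, t1) in ANALYSIS_WINDOWS.items():
        sub = saccade_table[(saccade_table["epoch"] == epoch_id)
                            & (saccade_table["onset_ms"] >= t0)
                            & (saccade_table["onset_ms"] <= t1)]
        ori = _relevant_orientation(trials, window)
        match = sub["trial_id"].map(ori)
        ok = match.notna()
        sub, match = sub[ok], match[ok].to_numpy(float)
        row = {"window": window, "n_saccades": len(sub),
               "R": np.nan, "R_p": np.nan, "rayleigh_z": np.nan, "rayleigh_p": np.nan,
               "aligned_mean_deg": np.nan}
        if len(sub) >= 3:
            R, p = circular_correlation(sub["direction_deg"].to_numpy(), match,
                                        n_perm=n_perm, seed=seed)
            aligned = (sub["direction_deg"].to_numpy() + (90.0 - match)) % 360.0
            z, pz = rayleigh_test(aligned)
            mean_dir = np.rad2deg(np.angle(np.exp(1j * np.deg2rad(aligned)).mean())) % 360.0
            row.update({"R": R, "R_p": p, "rayleigh_z": z, "rayleigh_p": pz,
                        "aligned_mean_deg": mean_dir})
        rows.append(row)
    return pd.DataFrame(rows)
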