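"""In-memory containers for gaze experiments and their on-disk formats.

A dataset holds one participant's trial table plus epoch-locked gaze arrays:
epoch 1 is time-locked to Stimulus 1 onset and runs to Test 1 onset, epoch 2
is time-locked to Cue 2 onset and exists only for trials with a second test.
Gaze is stored in screen pixels relative to screen centre with the y axis
increasing upward, so geometric angles match object orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = ["ScreenGeometry", "GazeEpoch", "GazeDataset", "EVENTS"]

# Trial event timeline in ms (epoch-relative)
EVENTS = {
    "stim1_on": 0.0, "stim1_off": 500.0,
    "stim2_on": 1000.0, "stim2_off": 1500.0,
    "cue1_on": 2000.0, "cue1_off": 2350.0,
    "test1_on": 5850.0,
    # epoch 2 (relative to Cue 2 onset)
    "cue2_on": 0.0, "cue2_off": 350.0,
    "test2_on": 2850.0,
}

EPOCH_WINDOWS = {1: (-500.0, 5850.0), 2: (-500.0, 2850.0)}


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry used for pixel <-> visual-angle conversion."""

    width_cm: float = 60.0
    height_cm: float = 34.0
    width_px: int = 2560
    height_px: int = 1440
    viewing_distance_cm: float = 62.0

    def __post_init__(self):
        for name in ("width_cm", "height_cm", "width_px", "height_px", "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def cm_per_px(self) -> float:
        return self.width_cm / self.width_px

    def px_to_deg(self, extent_px) -> float:
        """Full visual angle subtended by an on-screen extent in pixels."""
        extent_cm = np.asarray(extent_px, float) * self.cm_per_px
        out = np.degrees(2.0 * np.arctan(extent_cm / 2.0 / self.viewing_distance_cm))
        return float(out) if out.ndim == 0 else out

    def deg_to_px(self, extent_deg) -> float:
        extent_cm = 2.0 * self.viewing_distance_cm * np.tan(np.radians(np.asarray(extent_deg, float)) / 2.0)
        out = extent_cm / self.cm_per_px
        return float(out) if out.ndim == 0 else out


@dataclass
class GazeEpoch:
    """Epoch-locked gaze for a set of trials: (n_trials, n_times, 2) pixels."""

    time_ms: np.ndarray          # (T,)
    xy: np.ndarray               # (n, T, 2) float
    valid: np.ndarray            # (n, T) bool
    trial_ids: np.ndarray        # (n,)

    def __post_init__(self):
        assert self.xy.shape == (len(self.trial_ids), len(self.time_ms), 2)
        assert self.valid.shape == self.xy.shape[:2]

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    def copy(self) -> "GazeEpoch":
        return GazeEpoch(self.time_ms.copy(), self.xy.copy(), self.valid.copy(),
                         self.trial_ids.copy())


@dataclass
class GazeDataset:
    """One participant's trials and epoch-locked gaze."""

    trials: pd.DataFrame
    epochs: dict[int, GazeEpoch]
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    participant_id: str = "sim"
    meta: dict = field(default_factory=dict)

    def copy(self) -> "GazeDataset":
        return GazeDataset(trials=self.trials.copy(),
                           epochs={k: v.copy() for k, v in self.epochs.items()},
                           screen=self.screen, participant_id=self.participant_id,
                           meta=dict(self.meta))

    # -- persistence ---------------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["participant_id"] = self.participant_id
            f.attrs["screen_yaml"] = yaml.safe_dump(self.screen.__dict__)
            tg = f.create_group("trials")
            for col in self.trials.columns:
                data = self.trials[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                tg.create_dataset(col, data=data)
            for k, ep in self.epochs.items():
                g = f.create_group(f"epoch{k}")
                g.create_dataset("time_ms", data=ep.time_ms)
                g.create_dataset("xy", data=ep.xy.astype(np.float32))
                g.create_dataset("valid", data=ep.valid)
                g.create_dataset("trial_ids", data=ep.trial_ids)

    @classmethod
    def from_hdf5(cls, path) -> "GazeDataset":
        with h5py.File(path, "r") as f:
            screen = ScreenGeometry(**yaml.safe_load(f.attrs["screen_yaml"]))
            cols = {}
            for col in f["trials"]:
                data = f["trials"][col][()]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                cols[col] = data
            trials = pd.DataFrame(cols)
            epochs = {}
            for k in (1, 2):
                key = f"epoch{k}"
                if key in f:
                    g = f[key]
                    epochs[k] = GazeEpoch(g["time_ms"][()], g["xy"][()].astype(float),
                                          g["valid"][()].astype(bool), g["trial_ids"][()])
            return cls(trials=trials, epochs=epochs, screen=screen,
                       participant_id=str(f.attrs["participant_id"]))

    def samples_to_csv(self, path) -> None:
        """Long-format CSV: epoch, trial, time_ms, x_px, y_px, valid."""
        frames = []
        for k, ep in self.epochs.items():
            n, t = ep.valid.shape
            frames.append(pd.DataFrame({
                "epoch": k,
                "trial_id": np.repeat(ep.trial_ids, t),
                "time_ms": np.tile(ep.time_ms, n),
                "x_px": ep.xy[:, :, 0].ravel(),
                "y_px": ep.xy[:, :, 1].ravel(),
                "valid": ep.valid.ravel().astype(int),
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, trials_path, samples_path, screen: ScreenGeometry | None = None,
                 participant_id: str = "csv") -> "GazeDataset":
        trials = pd.read_csv(trials_path)
        long = pd.read_csv(samples_path)
        epochs = {}
        for k, sub in long.groupby("epoch"):
            piv_t = np.sort(sub["time_ms"].unique())
            ids = sub["trial_id"].unique()
            n, t = len(ids), len(piv_t)
            sub = sub.sort_values(["trial_id", "time_ms"])
            xy = np.column_stack([sub["x_px"], sub["y_px"]]).reshape(n, t, 2)
            valid = sub["valid"].to_numpy().astype(bool).reshape(n, t)
            epochs[int(k)] = GazeEpoch(piv_t.astype(float), xy, valid, ids)
        return cls(trials=trials, epochs=epochs, screen=screen or ScreenGeometry(),
                   participant_id=participant_id)
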