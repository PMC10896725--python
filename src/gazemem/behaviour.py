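"""Psychometric model of 2-AFC orientation reports with cardinal bias.

The remembered orientation is modelled as the bias mixture ``M_mix`` of the
veridical circle with the repulsion square (``B >= 0``) or attraction square
(``B < 0``); see :mod:`gazemem.geometry`.  At test, the probed object is
shown rotated by a small signed offset from the true orientation, and the
observer reports whether it should be rotated clockwise or anticlockwise to
match memory.  The probability of a clockwise report follows a logistic
choice rule on the signed circular difference d between the modelled
orientation and the probe,

    P_clockwise = 1 / (1 + exp(-d / s)),

where d is taken in radians and s > 0 is a dimensionless noise parameter
that relates inversely to memory strength (the fitting grid spans 0.01-1).
An oblique-effect parameter c rescales the noise for the eight orientations
nearest the cardinal axes: s_near_cardinal = exp(c) * s_near_diagonal, so
c < 0 means greater precision near the cardinals.

Parameters are fitted by exhaustive grid search (B -1..1, s 0.01..1,
c -0.5..0.5, step 0.01 each) minimising the sum of squared residuals between
the predicted clockwise probability and the observed 0/1 responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .geometry import blend_angles, build_orientation_set, signed_angle_diff

__all__ = [
    "PROBE_OFFSET_DEG",
    "PsychParams",
    "PsychFit",
    "mixed_orientation",
    "choice_probability",
    "fit_grid",
    "simulate_responses",
    "accuracy_summary",
]

PROBE_OFFSET_DEG = 6.43

# mnemonic distance levels, shortest -> longest unattended storage
MNEMONIC_LEVELS = [("2", "1"), ("1", "1"), ("2", "2"), ("1", "2")]  # (stimulus, test)


@dataclass(frozen=True)
class PsychParams:
    """Bias-mixture psychometric parameters."""

    B: float    # cardinal bias mixture, [-1, 1]; > 0 repulsion
    s: float    # logistic noise on the radian scale, > 0
    c: float    # oblique log-ratio: s_near_cardinal = exp(c) * s

    def __post_init__(self):
        if not -1.0 <= self.B <= 1.0:
            raise ValueError("B must lie in [-1, 1]")
        if self.s <= 0:
            raise ValueError("s must be positive")


@dataclass(frozen=True)
class PsychFit:
    params: PsychParams
    sse: float
    grid_resolution: float = 0.01
    condition: tuple | None = None
    degenerate: bool = False  # all responses identical


def mixed_orientation(true_orientation, B: float):
    """Remembered orientation under bias mixture B (degrees)."""
    out = blend_angles(true_orientation, B)
    return float(out[0]) if np.isscalar(true_orientation) else out


def _near_cardinal(angles) -> np.ndarray:
    oset = build_orientation_set()
    return oset.near_cardinal_mask()[
        np.array([oset.index_of(a) for a in np.atleast_1d(angles)])
    ]


def choice_probability(modelled, probe, s: float, near_cardinal, c: float = 0.0):
    """Probability of a 'clockwise' report.

    d = signed shortest circular difference (modelled - probe), converted to
    radians; the effective noise is exp(c) * s for near-cardinal
    orientations.  ``near_cardinal`` is a boolean (array) classifying the
    *true* orientation of the trial.
    """
    s_eff = np.where(np.asarray(near_cardinal, bool), np.exp(c) * s, s)
    if np.any(s_eff <= 0):
        raise ValueError("effective noise must be positive")
    d = np.deg2rad(signed_angle_diff(modelled, probe))
    return expit(d / s_eff)


def simulate_responses(true_orientation, probe_offset, params: PsychParams, rng) -> np.ndarray:
    """Sample clockwise (True) / anticlockwise (False) reports."""
    true_orientation = np.asarray(true_orientation, float)
    probe = true_orientation + np.asarray(probe_offset, float)
    p_cw = choice_probability(mixed_orientation(true_orientation, params.B), probe,
                              params.s, _near_cardinal(true_orientation), params.c)
    return rng.random(p_cw.shape) < p_cw


# -- grid-search fitting ------------------------------------------------------

_B_GRID = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.01), 2)
_S_GRID = np.round(np.arange(0.01, 1.0 + 1e-9, 0.01), 2)
_C_GRID = np.round(np.arange(-0.5, 0.5 + 1e-9, 0.01), 2)


def fit_grid(true_orientation, probe_offset, response_clockwise,
             condition: tuple | None = None) -> PsychFit:
    """Exhaustive grid-search least-squares fit of (B, s, c).

    Residuals are per-trial squared differences between the predicted
    clockwise probability and the 0/1 response.  Trials sharing an
    (orientation, probe-offset) cell have identical predictions, so the SSE
    is accumulated from cell counts.  Ties are broken toward smaller \\|B\\|,
    then smaller s, then smaller \\|c\\|.
    """
    oset = build_orientation_set()
    true_orientation = np.asarray(true_orientation, float)
    probe_offset = np.asarray(probe_offset, float)
    resp = np.asarray(response_clockwise, bool)
    if resp.size == 0:
        raise ValueError("no responses to fit")

    ori_idx = np.array([oset.index_of(a) for a in true_orientation])
    offsets = np.unique(probe_offset)
    off_idx = np.searchsorted(offsets, probe_offset)
    n_cells = (oset.n, len(offsets))
    n_cw = np.zeros(n_cells)
    n_acw = np.zeros(n_cells)
    np.add.at(n_cw, (ori_idx, off_idx), resp)
    np.add.at(n_acw, (ori_idx, off_idx), ~resp)

    near_card = oset.near_cardinal_mask()
    # s_eff grid (orientation-class, s, c)
    s_eff = np.where(near_card[:, None, None],
                     np.exp(_C_GRID)[None, None, :] * _S_GRID[None, :, None],
                     _S_GRID[None, :, None])

    best_sse = np.inf
    best = None
    for B in _B_GRID:
        mixed = blend_angles(oset.angles, B)
        d = np.deg2rad(signed_angle_diff(mixed[:, None], (oset.angles[:, None] + offsets[None, :])))
        p = expit(d[:, :, None, None] / s_eff[:, None, :, :])
        sse_sc = (np.einsum("ij,ijkl->kl", n_cw, (1.0 - p) ** 2)
                  + np.einsum("ij,ijkl->kl", n_acw, p ** 2))
        k = np.unravel_index(np.argmin(sse_sc), sse_sc.shape)
        cand = (sse_sc[k], abs(B), _S_GRID[k[0]], abs(_C_GRID[k[1]]))
        if best is None or cand < (best_sse, abs(best[0]), best[1], abs(best[2])):
            best_sse = sse_sc[k]
            best = (float(B), float(_S_GRID[k[0]]), float(_C_GRID[k[1]]))

    params = PsychParams(B=best[0], s=best[1], c=best[2])
    degenerate = bool(resp.all() or (~resp).all())
    return PsychFit(params=params, sse=float(best_sse), condition=condition,
                    degenerate=degenerate)


# -- behavioural summaries ----------------------------------------------------

def accuracy_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Percent correct per (stimulus, test) cell, ordered by mnemonic distance.

    A response is correct when its direction matches the sign of
    (true - probe): the probe sits ``probe_offset`` clockwise of the true
    orientation (positive = anticlockwise in screen terms is resolved by the
    generator's convention that correctness is stored per trial), so here we
    simply aggregate the stored correctness flags.
    """
    rows = []
    for level, (stim, test) in enumerate(MNEMONIC_LEVELS, start=1):
        col = f"correct_{test}"
        if test == "1":
            sub = trials.loc[trials["cued_first"].astype(str) == stim, col]
        else:
            sub = trials.loc[trials["has_test2"]
                             & (trials["cued_first"].astype(str) != stim), col]
        sub = sub.dropna()
        rows.append({"stimulus": int(stim), "test": int(test),
                     "mnemonic_level": level, "n": len(sub),
                     "accuracy_pct": 100.0 * sub.mean() if len(sub) else np.nan})
    return pd.DataFrame(rows)
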