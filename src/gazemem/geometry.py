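"""Parametric orientation geometries and their dissimilarity structures.

The stimulus set consists of 16 equidistant orientations (11.25° to 348.75°
in steps of 22.5°) that avoid the cardinal axes.  Reported and gaze-encoded
orientations may be biased away from (repulsion) or towards (attraction) the
cardinal axes.  This is modelled as a mixture, controlled by ``B`` in
[-1, 1], between the veridical circle geometry (``B = 0``) and a "square"
geometry in which every orientation collapses onto its nearest diagonal
(``B = 1``, repulsion) or nearest cardinal (``B = -1``, attraction).

The mixture is applied in angle space: each orientation is shifted along the
shortest circular path towards its axis target, by a fraction ``|B|`` of that
path.  The blended angles are then placed on the unit circle and a 16 x 16
matrix of pairwise Euclidean distances (the model RDM) is derived.  A row of
the RDM is the model representational dissimilarity vector (RDV) for the
orientation indexing that row.

Angles are measured anticlockwise from the positive x-axis, in degrees;
"object upright" corresponds to 90°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CARDINAL_AXES",
    "DIAGONAL_AXES",
    "OrientationSet",
    "BiasGeometry",
    "build_orientation_set",
    "nearest_axis_angle",
    "blend_geometry",
    "model_rdv",
    "rdm_correlation",
]

CARDINAL_AXES = np.array([0.0, 90.0, 180.0, 270.0])
DIAGONAL_AXES = np.array([45.0, 135.0, 225.0, 315.0])


def wrap_degrees(angle):
    """Wrap angles to [0, 360)."""
    return np.asarray(angle, dtype=float) % 360.0


def signed_angle_diff(a, b):
    """Signed shortest circular difference a - b, in (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


@dataclass(frozen=True)
class OrientationSet:
    """The canonical full-circle orientation grid.

    ``angles`` are equidistant, exclude the cardinal axes, and split evenly
    into near-cardinal and near-diagonal halves (11.25° from the nearest
    cardinal or diagonal axis, respectively).
    """

    angles: np.ndarray

    @property
    def n(self) -> int:
        return len(self.angles)

    def index_of(self, angle: float) -> int:
        """Index of an orientation in the set (exact match up to wrap)."""
        d = np.abs(signed_angle_diff(self.angles, angle))
        i = int(np.argmin(d))
        if d[i] > 1e-9:
            raise ValueError(f"{angle!r} is not in the orientation set")
        return i

    def near_cardinal_mask(self) -> np.ndarray:
        """True for orientations closer to a cardinal than a diagonal axis."""
        dist_card = np.abs(signed_angle_diff(self.angles[:, None], CARDINAL_AXES[None, :])).min(axis=1)
        dist_diag = np.abs(signed_angle_diff(self.angles[:, None], DIAGONAL_AXES[None, :])).min(axis=1)
        return dist_card < dist_diag


def build_orientation_set(n: int = 16) -> OrientationSet:
    """The canonical orientation grid: ``n`` equidistant angles offset by half
    a step so that no orientation falls on a cardinal axis (11.25° to 348.75°
    for the default n = 16)."""
    if n < 4 or n % 4:
        raise ValueError("n must be a positive multiple of 4")
    step = 360.0 / n
    return OrientationSet(angles=np.arange(n) * step + step / 2.0)


def nearest_axis_angle(angle: float, axis: str) -> float:
    """Closest diagonal (45/135/225/315°) or cardinal (0/90/180/270°) axis
    angle along the shortest circular path.

    Ties (angle exactly between two targets, which cannot occur for the
    canonical set) resolve toward the anticlockwise target.
    """
    targets = {"diagonal": DIAGONAL_AXES, "cardinal": CARDINAL_AXES}[axis]
    d = signed_angle_diff(targets, angle)
    # argmin is stable; order candidates so that on a tie the anticlockwise
    # (positive-difference) target wins
    order = np.argsort(np.abs(d) - 1e-9 * (d > 0))
    return float(wrap_degrees(targets[order[0]]))


@dataclass(frozen=True)
class BiasGeometry:
    """A B-parameterized set of 16 unit-circle points and its distance matrix."""

    B: float
    orientations: OrientationSet
    model_angles: np.ndarray  # degrees, len 16
    points: np.ndarray        # (16, 2) unit-circle coordinates
    rdm: np.ndarray = field(repr=False)  # (16, 16) Euclidean distances

    def to_csv(self, angles_path, rdm_path) -> None:
        np.savetxt(angles_path, self.model_angles, fmt="%.6f", header="model_angle_deg", comments="")
        np.savetxt(rdm_path, self.rdm, fmt="%.8f", delimiter=",")


def blend_angles(angles, B: float) -> np.ndarray:
    """Blend each angle toward its nearest diagonal (B >= 0) or cardinal
    (B < 0) axis by a fraction |B| of the shortest angular path."""
    if not -1.0 <= B <= 1.0:
        raise ValueError(f"B must lie in [-1, 1], got {B}")
    axis = "diagonal" if B >= 0 else "cardinal"
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    targets = np.array([nearest_axis_angle(a, axis) for a in angles])
    return wrap_degrees(angles + abs(B) * signed_angle_diff(targets, angles))


def blend_geometry(B: float, orientations: OrientationSet | None = None) -> BiasGeometry:
    """Construct the bias geometry for mixture parameter ``B`` in [-1, 1].

    ``B = 0`` reproduces the unbiased circle; ``B = 1`` collapses the
    orientations onto the diagonals (repulsion); ``B = -1`` onto the
    cardinals (attraction).  Points are on the unit circle (the radius is
    arbitrary for correlation-based analyses and fixed for reproducibility).
    """
    if orientations is None:
        orientations = build_orientation_set()
    model_angles = blend_angles(orientations.angles, B)
    theta = np.deg2rad(model_angles)
    points = np.column_stack([np.cos(theta), np.sin(theta)])
    rdm = squareform(pdist(points))
    return BiasGeometry(B=B, orientations=orientations, model_angles=model_angles,
                        points=points, rdm=rdm)


def model_rdv(geometry: BiasGeometry, anchor_index: int) -> np.ndarray:
    """The model RDV for one orientation: row ``anchor_index`` of the RDM."""
    n = geometry.rdm.shape[0]
    if not 0 <= anchor_index < n:
        raise IndexError(f"anchor_index {anchor_index} out of range 0..{n - 1}")
    return geometry.rdm[anchor_index].copy()


def rdm_correlation(a: BiasGeometry, b: BiasGeometry) -> float:
    """Pearson correlation between two model RDMs over the unique
    off-diagonal pairs (upper triangle, diagonal excluded)."""
    if a.rdm.shape != b.rdm.shape:
        raise ValueError("geometries must be built on the same orientation set")
    iu = np.triu_indices(a.rdm.shape[0], k=1)
    va, vb = a.rdm[iu], b.rdm[iu]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("degenerate geometry: RDM has zero variance")
    return float(np.corrcoef(va, vb)[0, 1])
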