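"""Horizontal-cell On-Off feature frontend.

A horizontal-cell-equivalent unit compares the center pixel of frame t with
each of its eight neighbors in frame t+dt, per RGB channel, and fires (1)
when the absolute intensity difference is below the discrimination threshold
theta_h, i.e. when the two pixels are perceptually "the same".  For a moving
object the neighbor lying along the motion direction tends to match the
center, so the 24 binary features (8 neighbors x 3 channels) at each interior
pixel carry a local direction cue.

theta_h defaults to 3, the smallest RGB difference treated as resolvable;
a difference exactly equal to theta_h counts as resolvable, hence feature 0.
Features are computed only at interior pixels (full 8-neighborhood); no
padding values are invented at the border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NEIGHBOR_OFFSETS", "HCFeatureField", "hc_response",
           "receptive_field_vector", "feature_matrix"]

#: Fixed neighbor order: (dy, dx) row-major over {-1,0,1}^2 excluding (0,0).
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

DEFAULT_THETA_H = 3


@dataclass
class HCFeatureField:
    """Binary On-Off features over the interior of a frame pair.

    ``features`` has shape (H-2, W-2, 8, 3) indexed by (interior row,
    interior col, neighbor, channel); entry (a-1, b-1, k, c) refers to image
    center (a, b).  The flattened 24-vector at a pixel is channel-major:
    [R over 8 neighbors, G over 8 neighbors, B over 8 neighbors].
    """

    features: np.ndarray
    theta_h: int
    shape: tuple[int, int]

    @property
    def n_fields(self) -> int:
        return self.features.shape[0] * self.features.shape[1]

    def valid_region(self) -> tuple[range, range]:
        h, w = self.shape
        return range(1, h - 1), range(1, w - 1)


def hc_response(frame_t: np.ndarray, frame_t1: np.ndarray,
                theta_h: int = DEFAULT_THETA_H) -> HCFeatureField:
    """Compute the On-Off field: 1 iff |t-center - (t+dt)-neighbor| < theta_h.

    Centers come from frame t only and neighbors from frame t+dt only, so the
    comparison is temporally asymmetric by construction.
    """
    if frame_t.shape != frame_t1.shape:
        raise ValueError("frame shapes differ")
    if frame_t.ndim != 3 or frame_t.shape[2] != 3:
        raise ValueError("frames must be (H, W, 3)")
    if theta_h <= 0:
        raise ValueError("theta_h must be positive")
    h, w = frame_t.shape[:2]
    if h < 3 or w < 3:
        raise ValueError("frames must be at least 3x3")
    center = frame_t[1:h - 1, 1:w - 1].astype(np.int16)
    feats = np.empty((h - 2, w - 2, 8, 3), dtype=np.int8)
    t1 = frame_t1.astype(np.int16)
    for k, (dy, dx) in enumerate(NEIGHBOR_OFFSETS):
        neighbor = t1[1 + dy:h - 1 + dy, 1 + dx:w - 1 + dx]
        feats[:, :, k, :] = np.abs(center - neighbor) < theta_h
    return HCFeatureField(features=feats, theta_h=theta_h, shape=(h, w))


def receptive_field_vector(field: HCFeatureField, a: int, b: int) -> np.ndarray:
    """The 24 binary inputs at image center (a, b), channel-major order."""
    h, w = field.shape
    if not (1 <= a <= h - 2 and 1 <= b <= w - 2):
        raise ValueError(f"({a}, {b}) is outside the valid interior region")
    # (8, 3) -> channel-major flattening: index = c*8 + k
    return field.features[a - 1, b - 1].T.reshape(24).copy()


def feature_matrix(field: HCFeatureField) -> np.ndarray:
    """All receptive fields stacked row-major, shape (n_fields, 24), int8."""
    hi, wi = field.features.shape[:2]
    # (hi, wi, 8, 3) -> (hi*wi, 3, 8) -> (F, 24) channel-major
    return np.ascontiguousarray(
        field.features.transpose(0, 1, 3, 2).reshape(hi * wi, 24)
    )
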