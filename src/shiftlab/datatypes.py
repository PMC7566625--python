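"""Shared containers and errors for paired H&E / immunofluorescence images."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class ShiftlabError(Exception):
    """Base class for package errors."""


class InvalidSpecError(ShiftlabError):
    """A generator or experiment specification is malformed."""


class DegenerateImageError(ShiftlabError):
    """An image has no usable content (constant, empty, zero variance)."""


class RegistrationError(ShiftlabError):
    """Affine registration could not be estimated."""


@dataclass
class RegisteredPair:
    """An RGB H&E image and a single-channel IF image in one coordinate frame.

    ``he`` is (H, W, 3) float in [0, 1]; ``if_chan`` is (H, W) float in [0, 1].
    ``marker_mask`` is the ground-truth marker support for synthetic phantoms.
    ``dapi`` is an optional nuclear-counterstain channel sharing the IF frame;
    it anchors registration (nuclei appear in both it and the hematoxylin).
    ``misalignment`` records a planted 3x3 forward affine (x, y convention)
    applied to the IF channel, when one exists; None means pixel-perfect
    registration.
    """

    he: np.ndarray
    if_chan: np.ndarray
    sample_id: str = "sample"
    row: int = 0
    col: int = 0
    marker_mask: Optional[np.ndarray] = None
    dapi: Optional[np.ndarray] = None
    misalignment: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.he.ndim != 3 or self.he.shape[2] != 3:
            raise InvalidSpecError("H&E image must be (H, W, 3)")
        if self.if_chan.ndim != 2:
            raise InvalidSpecError("IF image must be single-channel (H, W)")
        if self.he.shape[:2] != self.if_chan.shape:
            raise InvalidSpecError("H&E and IF dimensions differ")

    @property
    def shape(self):
        return self.if_chan.shape


@dataclass
class TileRecord:
    """One retained tile of a tiled WSI pair, with its grid position."""

    he_tile: np.ndarray
    if_tile: np.ndarray
    row: int
    col: int
    sample_id: str
    background_fraction: float


@dataclass
class RegistrationModel:
    """Estimated affine mapping the IF frame onto the H&E frame.

    ``affine`` is the 2x3 top of a 3x3 homogeneous matrix in (x, y)
    convention: a point p in the IF image maps to A @ [x, y, 1] in the H&E
    frame.
    """

    affine: np.ndarray
    n_matched_features: int
    inlier_fraction: float

    def __post_init__(self):
        a = np.asarray(self.affine, dtype=float)
        if a.shape != (2, 3):
            raise InvalidSpecError("affine must be 2x3")
        if abs(np.linalg.det(a[:, :2])) < 1e-12:
            raise InvalidSpecError("affine is not invertible")
        if not 0.0 <= self.inlier_fraction <= 1.0:
            raise InvalidSpecError("inlier_fraction outside [0, 1]")
        self.affine = a

    @property
    def matrix(self) -> np.ndarray:
        return np.vstack([self.affine, [0.0, 0.0, 1.0]])
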