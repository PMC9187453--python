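"""Core domain types for the discrete parallel-beam imaging model.

Conventions (documented here once, used everywhere):

* the image is a square ``D x D`` raster with its origin at the grid
  center; entry ``values[i, j]`` sits at physical coordinates
  ``x = (j - (D-1)/2) * pixel_size``, ``y = ((D-1)/2 - i) * pixel_size``
  (row 0 is the top of the image, as usual for rasters);
* projection angles are measured counterclockwise from the positive
  x-axis and live in ``[0, pi)``;
* the detector array is centered on the origin, with bin ``j`` at signed
  offset ``(j - (n_detectors-1)/2) * detector_spacing`` along the
  direction ``(cos(theta), sin(theta))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class ShapeError(ValueError):
    """Raised when array shapes are inconsistent with the declared geometry."""


@dataclass
class ImageGrid:
    """A square pixel raster: a phantom, a reconstruction, or a difference image.

    Parameters
    ----------
    values : (D, D) ndarray
        Pixel values, row-major, origin at the grid center.
    pixel_size : float
        Physical side length of one pixel (arbitrary units, default 1).
    """

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ShapeError(
                f"image must be a square 2-D array, got shape {self.values.shape}"
            )
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def side_length(self) -> int:
        return self.values.shape[0]

    def ravel(self) -> np.ndarray:
        """Row-major flattening used by all algebraic operators."""
        return self.values.ravel()


@dataclass
class ScanGeometry:
    """Parallel-beam acquisition description.

    ``angles`` must be strictly increasing and contained in ``[0, pi)``.
    A warning is emitted when the detector array is too short to cover
    the diagonal of a grid of ``grid_extent`` physical units (rays then
    miss part of the object and the sinogram is truncated).
    """

    angles: np.ndarray
    n_detectors: int
    detector_spacing: float = 1.0
    beam_kind: str = field(default="parallel")

    def __post_init__(self) -> None:
        self.angles = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if self.angles.size == 0:
            raise ValueError("need at least one projection angle")
        if np.any(self.angles < 0) or np.any(self.angles >= np.pi):
            raise ValueError("angles must lie in [0, pi)")
        if self.angles.size > 1 and np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if self.n_detectors < 1:
            raise ValueError("n_detectors must be a positive integer")
        if self.detector_spacing <= 0:
            raise ValueError("detector_spacing must be positive")
        if self.beam_kind != "parallel":
            raise ValueError("only parallel-beam geometry is supported")

    @property
    def n_angles(self) -> int:
        return int(self.angles.size)

    @property
    def detector_offsets(self) -> np.ndarray:
        """Signed detector-bin offsets from the rotation center."""
        j = np.arange(self.n_detectors, dtype=float)
        return (j - (self.n_detectors - 1) / 2.0) * self.detector_spacing

    def check_coverage(self, grid_extent: float) -> bool:
        """Warn (and return False) if the detector misses part of the grid."""
        span = self.n_detectors * self.detector_spacing
        diagonal = grid_extent * np.sqrt(2.0)
        if span < diagonal:
            warnings.warn(
                f"detector span {span:g} < grid diagonal {diagonal:g}: "
                "sinogram will be truncated",
                stacklevel=2,
            )
            return False
        return True

    @classmethod
    def uniform(
        cls, n_angles: int, n_detectors: int, detector_spacing: float = 1.0
    ) -> "ScanGeometry":
        """Evenly spaced view angles over ``[0, pi)``."""
        if n_angles < 1:
            raise ValueError("n_angles must be a positive integer")
        angles = np.arange(n_angles, dtype=float) * np.pi / n_angles
        return cls(angles=angles, n_detectors=n_detectors,
                   detector_spacing=detector_spacing)


@dataclass
class Sinogram:
    """Projection data: rows are view angles, columns are detector bins."""

    values: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.geometry.n_angles, self.geometry.n_detectors)
        if self.values.shape != expected:
            raise ShapeError(
                f"sinogram shape {self.values.shape} does not match geometry "
                f"{expected}"
            )

    def ravel(self) -> np.ndarray:
        return self.values.ravel()
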