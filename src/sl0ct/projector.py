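"""Sparse projection operator built from exact ray-pixel intersection lengths.

Each row of the system matrix corresponds to one (angle, detector-bin)
pair and stores the chord length of that ray through every pixel it
crosses (Siddon-style traversal).  Intersection lengths carry physical
units, so the forward projection of the all-ones image equals, per bin,
the geometric path length of the ray through the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .grid import ImageGrid, ScanGeometry, ShapeError, Sinogram

_EPS = 1e-12


@dataclass
class ProjectionOperator:
    """Sparse ``(n_angles * n_detectors) x D**2`` matrix of chord lengths.

    Row ``i * n_detectors + j`` encodes the ray at angle index ``i`` and
    detector bin ``j``; columns follow the row-major pixel order of
    :class:`~sl0ct.grid.ImageGrid`.  Rays that miss the grid keep their
    (all-zero) rows so sinogram shapes never change.
    """

    matrix: sparse.csr_matrix
    geometry: ScanGeometry
    grid_side: int
    pixel_size: float = 1.0

    @property
    def n_rays(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[1]


def _trace_ray(theta: float, offset: float, D: int, h: float):
    """Chord lengths of one ray through a D x D grid of pixel size h.

    The ray is the line ``x cos(theta) + y sin(theta) = offset``,
    traversed along the direction ``(-sin(theta), cos(theta))``.
    Returns (pixel_indices, lengths); both empty if the ray misses.
    """
    half = 0.5 * D * h
    ct, st = np.cos(theta), np.sin(theta)
    p0 = np.array([offset * ct, offset * st])
    d = np.array([-st, ct])

    # Entry/exit parameters against the bounding box (slab method).
    tmin, tmax = -np.inf, np.inf
    for axis in (0, 1):
        if abs(d[axis]) > _EPS:
            t1 = (-half - p0[axis]) / d[axis]
            t2 = (half - p0[axis]) / d[axis]
            lo, hi = min(t1, t2), max(t1, t2)
            tmin, tmax = max(tmin, lo), min(tmax, hi)
        elif not (-half <= p0[axis] <= half):
            return np.empty(0, dtype=np.intp), np.empty(0)
    if tmax - tmin <= _EPS * max(1.0, half):
        return np.empty(0, dtype=np.intp), np.empty(0)

    # Parameters at every grid-line crossing strictly inside (tmin, tmax).
    bounds = -half + h * np.arange(D + 1)
    ts = [np.array([tmin, tmax])]
    for axis in (0, 1):
        if abs(d[axis]) > _EPS:
            tc = (bounds - p0[axis]) / d[axis]
            ts.append(tc[(tc > tmin) & (tc < tmax)])
    t = np.unique(np.concatenate(ts))
    lengths = np.diff(t)  # d is a unit vector
    mid = p0[None, :] + 0.5 * (t[:-1] + t[1:])[:, None] * d[None, :]

    cols = np.floor((mid[:, 0] + half) / h).astype(np.intp)
    rows = np.floor((half - mid[:, 1]) / h).astype(np.intp)
    np.clip(cols, 0, D - 1, out=cols)
    np.clip(rows, 0, D - 1, out=rows)
    keep = lengths > _EPS * max(1.0, h)
    return rows[keep] * D + cols[keep], lengths[keep]


def build_projection_operator(
    geometry: ScanGeometry, D: int, pixel_size: float = 1.0
) -> ProjectionOperator:
    """Assemble the sparse system matrix for a grid/geometry pair.

    Deterministic for fixed inputs.  Raises ``ValueError`` for a
    non-positive grid size or pixel size.
    """
    if D < 1:
        raise ValueError(f"grid side must be a positive integer, got {D}")
    if pixel_size <= 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    geometry.check_coverage(D * pixel_size)

    offsets = geometry.detector_offsets
    data, indices, indptr = [], [], [0]
    for theta in geometry.angles:
        for s in offsets:
            cols, lengths = _trace_ray(float(theta), float(s), D, pixel_size)
            indices.append(cols)
            data.append(lengths)
            indptr.append(indptr[-1] + cols.size)
    matrix = sparse.csr_matrix(
        (np.concatenate(data) if data else np.empty(0),
         np.concatenate(indices) if indices else np.empty(0, dtype=np.intp),
         np.array(indptr, dtype=np.intp)),
        shape=(geometry.n_angles * geometry.n_detectors, D * D),
    )
    return ProjectionOperator(matrix=matrix, geometry=geometry,
                              grid_side=D, pixel_size=pixel_size)


def forward_project(A: ProjectionOperator, image: ImageGrid) -> Sinogram:
    """Line integrals ``p = A vec(x)`` of an image, as a sinogram."""
    if image.side_length != A.grid_side:
        raise ShapeError(
            f"image side {image.side_length} does not match operator grid "
            f"side {A.grid_side}"
        )
    p = A.matrix @ image.ravel()
    g = A.geometry
    return Sinogram(values=p.reshape(g.n_angles, g.n_detectors), geometry=g)


def back_project(A: ProjectionOperator, sino: Sinogram) -> ImageGrid:
    """Unfiltered backprojection ``A^T vec(p)``; exact adjoint of the forward."""
    if sino.values.shape != (A.geometry.n_angles, A.geometry.n_detectors):
        raise ShapeError(
            f"sinogram shape {sino.values.shape} does not match operator "
            f"({A.geometry.n_angles}, {A.geometry.n_detectors})"
        )
    x = A.matrix.T @ sino.ravel()
    D = A.grid_side
    return ImageGrid(values=x.reshape(D, D), pixel_size=A.pixel_size)
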