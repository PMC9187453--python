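"""Comparison reconstruction algorithms: FBP, ART, and (weighted) TV.

FBP is the analytic inversion: per-view ramp filtering in the frequency
domain followed by interpolated backprojection.  ART is the classical
Kaczmarz row-action solver for the algebraic system ``A x = p``.  The TV
and WTV reconstructions alternate ART data-consistency sweeps with
steepest-descent steps on a smoothed isotropic total-variation
functional (ASD-POCS-style coupling); WTV scales each pixel's gradient
contribution by an edge-preserving Gaussian weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from .grid import ImageGrid, ScanGeometry, ShapeError, Sinogram
from .projector import ProjectionOperator

FBP_FILTERS = ("ramlak", "shepp-logan-filter", "hann")


@dataclass
class ARTParams:
    """Kaczmarz sweep parameters.

    relaxation : under/over-relaxation factor, must lie in (0, 2).
    n_sweeps   : number of full passes over the rays.
    nonneg     : clamp negative pixels after each sweep.
    init       : "zeros" or "backprojection" starting image.
    """

    relaxation: float = 1.0
    n_sweeps: int = 20
    nonneg: bool = False
    init: str = "zeros"

    def __post_init__(self) -> None:
        if not 0 < self.relaxation < 2:
            raise ValueError("relaxation must lie in (0, 2)")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be positive")
        if self.init not in ("zeros", "backprojection"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class TVParams:
    """ASD-POCS-style TV/WTV parameters.

    n_tv_steps   : descent steps on the TV functional per ART sweep.
    tv_step      : TV step length as a fraction of the preceding ART
                   update norm (standard adaptive coupling).
    weighting    : "uniform" (plain TV) or "weighted" (WTV).
    weight_delta : edge scale of the WTV weight w = exp(-(|grad|/delta)^2);
                   weights are recomputed once per sweep.
    epsilon_tv   : smoothing of the isotropic gradient magnitude.
    """

    art: ARTParams = field(default_factory=ARTParams)
    n_tv_steps: int = 10
    tv_step: float = 0.2
    weighting: str = "uniform"
    weight_delta: float = 0.05
    epsilon_tv: float = 1e-8

    def __post_init__(self) -> None:
        if self.tv_step < 0:
            raise ValueError("tv_step must be nonnegative")
        if self.weighting not in ("uniform", "weighted"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.weight_delta <= 0:
            raise ValueError("weight_delta must be positive")
        if self.epsilon_tv <= 0:
            raise ValueError("epsilon_tv must be positive")


# ---------------------------------------------------------------------------
# Filtered back projection
# ---------------------------------------------------------------------------

def _ramp_filter(n: int, spacing: float, name: str) -> np.ndarray:
    freqs = np.fft.fftfreq(n, d=spacing)
    ramp = np.abs(freqs)
    nyquist = 0.5 / spacing
    if name == "ramlak":
        return ramp
    if name == "shepp-logan-filter":
        return ramp * np.sinc(freqs / (2 * nyquist))
    if name == "hann":
        return ramp * 0.5 * (1 + np.cos(np.pi * freqs / nyquist))
    raise ValueError(f"unknown filter {name!r}; expected one of {FBP_FILTERS}")


def fbp_reconstruct(sino: Sinogram, D: int, filter: str = "ramlak",
                    pixel_size: float = 1.0) -> ImageGrid:
    """Filtered back projection onto a D x D grid.

    Each view is ramp-filtered in the frequency domain (with zero
    padding to the next power of two at least twice the detector count)
    and backprojected with linear interpolation and ``pi / n_angles``
    angular weighting.  Linear in the sinogram and deterministic.
    """
    _ramp_filter(4, 1.0, filter)  # validate the name early
    geom = sino.geometry
    n_det = geom.n_detectors
    spacing = geom.detector_spacing
    n_pad = int(2 ** np.ceil(np.log2(max(2 * n_det, 16))))
    filt = _ramp_filter(n_pad, spacing, filter)

    proj = np.zeros((geom.n_angles, n_pad))
    proj[:, :n_det] = sino.values
    filtered = np.real(np.fft.ifft(np.fft.fft(proj, axis=1) * filt, axis=1))
    filtered = filtered[:, :n_det]

    j = np.arange(D)
    x = (j - (D - 1) / 2.0) * pixel_size
    y = ((D - 1) / 2.0 - np.arange(D)) * pixel_size
    X, Y = np.meshgrid(x, y)
    offsets = geom.detector_offsets
    recon = np.zeros((D, D))
    for k, theta in enumerate(geom.angles):
        s = X * np.cos(theta) + Y * np.sin(theta)
        recon += np.interp(s, offsets, filtered[k], left=0.0, right=0.0)
    recon *= np.pi / geom.n_angles
    return ImageGrid(values=recon, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# ART (Kaczmarz)
# ---------------------------------------------------------------------------

def _kaczmarz_sweep(x: np.ndarray, indptr, indices, data, p: np.ndarray,
                    row_norms: np.ndarray, relaxation: float) -> None:
    """One sequential pass over all usable rows, updating x in place."""
    for i in range(p.size):
        lo, hi = indptr[i], indptr[i + 1]
        if lo == hi:
            continue
        cols = indices[lo:hi]
        a = data[lo:hi]
        resid = p[i] - a @ x[cols]
        x[cols] += relaxation * resid / row_norms[i] * a


def kaczmarz_solve(matrix, p, relaxation: float = 1.0, n_sweeps: int = 20,
                   x0=None, nonneg: bool = False) -> np.ndarray:
    """Sequential Kaczmarz sweeps on an arbitrary linear system ``M x = p``.

    The row-action core behind :func:`art_reconstruct`, usable on any
    (sparse or dense) matrix.  On a consistent system started from zero
    it converges to the minimum-norm (pseudo-inverse) solution.
    """
    M = matrix if sparse.issparse(matrix) else sparse.csr_matrix(
        np.atleast_2d(np.asarray(matrix, dtype=float)))
    M = M.tocsr()
    if M.nnz == 0:
        raise ValueError("no usable rays: system matrix is all zero")
    p = np.asarray(p, dtype=float).ravel()
    if p.size != M.shape[0]:
        raise ShapeError(f"rhs length {p.size} != row count {M.shape[0]}")
    row_norms = np.asarray(M.multiply(M).sum(axis=1)).ravel()
    row_norms[row_norms == 0] = 1.0
    x = np.zeros(M.shape[1]) if x0 is None else np.array(x0, dtype=float)
    for _ in range(n_sweeps):
        _kaczmarz_sweep(x, M.indptr, M.indices, M.data, p, row_norms,
                        relaxation)
        if nonneg:
            np.maximum(x, 0.0, out=x)
    return x


def _art_state(A: ProjectionOperator, sino: Sinogram, params: ARTParams):
    M = A.matrix
    if M.nnz == 0:
        raise ValueError("no usable rays: projection operator is all zero")
    if sino.values.shape != (A.geometry.n_angles, A.geometry.n_detectors):
        raise ShapeError("sinogram shape does not match operator")
    row_norms = np.asarray(M.multiply(M).sum(axis=1)).ravel()
    row_norms[row_norms == 0] = 1.0  # zero rows are skipped anyway
    if params.init == "backprojection":
        x = (M.T @ sino.ravel()) / max(row_norms.sum(), 1.0)
    else:
        x = np.zeros(M.shape[1])
    return x, M.indptr, M.indices, M.data, sino.ravel(), row_norms


def art_reconstruct(A: ProjectionOperator, sino: Sinogram,
                    params: ARTParams | None = None) -> ImageGrid:
    """Classical ART: sequential Kaczmarz sweeps over the rays.

    Each row update projects the current image onto the hyperplane of
    one measured ray: ``x <- x + lam (p_i - a_i.x) / ||a_i||^2 a_i``.
    Zero rows (rays missing the grid) are skipped.  Deterministic
    (sequential row order).
    """
    params = params or ARTParams()
    x, indptr, indices, data, p, row_norms = _art_state(A, sino, params)
    for _ in range(params.n_sweeps):
        _kaczmarz_sweep(x, indptr, indices, data, p, row_norms,
                        params.relaxation)
        if params.nonneg:
            np.maximum(x, 0.0, out=x)
    D = A.grid_side
    return ImageGrid(values=x.reshape(D, D), pixel_size=A.pixel_size)


# ---------------------------------------------------------------------------
# (Weighted) total variation
# ---------------------------------------------------------------------------

def _tv_weights(v: np.ndarray, delta: float, eps: float) -> np.ndarray:
    gx = np.diff(v, axis=1, append=v[:, -1:])
    gy = np.diff(v, axis=0, append=v[-1:, :])
    mag = np.sqrt(gx * gx + gy * gy + eps * eps)
    return np.exp(-((mag / delta) ** 2))


def tv_gradient(v: np.ndarray, eps: float,
                weights: np.ndarray | None = None) -> np.ndarray:
    """Gradient of sum_ij w_ij sqrt(dx^2 + dy^2 + eps^2) (forward differences).

    With ``weights=None`` this is plain smoothed isotropic TV; a constant
    image has zero gradient exactly.
    """
    gx = np.diff(v, axis=1, append=v[:, -1:])
    gy = np.diff(v, axis=0, append=v[-1:, :])
    mag = np.sqrt(gx * gx + gy * gy + eps * eps)
    if weights is not None:
        tx, ty = weights * gx / mag, weights * gy / mag
    else:
        tx, ty = gx / mag, gy / mag
    grad = np.zeros_like(v)
    # adjoint of the forward-difference pair: -div of the unit-gradient field
    grad -= tx
    grad[:, 1:] += tx[:, :-1]
    grad -= ty
    grad[1:, :] += ty[:-1, :]
    return grad


def tv_reconstruct(A: ProjectionOperator, sino: Sinogram,
                   params: TVParams | None = None) -> ImageGrid:
    """TV- or WTV-regularized algebraic reconstruction.

    Alternates one full ART sweep with ``n_tv_steps`` normalized
    steepest-descent steps on the (weighted) TV functional; the TV step
    length is ``tv_step`` times the norm of the preceding ART update.
    ``tv_step = 0`` reduces exactly to :func:`art_reconstruct`.
    """
    params = params or TVParams()
    art = params.art
    x, indptr, indices, data, p, row_norms = _art_state(A, sino, art)
    D = A.grid_side
    for _ in range(art.n_sweeps):
        x_prev = x.copy()
        _kaczmarz_sweep(x, indptr, indices, data, p, row_norms, art.relaxation)
        if art.nonneg:
            np.maximum(x, 0.0, out=x)
        dx_art = float(np.linalg.norm(x - x_prev))
        if params.tv_step == 0 or dx_art == 0:
            continue
        v = x.reshape(D, D)
        weights = None
        if params.weighting == "weighted":
            weights = _tv_weights(v, params.weight_delta, params.epsilon_tv)
        step = params.tv_step * dx_art
        for _ in range(params.n_tv_steps):
            g = tv_gradient(v, params.epsilon_tv, weights)
            gnorm = float(np.linalg.norm(g))
            if gnorm == 0:
                break
            v = v - step * g / gnorm
        x = v.ravel()
    return ImageGrid(values=x.reshape(D, D), pixel_size=A.pixel_size)


def wtv_reconstruct(A: ProjectionOperator, sino: Sinogram,
                    params: TVParams | None = None) -> ImageGrid:
    """Weighted-TV reconstruction (TV with edge-preserving reweighting)."""
    params = params or TVParams()
    return tv_reconstruct(A, sino, replace(params, weighting="weighted"))
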