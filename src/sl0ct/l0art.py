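"""Smoothed-L0 regularized algebraic reconstruction (L0-ART).

The reconstruction solves

    min_x  H(x, beta, kappa) = sum_i v((Psi x)_i, beta) + kappa ||A x - p||^2

where ``v(t, beta) = 1 - exp(-t^2 / (2 beta^2))`` is a smooth surrogate
for the indicator ``1[t != 0]``: as the scale ``beta`` shrinks to zero,
``sum_i v`` converges to the counting "norm" ``||Psi x||_0``, so the
energy promotes exact sparsity of the transform coefficients while
staying differentiable.  ``Psi`` is either the discrete forward-
difference gradient (default — CT images are gradient-sparse) or the
identity (classical sparse signal recovery).

The solver nests two loops: the outer loop anneals ``beta`` by a fixed
factor ``gamma`` so the surrogate approaches the true L0 count, and the
inner loop runs damped fixed-point (gradient) steps on the energy at the
current ``beta``, with backtracking step halving whenever a step would
increase the energy.  Both loops stop on relative-change tolerances.

:func:`l0art_reconstruct` is the CT entry point (projection operator +
sinogram); :func:`sl0_recover` runs the same annealed scheme on an
arbitrary measurement matrix for classical sparse signal recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import sparse

from .baselines import fbp_reconstruct
from .grid import ImageGrid, ShapeError, Sinogram
from .projector import ProjectionOperator, back_project

logger = logging.getLogger(__name__)

TRANSFORMS = ("gradient", "identity")


class DivergenceError(RuntimeError):
    """Inner fixed-point iteration diverged despite step halving."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass
class SL0Params:
    """Tuning parameters of the smoothed-L0 reconstruction.

    beta0        : initial smoothing scale; ``None`` selects
                   ``2 * max|Psi x_init|`` (a scale well above every
                   transform coefficient, so the surrogate starts nearly
                   quadratic).
    gamma        : annealing factor in (0, 1); beta is multiplied by
                   gamma at the start of every outer iteration.
    kappa        : data-fidelity weight on ``||A x - p||^2``.
    mu_outer     : outer relative-change stopping tolerance.
    mu_inner     : inner relative-change stopping tolerance.
    step_size    : scale factor on the curvature-matched inner step
                   (1.0 = the safe Lipschitz estimate; see methods note).
    transform    : "gradient" or "identity" sparsifying transform Psi.
    init         : "fbp", "backprojection" or "zeros" starting image.
    data_projection : "none" (penalty only) or "exact" — re-project each
                   inner iterate onto ``{x : A x = p}``; classical SL0
                   behavior, feasible only for small dense systems.
    """

    beta0: float | None = None
    gamma: float = 0.7
    kappa: float = 1.0
    mu_outer: float = 1e-3
    mu_inner: float = 1e-3
    max_outer: int = 30
    max_inner: int = 50
    step_size: float = 1.0
    transform: str = "gradient"
    init: str = "fbp"
    data_projection: str = "none"

    def __post_init__(self) -> None:
        if self.beta0 is not None and self.beta0 <= 0:
            raise ValueError("beta0 must be positive")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        if self.mu_outer <= 0 or self.mu_inner <= 0:
            raise ValueError("stopping tolerances must be positive")
        if self.max_outer < 1 or self.max_inner < 1:
            raise ValueError("iteration caps must be positive")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.init not in ("fbp", "backprojection", "zeros"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.data_projection not in ("none", "exact"):
            raise ValueError(f"unknown data_projection {self.data_projection!r}")


@dataclass
class SL0State:
    """Trace of one reconstruction run (for convergence auditing)."""

    x: np.ndarray
    beta: float
    outer_index: int = 0
    inner_index: int = 0
    energy_trace: list = field(default_factory=list)
    beta_trace: list = field(default_factory=list)
    log: list = field(default_factory=list)  # dicts per accepted step


# ---------------------------------------------------------------------------
# smoothed-L0 surrogate
# ---------------------------------------------------------------------------

def smoothed_l0_value(t, beta: float):
    """Gaussian surrogate ``v(t, beta) = 1 - exp(-t^2 / (2 beta^2))``.

    Vanishes at t = 0, increases in |t|, and tends to 1 as |t|/beta
    grows — a smooth stand-in for the indicator 1[t != 0].
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    t = np.asarray(t, dtype=float)
    out = 1.0 - np.exp(-(t * t) / (2.0 * beta * beta))
    return float(out) if out.ndim == 0 else out


def smoothed_l0_sum(coeffs, beta: float) -> float:
    """Sum of the surrogate over a coefficient vector.

    Bounded above by the counting norm ``||coeffs||_0`` and converges to
    it as beta -> 0.  Empty input gives 0.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0:
        return 0.0
    return float(np.sum(smoothed_l0_value(coeffs, beta)))


def lambda_weights(coeffs, beta: float):
    """Diagonal weights ``Lambda_i = v'(t_i, beta) / t_i``.

    For the Gaussian surrogate this is ``exp(-t^2/(2 beta^2)) / beta^2``,
    whose analytic limit ``1 / beta^2`` at t = 0 avoids the 0/0.  All
    entries lie in (0, 1/beta^2].
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    t = np.asarray(coeffs, dtype=float)
    out = np.exp(-(t * t) / (2.0 * beta * beta)) / (beta * beta)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# sparsifying transforms and system adapters
# ---------------------------------------------------------------------------

def _psi_apply(x: np.ndarray, side: int | None, transform: str) -> np.ndarray:
    """Transform coefficients Psi x (length 2 D^2 for the gradient)."""
    if transform == "identity":
        return x
    v = x.reshape(side, side)
    gx = np.diff(v, axis=1, append=v[:, -1:])
    gy = np.diff(v, axis=0, append=v[-1:, :])
    return np.concatenate([gx.ravel(), gy.ravel()])


def _psi_adjoint(c: np.ndarray, side: int | None, transform: str) -> np.ndarray:
    if transform == "identity":
        return c
    tx = c[: side * side].reshape(side, side)
    ty = c[side * side:].reshape(side, side)
    out = np.zeros((side, side))
    out -= tx
    out[:, 1:] += tx[:, :-1]
    out -= ty
    out[1:, :] += ty[:-1, :]
    return out.ravel()


def _psi_norm_sq(transform: str) -> float:
    # ||Psi||^2: forward-difference gradient operator has norm^2 <= 8
    return 8.0 if transform == "gradient" else 1.0


def _as_system(A, transform: str):
    """Normalize a ProjectionOperator / sparse / dense matrix to CSR.

    Returns (matrix, grid_side); grid_side is None for generic systems
    and is required (square column count) by the gradient transform.
    """
    if isinstance(A, ProjectionOperator):
        return A.matrix, A.grid_side
    M = A.tocsr() if sparse.issparse(A) else sparse.csr_matrix(
        np.atleast_2d(np.asarray(A, dtype=float)))
    side = int(round(np.sqrt(M.shape[1])))
    if side * side != M.shape[1]:
        side = None
    if transform == "gradient" and side is None:
        raise ShapeError("gradient transform needs a square pixel count")
    return M, side


def _check_shapes(x: np.ndarray, p: np.ndarray, M) -> None:
    if x.size != M.shape[1]:
        raise ShapeError(f"image vector length {x.size} != {M.shape[1]}")
    if p.size != M.shape[0]:
        raise ShapeError(f"measurement vector length {p.size} != {M.shape[0]}")


# ---------------------------------------------------------------------------
# energy and its gradient
# ---------------------------------------------------------------------------

def energy(x, p, A, params: SL0Params, beta: float) -> float:
    """H(x, beta, kappa) = sum_i v((Psi x)_i, beta) + kappa ||A x - p||^2.

    Nonnegative; zero exactly when the transform coefficients vanish and
    the measurements are matched.  ``A`` may be a projection operator or
    any matrix.
    """
    M, side = _as_system(A, params.transform)
    x = np.asarray(x, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    _check_shapes(x, p, M)
    coeffs = _psi_apply(x, side, params.transform)
    resid = M @ x - p
    return smoothed_l0_sum(coeffs, beta) + params.kappa * float(resid @ resid)


def el_residual(x, p, A, params: SL0Params, beta: float) -> np.ndarray:
    """Stationarity residual of the energy (its exact gradient).

    R(x) = Psi^T diag(Lambda(Psi x, beta)) Psi x + 2 kappa A^T (A x - p);
    setting R = 0 is the Euler-Lagrange condition of the energy, and
    directional derivatives of :func:`energy` equal <R, d>.
    """
    M, side = _as_system(A, params.transform)
    x = np.asarray(x, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    _check_shapes(x, p, M)
    coeffs = _psi_apply(x, side, params.transform)
    sparsity_term = _psi_adjoint(lambda_weights(coeffs, beta) * coeffs, side,
                                 params.transform)
    data_term = 2.0 * params.kappa * (M.T @ (M @ x - p))
    return sparsity_term + data_term


# ---------------------------------------------------------------------------
# annealed fixed-point driver
# ---------------------------------------------------------------------------

def _spectral_norm_sq(M, n_iter: int = 20) -> float:
    """sigma_max(M)^2 by power iteration on M^T M (deterministic start)."""
    v = np.ones(M.shape[1]) / np.sqrt(M.shape[1])
    s = 1.0
    for _ in range(n_iter):
        w = M.T @ (M @ v)
        s = float(np.linalg.norm(w))
        if s == 0:
            return 1.0
        v = w / s
    return s


def _rel_change(x_new: np.ndarray, x_old: np.ndarray) -> float:
    denom = float(np.linalg.norm(x_old))
    if denom == 0:
        return float(np.linalg.norm(x_new) > 0)
    return float(np.linalg.norm(x_new - x_old)) / denom


def _sl0_core(M, p: np.ndarray, side: int | None, params: SL0Params,
              x0: np.ndarray) -> SL0State:
    """Nested annealing loops on an arbitrary system; returns the state."""
    x = np.asarray(x0, dtype=float).copy()
    coeffs0 = _psi_apply(x, side, params.transform)
    beta = params.beta0 if params.beta0 is not None else \
        2.0 * max(float(np.max(np.abs(coeffs0))), 1e-12)

    sigma_sq = _spectral_norm_sq(M)
    psi_sq = _psi_norm_sq(params.transform)

    projector = None
    if params.data_projection == "exact":
        # pseudo-inverse correction x <- x - A^T (A A^T)^+ (A x - p)
        Ad = M.toarray()
        projector = (Ad, Ad.T @ sla.pinv(Ad @ Ad.T))

    state = SL0State(x=x, beta=beta)
    diverge_streak = 0
    for outer in range(params.max_outer):
        x_outer = x.copy()
        beta *= params.gamma
        state.beta_trace.append(beta)

        # curvature-matched base step: the surrogate's second derivative
        # is bounded by 1/beta^2 and the data Hessian by 2 kappa sigma^2
        eta_base = params.step_size / (psi_sq / beta ** 2
                                       + 2.0 * params.kappa * sigma_sq)
        e_curr = _energy_raw(x, p, M, side, params, beta)
        made_step = False
        for inner in range(params.max_inner):
            x_inner = x.copy()
            coeffs = _psi_apply(x, side, params.transform)
            r = _psi_adjoint(lambda_weights(coeffs, beta) * coeffs, side,
                             params.transform) \
                + 2.0 * params.kappa * (M.T @ (M @ x - p))
            eta = eta_base
            accepted = False
            for _ in range(11):  # initial step + 10 halvings
                x_try = x - eta * r
                if projector is not None:
                    Ad, corr = projector
                    x_try = x_try - corr @ (Ad @ x_try - p)
                e_try = _energy_raw(x_try, p, M, side, params, beta)
                if e_try <= e_curr + 1e-15 * max(1.0, abs(e_curr)):
                    accepted = True
                    break
                eta *= 0.5
            if not accepted:
                diverge_streak += 1
                if diverge_streak >= 5:
                    raise DivergenceError(
                        "inner iteration diverged: energy increased on 5 "
                        "consecutive steps after 10 halvings", state.log)
                break
            diverge_streak = 0
            made_step = True
            x, e_curr = x_try, e_try
            state.energy_trace.append(e_curr)
            rel = _rel_change(x, x_inner)
            state.log.append({"outer": outer, "inner": inner, "beta": beta,
                              "energy": e_curr, "rel_change": rel,
                              "step": eta})
            state.inner_index = inner
            if rel < params.mu_inner:
                break

        state.outer_index = outer
        # a stalled outer pass (no accepted inner step) is not convergence:
        # keep annealing so the curvature-matched step can rescale
        if made_step and _rel_change(x, x_outer) < params.mu_outer:
            break

    state.x = x
    state.beta = beta
    return state


def _energy_raw(x, p, M, side, params: SL0Params, beta: float) -> float:
    coeffs = _psi_apply(x, side, params.transform)
    resid = M @ x - p
    return smoothed_l0_sum(coeffs, beta) + params.kappa * float(resid @ resid)


def _initial_image(A: ProjectionOperator, sino: Sinogram,
                   params: SL0Params) -> np.ndarray:
    if params.init == "zeros":
        return np.zeros(A.n_pixels)
    if params.init == "backprojection":
        x_bp = back_project(A, sino).ravel()
        fp = A.matrix @ x_bp
        denom = float(fp @ fp)
        scale = float(fp @ sino.ravel()) / denom if denom > 0 else 0.0
        return scale * x_bp
    return fbp_reconstruct(sino, A.grid_side, pixel_size=A.pixel_size).ravel()


def l0art_reconstruct(A: ProjectionOperator, sino: Sinogram,
                      params: SL0Params | None = None
                      ) -> tuple[ImageGrid, SL0State]:
    """Run the annealed smoothed-L0 reconstruction on a CT system.

    Outer loop: multiply beta by gamma, then run the inner loop at that
    scale; stop when the outer relative change drops below ``mu_outer``
    or ``max_outer`` is reached.  Inner loop: damped gradient steps
    ``x <- x - eta R(x)`` with a curvature-matched base step and
    backtracking halving on any energy increase; stop when the inner
    relative change drops below ``mu_inner`` or ``max_inner`` is
    reached.

    Returns the reconstructed image and the full iteration state.
    Deterministic for fixed inputs.  Raises :class:`DivergenceError` if
    the energy keeps increasing after exhausting 10 step halvings on 5
    consecutive inner steps.
    """
    params = params or SL0Params()
    if sino.values.shape != (A.geometry.n_angles, A.geometry.n_detectors):
        raise ShapeError("sinogram shape does not match operator")
    D = A.grid_side
    if not np.any(sino.values):
        logger.info("all-zero sinogram: returning the zero image")
        state = SL0State(x=np.zeros(A.n_pixels), beta=params.beta0 or 1.0)
        return ImageGrid(np.zeros((D, D)), pixel_size=A.pixel_size), state

    x0 = _initial_image(A, sino, params)
    state = _sl0_core(A.matrix, sino.ravel(), D, params, x0)
    return (ImageGrid(values=state.x.reshape(D, D), pixel_size=A.pixel_size),
            state)


def sl0_recover(matrix, p, params: SL0Params | None = None,
                x0=None) -> tuple[np.ndarray, SL0State]:
    """Annealed smoothed-L0 recovery on an arbitrary measurement matrix.

    Classical sparse-signal recovery: by default uses the identity
    transform, exact data projection, and the minimum-norm least-squares
    solution ``pinv(M) p`` as the starting point (the minimum-energy
    measurement-consistent signal).  Returns (solution, state).
    """
    if params is None:
        params = SL0Params(transform="identity", data_projection="exact",
                           mu_outer=1e-6, mu_inner=1e-6, max_outer=60)
    M, side = _as_system(matrix, params.transform)
    p = np.asarray(p, dtype=float).ravel()
    if p.size != M.shape[0]:
        raise ShapeError(f"measurement length {p.size} != {M.shape[0]}")
    if x0 is None:
        if params.init == "zeros":
            x0 = np.zeros(M.shape[1])
        else:
            x0 = sla.lstsq(M.toarray(), p)[0]
    state = _sl0_core(M, p, side, params, np.asarray(x0, dtype=float))
    return state.x, state
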