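"""Analytic ellipse phantoms and sinogram noise models.

Every test input of the package is generated here, so no external image
data is ever required.  The phantoms are piecewise constant, i.e. sparse
in the discrete-gradient domain — the premise that gradient-regularized
reconstruction exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grid import ImageGrid, Sinogram


@dataclass
class EllipseSpec:
    """One additive ellipse in normalized [-1, 1] grid coordinates.

    ``additive_value`` is added to every pixel whose center falls inside
    the (rotated) ellipse; overlapping ellipses accumulate.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0
    additive_value: float = 1.0

    def __post_init__(self) -> None:
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValueError("semi-axes must be positive")


@dataclass
class NoiseModel:
    """Sinogram noise description.

    kind = "none"      : identity.
    kind = "gaussian"  : additive i.i.d. noise with std ``level * max(p)``.
    kind = "poisson"   : transmission counts ``I0 * exp(-p)`` with
                         ``I0 = level`` incident photons, Poisson draw,
                         log-transformed back; zero counts are clamped
                         to one count to keep the log finite.
    """

    kind: str = "none"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.level < 0:
            raise ValueError("noise level must be nonnegative")
        if self.kind == "poisson" and self.level < 1:
            raise ValueError("poisson noise needs an incident count level >= 1")


def point_in_ellipse(x: float, y: float, e: EllipseSpec) -> bool:
    """Exact point-in-ellipse predicate (shared with the test oracle)."""
    ct, st = np.cos(e.rotation), np.sin(e.rotation)
    dx, dy = x - e.center[0], y - e.center[1]
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    return (u / e.semi_axes[0]) ** 2 + (v / e.semi_axes[1]) ** 2 <= 1.0


def rasterize_ellipses(ellipses: Sequence[EllipseSpec], D: int,
                       pixel_size: float = 1.0) -> ImageGrid:
    """Sum of additive ellipses sampled at pixel centers of a D x D grid."""
    j = np.arange(D)
    x = (2 * j - D + 1) / D  # normalized pixel-center abscissae in (-1, 1)
    y = (D - 1 - 2 * np.arange(D)) / D
    X, Y = np.meshgrid(x, y)
    img = np.zeros((D, D))
    for e in ellipses:
        ct, st = np.cos(e.rotation), np.sin(e.rotation)
        dx, dy = X - e.center[0], Y - e.center[1]
        u = ct * dx + st * dy
        v = -st * dx + ct * dy
        inside = (u / e.semi_axes[0]) ** 2 + (v / e.semi_axes[1]) ** 2 <= 1.0
        img[inside] += e.additive_value
    return ImageGrid(values=img, pixel_size=pixel_size)


# Modified Shepp-Logan head phantom: ten ellipses, gray levels in [0, 1]
# (value, semi-axis a, semi-axis b, x0, y0, rotation in degrees).
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6050, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


def shepp_logan_ellipses() -> list[EllipseSpec]:
    return [
        EllipseSpec(center=(x0, y0), semi_axes=(a, b),
                    rotation=np.deg2rad(phi), additive_value=val)
        for val, a, b, x0, y0, phi in SHEPP_LOGAN_ELLIPSES
    ]


def shepp_logan(D: int) -> ImageGrid:
    """Modified Shepp-Logan head phantom, deterministic, values in [0, 1]."""
    if D < 8:
        raise ValueError(f"grid side must be >= 8, got {D}")
    img = rasterize_ellipses(shepp_logan_ellipses(), D)
    # ellipse sums that cancel exactly leave +/-1 ulp residue; snap to 0
    img.values[np.abs(img.values) < 1e-12] = 0.0
    return img


def abdominal_phantom(D: int, seed: int = 0) -> ImageGrid:
    """Piecewise-constant abdominal-like phantom for sparse-view experiments.

    A body oval containing two soft-tissue "organ" ellipses, a
    thick-walled hollow viscus (bright annulus around a darker lumen,
    mimicking a thickened gastric wall), and 2-4 small high-contrast
    lesions whose positions are drawn from ``seed``.  Reproducible for a
    fixed seed; at least four distinct gray levels by construction.
    """
    if D < 32:
        raise ValueError(f"grid side must be >= 32, got {D}")
    rng = np.random.default_rng(seed)
    ellipses = [
        EllipseSpec(center=(0.0, 0.0), semi_axes=(0.88, 0.68),
                    rotation=0.0, additive_value=0.30),            # body
        EllipseSpec(center=(-0.42, 0.12), semi_axes=(0.26, 0.34),
                    rotation=0.25, additive_value=0.25),           # organ 1
        EllipseSpec(center=(0.48, -0.18), semi_axes=(0.22, 0.16),
                    rotation=-0.4, additive_value=0.15),           # organ 2
        EllipseSpec(center=(0.12, 0.22), semi_axes=(0.30, 0.22),
                    rotation=0.1, additive_value=0.45),            # wall outer
        EllipseSpec(center=(0.12, 0.22), semi_axes=(0.20, 0.13),
                    rotation=0.1, additive_value=-0.35),           # lumen
    ]
    n_lesions = int(rng.integers(2, 5))
    for _ in range(n_lesions):
        r = 0.5 * np.sqrt(rng.uniform())  # stay well inside the body oval
        phi = rng.uniform(0, 2 * np.pi)
        radius = rng.uniform(0.03, 0.06)
        ellipses.append(EllipseSpec(
            center=(0.85 * 0.88 * r * np.cos(phi), 0.85 * 0.68 * r * np.sin(phi)),
            semi_axes=(radius, radius * rng.uniform(0.7, 1.0)),
            rotation=rng.uniform(0, np.pi),
            additive_value=0.35,
        ))
    img = rasterize_ellipses(ellipses, D)
    np.clip(img.values, 0.0, 1.0, out=img.values)
    return img


def add_noise(sino: Sinogram, model: NoiseModel) -> Sinogram:
    """Return a (new) sinogram with the requested noise applied."""
    p = sino.values
    if model.kind == "none" or model.level == 0:
        return Sinogram(values=p.copy(), geometry=sino.geometry)
    rng = np.random.default_rng(model.seed)
    if model.kind == "gaussian":
        sigma = model.level * np.max(np.abs(p)) if p.size else 0.0
        noisy = p + rng.normal(0.0, sigma, size=p.shape)
    else:  # poisson transmission model
        i0 = model.level
        counts = rng.poisson(i0 * np.exp(-p)).astype(float)
        counts = np.maximum(counts, 1.0)
        noisy = np.log(i0 / counts)
    return Sinogram(values=noisy, geometry=sino.geometry)


def gradient_sparsity(image: ImageGrid, tol: float = 1e-12) -> float:
    """Fraction of pixels with nonzero discrete-gradient magnitude."""
    v = image.values
    gx = np.diff(v, axis=1, append=v[:, -1:])
    gy = np.diff(v, axis=0, append=v[-1:, :])
    mag = np.hypot(gx, gy)
    return float(np.count_nonzero(mag > tol)) / v.size
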