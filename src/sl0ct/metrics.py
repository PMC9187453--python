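"""Evaluation indicators and the four-algorithm benchmark harness.

The primary indicator is the STD of a reconstruction: the population
standard deviation of the difference image ``f = a - a0`` between the
reconstruction ``a`` and the reference ``a0``,

    STD = sqrt( sum_{x,y} (f(x,y) - fbar)^2 / D^2 ),   fbar = mean(f).

Lower is better; the mean-centering makes the indicator invariant to a
constant offset between reconstruction and reference.  Wall time is
recorded alongside but never asserted (hardware-dependent).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .baselines import (ARTParams, TVParams, art_reconstruct, fbp_reconstruct,
                        tv_reconstruct, wtv_reconstruct)
from .grid import ImageGrid, ScanGeometry, ShapeError, Sinogram
from .l0art import SL0Params, l0art_reconstruct
from .phantoms import NoiseModel, add_noise
from .projector import ProjectionOperator, build_projection_operator, \
    forward_project

ALGORITHMS = ("fbp", "art", "tv", "wtv", "l0art")

PSNR_CAP_DB = 99.0


@dataclass
class EvalReport:
    """One algorithm's evaluation on one reconstruction run."""

    algo: str
    std_metric: float
    rmse: float
    psnr: float
    wall_time_s: float
    params_digest: str = ""


def _check_pair(a: ImageGrid, a0: ImageGrid) -> tuple[np.ndarray, np.ndarray]:
    if a.values.shape != a0.values.shape:
        raise ShapeError(
            f"image shapes differ: {a.values.shape} vs {a0.values.shape}")
    return a.values, a0.values


def std_metric(a: ImageGrid, a0: ImageGrid) -> float:
    """Population standard deviation of the difference image a - a0."""
    va, v0 = _check_pair(a, a0)
    f = va - v0
    return float(np.sqrt(np.mean((f - f.mean()) ** 2)))


def rmse(a: ImageGrid, a0: ImageGrid) -> float:
    """Root-mean-square error between two images."""
    va, v0 = _check_pair(a, a0)
    return float(np.sqrt(np.mean((va - v0) ** 2)))


def psnr(a: ImageGrid, a0: ImageGrid, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB, capped at 99 dB for exact matches."""
    if peak <= 0:
        raise ValueError("peak must be positive")
    e = rmse(a, a0)
    if e < 1e-12:
        return PSNR_CAP_DB
    return min(float(20.0 * np.log10(peak / e)), PSNR_CAP_DB)


def _params_digest(obj) -> str:
    try:
        payload = json.dumps(asdict(obj), sort_keys=True, default=str)
    except TypeError:
        payload = repr(obj)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def make_reconstructor(algo: str, overrides: Mapping | None = None
                       ) -> tuple[Callable, object]:
    """(function of (A, sinogram) -> ImageGrid, parameter object) for a name."""
    overrides = dict(overrides or {})
    if algo == "fbp":
        filter_name = overrides.pop("filter", "ramlak")
        if overrides:
            raise ValueError(f"unknown fbp options {sorted(overrides)}")

        def run(A: ProjectionOperator, s: Sinogram) -> ImageGrid:
            return fbp_reconstruct(s, A.grid_side, filter=filter_name,
                                   pixel_size=A.pixel_size)
        return run, {"filter": filter_name}
    if algo == "art":
        params = ARTParams(**overrides)
        return (lambda A, s: art_reconstruct(A, s, params)), params
    if algo in ("tv", "wtv"):
        art_overrides = overrides.pop("art", {})
        params = TVParams(art=ARTParams(**art_overrides), **overrides)
        fn = tv_reconstruct if algo == "tv" else wtv_reconstruct
        return (lambda A, s: fn(A, s, params)), params
    if algo == "l0art":
        params = SL0Params(**overrides)
        return (lambda A, s: l0art_reconstruct(A, s, params)[0]), params
    raise ValueError(f"unknown algorithm {algo!r}; expected one of {ALGORITHMS}")


def benchmark(algos: Sequence[str | tuple[str, Mapping]],
              phantom: ImageGrid,
              geometry: ScanGeometry,
              noise: NoiseModel | None = None,
              n_repeats: int = 1,
              seed: int = 0,
              csv_path=None) -> pd.DataFrame:
    """Run each algorithm on identical seeded noisy sinograms.

    For every repeat a fresh noise realization is drawn (noise seeds are
    spawned deterministically from ``seed``) and every algorithm sees
    the *same* noisy sinogram, so the comparison is paired.  Returns a
    tidy per-run DataFrame with columns algo / repeat / std_metric /
    rmse / psnr / wall_time_s / params_digest; optionally also written
    to ``csv_path``.
    """
    if not algos:
        raise ValueError("need at least one algorithm")
    if n_repeats < 1:
        raise ValueError("n_repeats must be positive")
    resolved = []
    for entry in algos:
        name, overrides = entry if isinstance(entry, tuple) else (entry, None)
        run, params = make_reconstructor(name, overrides)
        resolved.append((name, run, _params_digest(params)))

    A = build_projection_operator(geometry, phantom.side_length,
                                  phantom.pixel_size)
    clean = forward_project(A, phantom)
    peak = float(np.max(phantom.values)) or 1.0
    seed_seq = np.random.SeedSequence(seed)
    rows = []
    for repeat, child in enumerate(seed_seq.spawn(n_repeats)):
        if noise is None or noise.kind == "none":
            noisy = clean
        else:
            noise_seed = int(child.generate_state(1)[0] % (2 ** 31))
            noisy = add_noise(clean, NoiseModel(kind=noise.kind,
                                                level=noise.level,
                                                seed=noise_seed))
        for name, run, digest in resolved:
            t0 = time.perf_counter()
            recon = run(A, noisy)
            elapsed = time.perf_counter() - t0
            rows.append(asdict(EvalReport(
                algo=name,
                std_metric=std_metric(recon, phantom),
                rmse=rmse(recon, phantom),
                psnr=psnr(recon, phantom, peak=peak),
                wall_time_s=elapsed,
                params_digest=digest,
            )) | {"repeat": repeat})
    table = pd.DataFrame(rows)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    return table


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Per-algorithm mean/std of the STD metric and wall time."""
    return (table.groupby("algo", sort=False)
            .agg(mean_std=("std_metric", "mean"),
                 sd_std=("std_metric", "std"),
                 mean_rmse=("rmse", "mean"),
                 mean_time_s=("wall_time_s", "mean"),
                 n_runs=("std_metric", "size"))
            .reset_index())
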