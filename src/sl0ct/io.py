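"""File formats and run configuration.

Arrays travel in two interchangeable forms:

* a whitespace-delimited plain-text format with a short ``#``-prefixed
  header (shape, spacing, and — for sinograms — the view angles),
  written with 17 significant digits so the round trip is bit-exact for
  finite doubles;
* 16-bit PNG/TIFF with a JSON sidecar (``<file>.meta.json``) holding
  the value range and spacing needed to undo the integer quantization.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .grid import ImageGrid, ScanGeometry, Sinogram

_MAGIC = "# sl0ct array v1"
_RASTER_SUFFIXES = (".png", ".tif", ".tiff")


class FormatError(ValueError):
    """Malformed array file (bad header, shape mismatch, missing sidecar)."""


# ---------------------------------------------------------------------------
# plain-text array format
# ---------------------------------------------------------------------------

def _write_text(path: Path, values: np.ndarray, header: dict) -> None:
    lines = [_MAGIC]
    lines.append(f"# shape: {values.shape[0]} {values.shape[1]}")
    for key, val in header.items():
        if isinstance(val, np.ndarray):
            val = " ".join(repr(float(v)) for v in val)
        lines.append(f"# {key}: {val}")
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in values)
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def _read_text(path: Path) -> tuple[np.ndarray, dict]:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise FormatError(f"{path}: line 1: missing '{_MAGIC}' header")
    header: dict[str, str] = {}
    body_start = 1
    for idx, line in enumerate(lines[1:], start=2):
        if not line.startswith("#"):
            body_start = idx - 1
            break
        key, _, val = line[1:].partition(":")
        header[key.strip()] = val.strip()
    if "shape" not in header:
        raise FormatError(f"{path}: header is missing a 'shape' line")
    try:
        n_rows, n_cols = (int(t) for t in header["shape"].split())
    except ValueError as exc:
        raise FormatError(f"{path}: malformed shape line: "
                          f"{header['shape']!r}") from exc
    flat = []
    for idx, line in enumerate(lines[body_start:], start=body_start + 1):
        if line.strip():
            try:
                flat.extend(float(t) for t in line.split())
            except ValueError as exc:
                raise FormatError(f"{path}: line {idx}: non-numeric "
                                  "value") from exc
    if len(flat) != n_rows * n_cols:
        raise FormatError(
            f"{path}: header declares {n_rows}x{n_cols} = {n_rows * n_cols} "
            f"values but body holds {len(flat)}")
    return np.array(flat).reshape(n_rows, n_cols), header


# ---------------------------------------------------------------------------
# 16-bit raster with sidecar
# ---------------------------------------------------------------------------

def _write_raster(path: Path, values: np.ndarray, meta: dict) -> None:
    vmin, vmax = float(values.min()), float(values.max())
    scale = vmax - vmin
    if scale > 0:
        quantized = np.round((values - vmin) / scale * 65535).astype(np.uint16)
    else:
        quantized = np.zeros(values.shape, dtype=np.uint16)
    iio.imwrite(path, quantized)
    sidecar = {"vmin": vmin, "vmax": vmax} | meta
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2))


def _read_raster(path: Path) -> tuple[np.ndarray, dict]:
    sidecar_path = Path(str(path) + ".meta.json")
    if not sidecar_path.exists():
        raise FormatError(f"{path}: missing sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    quantized = np.asarray(iio.imread(path), dtype=float)
    vmin, vmax = meta["vmin"], meta["vmax"]
    return vmin + quantized / 65535 * (vmax - vmin), meta


# ---------------------------------------------------------------------------
# public object-level API
# ---------------------------------------------------------------------------

def write_image(path, image: ImageGrid) -> None:
    path = Path(path)
    if path.suffix.lower() in _RASTER_SUFFIXES:
        _write_raster(path, image.values, {"pixel_size": image.pixel_size})
    else:
        _write_text(path, image.values, {"pixel_size": image.pixel_size})


def read_image(path) -> ImageGrid:
    path = Path(path)
    if path.suffix.lower() in _RASTER_SUFFIXES:
        values, meta = _read_raster(path)
    else:
        values, meta = _read_text(path)
    return ImageGrid(values=values,
                     pixel_size=float(meta.get("pixel_size", 1.0)))


def write_sinogram(path, sino: Sinogram) -> None:
    path = Path(path)
    g = sino.geometry
    meta = {"detector_spacing": g.detector_spacing}
    if path.suffix.lower() in _RASTER_SUFFIXES:
        _write_raster(path, sino.values,
                      meta | {"angles": [float(a) for a in g.angles]})
    else:
        _write_text(path, sino.values, meta | {"angles": g.angles})


def read_sinogram(path) -> Sinogram:
    path = Path(path)
    if path.suffix.lower() in _RASTER_SUFFIXES:
        values, meta = _read_raster(path)
        angles = np.array(meta["angles"], dtype=float)
    else:
        values, meta = _read_text(path)
        if "angles" not in meta:
            raise FormatError(f"{path}: sinogram header is missing 'angles'")
        angles = np.array([float(t) for t in meta["angles"].split()])
    geometry = ScanGeometry(
        angles=angles, n_detectors=values.shape[1],
        detector_spacing=float(meta.get("detector_spacing", 1.0)))
    return Sinogram(values=values, geometry=geometry)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

KNOWN_CONFIG_KEYS = frozenset({
    "phantom", "grid_side", "pixel_size", "phantom_seed",
    "n_angles", "n_detectors", "detector_spacing",
    "noise_kind", "noise_level", "noise_seed",
    "algo", "fbp_filter",
    "relaxation", "n_sweeps", "nonneg", "art_init",
    "n_tv_steps", "tv_step", "weighting", "weight_delta", "epsilon_tv",
    "beta0", "gamma", "kappa", "mu_outer", "mu_inner",
    "max_outer", "max_inner", "step_size", "transform", "init",
    "data_projection",
    "n_repeats", "seed", "output_dir",
})

DEFAULT_CONFIG = {
    "phantom": "abdominal",
    "grid_side": 64,
    "pixel_size": 1.0,
    "phantom_seed": 0,
    "n_angles": 30,
    "n_detectors": 95,
    "detector_spacing": 1.0,
    "noise_kind": "gaussian",
    "noise_level": 0.01,
    "algo": "l0art",
    "n_repeats": 5,
    "seed": 0,
}


def load_config(path) -> dict:
    """Load a flat key-value YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a flat key-value mapping")
    unknown = set(raw) - KNOWN_CONFIG_KEYS
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return raw


def dump_config(path, config: dict) -> None:
    """Persist the fully resolved configuration next to run outputs."""
    Path(path).write_text(yaml.safe_dump(dict(config), sort_keys=True))
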