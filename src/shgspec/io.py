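"""Configuration loading and shared TIFF/CSV/JSON readers and writers.

Model configs use micrometres (matching the physics conventions); imaging
and spectral configs use nanometres (matching acquisition metadata).  The
converters live here so each module sticks to one unit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .dispersion import DispersionModel, from_table, water
from .shg_model import DEFAULT_BASELINE_WIDTH, DEFAULT_NA, GridSpec
from .spectral_stack import BAND_START_NM, BAND_WIDTH_NM, SpectralStack

__all__ = [
    "RunConfig", "GridConfig", "ProfileConfig", "OpticsConfig",
    "WavelengthConfig", "DispersionConfig",
    "load_config", "save_config", "build_dispersion",
    "read_image", "write_image", "read_stack", "write_rgb",
    "um_to_nm", "nm_to_um",
]

SUPPORTED_DTYPES = {np.dtype("uint8"), np.dtype("uint16")}


def um_to_nm(x):
    return np.asarray(x, dtype=float) * 1e3 if np.iterable(x) else float(x) * 1e3


def nm_to_um(x):
    return np.asarray(x, dtype=float) / 1e3 if np.iterable(x) else float(x) / 1e3


@dataclass
class GridConfig:
    window_length_um: float = 96.0
    n_samples: int = 8192

    def to_grid(self) -> GridSpec:
        return GridSpec(self.window_length_um, self.n_samples)


@dataclass
class ProfileConfig:
    apodization: str = "hamming"
    diameter_um: float = 0.45
    period_um: float = 0.23
    baseline_amplitude: float = 1.0
    baseline_width_um: float = DEFAULT_BASELINE_WIDTH


@dataclass
class OpticsConfig:
    na: float = DEFAULT_NA
    direction: str = "epi"


@dataclass
class WavelengthConfig:
    min_um: float = 0.76
    max_um: float = 1.0
    step_um: float = 0.02

    def to_array(self) -> np.ndarray:
        n = int(round((self.max_um - self.min_um) / self.step_um)) + 1
        return np.round(self.min_um + self.step_um * np.arange(n), 9)


@dataclass
class DispersionConfig:
    name: str = "daimon-masumura-21.5C"
    temperature_C: float = 21.5
    table_csv: str | None = None  # two columns: wavelength_um, n


@dataclass
class RunConfig:
    """Effective configuration of a model run (fully serializable)."""

    grid: GridConfig = field(default_factory=GridConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    wavelengths: WavelengthConfig = field(default_factory=WavelengthConfig)
    dispersion: DispersionConfig = field(default_factory=DispersionConfig)


def _from_mapping(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} under {path!r}; "
            f"allowed: {sorted(fields)}"
        )
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if isinstance(value, dict):
            sub = {
                "grid": GridConfig, "profile": ProfileConfig,
                "optics": OpticsConfig, "wavelengths": WavelengthConfig,
                "dispersion": DispersionConfig,
            }.get(name)
            if sub is None:
                raise ValueError(f"key {name!r} under {path!r} does not take a mapping")
            kwargs[name] = _from_mapping(sub, value, f"{path}.{name}")
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration; unknown keys are rejected by
    name and missing sections fall back to the documented defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root in {path} must be a mapping")
    return _from_mapping(RunConfig, data, "config")


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))


def build_dispersion(cfg: DispersionConfig) -> DispersionModel:
    if cfg.table_csv is not None:
        table = np.loadtxt(cfg.table_csv, delimiter=",", comments="#")
        return from_table(table[:, 0], table[:, 1], name=cfg.name,
                          temperature_C=cfg.temperature_C)
    if cfg.name != "daimon-masumura-21.5C":
        raise ValueError(
            f"unknown dispersion model {cfg.name!r}; built-in: "
            "'daimon-masumura-21.5C', or supply table_csv"
        )
    return water(cfg.temperature_C)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale TIFF (single- or multi-page) as float."""
    arr = tifffile.imread(path)
    if arr.dtype not in SUPPORTED_DTYPES:
        raise ValueError(
            f"unsupported bit depth {arr.dtype} in {path}; supported: uint8, uint16"
        )
    return arr.astype(float)


def write_image(path: str | Path, data: np.ndarray, bit_depth: int = 16,
                metadata: dict | None = None) -> None:
    """Write intensity data as an 8/16-bit grayscale TIFF (lossless)."""
    if bit_depth == 8:
        dtype = np.uint8
    elif bit_depth == 16:
        dtype = np.uint16
    else:
        raise ValueError(f"unsupported bit depth {bit_depth}; supported: 8, 16")
    arr = np.asarray(data)
    if np.any(arr < 0) or np.any(arr > np.iinfo(dtype).max):
        raise ValueError(f"data out of range for {bit_depth}-bit output")
    tifffile.imwrite(Path(path), arr.astype(dtype), photometric="minisblack",
                     metadata=metadata or {})


def read_stack(path: str | Path, sidecar: str | Path | None = None,
               excitation_nm: float = float("nan")) -> SpectralStack:
    """Read a multi-page TIFF as a spectral stack.

    Band geometry (``start_nm``, ``width_nm``, optionally ``excitation_nm``)
    comes from a YAML sidecar when given, else the detector defaults.
    """
    bands = read_image(path)
    if bands.ndim == 2:
        bands = bands[None]
    start, width = BAND_START_NM, BAND_WIDTH_NM
    if sidecar is not None:
        meta = yaml.safe_load(Path(sidecar).read_text()) or {}
        unknown = set(meta) - {"start_nm", "width_nm", "excitation_nm"}
        if unknown:
            raise ValueError(f"unknown sidecar key(s) {sorted(unknown)}")
        start = float(meta.get("start_nm", start))
        width = float(meta.get("width_nm", width))
        excitation_nm = float(meta.get("excitation_nm", excitation_nm))
    return SpectralStack(bands=bands, excitation_nm=excitation_nm,
                         band_start_nm=start, band_width_nm=width)


def write_rgb(path: str | Path, rgb: np.ndarray) -> None:
    """Write a float [0, 1] RGB composite as 8-bit PNG or TIFF."""
    arr = np.clip(np.asarray(rgb), 0.0, 1.0)
    img = (np.round(arr * 255)).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, img)
    else:
        tifffile.imwrite(path, img, photometric="rgb")


def write_json(path: str | Path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
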