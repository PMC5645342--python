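"""Two-wavelength ratiometric SHG imaging.

Collagen's epi-generated SHG is stronger under 920 nm excitation than under
860 nm, while myosin responds almost equally at the two wavelengths.  A
registered 920/860 nm image pair therefore discriminates the two materials:
in the false-colour composite the 920 nm image drives the red and blue
display channels and the 860 nm image the green channel, so 920-dominant
pixels appear purple, 860-dominant pixels green, and balanced pixels
greyscale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

__all__ = [
    "ShgImage",
    "RegisteredPair",
    "RatioComposite",
    "register_pair",
    "ratio_composite",
    "mean_intensity",
    "normalize_series",
    "calibration_ratio",
]

#: gray-level tolerance defaults for the "no difference" class (8-bit scale)
DEFAULT_TOL_ABS = 2.0
DEFAULT_TOL_REL = 0.1


@dataclass(frozen=True)
class ShgImage:
    """A single-channel SHG intensity image and its acquisition metadata."""

    pixels: np.ndarray = field(repr=False)
    excitation_nm: float = float("nan")
    emission_band_nm: tuple[float, float] | None = None
    bit_depth: int = 16

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if np.any(px < 0) or np.any(px > 2**self.bit_depth - 1):
            raise ValueError(
                f"intensities must lie in [0, {2 ** self.bit_depth - 1}] "
                f"for bit depth {self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class RegisteredPair:
    """A 920/860 nm pair after translation-only alignment.

    ``img_860`` holds the *shifted* (aligned) 860 nm pixels; ``shift`` is the
    (dy, dx) translation applied to reach them and ``overlap_mask`` excludes
    the border rows/columns that wrapped in.
    """

    img_920: ShgImage
    img_860: ShgImage
    shift: tuple[int, int]
    overlap_mask: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class RatioComposite:
    """False-colour overlay plus per-pixel material classification."""

    rgb: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)  # "purple" / "green" / "gray" / ""
    purple_fraction: float
    green_fraction: float
    gray_fraction: float
    scaling: str = "per_channel"


def register_pair(img_920: ShgImage, img_860: ShgImage) -> RegisteredPair:
    """Align the 860 nm image onto the 920 nm image by the cross-correlation
    maximum (whole-pixel translation; acquisitions of the same field differ
    by drift only, so no rotation or warp is fitted)."""
    a, b = img_920.pixels, img_860.pixels
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("registration undefined for an empty or constant image")
    shift, _, _ = phase_cross_correlation(a, b, normalization=None)
    dy, dx = int(round(shift[0])), int(round(shift[1]))
    aligned = np.roll(b, (dy, dx), axis=(0, 1))
    mask = np.ones(a.shape, dtype=bool)
    if dy > 0:
        mask[:dy, :] = False
    elif dy < 0:
        mask[dy:, :] = False
    if dx > 0:
        mask[:, :dx] = False
    elif dx < 0:
        mask[:, dx:] = False
    aligned_img = ShgImage(
        pixels=aligned,
        excitation_nm=img_860.excitation_nm,
        emission_band_nm=img_860.emission_band_nm,
        bit_depth=img_860.bit_depth,
    )
    return RegisteredPair(
        img_920=img_920, img_860=aligned_img, shift=(dy, dx), overlap_mask=mask
    )


def _background_mask(i920, i860, overlap):
    """Pixels dark in both channels: below twice the background level.

    The background level per channel is the median of the darkest half of
    the overlap pixels — a robust location of the empty-background count
    distribution as long as fibres cover less than half the field.  Twice
    that level clears essentially all Poisson background fluctuations.
    """
    out = np.zeros_like(overlap)
    dark = np.ones_like(overlap)
    for img in (i920, i860):
        vals = img[overlap]
        level = np.median(vals[vals <= np.median(vals)])
        thr = max(2.0 * level, 1.0)
        dark &= img < thr
    out[overlap] = dark[overlap]
    return out


def _scale(channel, mask, lo, hi):
    if hi <= lo:
        return np.zeros_like(channel)
    return np.clip((channel - lo) / (hi - lo), 0.0, 1.0)


def ratio_composite(
    pair: RegisteredPair,
    scaling: Literal["per_channel", "shared"] = "per_channel",
    tol_abs: float = DEFAULT_TOL_ABS,
    tol_rel: float = DEFAULT_TOL_REL,
    exclude_background: bool = True,
) -> RatioComposite:
    """Build the false-colour overlay and classify pixels.

    A pixel is *gray* when ``|I920 - I860| <= max(tol_abs,
    tol_rel * (I920 + I860) / 2)`` — an absolute noise floor plus a
    proportional band mimicking visually balanced greyscale — otherwise
    *purple* (920-dominant) or *green* (860-dominant).  Classification uses
    raw registered intensities; ``scaling`` only affects the display
    channels (``per_channel`` min-max stretch, or ``shared`` limits across
    both channels to preserve the quantitative ratio in the display).
    Fractions are reported over the overlap mask with background (dark in
    both channels) excluded; they sum to 1.
    """
    i920 = pair.img_920.pixels
    i860 = pair.img_860.pixels
    overlap = pair.overlap_mask
    diff = i920 - i860
    tol = np.maximum(tol_abs, tol_rel * (i920 + i860) / 2.0)
    labels = np.full(i920.shape, "", dtype="U6")
    labels[overlap & (np.abs(diff) <= tol)] = "gray"
    labels[overlap & (diff > tol)] = "purple"
    labels[overlap & (diff < -tol)] = "green"

    stat_mask = overlap.copy()
    if exclude_background:
        fg = ~_background_mask(i920, i860, overlap)
        if (stat_mask & fg).any():
            stat_mask &= fg
    n = stat_mask.sum()
    fractions = {
        lab: float((labels[stat_mask] == lab).sum()) / n
        for lab in ("purple", "green", "gray")
    }

    if scaling == "shared":
        lo = min(i920[overlap].min(), i860[overlap].min())
        hi = max(i920[overlap].max(), i860[overlap].max())
        s920, s860 = _scale(i920, overlap, lo, hi), _scale(i860, overlap, lo, hi)
    elif scaling == "per_channel":
        s920 = _scale(i920, overlap, i920[overlap].min(), i920[overlap].max())
        s860 = _scale(i860, overlap, i860[overlap].min(), i860[overlap].max())
    else:
        raise ValueError(f"scaling must be 'per_channel' or 'shared', got {scaling!r}")
    rgb = np.stack([s920, s860, s920], axis=-1)
    rgb[~overlap] = 0.0
    return RatioComposite(
        rgb=rgb,
        labels=labels,
        purple_fraction=fractions["purple"],
        green_fraction=fractions["green"],
        gray_fraction=fractions["gray"],
        scaling=scaling,
    )


def mean_intensity(img: ShgImage, mask: np.ndarray | None = None) -> float:
    """Mean intensity over a mask (default: the whole field of view)."""
    if mask is None:
        return float(img.pixels.mean())
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return float(img.pixels[mask].mean())


def normalize_series(means: pd.Series, reference_nm: float = 800.0) -> pd.Series:
    """Express per-wavelength mean intensities as a percentage of the value
    at the reference excitation wavelength (800 nm by convention)."""
    s = pd.Series(means).astype(float)
    if reference_nm not in s.index:
        raise KeyError(f"reference wavelength {reference_nm} nm missing from series")
    ref = s.loc[reference_nm]
    if ref <= 0:
        raise ValueError(f"reference intensity at {reference_nm} nm must be positive")
    return 100.0 * s / ref


def calibration_ratio(measured: pd.Series, reference: pd.Series) -> pd.Series:
    """Pointwise measured/reference after interpolating the reference onto
    the measured wavelengths.

    A ratio near 1 across the band indicates no systematic spectral bias in
    the detection path.  Points where the interpolated reference is zero (or
    outside the reference support) are returned as NaN rather than raising.
    """
    ms = pd.Series(measured).astype(float).sort_index()
    rs = pd.Series(reference).astype(float).sort_index()
    lo = max(ms.index.min(), rs.index.min())
    hi = min(ms.index.max(), rs.index.max())
    if lo > hi:
        raise ValueError("measured and reference series share no wavelength overlap")
    keep = (ms.index >= lo) & (ms.index <= hi)
    wl = ms.index[keep].to_numpy(dtype=float)
    ref_interp = np.interp(wl, rs.index.to_numpy(dtype=float), rs.to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ref_interp > 0, ms[keep].to_numpy() / ref_interp, np.nan)
    return pd.Series(ratio, index=wl, name="calibration_ratio")
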