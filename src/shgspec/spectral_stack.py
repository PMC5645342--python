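"""Multispectral emission-stack analysis: locating SHG against the TPEF tail.

A spectral detector acquires the emission in 32 contiguous pass-bands of
10.8 nm covering 362-704 nm.  SHG is coherent and appears as a narrow line
at exactly half the excitation wavelength; two-photon excited fluorescence
(TPEF) is incoherent and red-shifted from that line.  Splitting the mean
emission spectrum at the SHG band therefore separates the two contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BAND_START_NM",
    "BAND_WIDTH_NM",
    "N_BANDS",
    "SpectralStack",
    "EmissionSpectrum",
    "band_centers",
    "shg_band_index",
    "emission_spectrum",
    "split_shg_tpef",
]

BAND_START_NM = 362.0
BAND_WIDTH_NM = 10.8
N_BANDS = 32


def band_centers(
    start_nm: float = BAND_START_NM,
    width_nm: float = BAND_WIDTH_NM,
    n: int = N_BANDS,
) -> np.ndarray:
    """Centre wavelengths of ``n`` contiguous bands of ``width_nm`` starting
    at the edge ``start_nm``: ``start + width*(i + 1/2)``."""
    if n < 1 or width_nm <= 0:
        raise ValueError("need n >= 1 and width_nm > 0")
    return start_nm + width_nm * (np.arange(n) + 0.5)


@dataclass(frozen=True)
class SpectralStack:
    """A stack of band images plus its band geometry.

    ``bands`` has shape ``(n_bands, height, width)``; band ``i`` covers
    ``[start + i*width, start + (i+1)*width]`` nm.
    """

    bands: np.ndarray = field(repr=False)
    excitation_nm: float
    band_start_nm: float = BAND_START_NM
    band_width_nm: float = BAND_WIDTH_NM

    def __post_init__(self):
        b = np.asarray(self.bands)
        if b.ndim != 3:
            raise ValueError(f"bands must be (n_bands, h, w), got shape {b.shape}")
        object.__setattr__(self, "bands", b)

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    @property
    def centers(self) -> np.ndarray:
        return band_centers(self.band_start_nm, self.band_width_nm, self.n_bands)


@dataclass(frozen=True)
class EmissionSpectrum:
    """Whole-field mean intensity per band."""

    band_centers_nm: np.ndarray
    mean_intensity: np.ndarray
    n_fields: int = 1

    def __post_init__(self):
        c = np.asarray(self.band_centers_nm, dtype=float)
        m = np.asarray(self.mean_intensity, dtype=float)
        if c.shape != m.shape or c.ndim != 1:
            raise ValueError("band_centers_nm and mean_intensity must be matching 1-D")
        if np.any(m < 0):
            raise ValueError("mean intensities must be non-negative")
        object.__setattr__(self, "band_centers_nm", c)
        object.__setattr__(self, "mean_intensity", m)


def shg_band_index(excitation_nm: float, centers: np.ndarray) -> int:
    """Index of the band whose centre is nearest the SHG line at
    ``excitation/2``; ties break toward the shorter wavelength."""
    centers = np.asarray(centers, dtype=float)
    target = excitation_nm / 2.0
    half = np.median(np.diff(centers)) / 2.0 if centers.size > 1 else 0.0
    lo = centers[0] - half
    hi = centers[-1] + half
    if not lo <= target <= hi:
        raise ValueError(
            f"SHG line at {target:.1f} nm falls outside the band span "
            f"[{lo:.1f}, {hi:.1f}] nm"
        )
    dist = np.abs(centers - target)
    # argmin returns the first minimum, i.e. the shorter-wavelength band on a tie
    return int(np.argmin(dist))


def emission_spectrum(stack: SpectralStack, n_fields: int = 1) -> EmissionSpectrum:
    """Mean emission spectrum: whole-field average of each band image."""
    if stack.bands.size == 0 or stack.bands.shape[1] * stack.bands.shape[2] == 0:
        raise ValueError("stack contains an empty band image")
    means = stack.bands.reshape(stack.n_bands, -1).mean(axis=1)
    return EmissionSpectrum(
        band_centers_nm=stack.centers, mean_intensity=means, n_fields=n_fields
    )


def split_shg_tpef(
    spectrum: EmissionSpectrum, excitation_nm: float
) -> tuple[float, float]:
    """Partition the spectrum into SHG and TPEF signal.

    The SHG window is the band nearest ``excitation/2`` plus one neighbour on
    each side (a ~10 nm line near a band edge straddles two 10.8 nm bins).
    TPEF is summed over bands whose centres lie more than one band width
    beyond the window's upper edge, guarding against line spill-over.
    """
    centers = spectrum.band_centers_nm
    idx = shg_band_index(excitation_nm, centers)
    lo = max(idx - 1, 0)
    hi = min(idx + 1, centers.size - 1)
    shg = float(spectrum.mean_intensity[lo : hi + 1].sum())
    width = float(np.median(np.diff(centers))) if centers.size > 1 else 0.0
    tpef_mask = centers > centers[hi] + 1.5 * width  # window edge + one width
    tpef = float(spectrum.mean_intensity[tpef_mask].sum())
    return shg, tpef
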