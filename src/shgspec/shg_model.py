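"""One-dimensional non-linear structure-factor model of SHG excitation efficiency.

The axial second-order susceptibility profile ``chi2(z)`` of a fibre —
an oscillation in harmonophore polarity apodized by the fibre envelope —
determines the far-field SHG yield through the Gouy-apodized 1-D structure
factor

    G(dk) = integral chi2(z) * exp(i*dk*z) / (1 + i*zeta(z)) dz,
    zeta(z) = pi * NA**2 * z / (n * lambda),

evaluated at the momentum mismatch ``dk(lambda)`` of the chosen detection
geometry.  The detected intensity follows ``S2(lambda) ∝ |G(dk(lambda))|**2
/ lambda**4``; all intensities here are in arbitrary units and only ratios
and normalized spectra are meaningful.

Because the forward mismatch is tiny (|dk| < 0.3 um^-1) while the epi
mismatch is large (~33-44 um^-1 over a 0.76-1.0 um scan), a wavelength scan
samples G near the origin in the forward geometry but sweeps across the
quasi-phase-matching peak of the polarity oscillation in the epi geometry —
which is why small changes in fibre diameter reshape the epi wavelength
dependence while leaving the forward dependence an almost pure 1/lambda**4
fall.

The transform is computed on a long zero-padded grid (96 um window, 8192
samples by default) so that the momentum-space sampling interval
(2*pi/window ≈ 0.065 um^-1) resolves the narrow forward band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .dispersion import Direction, DispersionModel, delta_k, refractive_index

__all__ = [
    "GridSpec",
    "Chi2Profile",
    "StructureFactor",
    "ExcitationSpectrum",
    "build_profile",
    "gouy_weight",
    "structure_factor",
    "sample_structure_factor",
    "excitation_spectrum",
    "wavelength_ratio",
    "normalize_to_reference",
    "fit_diameter",
    "DEFAULT_NA",
    "DEFAULT_BASELINE_WIDTH",
]

Apodization = Literal["hamming", "tophat"]

#: Numerical aperture of the imaging objective (oil immersion, 40x).
DEFAULT_NA = 1.3

#: Full width (um) of the added phase-matching baseline window.  A single
#: fixed width, shared by all fibre profiles, reproduces the published model
#: ratios for both the 0.45 um and 0.5 um reference fibres simultaneously;
#: see docs/methods.md for the calibration.
DEFAULT_BASELINE_WIDTH = 0.35


@dataclass(frozen=True)
class GridSpec:
    """Uniform axial grid: ``n_samples`` points across ``window_length`` um.

    The profile occupies the centre of the window; the rest is zero padding
    that refines the momentum-space sampling.
    """

    window_length: float = 96.0
    n_samples: int = 8192

    def __post_init__(self):
        if self.window_length <= 0 or self.n_samples < 2:
            raise ValueError("window_length must be > 0 and n_samples >= 2")

    @property
    def dz(self) -> float:
        """Spatial sample spacing, um."""
        return self.window_length / self.n_samples

    @property
    def sampling_rate(self) -> float:
        """Spatial sampling rate, samples per um (85.33 for the default grid)."""
        return self.n_samples / self.window_length

    @property
    def delta_k_interval(self) -> float:
        """Momentum-space sampling interval 2*pi/window, um^-1 (~0.065 default)."""
        return 2.0 * math.pi / self.window_length

    @property
    def delta_k_max(self) -> float:
        """Maximum unaliased |dk| = pi * sampling rate, um^-1 (~268 default)."""
        return math.pi * self.sampling_rate

    @property
    def z(self) -> np.ndarray:
        """Sample positions, centred so that z = 0 falls on sample n/2."""
        return (np.arange(self.n_samples) - self.n_samples // 2) * self.dz


def _hamming(z: np.ndarray, width: float) -> np.ndarray:
    """Hamming window of full support ``width`` centred at z = 0, zero outside."""
    inside = np.abs(z) <= width / 2.0
    out = np.zeros_like(z)
    out[inside] = 0.54 + 0.46 * np.cos(2.0 * np.pi * z[inside] / width)
    return out


def _tophat(z: np.ndarray, width: float) -> np.ndarray:
    return (np.abs(z) <= width / 2.0).astype(float)


_WINDOWS = {"hamming": _hamming, "tophat": _tophat}


@dataclass(frozen=True)
class Chi2Profile:
    """Sampled axial susceptibility distribution chi2(z) on a uniform grid."""

    grid: GridSpec
    values: np.ndarray = field(repr=False)
    apodization: str = "custom"
    diameter: float = float("nan")
    period: float = float("nan")
    baseline_amplitude: float = float("nan")
    baseline_width: float = float("nan")

    def scaled(self, factor: float) -> "Chi2Profile":
        return replace(self, values=self.values * factor)


def build_profile(
    apodization: Apodization,
    diameter: float,
    period: float,
    baseline_amplitude: float = 1.0,
    grid: GridSpec | None = None,
    baseline_width: float | None = None,
) -> Chi2Profile:
    """Fibre profile: polarity oscillation under an envelope, plus a baseline bump.

    ``chi2(z) = cos(2*pi*z/period) * W(z; diameter) + baseline_amplitude * H(z)``
    where ``W`` is the chosen apodization window (``hamming`` or ``tophat``)
    of full width ``diameter`` and ``H`` is a Hamming window of full width
    ``baseline_width`` (default :data:`DEFAULT_BASELINE_WIDTH`).  The
    baseline supplies the phase-matching peak at the momentum-space origin.

    Parameters are in micrometres.  The oscillation ``period`` must exceed
    two spatial samples or the polarity modulation would alias.
    """
    grid = grid or GridSpec()
    if not 0 < diameter < grid.window_length:
        raise ValueError(
            f"diameter must lie in (0, window_length={grid.window_length}), got {diameter}"
        )
    if period <= 2.0 * grid.dz:
        raise ValueError(
            f"period {period} um is at or below two spatial samples "
            f"({2 * grid.dz:.4f} um) and would alias"
        )
    try:
        window = _WINDOWS[apodization]
    except KeyError:
        raise ValueError(
            f"apodization must be one of {sorted(_WINDOWS)}, got {apodization!r}"
        ) from None
    if baseline_width is None:
        baseline_width = DEFAULT_BASELINE_WIDTH
    z = grid.z
    values = np.cos(2.0 * np.pi * z / period) * window(z, diameter)
    if baseline_amplitude != 0.0:
        values = values + baseline_amplitude * _hamming(z, baseline_width)
    return Chi2Profile(
        grid=grid,
        values=values,
        apodization=apodization,
        diameter=diameter,
        period=period,
        baseline_amplitude=baseline_amplitude,
        baseline_width=baseline_width,
    )


def gouy_weight(z, wavelength: float, na: float, n: float):
    """Axial Gouy apodization ``1 / (1 + i*zeta)`` of a focused Gaussian beam.

    ``zeta = pi * NA**2 * z / (n * lambda)`` is the dimensionless defocus of
    the fundamental beam; at ``NA = 0`` (plane wave) the weight is unity.
    """
    if na < 0 or n <= 0 or wavelength <= 0:
        raise ValueError("require NA >= 0, n > 0, wavelength > 0")
    zeta = np.pi * na**2 * np.asarray(z, dtype=float) / (n * wavelength)
    return 1.0 / (1.0 + 1j * zeta)


@dataclass(frozen=True)
class StructureFactor:
    """Complex G sampled on the momentum grid conjugate to the spatial window."""

    delta_k_grid: np.ndarray = field(repr=False)
    G: np.ndarray = field(repr=False)
    wavelength: float = float("nan")
    na: float = 0.0
    grid: GridSpec = field(default_factory=GridSpec)


def structure_factor(
    profile: Chi2Profile,
    wavelength: float,
    na: float = DEFAULT_NA,
    dispersion: DispersionModel | None = None,
    n_medium: float | None = None,
) -> StructureFactor:
    """Discrete transform ``G(dk) = sum chi2(z) exp(i*dk*z)/(1+i*zeta) dz``.

    The Gouy factor uses the fundamental index ``n(lambda)`` from
    ``dispersion`` (or an explicit ``n_medium``; with ``na = 0`` neither is
    needed).  Momentum samples are spaced ``2*pi/window_length`` apart and
    run over ``[-dk_max, dk_max)``.
    """
    grid = profile.grid
    if n_medium is None:
        if na == 0.0:
            n_medium = 1.0  # weight is identically 1, index irrelevant
        elif dispersion is None:
            raise ValueError("need a dispersion model or n_medium when NA > 0")
        else:
            n_medium = refractive_index(dispersion, wavelength)
    f = profile.values * gouy_weight(grid.z, wavelength, na, n_medium)
    # z_j = (j - n//2) dz, so centre the array before the transform; the
    # +i*dk*z kernel is numpy's inverse-transform sign convention.
    spec = np.fft.ifft(np.fft.ifftshift(f)) * grid.n_samples * grid.dz
    dk = 2.0 * np.pi * np.fft.fftshift(np.fft.fftfreq(grid.n_samples, d=grid.dz))
    return StructureFactor(
        delta_k_grid=dk,
        G=np.fft.fftshift(spec),
        wavelength=wavelength,
        na=na,
        grid=grid,
    )


def sample_structure_factor(sf: StructureFactor, dk) -> complex | np.ndarray:
    """Interpolate G at arbitrary momentum values (cubic spline on Re and Im).

    Momentum values on grid nodes reproduce the node values; |dk| beyond the
    unaliased maximum raises.
    """
    dk_arr = np.asarray(dk, dtype=float)
    kmax = sf.grid.delta_k_max
    if np.any(np.abs(dk_arr) > kmax):
        raise ValueError(f"|delta_k| exceeds the unaliased maximum {kmax:.1f} 1/um")
    re = CubicSpline(sf.delta_k_grid, sf.G.real)(dk_arr)
    im = CubicSpline(sf.delta_k_grid, sf.G.imag)(dk_arr)
    out = re + 1j * im
    return complex(out) if np.isscalar(dk) else out


def _s2_at(sf: StructureFactor, dk: float) -> float:
    """|G|^2 interpolated cubically in dk (the quantity the spectra need)."""
    kmax = sf.grid.delta_k_max
    if abs(dk) > kmax:
        raise ValueError(f"|delta_k| exceeds the unaliased maximum {kmax:.1f} 1/um")
    g2 = np.abs(sf.G) ** 2
    return float(CubicSpline(sf.delta_k_grid, g2)(dk))


@dataclass(frozen=True)
class ExcitationSpectrum:
    """SHG yield S2 (arbitrary units) versus excitation wavelength."""

    wavelengths: np.ndarray
    S2: np.ndarray
    direction: str
    na: float
    profile: Chi2Profile | None = None
    units: str = "arb"

    def __post_init__(self):
        if np.any(~np.isfinite(self.S2)) or np.any(self.S2 < 0):
            raise ValueError("S2 must be finite and non-negative")


def excitation_spectrum(
    profile: Chi2Profile,
    wavelengths: Sequence[float],
    direction: Direction,
    na: float = DEFAULT_NA,
    dispersion: DispersionModel | None = None,
) -> ExcitationSpectrum:
    """Evaluate ``S2(lambda) = |G(dk(lambda))|**2 / lambda**4`` per wavelength.

    G is recomputed at every wavelength because the Gouy weight depends on
    ``lambda`` (a no-op when NA = 0, where one transform would serve all).
    """
    if dispersion is None:
        from .dispersion import water

        dispersion = water()
    wl = np.asarray(wavelengths, dtype=float)
    s2 = np.empty_like(wl)
    for i, w in enumerate(wl):
        sf = structure_factor(profile, w, na=na, dispersion=dispersion)
        dk = delta_k(dispersion, w, direction)
        s2[i] = _s2_at(sf, dk) / w**4
    return ExcitationSpectrum(
        wavelengths=wl, S2=s2, direction=direction, na=na, profile=profile
    )


def _s2_of_wavelength(spectrum: ExcitationSpectrum, wavelength: float) -> float:
    wl, s2 = spectrum.wavelengths, spectrum.S2
    exact = np.isclose(wl, wavelength, rtol=0, atol=1e-12)
    if exact.any():
        return float(s2[exact.argmax()])
    if not wl.min() <= wavelength <= wl.max():
        raise ValueError(
            f"wavelength {wavelength} um outside the evaluated range "
            f"[{wl.min()}, {wl.max()}] um"
        )
    return float(CubicSpline(wl, s2)(wavelength))


def wavelength_ratio(
    spectrum: ExcitationSpectrum, wavelength_num: float, wavelength_den: float
) -> float:
    """Intensity ratio ``S2(l_num) / S2(l_den)``, e.g. the 920/860 nm contrast."""
    num = _s2_of_wavelength(spectrum, wavelength_num)
    den = _s2_of_wavelength(spectrum, wavelength_den)
    if den == 0.0:
        raise ZeroDivisionError(
            f"S2({wavelength_den} um) is zero; the ratio is undefined"
        )
    return num / den


def fit_diameter(
    target: ExcitationSpectrum,
    diameters: Sequence[float],
    apodization: Apodization,
    period: float = 0.23,
    baseline_amplitude: float = 1.0,
    baseline_width: float | None = None,
    grid: GridSpec | None = None,
    dispersion: DispersionModel | None = None,
) -> float:
    """Recover a fibre diameter from an excitation spectrum by grid search.

    Candidate spectra are computed at the target's wavelengths, direction
    and NA; because intensities are in arbitrary units, each candidate is
    scaled by the least-squares amplitude before comparison.  Returns the
    candidate diameter minimizing the squared error.
    """
    best, best_err = None, np.inf
    y = target.S2
    for d in diameters:
        profile = build_profile(
            apodization, d, period, baseline_amplitude, grid=grid,
            baseline_width=baseline_width,
        )
        cand = excitation_spectrum(
            profile, target.wavelengths, target.direction, na=target.na,
            dispersion=dispersion,
        ).S2
        denom = float(cand @ cand)
        scale = float(cand @ y) / denom if denom > 0 else 0.0
        err = float(np.sum((y - scale * cand) ** 2))
        if err < best_err:
            best, best_err = float(d), err
    return best


def normalize_to_reference(
    spectrum: ExcitationSpectrum, wavelength_ref: float
) -> ExcitationSpectrum:
    """Express the spectrum as a percentage of its value at a reference
    wavelength (the field's convention uses 800 nm)."""
    ref = _s2_of_wavelength(spectrum, wavelength_ref)
    if ref == 0.0:
        raise ZeroDivisionError(f"S2({wavelength_ref} um) is zero; cannot normalize")
    return replace(spectrum, S2=100.0 * spectrum.S2 / ref, units="percent_of_reference")
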