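"""Synthetic fixtures: fibre image pairs, emission stacks, and profile ensembles.

Every analysis stage in the package can be exercised without microscope
data.  The generators target the *statistical* structure of the real
acquisitions — material-specific 920/860 intensity ratios, a narrow SHG
emission line at half the excitation wavelength with an optional broad
red-shifted TPEF tail, and photon-count (Poisson) noise with a constant
read background — not anatomical realism.  Fibres are rendered as random
line strokes with a Gaussian cross-profile.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .ratiometric import ShgImage
from .shg_model import Chi2Profile, GridSpec, build_profile
from .spectral_stack import BAND_START_NM, BAND_WIDTH_NM, N_BANDS, SpectralStack

__all__ = [
    "SceneConfig",
    "StackConfig",
    "MATERIAL_RATIOS",
    "render_fibre_scene",
    "make_image_pair",
    "make_spectral_stack",
    "make_profile_ensemble",
    "EnsembleMember",
]

#: Default 920/860 intensity ratios per material class, matching the model's
#: predictions for 0.5 um (collagen-like) and 0.45 um (myosin-like) fibres.
MATERIAL_RATIOS = {"collagen_like": 1.73, "myosin_like": 1.03}


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, material and noise settings for one synthetic field of view."""

    image_shape: tuple[int, int] = (128, 128)
    n_fibres: int = 15
    fibre_width: float = 6.0  # cross-profile FWHM, pixels
    profile_exponent: float = 6.0  # supergaussian order: flat-topped bundles
    material: str = "collagen_like"
    ratio_920_860: float | None = None  # default: MATERIAL_RATIOS[material]
    photon_scale: float = 2000.0  # expected photons on a fully bright fibre
    background: float = 10.0  # constant read background, counts
    seed: int = 0
    shift: tuple[int, int] = (0, 0)  # drift applied to the 860 nm acquisition
    noise: bool = True  # False returns the expected intensities

    def __post_init__(self):
        if self.material not in MATERIAL_RATIOS:
            raise ValueError(
                f"material must be one of {sorted(MATERIAL_RATIOS)}, got {self.material!r}"
            )
        if self.ratio_920_860 is None:
            object.__setattr__(self, "ratio_920_860", MATERIAL_RATIOS[self.material])
        if self.ratio_920_860 <= 0:
            raise ValueError("ratio_920_860 must be positive")
        h, w = self.image_shape
        if h < 8 or w < 8:
            raise ValueError(f"image_shape too small: {self.image_shape}")


@dataclass(frozen=True)
class StackConfig:
    """Spectral content of a synthetic 32-band emission stack.

    Line widths are Gaussian sigmas in nm.  If ``tpef_excitation_cutoff_nm``
    is set, the TPEF amplitude is scaled by a ramp that vanishes for
    excitation wavelengths at or beyond the cutoff, emulating a fluorophore
    whose two-photon excitation band ends there.
    """

    excitation_nm: float = 840.0
    shg_amplitude: float = 1.0
    tpef_amplitude: float = 0.0
    tpef_peak_nm: float = 500.0
    tpef_width_nm: float = 60.0
    shg_linewidth_nm: float = 5.0
    noise_seed: int = 0
    tpef_excitation_cutoff_nm: float | None = None

    def __post_init__(self):
        if min(self.shg_amplitude, self.tpef_amplitude) < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def effective_tpef_amplitude(self) -> float:
        if self.tpef_excitation_cutoff_nm is None:
            return self.tpef_amplitude
        ramp = (self.tpef_excitation_cutoff_nm - self.excitation_nm) / 100.0
        return self.tpef_amplitude * float(np.clip(ramp, 0.0, 1.0))


def render_fibre_scene(config: SceneConfig) -> np.ndarray:
    """Unit-amplitude fibre field: random line strokes with a flat-topped
    (supergaussian) cross-profile, emulating bright, densely packed fibre
    bundles.  Returns an array in [0, 1] (overlaps saturate at 1).
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    half_width = config.fibre_width / 2.0
    p = config.profile_exponent
    scene = np.zeros((h, w))
    for _ in range(config.n_fibres):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        theta = rng.uniform(0, np.pi)
        half = rng.uniform(0.3, 0.7) * max(h, w)
        uy, ux = np.sin(theta), np.cos(theta)
        # distance from each pixel to the stroke segment
        py, px = yy - cy, xx - cx
        t = np.clip(py * uy + px * ux, -half, half)
        d2 = (py - t * uy) ** 2 + (px - t * ux) ** 2
        # exp(-ln2 * (d/halfwidth)^p): value 1/2 at d = halfwidth (FWHM)
        scene += np.exp(-np.log(2.0) * (d2 / half_width**2) ** (p / 2.0))
    return np.clip(scene, 0.0, 1.0)


def make_image_pair(
    config: SceneConfig,
) -> tuple[ShgImage, ShgImage, dict]:
    """Synthetic 920/860 nm acquisition pair plus ground truth.

    Expected intensities are ``E860 = background + photon_scale * scene`` and
    ``E920 = ratio * E860`` pixel-for-pixel, so the mean ratio over any mask
    equals the configured material ratio exactly before noise.  Pixel values
    are independent Poisson draws (or the expectations when ``noise=False``);
    the 860 nm expectation is cyclically shifted by ``config.shift`` before
    the draw to exercise registration.

    The truth dict records the fibre mask, applied shift and true ratio.
    """
    scene = render_fibre_scene(config)
    e860 = config.background + config.photon_scale * scene
    e920 = config.ratio_920_860 * e860
    dy, dx = config.shift
    e860_drifted = np.roll(e860, (-dy, -dx), axis=(0, 1))
    if config.noise:
        rng = np.random.default_rng(config.seed + 1)
        img920 = rng.poisson(e920).astype(float)
        img860 = rng.poisson(e860_drifted).astype(float)
    else:
        img920, img860 = e920, e860_drifted
    truth = {
        "fibre_mask": scene > 0.05,
        "ratio_920_860": config.ratio_920_860,
        "shift": (dy, dx),
        "material": config.material,
        "expected_860": e860,
        "expected_920": e920,
    }
    meta = dict(bit_depth=16)
    return (
        ShgImage(pixels=img920, excitation_nm=920.0,
                 emission_band_nm=(445.0, 475.0), **meta),
        ShgImage(pixels=img860, excitation_nm=860.0,
                 emission_band_nm=(410.0, 430.0), **meta),
        truth,
    )


def _band_integrals(center: float, sigma: float) -> np.ndarray:
    """Fraction of a Gaussian emission line landing in each detector band."""
    edges = BAND_START_NM + BAND_WIDTH_NM * np.arange(N_BANDS + 1)
    cdf = norm.cdf(edges, loc=center, scale=sigma)
    return np.diff(cdf)


def make_spectral_stack(scene_cfg: SceneConfig, stack_cfg: StackConfig) -> SpectralStack:
    """Synthetic 32-band emission stack over a fibre field.

    Per-band expected intensity is the fibre scene scaled by the band's share
    of a narrow SHG line at ``excitation/2`` plus a broad TPEF line, with the
    scene's photon scale and background, then Poisson noise.
    """
    half = stack_cfg.excitation_nm / 2.0
    span = (BAND_START_NM, BAND_START_NM + BAND_WIDTH_NM * N_BANDS)
    if not span[0] <= half <= span[1]:
        raise ValueError(
            f"SHG line at {half:.1f} nm outside the detector span {span} nm"
        )
    scene = render_fibre_scene(scene_cfg)
    weights = stack_cfg.shg_amplitude * _band_integrals(half, stack_cfg.shg_linewidth_nm)
    weights = weights + stack_cfg.effective_tpef_amplitude * _band_integrals(
        stack_cfg.tpef_peak_nm, stack_cfg.tpef_width_nm
    )
    expected = (
        scene_cfg.background
        + scene_cfg.photon_scale * weights[:, None, None] * scene[None, :, :]
    )
    if scene_cfg.noise:
        rng = np.random.default_rng(stack_cfg.noise_seed)
        bands = rng.poisson(expected).astype(float)
    else:
        bands = expected
    return SpectralStack(bands=bands, excitation_nm=stack_cfg.excitation_nm)


@dataclass(frozen=True)
class EnsembleMember:
    """One jittered fibre profile with its generating parameters."""

    profile: Chi2Profile
    nominal_diameter: float
    actual_diameter: float


def make_profile_ensemble(
    diameters: Sequence[float],
    jitter_sd: float,
    n_per_diameter: int,
    seed: int = 0,
    apodization: str = "hamming",
    period: float = 0.23,
    grid: GridSpec | None = None,
    max_retries: int = 100,
) -> list[EnsembleMember]:
    """Fibre-profile ensemble with zero-mean Gaussian diameter jitter.

    Jitter draws producing a non-positive (or window-filling) diameter are
    resampled, up to ``max_retries`` per member.
    """
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)
    members: list[EnsembleMember] = []
    for nominal in diameters:
        for _ in range(n_per_diameter):
            for _attempt in range(max_retries):
                d = nominal + rng.normal(0.0, jitter_sd) if jitter_sd > 0 else nominal
                if 0.0 < d < grid.window_length:
                    break
            else:
                raise RuntimeError(
                    f"could not draw a valid diameter around {nominal} um "
                    f"after {max_retries} tries"
                )
            profile = build_profile(apodization, d, period, grid=grid)
            members.append(
                EnsembleMember(profile=profile, nominal_diameter=float(nominal),
                               actual_diameter=float(d))
            )
    return members
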