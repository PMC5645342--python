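"""Refractive-index dispersion of the embedding medium and momentum-shift mapping.

Second-harmonic generation transfers momentum ``delta_k = 2 k1 - k2`` between
two fundamental photons (wavevector ``k1`` at wavelength ``lambda``) and one
harmonic photon (``k2`` at ``lambda/2``).  In a dispersive medium of index
``n(lambda)`` the magnitude of the mismatch along the optic axis is

* forward detection:  ``|delta_k| = 4*pi*(n(lambda/2) - n(lambda)) / lambda``
* epi detection:      ``|delta_k| = 4*pi*(n(lambda/2) + n(lambda)) / lambda``

so a wavelength scan translates the detection point through momentum space —
slowly in the forward direction (difference of indices) and rapidly in the
epi direction (sum of indices).

All wavelengths are vacuum wavelengths in micrometres; momentum shifts are in
inverse micrometres (angular, i.e. ``2*pi/period``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "DispersionModel",
    "Direction",
    "water",
    "constant_index",
    "from_table",
    "refractive_index",
    "delta_k",
    "delta_k_span",
]

Direction = Literal["forward", "epi"]


@dataclass(frozen=True)
class DispersionModel:
    """A named empirical refractive-index model ``n(lambda)``.

    Parameters
    ----------
    name
        Identifier of the dataset or formula.
    temperature_C
        Temperature the formula is valid for, degrees Celsius.
    valid_range
        ``(lambda_min, lambda_max)`` in micrometres.
    n_of_wavelength
        Vectorised callable evaluating the index at vacuum wavelength(s) in
        micrometres.  Range checking is done by :func:`refractive_index`,
        not by the callable.
    """

    name: str
    temperature_C: float
    valid_range: tuple[float, float]
    n_of_wavelength: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def __call__(self, wavelength_um):
        return refractive_index(self, wavelength_um)


def _sellmeier_water(wavelength_um: np.ndarray) -> np.ndarray:
    # Four-term Sellmeier fit for pure water at 21.5 C
    # (Daimon & Masumura, Appl. Opt. 46, 3811 (2007)).
    w2 = np.asarray(wavelength_um, dtype=float) ** 2
    n2 = (
        1.0
        + 5.684027565e-1 * w2 / (w2 - 5.101829712e-3)
        + 1.726177391e-1 * w2 / (w2 - 1.821153936e-2)
        + 2.086189578e-2 * w2 / (w2 - 2.620722293e-2)
        + 1.130748688e-1 * w2 / (w2 - 1.069792721e1)
    )
    return np.sqrt(n2)


def water(temperature_C: float = 21.5) -> DispersionModel:
    """Default dispersion model: pure water, Sellmeier fit, 0.18-1.13 um.

    Only the 21.5 C fit is shipped; other temperatures raise.
    """
    if abs(temperature_C - 21.5) > 1e-9:
        raise ValueError(
            "only the 21.5 C water fit is built in; supply a table via "
            "from_table() for other temperatures"
        )
    return DispersionModel(
        name="daimon-masumura-21.5C",
        temperature_C=21.5,
        valid_range=(0.18, 1.13),
        n_of_wavelength=_sellmeier_water,
    )


def constant_index(n: float, name: str = "constant") -> DispersionModel:
    """Dispersionless medium of fixed index ``n`` (useful for limit checks:
    the forward mismatch collapses to zero, the epi mismatch to ``8*pi*n/lambda``)."""
    if n <= 0:
        raise ValueError(f"index must be positive, got {n}")
    return DispersionModel(
        name=name,
        temperature_C=float("nan"),
        valid_range=(0.0, float("inf")),
        n_of_wavelength=lambda w: np.full_like(np.asarray(w, dtype=float), n),
    )


def from_table(
    wavelengths_um: Sequence[float],
    n_values: Sequence[float],
    name: str = "table",
    temperature_C: float = float("nan"),
) -> DispersionModel:
    """Dispersion model from tabulated (wavelength_um, n) pairs.

    Cubic interpolation inside the tabulated range; the valid range is the
    table's span.  Rows need not be sorted.
    """
    from scipy.interpolate import CubicSpline

    w = np.asarray(wavelengths_um, dtype=float)
    n = np.asarray(n_values, dtype=float)
    if w.ndim != 1 or w.size < 2 or w.shape != n.shape:
        raise ValueError("need two matching 1-D columns of at least 2 rows")
    order = np.argsort(w)
    spline = CubicSpline(w[order], n[order])
    return DispersionModel(
        name=name,
        temperature_C=temperature_C,
        valid_range=(float(w.min()), float(w.max())),
        n_of_wavelength=lambda x: spline(np.asarray(x, dtype=float)),
    )


def refractive_index(model: DispersionModel, wavelength_um):
    """Evaluate ``n(lambda)``; raises ``ValueError`` outside the model's range."""
    w = np.asarray(wavelength_um, dtype=float)
    lo, hi = model.valid_range
    if np.any(w < lo) or np.any(w > hi):
        raise ValueError(
            f"wavelength {wavelength_um} um outside the valid range "
            f"[{lo}, {hi}] um of dispersion model {model.name!r}"
        )
    n = model.n_of_wavelength(w)
    return float(n) if np.isscalar(wavelength_um) else n


def _check_direction(direction: str) -> None:
    if direction not in ("forward", "epi"):
        raise ValueError(f"direction must be 'forward' or 'epi', got {direction!r}")


def delta_k(model: DispersionModel, wavelength_um, direction: Direction):
    """Momentum-shift magnitude ``|delta_k|`` in 1/um for the given geometry.

    Requires both ``lambda`` and the harmonic ``lambda/2`` to lie inside the
    model's valid range.
    """
    _check_direction(direction)
    w = np.asarray(wavelength_um, dtype=float)
    n_fund = refractive_index(model, w)
    n_harm = refractive_index(model, w / 2.0)
    if direction == "forward":
        out = 4.0 * np.pi * (n_harm - n_fund) / w
    else:
        out = 4.0 * np.pi * (n_harm + n_fund) / w
    return float(out) if np.isscalar(wavelength_um) else out


def delta_k_span(
    model: DispersionModel,
    wavelength_min_um: float,
    wavelength_max_um: float,
    direction: Direction,
) -> float:
    """Width ``|delta_k(l_min) - delta_k(l_max)|`` of the momentum-space range
    swept by a wavelength scan (``delta_k`` varies monotonically in-band)."""
    if wavelength_min_um > wavelength_max_um:
        raise ValueError("wavelength_min_um must not exceed wavelength_max_um")
    k_lo = delta_k(model, wavelength_min_um, direction)
    k_hi = delta_k(model, wavelength_max_um, direction)
    return abs(k_lo - k_hi)
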