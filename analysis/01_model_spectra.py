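#!/usr/bin/env python
"""Model the wavelength dependence of forward- and epi-generated SHG.

Builds the two reference fibre structures (0.45 um Hamming, 0.5 um top-hat;
0.23 um polarity period), maps the 0.76-1.0 um excitation band into momentum
space through the water dispersion relation, and evaluates the excitation
spectra S2(lambda) in both detection geometries.  Writes per-wavelength
spectra and the 920/860 nm ratio table under results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from shgspec.dispersion import delta_k, delta_k_span, water
from shgspec.shg_model import (
    build_profile,
    excitation_spectrum,
    normalize_to_reference,
    wavelength_ratio,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
BAND_UM = np.round(np.arange(0.76, 1.0001, 0.02), 4)
PROFILES = {"hamming_0.45um": ("hamming", 0.45), "tophat_0.50um": ("tophat", 0.50)}


def main():
    RESULTS.mkdir(exist_ok=True)
    dispersion = water()
    print("Momentum-space mapping (water dispersion):")
    print(f"  epi dk(0.76 um)      = {delta_k(dispersion, 0.76, 'epi'):6.2f} 1/um "
          "(the quasi-phase-matching peak)")
    for direction in ("forward", "epi"):
        span = delta_k_span(dispersion, 0.76, 1.0, direction)
        print(f"  {direction:7s} span 0.76-1.0 um = {span:6.3f} 1/um")
    print("  -> a wavelength scan barely moves through momentum space forward,"
          " but sweeps ~11 1/um in epi detection.\n")

    rows, ratios = [], []
    for name, (apod, diam) in PROFILES.items():
        profile = build_profile(apod, diam, 0.23)
        for direction in ("forward", "epi"):
            spec = excitation_spectrum(profile, BAND_UM, direction,
                                       dispersion=dispersion)
            pct = normalize_to_reference(spec, 0.8)
            for wl, s2, p in zip(BAND_UM, spec.S2, pct.S2):
                rows.append({
                    "profile": name, "direction": direction,
                    "wavelength_um": wl,
                    "delta_k_um_inv": delta_k(dispersion, wl, direction),
                    "S2_arb": s2, "S2_percent_of_800nm": p,
                })
            r = wavelength_ratio(spec, 0.92, 0.86)
            ratios.append({"profile": name, "direction": direction,
                           "ratio_920_860": round(r, 4)})
            print(f"{name:15s} {direction:7s}: 920/860 ratio = {r:.3f}")

    pd.DataFrame(rows).to_csv(RESULTS / "model_spectra.csv", index=False)
    pd.DataFrame(ratios).to_csv(RESULTS / "model_ratios.csv", index=False)
    print("\nForward ratios sit near the pure 1/lambda^4 value of "
          f"{(860 / 920) ** 4:.3f} for both structures, while the epi ratio "
          "jumps from ~1.0 to ~1.7 when the diameter grows 0.45 -> 0.50 um: "
          "epi-detected SHG carries the structural contrast.")
    print(f"wrote {RESULTS/'model_spectra.csv'} and {RESULTS/'model_ratios.csv'}")


if __name__ == "__main__":
    main()
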