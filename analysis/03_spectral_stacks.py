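#!/usr/bin/env python
"""Emission-stack analysis: SHG line versus TPEF tail across excitation.

Simulates 32-band emission stacks at 760/780/840/940 nm excitation over a
fibre field, with a TPEF fluorophore whose two-photon band ends at 800 nm.
Extracts mean emission spectra, locates the SHG band at half the excitation
wavelength, and splits SHG from TPEF.  Writes results/emission_spectra.csv
and results/shg_tpef_split.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from shgspec.spectral_stack import emission_spectrum, shg_band_index, split_shg_tpef
from shgspec.synthetic import SceneConfig, StackConfig, make_spectral_stack

RESULTS = Path(__file__).resolve().parents[1] / "results"
EXCITATIONS = (760.0, 780.0, 840.0, 940.0)


def main():
    RESULTS.mkdir(exist_ok=True)
    spectra_rows, split_rows = [], []
    for exc in EXCITATIONS:
        cfg = StackConfig(excitation_nm=exc, tpef_amplitude=2.0,
                          tpef_excitation_cutoff_nm=800.0, noise_seed=int(exc))
        stack = make_spectral_stack(SceneConfig(seed=int(exc)), cfg)
        spec = emission_spectrum(stack)
        idx = shg_band_index(exc, spec.band_centers_nm)
        shg, tpef = split_shg_tpef(spec, exc)
        for c, m in zip(spec.band_centers_nm, spec.mean_intensity):
            spectra_rows.append({"excitation_nm": exc, "band_center_nm": c,
                                 "mean_intensity": m})
        split_rows.append({
            "excitation_nm": exc,
            "shg_band_center_nm": spec.band_centers_nm[idx],
            "shg_signal": round(shg, 2),
            "tpef_signal": round(tpef, 2),
            "tpef_fraction": round(tpef / (shg + tpef), 3),
        })
        print(f"exc {exc:.0f} nm: SHG band at {spec.band_centers_nm[idx]:.1f} nm, "
              f"TPEF fraction {tpef / (shg + tpef):.2f}")

    pd.DataFrame(spectra_rows).to_csv(RESULTS / "emission_spectra.csv", index=False)
    pd.DataFrame(split_rows).to_csv(RESULTS / "shg_tpef_split.csv", index=False)
    print("\nThe SHG line tracks half the excitation wavelength exactly; the "
          "TPEF tail is strongest at 760 nm and falls to the background "
          "level beyond the 800 nm two-photon cutoff (the residual "
          "'tpef_signal' there is summed background counts) — emission "
          "position, not intensity alone, identifies SHG.")
    print(f"wrote {RESULTS/'emission_spectra.csv'} and {RESULTS/'shg_tpef_split.csv'}")


if __name__ == "__main__":
    main()
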