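# shgspec

Wavelength-dependent second-harmonic-generation (SHG) excitation efficiency
in fibrillar tissues, and the two-wavelength ratiometric imaging that turns
it into material contrast.

## The problem

Second harmonic imaging microscopy (SHIM) maps non-centrosymmetric
structures — chiefly collagen and myosin — by detecting light at exactly
half the excitation wavelength. Under the common Kleinman-symmetry
assumption the SHG yield should fall monotonically with wavelength in a
material-independent way, yet epi-detected measurements on collagen show
the opposite: intensity *rising* toward 1000 nm. This package implements a
quantitative explanation and the analysis built on it:

- **Momentum-space mapping.** SHG transfers momentum
  `Δk = 2k₁ − k₂` between two fundamental photons and one harmonic photon.
  In water, `|Δk| = 4π(n(λ/2) − n(λ))/λ` for forward detection but
  `4π(n(λ/2) + n(λ))/λ` for epi detection. Scanning 0.76–1.0 µm moves the
  forward detection point by only ~0.1 µm⁻¹, but sweeps the epi point from
  44 down to 33 µm⁻¹ — across the quasi-phase-matching peak produced by the
  periodic up/down polarity of harmonophores in a fibril.
- **The 1-D non-linear structure factor.** For a focused Gaussian beam
  (numerical aperture NA), the axial susceptibility profile χ²(z)
  determines the far-field yield through

  `G(Δk) = ∫ χ²(z) · exp(iΔk·z) / (1 + iζ) dz`,  `ζ = πNA²z/(nλ)`,

  with detected intensity `S₂(λ) ∝ |G(Δk(λ))|² / λ⁴`. The Gouy factor
  `1/(1+iζ)` apodizes the profile and smears momentum-space features.
- **Consequence.** A tiny change in fibre structure (0.45 → 0.50 µm
  diameter at a 0.23 µm polarity period) barely moves the forward 920/860 nm
  intensity ratio (0.767 → 0.781, both near the pure λ⁻⁴ value 0.764) but
  flips the epi ratio from 1.02 to 1.73. Epi-detected SHG therefore carries
  structural, material-specific contrast: collagen-like fibres brighten at
  920 nm, myosin-like fibres do not.

The package also implements the imaging side: registration of 860/920 nm
image pairs, the false-colour composite (920 nm → red+blue, 860 nm → green,
so 920-dominant pixels appear purple), per-pixel classification with
tolerance for noise, 32-band emission-stack analysis that separates the SHG
line at λ/2 from the red-shifted two-photon fluorescence (TPEF) tail, and a
synthetic-data generator so every stage is testable without microscope data.

## Worked example

```python
import numpy as np
from shgspec import build_profile, excitation_spectrum, wavelength_ratio, water

band = np.round(np.arange(0.76, 1.0001, 0.02), 4)   # µm
for apod, diameter in (("hamming", 0.45), ("tophat", 0.50)):
    profile = build_profile(apod, diameter, period=0.23)
    for direction in ("forward", "epi"):
        spec = excitation_spectrum(profile, band, direction, dispersion=water())
        print(apod, diameter, direction,
              round(wavelength_ratio(spec, 0.92, 0.86), 3))
```

prints

```
hamming 0.45 forward 0.767
hamming 0.45 epi 1.022
tophat 0.5 forward 0.781
tophat 0.5 epi 1.727
```

i.e. the forward 920/860 ratios stay within 2% of each other while the epi
ratios differ by 0.7 — the structural contrast described above. The
`analysis/` scripts run the full narrative: `01_model_spectra.py` (spectra
and ratios), `02_ratiometric_imaging.py` (synthetic collagen/myosin/combined
fields: the collagen field classifies 99% purple, the myosin field 90%
gray), `03_spectral_stacks.py` (SHG band tracking λ/2 at 760–940 nm
excitation against a TPEF tail) and `04_detector_calibration.py`
(measured-vs-reference response ratio). Tables and composites land in
`results/`.

A CLI covers the same operations on files:

```
shgspec simulate-spectrum --config model.yaml --out spectrum.csv --ratio 920:860
shgspec ratio-image --img920 a.tif --img860 b.tif --out composite.png --stats s.json
shgspec analyze-stack --stack stack.tif --exc 840 --out spectrum.csv
shgspec synth pair --material collagen_like --seed 0 --out-prefix fix/col
```

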