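# Methods

## Model

The model treats a fibril as a one-dimensional axial distribution of
second-order susceptibility,

    chi2(z) = cos(2*pi*z / p) * W(z; d)  +  a * H(z; w_b),

an oscillation of period `p` (the up/down polarity alternation of
harmonophores) under an envelope `W` of full width `d` (the fibre
"diameter": a Hamming or top-hat window), plus a low-frequency baseline
bump `H` (a Hamming window of amplitude `a` and width `w_b`) that supplies
a stable phase-matching peak at the momentum-space origin. Focused
illumination is handled in the paraxial Gaussian-beam approximation: the
beam's Gouy phase slippage enters as the axial weight `1/(1 + i*zeta)`,
`zeta = pi*NA^2*z/(n*lambda)`, applied to chi2 before the transform

    G(dk) = integral chi2(z) * exp(i*dk*z) / (1 + i*zeta) dz,

and the detected yield is `S2(lambda) ∝ |G(dk(lambda))|^2 / lambda^4`.
All radiometric prefactors (field amplitudes, indices at the harmonic,
beam cross-section) are deliberately folded into the arbitrary intensity
unit: only ratios and normalized spectra are meaningful outputs.

Assumptions: 1-D axial model (no tensor/polarization response, no 3-D
vectorial focal fields); wavelength-independent chi2 (Kleinman symmetry);
homogeneous embedding medium (water) for both dispersion and the Gouy
factor; plane-wave-like detection so the geometry enters only through
`dk(lambda)`.

## Momentum mapping and dispersion

Vacuum wavelengths are in micrometres, momenta in inverse micrometres
(angular). The mismatch magnitudes are `4*pi*(n(lambda/2) - n(lambda)) /
lambda` (forward) and `4*pi*(n(lambda/2) + n(lambda)) / lambda` (epi).
The default index model is the four-term Sellmeier fit for pure water at
21.5 C (valid 0.18-1.13 um); it is a named, swappable component and a CSV
table loader with cubic interpolation accepts user-supplied data. With
this model the 0.76-1.0 um band maps to forward mismatches of
0.269 -> 0.142 1/um (span 0.127 1/um; the band lies within ~0.27 1/um of
the origin) and epi mismatches of 44.23 -> 33.46 1/um (span 10.8 1/um),
crossing the quasi-phase-matching peak of a 0.23 um polarity period
(2*pi/0.23 = 27.3 1/um) on its high-momentum shoulder. These endpoint
values are robust at the percent level across published water datasets;
coarser figures sometimes quoted for the band (e.g. a forward extent of
~0.25 1/um) refer to the distance from the origin, not the swept width.

## Discretization

The profile is sampled on a 96 um window with N = 8192 points (sampling
rate 85.33 1/um), zero-padded by construction since the structure occupies
less than a micrometre at the window centre. The discrete transform (FFT
with the `exp(+i*dk*z)` kernel, z = 0 on sample N/2) yields G on a
momentum grid of spacing 2*pi/96 = 0.0654 1/um up to the unaliased maximum
pi*85.33 = 268 1/um. The long window exists purely to refine the momentum
grid: the whole forward band spans only ~4 grid nodes, and spectra are read
off by cubic interpolation (splines on Re/Im of G for sampling, and on
|G|^2 for intensities; the interpolant agrees with direct quadrature of
the integral to ~1e-9 relative error away from zeros of G). The
oscillation period must exceed two spatial samples or profile construction
raises an aliasing error.

Per-wavelength spectra recompute G with that wavelength's Gouy weight
(`zeta` uses the excitation wavelength and `n(lambda)` from the active
dispersion model); single momentum-space maps use a fixed reference
wavelength of 0.88 um (band centre). Default NA is 1.3 (oil-immersion
objective).

## Baseline-width calibration

The width of the added baseline window is not determined by first
principles; it controls the shape of the origin peak whose shoulder the
epi band samples. It was calibrated once against the four published
reference ratios (forward 0.77/0.79 and epi 1.03/1.73 for the
0.45 um Hamming / 0.50 um top-hat structures): a single shared width of
0.35 um reproduces all four to within 0.01

    forward: 0.767, 0.781        epi: 1.022, 1.727

whereas tying the baseline width to the fibre diameter leaves the
0.45 um epi ratio at 0.97. The value is the package default
(`DEFAULT_BASELINE_WIDTH`) and an explicit parameter everywhere.

## Ratiometric imaging

Image pairs are aligned by whole-pixel translation at the
cross-correlation maximum (same-field acquisitions differ by drift only;
no rotation or warping), with a validity mask excluding wrapped borders.
The composite assigns the 920 nm channel to red and blue and the 860 nm
channel to green; display scaling is per-channel min-max by default, or
shared-limits to preserve the quantitative ratio in the display.
Classification uses raw registered intensities: a pixel is "gray" when
`|I920 - I860| <= max(tol_abs, tol_rel*(I920+I860)/2)` with defaults
tol_abs = 2 gray levels and tol_rel = 0.1 — an absolute noise floor plus a
proportional band emulating visually balanced greyscale — otherwise purple
or green by sign. Label fractions are reported over the overlap mask with
background excluded: a pixel is background when, in both channels, it
falls below twice the channel's background level, estimated as the median
of the darkest half of the overlap pixels (robust while fibres cover less
than half the field; quantile-based floors estimated from the darkest
decile alone sit below the Poisson background median and leak empty pixels
into the statistics).

## Spectral stacks

Band centres follow `start + width*(i + 1/2)` with the detector defaults
start = 362 nm, width = 10.8 nm, 32 bands (centres 367.4-702.2 nm). The
SHG band for excitation `lambda_exc` is the band whose centre is nearest
`lambda_exc/2`, ties toward shorter wavelengths; the SHG window adds one
neighbour on each side, since a ~10 nm line near a band edge straddles two
bins. TPEF is summed over bands whose centres lie more than one band
width beyond the window's upper edge (guard band against spill-over).

## Synthetic data

The generators emulate the statistical structure of the real
acquisitions, not their anatomy. Fields are random line strokes with a
flat-topped supergaussian cross-profile (order 6, FWHM 6 px, 15 strokes on
128x128) — dense, bright fibre bundles rather than sparse Gaussian
filaments, so bright plateau pixels dominate as they do in tendon/muscle
images. Expected intensities are `E860 = background + photon_scale *
scene` and `E920 = ratio * E860` with defaults photon_scale = 2000,
background = 10 counts, and material ratios 1.73 (collagen-like) / 1.03
(myosin-like) taken from the model's two reference structures; pixel
values are independent Poisson draws, and an optional cyclic shift of the
860 nm expectation exercises registration. Emission stacks distribute a
Gaussian SHG line at `lambda_exc/2` (sigma 5 nm) and an optional broad
TPEF line (default 500/60 nm) over the bands by exact Gaussian band
integrals; an optional excitation cutoff ramps the TPEF amplitude to zero
at the cutoff wavelength. Profile ensembles jitter the fibre diameter with
zero-mean Gaussian noise, resampling invalid draws.

What the generators do *not* model: optical blur (PSF convolution), depth
sectioning and scattering, detector gain non-linearity, fibre crimp and
orientation-dependent polarization response, spatially varying background.
Passing round-trip tests therefore shows the analysis recovers the
statistical truth it defines — ratios, line positions, label fractions —
not that it is robust to every instrumental artefact of real tissue data.

## Numerical choices and degenerate inputs

Out-of-range wavelengths and momenta raise range errors naming the valid
interval; zero reference intensities and zero ratio denominators raise
explicit errors; a zero in a calibration reference yields NaN at that
point rather than failing the series. Registration refuses constant
images. Ensemble jitter retries up to a bounded number of draws.
Interpolation schemes and the transform sign convention are fixed as
above; results in the tests are asserted at tolerances reflecting
discretization (e.g. top-hat transforms agree with the analytic sinc to
the edge-resolution limit dz/2).

## Known limitations

The 1-D paraxial model cannot predict absolute intensities or
polarization-resolved behaviour, and the reference structures are
illustrative: the epi-ratio's sensitivity to tenths of micrometres in
diameter means real tissue heterogeneity produces a distribution of
ratios, not two clean values. The water dispersion model ignores
temperature/salinity corrections and tissue refractive indices. The
imaging classifier is translation-only and assumes a common laser-power
scale per channel across the field.
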