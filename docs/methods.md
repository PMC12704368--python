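# Methods

## Calibration model

Reflectance is reconstructed per voxel from a sample / white-reference /
dark cube triplet as

    R = (Is − (ts/td)·Idark) / ((ts/tw)·Iwhite − (ts/td)·Idark),

which removes dark counts, normalizes out the spectral response of the
illumination and detection chain, and compensates minor spatial
illumination inhomogeneity, under the assumptions that (i) detector
counts are linear in integration time over the used range, (ii) the
white target is spectrally flat, and (iii) the dark level is stable
between the dark and sample acquisitions. Nominal times default to each
cube's stored value; explicit arguments override.

Attenuation uses the Beer–Lambert form A = −log₁₀ R. The base of the
logarithm is a convention choice; we use base 10 so A is in optical
density units, the standard for attenuation imaging. Two clamps keep A
finite and bounded:

- negative numerators (sample counts below the scaled dark level, a
  noise effect) clamp to 0 and are flagged;
- R is floored at 1e−4 before the log, capping A at 4 OD — roughly the
  dynamic range a 16-bit sensor (ceiling 65 535 counts) can support.

Flagged voxels are censored, not measured: they are excluded from
per-FOV summaries downstream.

Integration-time flattening computes per-band times
t(λ) = t₀ · target / white(λ) so a white target reads a uniform count
level across the spectrum. The target level defaults to 80% of the
detector ceiling (headroom against saturation); if any band would still
saturate, the whole table is scaled down uniformly so the flattened
response stays spectrally flat. Whether an instrument's own corrective
factor targets a fixed level or the dimmest band is an open question;
the fixed-level rule is our choice and is configurable.

## Spectral unmixing

The modified Beer–Lambert law treats an attenuation change relative to
a reference spectrum as linear in chromophore concentration changes:

    ΔA(λ) = Σᵢ εᵢ(λ)·Δcᵢ + k.

Design choices, each genuinely open given only the model statement:

- **Pathlength.** A unit (1 cm) pathlength is absorbed into the
  coefficients, so molar results are concentration-differences per unit
  pathlength (μM/cm) and volumetric contents are cm⁻¹. No
  wavelength-dependent differential-pathlength factor is modeled.
- **Nuisance terms.** A single wavelength-independent offset k absorbs
  scattering-driven baseline shifts; it is the only nuisance regressor.
  Scattering is otherwise assumed to be largely cancelled by the
  reference subtraction.
- **Solver.** Per-pixel linear least squares; box bounds (when set) are
  handled by `scipy.optimize.lsq_linear`, the unbounded default by a
  direct `lstsq` solve vectorized across all pixels. Default bounds are
  ±∞ with the offset enabled, since results are signed differences.
- **Reference spectrum.** Default is the mean attenuation over a
  centered ROI covering 10% of each spatial dimension of a designated
  reference cube; an explicit spectrum or ROI overrides. The
  `MBLLUnmixer` estimator freezes the reference at `fit` time so
  several fields of view share one reference.
- **Fit window.** Default 500–900 nm: good tissue penetration, low
  water absorption, and coverage of the hemoglobin and cytochrome
  features.
- **Degenerate designs.** A design matrix with condition number above
  1e8 on the fit window (collinear extinction columns, or columns with
  essentially no support in the window) raises / flags the whole result
  rather than returning unstable coefficients.

The per-pixel residual is the RMS spectral misfit over the window.
Per-FOV summaries are arithmetic means over unflagged pixels.

## Autofluorescence redox analysis

Channel intensities through the 450/20 and 520/20 nm filters are
modeled as (I450, I520)ᵀ = C·(xN, xF)ᵀ. C is calibrated from boundary
measurements on pure stocks (defaults 281.9 μM NADH, 120.5 μM FAD):
a = I450N/x̂N, b = I450F/x̂F, c = I520N/x̂N, d = I520F/x̂F. The model
assumes intensities are linear in concentration (no inner-filter or
quenching effects) and that the cross-talk matrix is constant across
the field of view.

ORR = xF/(xF + xN) is computed after inverting C. Negative inverted
concentrations (noise-driven) are retained for diagnostics but clamped
at 0 for the ratio, with the pixel flagged — this keeps ORR in [0, 1]
without hiding model misfit. Pixels with no net signal (xN + xF ≤ ε)
are masked. A single scalar dark offset per channel is subtracted
before inversion (no dark cube exists for the LED path). Whether
boundary intensities should be dark-subtracted before calibration is
not fixed by the model; the calibration accepts either convention since
it is linear in the supplied intensities.

Box statistics for grade-wise comparisons use linear-interpolation
percentiles and Tukey whiskers (most extreme points within 1.5 IQR of
the box); points beyond are listed as outliers. We compute descriptive
statistics only and leave inference to the user.

## Synthetic data

The simulators emit exactly the objects the analysis consumes, with
ground truth attached, and are pure functions of (spec, seed):

- **Solid phantoms.** The 16-disk calibration set spans μa 0.06–0.36
  cm⁻¹ × μs 5.9–22.4 cm⁻¹ (the B3 disk, μa = 0.12, μs = 11.1, mimics
  brain tissue). The forward model A\* = k₀ + k₁·(μa/μs) is a
  deliberate surrogate: it is the simplest form consistent with
  attenuation varying linearly in the absorption-to-scattering ratio.
  It is not diffusion theory, and recovering its coefficients validates
  the pipeline arithmetic, not radiative transport.
- **Liquid phantoms.** Two irregular compartments separated by a
  diagonal wall; compartment attenuation = intralipid baseline +
  ε_fluor(λ)·c, wall reflectance 0.005 (near-black, to exercise
  threshold masks). Default concentrations (0.25, 1.0) keep peak
  attenuation inside the 4-OD range while preserving the 4:1
  concentration ratio the band-integral maps must resolve within 1%.
  Fluorophore band shapes are single Gaussians (fluorescein centered at
  490 nm, PpIX at 408 nm), so band integrals are exactly linear in
  concentration.
- **Tissue scenes.** A(x,y,λ) = background(λ) + Σᵢ εᵢ(λ)·cᵢ(x,y),
  converted to reflectance, scaled to white counts (80% of the
  detector ceiling) over a dark level of 100 counts. Noise is Gaussian
  read noise plus optional Poisson shot noise on counts.
- **AF mixtures.** (I450, I520) = C·(xN, xF) + Gaussian noise; the
  dilution series pairs NADH fraction f with FAD fraction 1 − f at
  f·stock and (1−f)·stock, rounded half-up to one decimal as such
  tables are conventionally printed.

The synthetic extinction library assigns each of the ten chromophores
(HbO2, HHb, ox/redCCO, ox/red cytochromes b and c, water, lipid) a
fixed Gaussian-mixture band shape. Centers and widths are spread so the
500–900 nm design matrix has condition number ≈ 35 (< 100), making
recovery tests well posed by construction. **What passing tests
therefore show:** the pipeline inverts its own forward models exactly
and degrades gracefully under noise. **What they do not show:**
performance under real tissue spectra (overlapping literature ε, with
condition numbers far above 100), wavelength-dependent pathlength,
specular artifacts, chromatic focus shifts, or camera-specific noise.

## Numerical choices

- Band lookup tolerance defaults to half the median grid step, ties
  break toward the lower wavelength; on the 5-nm grid anchored at
  385 nm this makes a 530 nm or 532 nm request resolve to the 530 band.
- ROIs are 0-based, half-open, row-major, origin top-left — one
  convention, tested everywhere.
- Cubes are stored as multi-page TIFF (one page per band, ascending
  wavelength) + JSON sidecar; integer counts within 16 bits round-trip
  bit-exactly as uint16, anything else as float32.
- Degenerate calibration denominators (≤ 1e−12) are flagged per voxel;
  an everywhere-degenerate denominator raises.
- R² = 1 − SS_res/SS_tot; a zero-variance predictor raises; a constant
  response returns slope 0 and R² = 0.
- Cross-talk matrices are declared singular when |det| falls below
  1e−12 relative to the matrix scale.

## Problem sizes

Tests run on 64×64×81 cubes for calibration round trips, 12–32 px
tissue scenes for unmixing, 200 seeded repeats for noise-bias checks,
and the full 16-disk set for linearity — sizes chosen so the whole
suite completes in seconds while keeping Monte-Carlo error well below
the tested tolerances. The acceptance script uses the same scales.

## Known limitations

- The solid-phantom forward model is a linear surrogate, not photon
  transport; its coefficients have no physical calibration.
- Band-integral fluorophore maps are relative (min–max normalized);
  absolute quantification in μM is out of scope.
- No spatial regularization: every pixel is fit independently.
- Grade-wise ORR and chromophore trends on real tumor tissue are not
  claimed: no tissue data ships with the package, and the statistics
  module is descriptive only.
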