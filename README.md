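# hsikit

Analysis tools for wide-field hyperspectral reflectance imaging of
tissue: cube calibration to reflectance and attenuation, modified
Beer–Lambert spectral unmixing of chromophore concentration changes,
molecular contrast maps, and two-channel NADH/FAD autofluorescence
redox-ratio analysis — with seeded forward simulators that generate
every input with known ground truth.

It is written for researchers working with scanned-illumination
hyperspectral systems (sample / white-reference / dark cube triplets
with per-band integration times) who want a tested, scriptable pipeline
from raw detector counts to chromophore maps and per-sample summaries.

## The models

**Calibration.** A cube triplet is reduced to per-voxel reflectance

```
R(x,y,λ) = (Is − (ts/td)·Idark) / ((ts/tw)·Iwhite − (ts/td)·Idark)
```

with ts, tw, td the nominal integration times of the sample, white and
dark acquisitions, and attenuation in optical-density units

```
A(x,y,λ) = −log10 R(x,y,λ).
```

Negative numerators clamp to 0 and R is floored at 1e−4 before the log
(A capped at 4 OD); clamped voxels are flagged as censored.

**Spectral unmixing.** Attenuation differences relative to a reference
spectrum follow the modified Beer–Lambert law

```
ΔA(λ) = Σᵢ εᵢ(λ)·Δcᵢ + k
```

solved per pixel by (optionally box-bounded) least squares over a fit
window (default 500–900 nm), with a unit-pathlength convention: molar
species in μM/cm, volumetric contents (water, lipid) in cm⁻¹. Derived
maps: Δ[HbT] = Δ[HbO2] + Δ[HHb] (vascular density) and
Δ[DiffCCO] = Δ[oxCCO] − Δ[redCCO] (mitochondrial redox balance).

**Redox ratio.** Two-channel autofluorescence intensities are modeled
as a linear mix of NADH and FAD concentrations through a 2×2
cross-talk matrix C calibrated on pure stock solutions; inverting C
gives (xN, xF) and the optical redox ratio

```
ORR = xFAD / (xFAD + xNADH) ∈ [0, 1].
```

## Worked example

Simulate a noiseless tissue-like scene with known chromophore fields,
calibrate it, and unmix it back:

```python
import numpy as np
from hsikit import reflectance, attenuation
from hsikit.calibration import CalibrationSet
from hsikit.synthetic import TissueScene, simulate_tissue, synthetic_extinction_library
from hsikit.unmixing import unmix_cube, fov_summary

lib = synthetic_extinction_library().subset(["HbO2", "HHb", "oxCCO", "redCCO"])
rng = np.random.default_rng(0)
fields = {name: 0.5 * rng.random((32, 32)) for name in lib.chromophores}
scene = TissueScene(fields, lib, background_spectrum=np.full(127, 0.2), seed=0)
sample, white, dark, truth = simulate_tissue(scene)

att = attenuation(reflectance(sample, CalibrationSet(white=white, dark=dark)))
result = unmix_cube(att, lib, reference=np.full(127, 0.2))

summary = fov_summary(result, sample_id="demo", fov_id="fov0")
for name in lib.chromophores:
    print(f"mean d[{name}] = {summary[name]:.4f}  (truth {fields[name].mean():.4f})")
print(f"mean d[HbT]     = {summary['HbT']:.4f}")
print(f"mean d[DiffCCO] = {summary['DiffCCO']:.4f}")
print(f"max residual    = {result.residual_map.max():.2e}")
```

prints

```
mean d[HbO2] = 0.2573  (truth 0.2573)
mean d[HHb] = 0.2404  (truth 0.2404)
mean d[oxCCO] = 0.2485  (truth 0.2485)
mean d[redCCO] = 0.2467  (truth 0.2467)
mean d[HbT]     = 0.4977
mean d[DiffCCO] = 0.0018
max residual    = 6.48e-16
```

The per-chromophore spatial means recover the simulated fields to
machine precision on noiseless input; the residual map confirms the fit
is exact. The same pipeline runs from the shell:

```
hsikit simulate --kind tissue --seed 7 --out scene/
hsikit calibrate --sample scene/sample.tif --white scene/white.tif \
                 --dark scene/dark.tif --out refl.tif --attenuation att.tif
hsikit unmix --attenuation att.tif --extinction scene/extinction.csv --out unmixed/
```

Estimator-style interfaces (`ReflectanceCalibrator`, `MBLLUnmixer`,
`CrosstalkModel`) wrap the same computations with sklearn
`fit`/`transform` semantics for use in pipelines.

The extinction library shipped in `hsikit.synthetic` is **synthetic**
(Gaussian-mixture band shapes chosen for well-posed recovery tests);
supply your own `wavelength_nm,<chromophore>,...` CSV for real data.

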