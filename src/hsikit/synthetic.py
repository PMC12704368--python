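"""Seeded forward simulators with known ground truth.

Every input the analysis modules consume can be generated here: solid
tissue-mimicking phantom cubes (homogeneous disks with known absorption
and scattering coefficients), two-compartment liquid phantoms spiked
with a fluorophore, tissue-like scenes with spatial chromophore
concentration fields, and two-channel NADH/FAD autofluorescence
mixtures. All simulators are pure functions of (spec, seed) and
bit-reproducible.

The extinction library shipped here is SYNTHETIC: smooth
Gaussian-mixture band shapes per chromophore, chosen mutually
distinguishable (design-matrix condition number < 100 on the 500-900 nm
window) so recovery tests are well posed. It is not a literature
compilation and carries no real spectroscopic meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autofluorescence import ChannelPair, CrosstalkMatrix
from .cubes import DETECTOR_CEILING, RawCube, SpectralGrid
from .unmixing import ExtinctionLibrary

__all__ = [
    "MEDPHOT_DISKS",
    "PhantomSpec",
    "TissueScene",
    "AFMixture",
    "NoiseModel",
    "NADH_STOCK_UM",
    "FAD_STOCK_UM",
    "dilution_series",
    "simulate_af_mixture",
    "simulate_solid_phantom",
    "simulate_liquid_phantom",
    "simulate_tissue",
    "synthetic_extinction_library",
    "fluorophore_spectrum",
    "two_compartment_geometry",
]

#: stock concentrations (μM) of the pure NADH / FAD calibration solutions
NADH_STOCK_UM = 281.9
FAD_STOCK_UM = 120.5

#: absorption / scattering coefficients (cm^-1, 690 nm) of the 16
#: homogeneous calibration disks; B3 mimics human brain tissue
MEDPHOT_DISKS: dict[str, tuple[float, float]] = {
    "A2": (0.06, 5.9), "A3": (0.12, 6.2), "A5": (0.24, 6.1), "A7": (0.36, 6.2),
    "B2": (0.06, 11.0), "B3": (0.12, 11.1), "B5": (0.23, 11.3), "B7": (0.36, 11.8),
    "C2": (0.06, 16.5), "C3": (0.11, 16.0), "C5": (0.23, 16.6), "C7": (0.35, 16.3),
    "D2": (0.06, 21.0), "D3": (0.11, 21.3), "D5": (0.23, 21.8), "D7": (0.35, 22.4),
}

DEFAULT_WHITE_LEVEL = 0.8 * DETECTOR_CEILING
DEFAULT_DARK_LEVEL = 100.0
DEFAULT_TIME_MS = 50.0


@dataclass(frozen=True)
class PhantomSpec:
    """One homogeneous solid phantom disk."""

    mu_a: float
    mu_s: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.mu_a <= 0 or self.mu_s <= 0:
            raise ValueError("optical coefficients must be positive")

    @classmethod
    def from_disk(cls, label: str) -> "PhantomSpec":
        mu_a, mu_s = MEDPHOT_DISKS[label]
        return cls(mu_a=mu_a, mu_s=mu_s, label=label)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian read noise (counts, sd) plus optional Poisson shot noise."""

    gaussian_sd: float = 0.0
    poisson: bool = False

    def apply(self, counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = counts.astype(float)
        if self.poisson:
            out = rng.poisson(np.maximum(out, 0.0)).astype(float)
        if self.gaussian_sd > 0:
            out = out + rng.normal(0.0, self.gaussian_sd, size=out.shape)
        return np.maximum(out, 0.0)


@dataclass
class TissueScene:
    """Spatial chromophore fields over a baseline attenuation spectrum."""

    concentration_fields: dict[str, np.ndarray]
    lib: ExtinctionLibrary
    background_spectrum: np.ndarray
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        shapes = {f.shape for f in self.concentration_fields.values()}
        if len(shapes) > 1:
            raise ValueError("concentration fields must share a shape")
        self.background_spectrum = np.asarray(self.background_spectrum, dtype=float)
        if self.background_spectrum.shape != (len(self.lib.grid),):
            raise ValueError("background spectrum does not match library grid")
        for name in self.concentration_fields:
            if name not in self.lib.epsilon:
                raise KeyError(f"chromophore {name} not in library")


@dataclass(frozen=True)
class AFMixture:
    """One NADH/FAD mixture imaged through a known cross-talk matrix."""

    xN: float
    xF: float
    truth: CrosstalkMatrix
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.xN < 0 or self.xF < 0:
            raise ValueError("concentrations must be non-negative")


def _round_half_up(x: np.ndarray, decimals: int = 1) -> np.ndarray:
    factor = 10.0**decimals
    return np.floor(np.asarray(x, dtype=float) * factor + 0.5) / factor


def dilution_series(
    stock_N: float = NADH_STOCK_UM,
    stock_F: float = FAD_STOCK_UM,
    fractions=(0.0, 0.2, 0.4, 0.5, 0.6, 0.8, 1.0),
):
    """Inverse-dilution mixture table: NADH fraction f pairs with FAD 1 - f.

    Concentrations are fraction · stock, rounded half-up to one decimal
    (matching how such tables are printed). Returns a DataFrame with
    columns ``fraction_N, xN, fraction_F, xF``.
    """
    import pandas as pd

    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0) or np.any(fractions > 1):
        raise ValueError("fractions must lie in [0, 1]")
    xN = _round_half_up(fractions * stock_N)
    xF = _round_half_up((1.0 - fractions) * stock_F)
    return pd.DataFrame(
        {"fraction_N": fractions, "xN": xN, "fraction_F": 1.0 - fractions, "xF": xF}
    )


def simulate_af_mixture(mix: AFMixture, shape: tuple[int, int] | None = None):
    """Channel intensities for one mixture through its true cross-talk matrix.

    Returns a scalar ``(I450, I520)`` pair when ``shape`` is None, else a
    :class:`ChannelPair` of constant-plus-noise images. Noiseless when
    ``noise_sd`` is 0.
    """
    I450, I520 = mix.truth.forward(mix.xN, mix.xF)
    if shape is None and mix.noise_sd == 0:
        return float(I450), float(I520)
    rng = np.random.default_rng(mix.seed)
    if shape is None:
        return (
            float(I450 + rng.normal(0.0, mix.noise_sd)),
            float(I520 + rng.normal(0.0, mix.noise_sd)),
        )
    a = np.clip(I450 + rng.normal(0.0, mix.noise_sd, shape), 0, DETECTOR_CEILING)
    b = np.clip(I520 + rng.normal(0.0, mix.noise_sd, shape), 0, DETECTOR_CEILING)
    return ChannelPair(I450=a, I520=b)


def _emit_triplet(
    true_R: np.ndarray,
    grid: SpectralGrid,
    noise: NoiseModel,
    rng: np.random.Generator,
    white_level: float = DEFAULT_WHITE_LEVEL,
    dark_level: float = DEFAULT_DARK_LEVEL,
    time_ms: float = DEFAULT_TIME_MS,
) -> tuple[RawCube, RawCube, RawCube]:
    """Sample/white/dark cubes whose calibration recovers ``true_R`` exactly
    in the noiseless case (all nominal times equal)."""
    shape = true_R.shape
    white = np.full(shape, white_level)
    dark = np.full(shape, dark_level)
    sample_counts = true_R * (white - dark) + dark

    def cube(counts: np.ndarray, kind: str) -> RawCube:
        return RawCube(
            counts=noise.apply(counts, rng),
            grid=grid,
            integration_times=np.full(len(grid), time_ms),
            kind=kind,
            nominal_time=time_ms,
        )

    return cube(sample_counts, "sample"), cube(white, "white"), cube(dark, "dark")


def simulate_solid_phantom(
    spec: PhantomSpec,
    model: tuple[float, float] = (0.0, 10.0),
    shape: tuple[int, int] = (32, 32),
    grid: SpectralGrid | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> tuple[RawCube, RawCube, RawCube, float]:
    """Homogeneous-disk cube triplet under a linear attenuation model.

    The surrogate forward model puts the true attenuation at
    ``A* = k0 + k1 * (mu_a / mu_s)`` at every band and pixel — the
    simplest form consistent with attenuation varying linearly in the
    absorption-to-scattering ratio. Returns (sample, white, dark, A*).
    """
    k0, k1 = model
    grid = grid or SpectralGrid.default()
    a_true = k0 + k1 * (spec.mu_a / spec.mu_s)
    if a_true < 0:
        raise ValueError("model coefficients give negative attenuation")
    true_R = np.full((*shape, len(grid)), 10.0 ** (-a_true))
    rng = np.random.default_rng(seed)
    sample, white, dark = _emit_triplet(true_R, grid, noise, rng)
    return sample, white, dark, float(a_true)


def fluorophore_spectrum(grid: SpectralGrid, label: str, scale: float = 1.0) -> np.ndarray:
    """Synthetic absorption band shape for a liquid-phantom fluorophore.

    ``fluorescein`` peaks near 490 nm, ``PpIX`` near 405 nm (Soret-like
    band); both are single Gaussians, so band integrals scale exactly
    linearly with concentration.
    """
    wl = grid.wavelengths
    if label == "fluorescein":
        return scale * np.exp(-0.5 * ((wl - 490.0) / 22.0) ** 2)
    if label == "PpIX":
        return scale * np.exp(-0.5 * ((wl - 408.0) / 14.0) ** 2)
    raise KeyError(f"unknown fluorophore {label!r}")


def two_compartment_geometry(shape: tuple[int, int], wall_frac: float = 0.12) -> np.ndarray:
    """Label image: 1 = upper-right channel, 2 = lower-left channel, 0 = wall.

    A diagonal plastic wall of fractional width ``wall_frac`` separates
    the two irregular compartments.
    """
    rows, cols = shape
    r, c = np.mgrid[0:rows, 0:cols]
    # signed distance from the main diagonal, normalized
    d = (c / max(cols - 1, 1)) - (r / max(rows - 1, 1))
    labels = np.zeros(shape, dtype=np.uint8)
    labels[d > wall_frac / 2] = 1
    labels[d < -wall_frac / 2] = 2
    return labels


def simulate_liquid_phantom(
    fluorophore: str = "fluorescein",
    concentrations: tuple[float, float] = (0.25, 1.0),
    baseline: float | np.ndarray = 0.15,
    shape: tuple[int, int] = (48, 48),
    grid: SpectralGrid | None = None,
    wall_reflectance: float = 0.005,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
):
    """Two-compartment intralipid phantom spiked with one fluorophore.

    Compartment attenuation is ``baseline + eps_fluor(λ) * c`` with the
    two concentrations in the two channels; the plastic wall gets
    near-zero reflectance so threshold masks have something to catch.
    Returns (sample, white, dark, truth) where truth holds the label
    image, per-compartment concentrations and the baseline spectrum.
    """
    if min(concentrations) < 0:
        raise ValueError("concentrations must be non-negative")
    grid = grid or SpectralGrid.default()
    baseline = np.broadcast_to(np.asarray(baseline, dtype=float), (len(grid),))
    eps = fluorophore_spectrum(grid, fluorophore)
    labels = two_compartment_geometry(shape)

    att = np.empty((*shape, len(grid)))
    att[labels == 1] = baseline + eps * concentrations[0]
    att[labels == 2] = baseline + eps * concentrations[1]
    true_R = 10.0 ** (-att)
    true_R[labels == 0] = wall_reflectance

    rng = np.random.default_rng(seed)
    sample, white, dark = _emit_triplet(true_R, grid, noise, rng)
    truth = {
        "labels": labels,
        "concentrations": {1: concentrations[0], 2: concentrations[1]},
        "baseline": np.asarray(baseline),
        "epsilon": eps,
        "fluorophore": fluorophore,
    }
    return sample, white, dark, truth


def simulate_tissue(scene: TissueScene) -> tuple[RawCube, RawCube, RawCube, dict]:
    """Tissue-like cube triplet from spatial chromophore fields.

    The true attenuation is ``A(x, y, λ) = background(λ) +
    Σ_i eps_i(λ) c_i(x, y)``, converted to reflectance, scaled to white
    counts and offset by the dark level, with optional noise. Returns
    (sample, white, dark, truth) with the generating fields.
    """
    grid = scene.lib.grid
    fields = scene.concentration_fields
    shape = next(iter(fields.values())).shape
    att = np.broadcast_to(scene.background_spectrum, (*shape, len(grid))).copy()
    for name, cmap in fields.items():
        att += cmap[:, :, None] * scene.lib.epsilon[name][None, None, :]
    if att.max() > 4.0:
        import warnings

        warnings.warn("true attenuation exceeds the 4-OD clamping range", stacklevel=2)
    true_R = 10.0 ** (-att)
    rng = np.random.default_rng(scene.seed)
    sample, white, dark = _emit_triplet(true_R, grid, scene.noise, rng)
    truth = {
        "concentration_fields": {k: v.copy() for k, v in fields.items()},
        "attenuation": att,
        "background": scene.background_spectrum.copy(),
    }
    return sample, white, dark, truth


# synthetic chromophore band shapes: (center nm, sd nm, amplitude) triples.
# Centers and widths are spread so the 500-900 nm design matrix stays
# well conditioned; amplitudes are per-μM·per-cm for molar species and
# per-cm for water/lipid.
_BAND_SHAPES: dict[str, tuple[tuple[float, float, float], ...]] = {
    "HbO2": ((542.0, 15.0, 1.0), (577.0, 12.0, 0.8)),
    "HHb": ((556.0, 18.0, 1.0), (760.0, 30.0, 0.6)),
    "oxCCO": ((830.0, 60.0, 0.9),),
    "redCCO": ((605.0, 14.0, 1.0), (880.0, 50.0, 0.5)),
    "oxCyt_b": ((520.0, 20.0, 1.0), (700.0, 40.0, 0.4)),
    "redCyt_b": ((430.0, 15.0, 0.5), (562.0, 10.0, 1.0)),
    "oxCyt_c": ((525.0, 12.0, 0.3), (695.0, 25.0, 1.0)),
    "redCyt_c": ((550.0, 8.0, 1.0), (640.0, 20.0, 0.6)),
    "water": ((740.0, 30.0, 0.3), (970.0, 45.0, 1.0)),
    "lipid": ((760.0, 15.0, 0.2), (930.0, 25.0, 1.0)),
}


def synthetic_extinction_library(
    grid: SpectralGrid | None = None,
    chromophores=None,
) -> ExtinctionLibrary:
    """SYNTHETIC extinction library of Gaussian-mixture band shapes.

    Deterministic, smooth, mutually distinguishable spectra for the ten
    chromophore names used throughout the package. For tests and
    simulations only — not literature extinction coefficients.
    """
    grid = grid or SpectralGrid.default()
    names = tuple(chromophores) if chromophores is not None else tuple(_BAND_SHAPES)
    wl = grid.wavelengths
    eps = {}
    for name in names:
        spectrum = np.zeros_like(wl)
        for center, sd, amp in _BAND_SHAPES[name]:
            spectrum = spectrum + amp * np.exp(-0.5 * ((wl - center) / sd) ** 2)
        eps[name] = spectrum
    return ExtinctionLibrary(grid, eps)
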