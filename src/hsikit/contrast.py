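"""Display-oriented molecular contrast maps.

Pseudo-RGB renderings from three narrow bands, the hemoglobin-saturation
ratio map A470/A530 (oxyhemoglobin-dominated band over the isosbestic
point), and background-subtracted band-integral maps that localize a
fluorophore by integrating the attenuation difference over its main
absorption band. All normalized outputs are dimensionless in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cubes import AttenuationCube, ReflectanceCube, band_at

__all__ = [
    "BandWindow",
    "ContrastMap",
    "pseudo_rgb",
    "saturation_ratio",
    "band_integral_map",
    "FLUORESCEIN_WINDOW",
    "PPIX_WINDOW",
]


@dataclass(frozen=True)
class BandWindow:
    """Integration window [low, high] nm with a fluorophore label."""

    low: float
    high: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.low >= self.high:
            raise ValueError("window low must be below high")


# default integration windows for the synthetic fluorophore library
FLUORESCEIN_WINDOW = BandWindow(460.0, 510.0, "fluorescein")
PPIX_WINDOW = BandWindow(390.0, 430.0, "PpIX")


@dataclass
class ContrastMap:
    """2-D map plus exclusion mask (True = excluded) and normalization record."""

    values: np.ndarray
    mask: np.ndarray
    normalization: dict

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        unmasked = self.values[~self.mask]
        if unmasked.size and not np.all(np.isfinite(unmasked)):
            raise ValueError("unmasked values must be finite")


def pseudo_rgb(
    cube: AttenuationCube | ReflectanceCube,
    bands: tuple[float, float, float] = (670.0, 520.0, 470.0),
    percentile: float = 99.0,
) -> np.ndarray:
    """Three-band false-color image, channel order (R, G, B).

    The default maps 670 nm to red, 520 nm to green, 470 nm to blue —
    long to short wavelength in natural color order. Each channel is
    scaled to [0, 1] by its own ``percentile`` and clipped.
    """
    channels = []
    for wl in bands:
        img = band_at(cube, wl).astype(float)
        scale = np.percentile(img, percentile)
        if scale <= 0:
            scale = 1.0
        channels.append(np.clip(img / scale, 0.0, 1.0))
    return np.stack(channels, axis=-1)


def saturation_ratio(att: AttenuationCube, eps: float = 1e-6) -> ContrastMap:
    """Hemoglobin-saturation proxy A470/A530 per pixel.

    470 nm sits where oxyhemoglobin absorption dominates; 530 nm is the
    oxy/deoxy isosbestic point and serves as an oxygenation-insensitive
    reference. Pixels with A530 <= ``eps`` are masked, not infinite.
    """
    a470 = band_at(att, 470.0).astype(float)
    a530 = band_at(att, 530.0).astype(float)
    mask = a530 <= eps
    values = np.where(mask, 0.0, a470 / np.where(mask, 1.0, a530))
    return ContrastMap(values=values, mask=mask, normalization={"kind": "ratio"})


def band_integral_map(
    att: AttenuationCube,
    background_reference: np.ndarray,
    window: BandWindow,
    reflectance_cutoff: float = 0.02,
    normalize: bool = True,
) -> ContrastMap:
    """Fluorophore map from background-subtracted band integrals.

    Per pixel, the trapezoidal integral over ``window`` of
    (A - background_reference), then min-max normalized to [0, 1] over
    unmasked pixels (set ``normalize=False`` for the raw integrals, which
    scale linearly with fluorophore concentration). Pixels whose mean
    window reflectance 10^(-A) falls below ``reflectance_cutoff`` — e.g.
    the near-black phantom wall — are masked and excluded from the
    normalization statistics.
    """
    background_reference = np.asarray(background_reference, dtype=float)
    if background_reference.shape != (len(att.grid),):
        raise ValueError("background reference does not match cube grid")
    in_window = att.grid.window_slice(window.low, window.high)
    if int(in_window.sum()) < 2:
        raise ValueError("window covers fewer than 2 grid bands")
    wl = att.grid.wavelengths[in_window]
    diff = att.values[:, :, in_window] - background_reference[in_window][None, None, :]
    integrals = np.trapezoid(diff, wl, axis=2)

    mean_refl = np.power(10.0, -att.values[:, :, in_window]).mean(axis=2)
    mask = mean_refl < reflectance_cutoff

    norm_record: dict = {"kind": "none", "window": (window.low, window.high)}
    values = integrals
    if normalize:
        unmasked = integrals[~mask]
        if unmasked.size == 0:
            raise ValueError("all pixels masked; nothing to normalize")
        vmin, vmax = float(unmasked.min()), float(unmasked.max())
        span = vmax - vmin if vmax > vmin else 1.0
        values = np.clip((integrals - vmin) / span, 0.0, 1.0)
        norm_record = {"kind": "minmax", "min": vmin, "max": vmax,
                       "window": (window.low, window.high)}
    return ContrastMap(values=values, mask=mask, normalization=norm_record)
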