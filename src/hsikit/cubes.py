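"""Hyperspectral cube containers and on-disk round trip.

A hyperspectral cube is a ``rows x cols x bands`` stack where each pixel
holds a full spectrum. Cubes travel on disk as a multi-page TIFF (one page
per band, ascending wavelength) next to a JSON sidecar carrying the
spectral grid and acquisition metadata. Conventions used throughout the
package: 0-based indices, half-open ROIs, row-major arrays with the origin
at the top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "SpectralGrid",
    "RawCube",
    "ReflectanceCube",
    "AttenuationCube",
    "ROISpec",
    "read_cube",
    "write_cube",
    "band_at",
    "roi_mean_spectrum",
]

#: detector ceiling of the 16-bit camera, counts
DETECTOR_CEILING = 65535

CUBE_KINDS = ("sample", "white", "dark")


@dataclass(frozen=True)
class SpectralGrid:
    """Band-center wavelengths (nm) plus the nominal per-band FWHM (nm).

    Wavelengths must be strictly increasing and, by default, lie inside
    the instrument's 385-1015 nm scan range.
    """

    wavelengths: np.ndarray
    bandwidth: float = 5.0
    valid_range: tuple[float, float] = (385.0, 1015.0)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("grid needs at least 2 wavelengths")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        lo, hi = self.valid_range
        if wl[0] < lo or wl[-1] > hi:
            raise ValueError(f"wavelengths outside [{lo}, {hi}] nm")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def step(self) -> float:
        """Median grid step (nm)."""
        return float(np.median(np.diff(self.wavelengths)))

    def index_of(self, wavelength: float, tolerance: float | None = None) -> int:
        """Index of the band nearest ``wavelength``.

        ``tolerance`` defaults to half the median grid step. Ties between
        two equidistant bands resolve toward the lower wavelength.
        """
        if tolerance is None:
            tolerance = 0.5 * self.step
        dist = np.abs(self.wavelengths - wavelength)
        # stable argmin → lower-wavelength tie-break on the ascending grid
        idx = int(np.argmin(dist))
        if dist[idx] > tolerance:
            raise ValueError(
                f"no band within {tolerance} nm of {wavelength} nm "
                f"(nearest: {self.wavelengths[idx]} nm)"
            )
        return idx

    def window_slice(self, low: float, high: float) -> np.ndarray:
        """Boolean mask of bands with low <= wavelength <= high."""
        return (self.wavelengths >= low) & (self.wavelengths <= high)

    @classmethod
    def default(cls, low: float = 385.0, high: float = 1015.0, step: float = 5.0) -> "SpectralGrid":
        """The instrument's full scan grid: 385-1015 nm in 5-nm steps."""
        return cls(np.arange(low, high + step / 2, step), bandwidth=step)


def _check_cube_values(values: np.ndarray, grid: SpectralGrid) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError("cube values must be rows x cols x bands")
    if values.shape[2] != len(grid):
        raise ValueError(
            f"band axis ({values.shape[2]}) does not match grid ({len(grid)})"
        )
    return values


@dataclass
class RawCube:
    """Detector counts with per-band integration times.

    ``kind`` tags the acquisition role: ``sample``, ``white`` (reference
    plate) or ``dark`` (source off). ``nominal_time`` is the nominal
    integration time set in software; ``integration_times`` are the
    per-band times after the response-flattening correction.
    """

    counts: np.ndarray
    grid: SpectralGrid
    integration_times: np.ndarray
    kind: str = "sample"
    nominal_time: float = 50.0

    def __post_init__(self) -> None:
        self.counts = _check_cube_values(self.counts, self.grid)
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.integration_times = np.broadcast_to(
            np.asarray(self.integration_times, dtype=float), (len(self.grid),)
        ).copy()
        if np.any(self.integration_times <= 0):
            raise ValueError("integration times must be positive")
        if self.kind not in CUBE_KINDS:
            raise ValueError(f"kind must be one of {CUBE_KINDS}")
        if self.nominal_time <= 0:
            raise ValueError("nominal_time must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape


@dataclass
class ReflectanceCube:
    """Dimensionless reflectance R(x, y, λ) in [0, ∞), clamped at 0.

    ``clip_mask`` marks voxels where the calibration clamped a negative
    numerator or a degenerate denominator; those values are censored, not
    measured.
    """

    values: np.ndarray
    grid: SpectralGrid
    clip_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _check_cube_values(self.values, self.grid)
        if np.any(self.values < 0):
            raise ValueError("reflectance must be non-negative after clamping")
        if self.clip_mask is None:
            self.clip_mask = np.zeros(self.values.shape, dtype=bool)
        elif self.clip_mask.shape != self.values.shape:
            raise ValueError("clip_mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class AttenuationCube:
    """Attenuation A(x, y, λ) = -log10 R in optical-density units (base 10)."""

    values: np.ndarray
    grid: SpectralGrid
    floor_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _check_cube_values(self.values, self.grid)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attenuation must be finite (clamp upstream)")
        if self.floor_mask is not None and self.floor_mask.shape != self.values.shape:
            raise ValueError("floor_mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ROISpec:
    """Half-open, 0-based rectangular region: rows [row_start, row_stop)."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("ROI bounds must be non-negative")
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("ROI must be non-empty")

    def validate(self, shape: tuple[int, ...]) -> None:
        if self.row_stop > shape[0] or self.col_stop > shape[1]:
            raise ValueError(f"ROI {self} exceeds image shape {shape[:2]}")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_start, self.row_stop), slice(self.col_start, self.col_stop)

    @classmethod
    def centered(cls, shape: tuple[int, ...], fraction: float = 0.1) -> "ROISpec":
        """Centered ROI covering ``fraction`` of each spatial dimension."""
        rows, cols = shape[0], shape[1]
        h = max(1, int(round(rows * fraction)))
        w = max(1, int(round(cols * fraction)))
        r0 = (rows - h) // 2
        c0 = (cols - w) // 2
        return cls(r0, r0 + h, c0, c0 + w)


def write_cube(cube: RawCube, path: str | Path) -> None:
    """Write a cube as multi-page TIFF + JSON sidecar.

    Integer counts within the 16-bit range are stored as uint16
    (bit-exact round trip); anything else as float32.
    """
    path = Path(path)
    counts = cube.counts
    if np.issubdtype(counts.dtype, np.integer) and counts.max(initial=0) <= DETECTOR_CEILING:
        pages = counts.astype(np.uint16)
    else:
        pages = counts.astype(np.float32)
    # pages are (band, row, col) in the file, ascending wavelength
    tifffile.imwrite(path, np.moveaxis(pages, 2, 0), photometric="minisblack")
    sidecar = {
        "wavelengths_nm": cube.grid.wavelengths.tolist(),
        "bandwidth_nm": cube.grid.bandwidth,
        "integration_times_ms": cube.integration_times.tolist(),
        "kind": cube.kind,
        "nominal_time_ms": cube.nominal_time,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_cube(path: str | Path) -> RawCube:
    """Read a cube written by :func:`write_cube`.

    Raises if the sidecar is missing, the page count disagrees with the
    sidecar wavelength list, or the wavelengths are non-monotone.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    wavelengths = np.asarray(meta["wavelengths_nm"], dtype=float)
    if pages.shape[0] != wavelengths.size:
        raise ValueError(
            f"{pages.shape[0]} TIFF pages but sidecar lists {wavelengths.size} wavelengths"
        )
    grid = SpectralGrid(wavelengths, bandwidth=float(meta.get("bandwidth_nm", 5.0)))
    return RawCube(
        counts=np.moveaxis(pages, 0, 2),
        grid=grid,
        integration_times=np.asarray(meta["integration_times_ms"], dtype=float),
        kind=meta.get("kind", "sample"),
        nominal_time=float(meta.get("nominal_time_ms", 50.0)),
    )


def band_at(cube, wavelength: float, tolerance: float | None = None) -> np.ndarray:
    """The single 2-D image at the grid band nearest ``wavelength``.

    Works on any cube type carrying ``grid`` plus ``counts`` or ``values``.
    """
    idx = cube.grid.index_of(wavelength, tolerance)
    data = cube.counts if isinstance(cube, RawCube) else cube.values
    return data[:, :, idx]


def roi_mean_spectrum(cube, roi: ROISpec) -> np.ndarray:
    """Arithmetic mean spectrum over the ROI pixels, one value per band."""
    data = cube.counts if isinstance(cube, RawCube) else cube.values
    roi.validate(data.shape)
    rs, cs = roi.slices()
    return data[rs, cs, :].mean(axis=(0, 1))
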