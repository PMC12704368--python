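"""Reflectance reconstruction and attenuation conversion.

Per-pixel reflectance is recovered from a sample / white-reference / dark
cube triplet,

    R = (Is - (ts/td) Idark) / ((ts/tw) Iwhite - (ts/td) Idark),

where ts, tw, td are the nominal integration times of the three
acquisitions. Attenuation follows the Beer-Lambert law in base-10
(optical-density) units, A = -log10 R. Negative numerators (noise below
the dark level) clamp to 0, and R is floored at ``REFLECTANCE_FLOOR``
before the log so A is bounded at 4 OD — the realistic dynamic range of a
16-bit sensor.

The module also implements the integration-time flattening used to
equalize the instrument's spectral response: each band's integration time
is scaled so a white target reads a common count level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .cubes import (
    DETECTOR_CEILING,
    AttenuationCube,
    RawCube,
    ReflectanceCube,
)

__all__ = [
    "CalibrationSet",
    "TimeFactorTable",
    "compute_time_factors",
    "reflectance",
    "attenuation",
    "ReflectanceCalibrator",
    "REFLECTANCE_FLOOR",
    "DENOMINATOR_EPS",
]

#: reflectance floor applied before the log; caps attenuation at 4 OD
REFLECTANCE_FLOOR = 1e-4
#: denominators at or below this are treated as degenerate and flagged
DENOMINATOR_EPS = 1e-12
#: default flattening target as a fraction of the detector ceiling
DEFAULT_TARGET_FRACTION = 0.8


@dataclass
class CalibrationSet:
    """White and dark reference cubes sharing grid and shape."""

    white: RawCube
    dark: RawCube
    acquired_at: str | None = None

    def __post_init__(self) -> None:
        if self.white.kind != "white" or self.dark.kind != "dark":
            raise ValueError("CalibrationSet needs kind=white and kind=dark cubes")
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark shapes differ")
        if not np.array_equal(self.white.grid.wavelengths, self.dark.grid.wavelengths):
            raise ValueError("white and dark grids differ")


@dataclass
class TimeFactorTable:
    """Per-band corrected integration times (ms) flattening the response."""

    times: np.ndarray
    base_time: float
    target_level: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if not np.all(np.isfinite(self.times)) or np.any(self.times <= 0):
            raise ValueError("corrected times must be positive and finite")


def compute_time_factors(
    white_response: np.ndarray,
    base_time: float,
    target_level: float | None = None,
    saturation_cap: float = DETECTOR_CEILING,
) -> TimeFactorTable:
    """Integration times equalizing the white response across bands.

    ``white_response`` is the per-band mean white-target count measured at
    ``base_time``. Counts are assumed proportional to exposure, so
    ``time(λ) = base_time * target_level / white_response(λ)``. If any
    band's predicted counts would exceed ``saturation_cap`` the whole
    table is scaled down uniformly, preserving spectral flatness.
    """
    white_response = np.asarray(white_response, dtype=float)
    if np.any(white_response <= 0):
        raise ValueError("white response must be positive at every band")
    if target_level is None:
        target_level = DEFAULT_TARGET_FRACTION * saturation_cap
    times = base_time * target_level / white_response
    predicted = white_response * times / base_time  # == target_level per band
    worst = predicted.max()
    if worst > saturation_cap:
        times = times * (saturation_cap / worst)
    return TimeFactorTable(times=times, base_time=base_time, target_level=target_level)


def reflectance(
    sample: RawCube,
    cal: CalibrationSet,
    ts: float | None = None,
    tw: float | None = None,
    td: float | None = None,
) -> ReflectanceCube:
    """Per-voxel reflectance from a sample cube and its calibration pair.

    Nominal times default to each cube's stored ``nominal_time``;
    explicit arguments override. Degenerate denominators and negative
    numerators are clamped and flagged in ``clip_mask``.
    """
    if sample.shape != cal.white.shape:
        raise ValueError("sample and calibration shapes differ")
    if not np.array_equal(sample.grid.wavelengths, cal.white.grid.wavelengths):
        raise ValueError("sample and calibration grids differ")
    ts = sample.nominal_time if ts is None else ts
    tw = cal.white.nominal_time if tw is None else tw
    td = cal.dark.nominal_time if td is None else td

    dark = (ts / td) * cal.dark.counts.astype(float)
    num = sample.counts.astype(float) - dark
    den = (ts / tw) * cal.white.counts.astype(float) - dark

    bad_den = den <= DENOMINATOR_EPS
    if np.all(bad_den):
        raise ValueError("denominator cube is degenerate everywhere")
    neg_num = num < 0
    num = np.where(neg_num, 0.0, num)
    values = np.where(bad_den, 0.0, num / np.where(bad_den, 1.0, den))
    return ReflectanceCube(values=values, grid=sample.grid, clip_mask=bad_den | neg_num)


def attenuation(refl: ReflectanceCube, floor: float = REFLECTANCE_FLOOR) -> AttenuationCube:
    """Attenuation A = -log10(max(R, floor)) in OD units.

    The floor guarantees finite output; floored voxels are flagged in
    ``floor_mask`` (their OD is censored at -log10(floor)).
    """
    floored = refl.values < floor
    values = -np.log10(np.maximum(refl.values, floor))
    return AttenuationCube(
        values=values, grid=refl.grid, floor_mask=floored | refl.clip_mask
    )


class ReflectanceCalibrator(TransformerMixin, BaseEstimator):
    """Estimator wrapper for the reflectance/attenuation calibration.

    ``fit`` stores the white/dark reference cubes; ``transform`` maps a
    sample :class:`RawCube` to a :class:`ReflectanceCube` (or an
    :class:`AttenuationCube` with ``output="attenuation"``).

    Parameters
    ----------
    output : {"reflectance", "attenuation"}
        What ``transform`` returns.
    floor : float
        Reflectance floor applied before the log.
    ts, tw, td : float or None
        Nominal integration-time overrides; ``None`` uses each cube's
        stored nominal time.
    """

    def __init__(
        self,
        output: str = "reflectance",
        floor: float = REFLECTANCE_FLOOR,
        ts: float | None = None,
        tw: float | None = None,
        td: float | None = None,
    ):
        self.output = output
        self.floor = floor
        self.ts = ts
        self.tw = tw
        self.td = td

    def fit(self, X: CalibrationSet | tuple[RawCube, RawCube], y=None) -> "ReflectanceCalibrator":
        """Store the calibration pair. ``X`` is a CalibrationSet or (white, dark)."""
        if self.output not in ("reflectance", "attenuation"):
            raise ValueError("output must be 'reflectance' or 'attenuation'")
        if isinstance(X, CalibrationSet):
            self.calibration_ = X
        else:
            white, dark = X
            self.calibration_ = CalibrationSet(white=white, dark=dark)
        return self

    def transform(self, X: RawCube) -> ReflectanceCube | AttenuationCube:
        if not hasattr(self, "calibration_"):
            raise ValueError("ReflectanceCalibrator is not fitted")
        refl = reflectance(X, self.calibration_, ts=self.ts, tw=self.tw, td=self.td)
        if self.output == "attenuation":
            return attenuation(refl, floor=self.floor)
        return refl
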