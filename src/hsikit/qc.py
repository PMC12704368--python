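"""System-characterization metrics.

Michelson contrast between a bright and a dark ROI, signal-to-background
ratio across the field of view, temporal-stability series on repeated
phantom acquisitions, ordinary-least-squares linearity of attenuation
versus optical properties, and the USAF-1951 resolution-target line-width
arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cubes import AttenuationCube, ROISpec, band_at

__all__ = [
    "LinearFit",
    "contrast",
    "sbr",
    "stability_series",
    "linearity_fit",
    "usaf_linewidth",
    "cohort_summary",
]


@dataclass(frozen=True)
class LinearFit:
    """OLS slope/intercept/R² for attenuation vs an optical property."""

    slope: float
    intercept: float
    r_squared: float
    predictor: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


def _roi_mean(image: np.ndarray, roi: ROISpec) -> float:
    roi.validate(image.shape)
    rs, cs = roi.slices()
    return float(image[rs, cs].mean())


def contrast(image: np.ndarray, bright_roi: ROISpec, dark_roi: ROISpec) -> float:
    """Michelson contrast (Imax - Imin)/(Imax + Imin) between two ROI means.

    ROI means — not extreme pixels — define Imax and Imin, so the metric
    reflects average intensity in two representative regions. Scale
    invariant, and in [0, 1] for non-negative images with Imax >= Imin.
    """
    imax = _roi_mean(np.asarray(image, dtype=float), bright_roi)
    imin = _roi_mean(np.asarray(image, dtype=float), dark_roi)
    if imax + imin == 0:
        raise ZeroDivisionError("contrast undefined: ROI means sum to zero")
    return (imax - imin) / (imax + imin)


def sbr(signal_image: np.ndarray, background_image: np.ndarray) -> float:
    """Signal-to-background ratio: mean(signal) / mean(background) over the FOV."""
    signal_image = np.asarray(signal_image, dtype=float)
    background_image = np.asarray(background_image, dtype=float)
    if signal_image.shape != background_image.shape:
        raise ValueError("signal and background shapes differ")
    bg = background_image.mean()
    if bg <= 0:
        raise ZeroDivisionError("background mean must be positive")
    return float(signal_image.mean() / bg)


def stability_series(
    cubes: list[AttenuationCube], wavelength: float, roi: ROISpec
) -> pd.DataFrame:
    """Per-acquisition ROI mean ± sd of one band across repeated cubes.

    Returns a DataFrame with columns ``mean`` and ``sd`` (one row per
    acquisition) and the across-acquisition coefficient of variation in
    ``df.attrs["cv"]``; CV = 0 for identical cubes.
    """
    if not cubes:
        raise ValueError("need at least one cube")
    rows = []
    for cube in cubes:
        img = band_at(cube, wavelength)
        roi.validate(img.shape)
        rs, cs = roi.slices()
        patch = img[rs, cs]
        rows.append({"mean": float(patch.mean()), "sd": float(patch.std())})
    df = pd.DataFrame(rows)
    m = df["mean"].to_numpy()
    df.attrs["cv"] = float(m.std() / m.mean()) if m.mean() != 0 else np.nan
    return df


def linearity_fit(x, y, predictor: str = "") -> LinearFit:
    """Ordinary least-squares line through (x, y) with R² = 1 - SSres/SStot.

    A constant y gives slope 0 and R² = 0; a degenerate x (zero
    variance) raises rather than returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else (1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    if ss_tot == 0:
        # constant response: the fit explains nothing
        slope, r2 = 0.0, 0.0
    return LinearFit(slope=float(slope), intercept=float(intercept),
                     r_squared=min(max(r2, 0.0), 1.0), predictor=predictor)


def usaf_linewidth(group: int, element: int) -> float:
    """USAF-1951 bar width in μm, to 2 decimals.

    The chart's spatial frequency is 2^(group + (element-1)/6)
    line-pairs per mm; one bar is half a line pair, so the width is
    1000 / (2 * frequency) μm. Halves every 6 elements (one group).
    """
    if not 1 <= element <= 6:
        raise ValueError("element must be in 1..6")
    if not -2 <= group <= 9:
        raise ValueError("group outside the standard USAF-1951 range")
    resolution = 2.0 ** (group + (element - 1) / 6.0)  # lp/mm
    return round(1000.0 / (2.0 * resolution), 2)


def cohort_summary(samples: pd.DataFrame) -> dict:
    """Enrollment arithmetic for a biopsy cohort table.

    ``samples`` needs one row per enrolled case with a boolean
    ``excluded`` column (e.g. inconclusive histopathology) and
    optionally a ``grade`` column. Returns enrolled / excluded /
    analyzed counts and the per-grade breakdown of the analyzed cases.
    """
    if "excluded" not in samples.columns:
        raise ValueError("samples table needs an 'excluded' column")
    excluded = int(samples["excluded"].sum())
    analyzed = samples.loc[~samples["excluded"].astype(bool)]
    out = {
        "enrolled": int(len(samples)),
        "excluded": excluded,
        "analyzed": int(len(analyzed)),
    }
    if "grade" in samples.columns:
        out["by_grade"] = analyzed["grade"].value_counts().sort_index().to_dict()
    return out
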