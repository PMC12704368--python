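"""Two-channel NADH/FAD autofluorescence analysis.

Under 370-nm excitation, NADH emits around 450 nm and FAD around 520 nm,
but each fluorophore leaks into the other's bandpass filter. Measured
channel intensities are modeled as a linear mix of the two
concentrations,

    (I450, I520)ᵀ = C (xN, xF)ᵀ,   C = [[a, b], [c, d]],

with the cross-talk matrix C calibrated from boundary measurements on
pure-NADH and pure-FAD stock solutions (a = I450N/x̂N, b = I450F/x̂F,
c = I520N/x̂N, d = I520F/x̂F). Inverting C recovers the concentrations,
from which the optical redox ratio

    ORR = xF / (xF + xN) = 1 / (1 + xN/xF)

is a label-free metabolic index in [0, 1]: 0 for pure NADH (glycolysis
dominated), 1 for pure FAD (oxidative phosphorylation dominated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .cubes import DETECTOR_CEILING

__all__ = [
    "ChannelPair",
    "CrosstalkMatrix",
    "ORRMap",
    "calibrate_crosstalk",
    "invert_concentrations",
    "orr",
    "orr_map",
    "grade_boxstats",
    "CrosstalkModel",
]

#: |det| below this (relative to the matrix scale) counts as singular
DET_RTOL = 1e-12


@dataclass
class ChannelPair:
    """Co-registered intensity images through the 450/20 and 520/20 nm filters."""

    I450: np.ndarray
    I520: np.ndarray
    exposure: float = 200.0

    def __post_init__(self) -> None:
        self.I450 = np.asarray(self.I450, dtype=float)
        self.I520 = np.asarray(self.I520, dtype=float)
        if self.I450.shape != self.I520.shape:
            raise ValueError("channel images must share a shape")
        for img in (self.I450, self.I520):
            if np.any(img < 0) or np.any(img > DETECTOR_CEILING):
                raise ValueError("counts must lie in [0, detector ceiling]")


@dataclass(frozen=True)
class CrosstalkMatrix:
    """2x2 map from (xN, xF) μM to (I450, I520) counts.

    ``a`` and ``c`` are the NADH responses in the 450 and 520 channels;
    ``b`` and ``d`` the FAD responses. Off-diagonal terms quantify the
    spectral cross-talk.
    """

    a: float
    b: float
    c: float
    d: float
    xN_hat: float = 281.9
    xF_hat: float = 120.5

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError("cross-talk coefficients must be non-negative")
        scale = max(abs(self.a * self.d), abs(self.b * self.c), 1.0)
        if abs(self.det) <= DET_RTOL * scale:
            raise ValueError("cross-talk matrix is singular")

    @property
    def det(self) -> float:
        return self.a * self.d - self.b * self.c

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def forward(self, xN, xF) -> tuple[np.ndarray, np.ndarray]:
        """Noiseless channel intensities for concentrations (xN, xF)."""
        xN = np.asarray(xN, dtype=float)
        xF = np.asarray(xF, dtype=float)
        return self.a * xN + self.b * xF, self.c * xN + self.d * xF

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d,
                "xN_hat_uM": self.xN_hat, "xF_hat_uM": self.xF_hat}

    @classmethod
    def from_dict(cls, d: dict) -> "CrosstalkMatrix":
        return cls(a=d["a"], b=d["b"], c=d["c"], d=d["d"],
                   xN_hat=d.get("xN_hat_uM", 281.9), xF_hat=d.get("xF_hat_uM", 120.5))


@dataclass
class ORRMap:
    """Optical-redox-ratio image in [0, 1] on valid pixels.

    ``valid`` is False where xN + xF fell at or below ``eps`` (no
    fluorophore signal); ``negative_flag`` marks pixels where inversion
    produced a negative concentration that was clamped before the ratio.
    """

    values: np.ndarray
    valid: np.ndarray
    negative_flag: np.ndarray

    def __post_init__(self) -> None:
        good = self.values[self.valid]
        if good.size and (np.any(good < 0) or np.any(good > 1)):
            raise ValueError("ORR must lie in [0, 1] on valid pixels")


def calibrate_crosstalk(
    I450N: float, I520N: float, I450F: float, I520F: float,
    xN_hat: float = 281.9, xF_hat: float = 120.5,
) -> CrosstalkMatrix:
    """Cross-talk coefficients from pure-stock boundary measurements.

    ``I450N``/``I520N`` are mean intensities of the pure-NADH stock at
    concentration ``xN_hat`` (μM); ``I450F``/``I520F`` of the pure-FAD
    stock at ``xF_hat``. Raises on zero stock concentrations or a
    singular resulting matrix (proportional channel responses).
    """
    if xN_hat <= 0 or xF_hat <= 0:
        raise ValueError("stock concentrations must be positive")
    return CrosstalkMatrix(
        a=I450N / xN_hat, b=I450F / xF_hat,
        c=I520N / xN_hat, d=I520F / xF_hat,
        xN_hat=xN_hat, xF_hat=xF_hat,
    )


def invert_concentrations(pair, M: CrosstalkMatrix):
    """Recover (xN, xF) from channel intensities by inverting the mix matrix.

    ``pair`` is a :class:`ChannelPair` or an ``(I450, I520)`` tuple of
    scalars/arrays. Negative results are retained (flag downstream).
    """
    if isinstance(pair, ChannelPair):
        I450, I520 = pair.I450, pair.I520
    else:
        I450, I520 = (np.asarray(v, dtype=float) for v in pair)
    det = M.det
    xN = (M.d * I450 - M.b * I520) / det
    xF = (M.a * I520 - M.c * I450) / det
    return xN, xF


def orr(xN, xF, eps: float = 0.0):
    """Optical redox ratio xF / (xF + xN); NaN where xN + xF <= eps."""
    xN = np.asarray(xN, dtype=float)
    xF = np.asarray(xF, dtype=float)
    total = xN + xF
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total > eps, xF / np.where(total > eps, total, 1.0), np.nan)
    return out if out.ndim else float(out)


def orr_map(
    pair: ChannelPair,
    M: CrosstalkMatrix,
    dark_offset: float | tuple[float, float] = 0.0,
    eps: float = 0.0,
) -> ORRMap:
    """Pixel-level ORR map from a two-channel acquisition.

    Subtracts the per-channel dark offset, inverts the cross-talk
    matrix, clamps negative concentrations at 0 (flagging those pixels),
    and masks pixels with no net fluorophore signal.
    """
    if np.isscalar(dark_offset):
        off450 = off520 = float(dark_offset)
    else:
        off450, off520 = dark_offset
    xN, xF = invert_concentrations((pair.I450 - off450, pair.I520 - off520), M)
    negative = (xN < 0) | (xF < 0)
    xN = np.maximum(xN, 0.0)
    xF = np.maximum(xF, 0.0)
    total = xN + xF
    valid = total > eps
    values = np.where(valid, xF / np.where(valid, total, 1.0), 0.0)
    return ORRMap(values=values, valid=valid, negative_flag=negative)


def grade_boxstats(per_sample_means, grades) -> dict:
    """Tukey box-plot statistics of per-sample values grouped by grade.

    For each grade: median, 25th/75th percentiles (linear interpolation
    between order statistics), whiskers at the most extreme data points
    within 1.5 IQR of the box edges, and the remaining points as
    outliers. Raises on an empty group.
    """
    values = np.asarray(per_sample_means, dtype=float)
    grades = np.asarray(grades)
    if values.shape != grades.shape:
        raise ValueError("values and grades must align")
    if values.size == 0:
        raise ValueError("no samples to summarize")
    stats: dict = {}
    for grade in np.unique(grades):
        group = values[grades == grade]
        if group.size == 0:
            raise ValueError(f"empty group for grade {grade}")
        q25, med, q75 = np.percentile(group, [25, 50, 75])
        iqr = q75 - q25
        lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
        inside = group[(group >= lo_fence) & (group <= hi_fence)]
        outliers = group[(group < lo_fence) | (group > hi_fence)]
        stats[grade] = {
            "n": int(group.size),
            "median": float(med),
            "q25": float(q25),
            "q75": float(q75),
            "whisker_lo": float(inside.min()),
            "whisker_hi": float(inside.max()),
            "outliers": sorted(float(v) for v in outliers),
        }
    return stats


class CrosstalkModel(BaseEstimator):
    """Estimator interface to the cross-talk calibration and inversion.

    ``fit`` takes the four boundary intensities; ``transform`` maps a
    :class:`ChannelPair` (or intensity tuple) to the (xN, xF)
    concentration pair, and :meth:`orr_map` produces the redox-ratio
    image. Fitted coefficients live in ``matrix_``.
    """

    def __init__(self, xN_hat: float = 281.9, xF_hat: float = 120.5):
        self.xN_hat = xN_hat
        self.xF_hat = xF_hat

    def fit(self, X, y=None) -> "CrosstalkModel":
        """``X`` is (I450N, I520N, I450F, I520F) mean boundary intensities."""
        I450N, I520N, I450F, I520F = X
        self.matrix_ = calibrate_crosstalk(
            I450N, I520N, I450F, I520F, xN_hat=self.xN_hat, xF_hat=self.xF_hat
        )
        return self

    def transform(self, X):
        if not hasattr(self, "matrix_"):
            raise ValueError("CrosstalkModel is not fitted")
        return invert_concentrations(X, self.matrix_)

    def orr_map(self, pair: ChannelPair, dark_offset=0.0, eps: float = 0.0) -> ORRMap:
        if not hasattr(self, "matrix_"):
            raise ValueError("CrosstalkModel is not fitted")
        return orr_map(pair, self.matrix_, dark_offset=dark_offset, eps=eps)
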