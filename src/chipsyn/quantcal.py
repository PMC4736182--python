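"""Well-intensity extraction, induction fold change, exponential calibration.

The platform reads chip images with a fixed 21 x 21 pixel window centered
on each well, using only the green channel, scaled to [0, 1]. Reporter
induction is summarized as the ratio of group mean intensities in linear
space. Colorimetric assays are calibrated by an exponential curve

    conc = a * exp(b * x)

where the predictor x is (1 - intensity) for on-chip images (darker blue
means more analyte) or the OD620 absorbance off-chip. The fit is ordinary
least squares of ln(conc) on x, the standard "exponential trendline".
A multiplicative brightness factor compensates global image exposure; it
is an imaging artifact, kept out of the fitted curve and applied only at
prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "WellRegion",
    "IntensityReading",
    "InductionResult",
    "CalibrationCurve",
    "WINDOW",
    "well_mean_intensity",
    "induction_fold",
    "fit_exponential",
    "apply_calibration",
]

WINDOW = 21  # pixels per side of the sampling square


@dataclass(frozen=True)
class WellRegion:
    well_id: str
    center_x: int
    center_y: int
    window: int = WINDOW


@dataclass(frozen=True)
class IntensityReading:
    well_id: str
    mean_intensity: float
    channel: str = "green"

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_intensity <= 1.0):
            raise ValueError(
                f"{self.well_id}: intensity {self.mean_intensity} outside [0, 1]"
            )


@dataclass(frozen=True)
class InductionResult:
    induced_mean: float
    uninduced_mean: float

    @property
    def fold(self) -> float:
        return self.induced_mean / self.uninduced_mean


def _green_plane(image: np.ndarray) -> np.ndarray:
    """Green channel as float in [0, 1]; 8-bit images are divided by 255."""
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr[..., 1]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / 255.0
    else:
        arr = arr.astype(np.float64)
    return arr


def well_mean_intensity(image: np.ndarray, region: WellRegion) -> IntensityReading:
    """Mean green intensity over the region's window (441 pixels for 21 x 21)."""
    plane = _green_plane(image)
    half = region.window // 2
    y0, y1 = region.center_y - half, region.center_y + half + 1
    x0, x1 = region.center_x - half, region.center_x + half + 1
    if y0 < 0 or x0 < 0 or y1 > plane.shape[0] or x1 > plane.shape[1]:
        raise ValueError(
            f"{region.well_id}: {region.window}x{region.window} window at "
            f"({region.center_x},{region.center_y}) exceeds image bounds {plane.shape}"
        )
    mean = float(plane[y0:y1, x0:x1].mean())
    return IntensityReading(region.well_id, mean)


def induction_fold(
    induced: Sequence[IntensityReading | float],
    uninduced: Sequence[IntensityReading | float],
) -> InductionResult:
    """Group means and their ratio, in linear intensity space."""

    def values(group) -> np.ndarray:
        return np.array(
            [g.mean_intensity if isinstance(g, IntensityReading) else float(g) for g in group]
        )

    if not len(induced) or not len(uninduced):
        raise ValueError("both well groups must be non-empty")
    ind, non = values(induced), values(uninduced)
    if non.mean() == 0:
        raise ZeroDivisionError("uninduced mean intensity is zero")
    return InductionResult(float(ind.mean()), float(non.mean()))


@dataclass(frozen=True)
class CalibrationCurve:
    """conc = a * exp(b * x); x = (1 - intensity) on-chip, OD620 off-chip."""

    form: str  # 'onchip' | 'offchip'
    a: float
    b: float
    residuals: tuple[float, ...] = field(default=())  # ln-space fit residuals

    def __post_init__(self) -> None:
        if self.form not in ("onchip", "offchip"):
            raise ValueError(f"unknown curve form {self.form!r}")
        if self.a <= 0:
            raise ValueError("prefactor a must be positive")

    def predictor(self, measurement: float) -> float:
        return 1.0 - measurement if self.form == "onchip" else measurement

    def predict(self, measurement: float, brightness_factor: float = 1.0) -> float:
        return brightness_factor * self.a * np.exp(self.b * self.predictor(measurement))


def fit_exponential(
    points: Sequence[tuple[float, float]], form: str = "offchip"
) -> CalibrationCurve:
    """Least-squares fit of ln(conc) on the predictor.

    ``points`` are (predictor, concentration) pairs -- the predictor
    already on the curve's scale (OD620 off-chip, (1 - intensity)
    on-chip). Requires >= 3 points with positive concentrations.
    """
    if len(points) < 3:
        raise ValueError("calibration fit needs at least 3 points")
    x = np.array([p[0] for p in points], dtype=np.float64)
    c = np.array([p[1] for p in points], dtype=np.float64)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive for a log-linear fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: no variance")
    y = np.log(c)
    b, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + b * x)
    return CalibrationCurve(form, float(np.exp(intercept)), float(b), tuple(resid))


def apply_calibration(
    measurement: float, curve: CalibrationCurve, brightness_factor: float = 1.0
) -> float:
    """Concentration (mg/L) for one measurement under ``curve``."""
    return float(curve.predict(measurement, brightness_factor))
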