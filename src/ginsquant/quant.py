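"""External-standard calibration, LOD/LOQ and assay validation metrics.

Calibration is ordinary least squares of peak area on concentration. LOD and
LOQ are the concentrations whose predicted apex height reaches 3x and 10x
the baseline noise; with a Gaussian peak of width sigma the apex height of a
peak of area A is A / (sigma * sqrt(2*pi)), so height-per-area is fixed by
the peak shape. RSDs use the n-1 sample standard deviation throughout (the
estimator that reproduces the reported validation tables), and relative
error is reported as an absolute percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _spstats

__all__ = [
    "CalibrationCurve",
    "ValidationReport",
    "fit_curve",
    "lod_loq",
    "quantify_esm",
    "precision_accuracy",
    "stability_series",
    "rsd",
    "gaussian_height_per_area",
]


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent (n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values for an RSD")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / abs(mean))


def gaussian_height_per_area(sigma_min: float) -> float:
    """Apex height per unit area of a Gaussian peak of width *sigma_min*."""
    return 1.0 / (sigma_min * np.sqrt(2.0 * np.pi))


@dataclass
class CalibrationCurve:
    """A fitted linear response: area = slope * conc + intercept.

    Concentrations in ug/mL; LOD/LOQ in ng/mL once assigned.
    """

    analyte: str
    slope: float
    intercept: float
    r2: float
    range: tuple[float, float]
    lod: float | None = None
    loq: float | None = None

    def predict(self, conc: float) -> float:
        return self.slope * conc + self.intercept


@dataclass
class ValidationReport:
    """Per-analyte assay validation metrics, all in percent."""

    precision_rsd: dict[str, float]
    accuracy_re: dict[str, float]
    stability_rsd: dict[str, float]
    repeatability_rsd: dict[str, float]


def fit_curve(points: Sequence[tuple[float, float]], *, analyte: str = "",
              weighting: str | None = None,
              through_origin: bool = False) -> CalibrationCurve:
    """Least-squares line through (concentration, area) points.

    ``weighting="1/x"`` optionally down-weights high concentrations; the
    default is unweighted OLS. ``through_origin`` constrains the intercept
    to zero, the right model for proportional detector response. r2 is the
    squared Pearson correlation of observed and fitted areas.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least three calibration points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 3:
        raise ValueError("need at least three distinct concentrations")
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        r2 = float(np.corrcoef(y, slope * x)[0, 1] ** 2)
    elif weighting is None:
        res = _spstats.linregress(x, y)
        slope, intercept, r2 = (float(res.slope), float(res.intercept),
                                float(res.rvalue ** 2))
    elif weighting == "1/x":
        if np.any(x <= 0):
            raise ValueError("1/x weighting needs positive concentrations")
        coeffs = np.polyfit(x, y, 1, w=1.0 / np.sqrt(x))
        slope, intercept = float(coeffs[0]), float(coeffs[1])
        fitted = slope * x + intercept
        r2 = float(np.corrcoef(y, fitted)[0, 1] ** 2)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if slope <= 0:
        warnings.warn(f"{analyte or 'curve'}: fitted slope is not positive",
                      stacklevel=2)
    return CalibrationCurve(analyte=analyte, slope=slope, intercept=intercept,
                            r2=min(r2, 1.0),
                            range=(float(x.min()), float(x.max())))


def lod_loq(curve: CalibrationCurve, noise: float,
            height_per_area: float) -> tuple[float, float]:
    """Detection and quantification limits in ng/mL.

    The concentration whose predicted apex height (slope * C *
    height_per_area, i.e. the response above the calibration baseline)
    equals 3x noise gives the LOD; 10x gives the LOQ. Their ratio is 10/3 by
    construction.
    """
    if noise <= 0:
        raise ValueError("noise must be positive")
    if curve.slope <= 0:
        raise ValueError("cannot compute LOD/LOQ for a nonpositive slope")
    if height_per_area <= 0:
        raise ValueError("height_per_area must be positive")
    conc_per_noise = 1.0 / (curve.slope * height_per_area)  # ug/mL per count
    lod = 3.0 * noise * conc_per_noise * 1000.0  # -> ng/mL
    loq = 10.0 * noise * conc_per_noise * 1000.0
    return lod, loq


def quantify_esm(area: float, curve: CalibrationCurve) -> float:
    """Back-calculate concentration from a peak area: (area - b) / m.

    Emits a warning (never a silent clamp) for negative results or results
    outside the calibrated range.
    """
    conc = (area - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(f"{curve.analyte or 'analyte'}: negative back-calculated "
                      f"concentration {conc:.4g}", stacklevel=2)
    elif not curve.range[0] <= conc <= curve.range[1]:
        warnings.warn(f"{curve.analyte or 'analyte'}: concentration {conc:.4g} "
                      f"outside calibrated range {curve.range}", stacklevel=2)
    return float(conc)


def precision_accuracy(measured: Sequence[float],
                       target: float) -> tuple[float, float]:
    """(RSD%, |RE|%) of a replicate series against its nominal value."""
    arr = np.asarray(measured, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two replicates")
    if target == 0:
        raise ValueError("target must be nonzero for a relative error")
    prec = rsd(arr)
    re = float(100.0 * abs(arr.mean() - target) / abs(target))
    return prec, re


def stability_series(areas_by_timepoint: Sequence[float]) -> float:
    """RSD% of peak areas across storage timepoints (same estimator as
    precision)."""
    return rsd(areas_by_timepoint)
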