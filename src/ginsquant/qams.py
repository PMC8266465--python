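"""Single-marker quantification (QAMS) with relative response factors.

One internal reference standard (Rb2 by default) stands in for the other 24
ginsenoside standards. The relative response factor of analyte x against
reference s is the ratio of per-unit-concentration responses

    Fx = (As / Cs) / (Ax / Cx),

averaged over a series of working levels. A sample is then quantified from
the analyte's own peak area and the reference's unit response alone:

    Cx = Ax / (As / Cs) * Fx.

For proportional (zero-intercept) response this is algebraically identical
to external-standard quantification; the standard method difference

    SMD% = |C_ESM - C_QAMS| / C_ESM * 100

measures the residual discrepancy on real or noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence
import warnings

import numpy as np

from .quant import rsd

__all__ = [
    "RcfEntry",
    "QuantComparison",
    "rcf_single",
    "rcf_series",
    "quantify_qams",
    "smd",
    "rcf_robustness",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, the convention of the printed report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q,
                                                      rounding=ROUND_HALF_UP))


@dataclass
class RcfEntry:
    """Relative response factor series of one analyte against the marker."""

    analyte: str
    reference: str
    per_level: list[tuple[float, float]]  # (concentration, Fx)
    mean_fx: float
    rsd: float | None  # None for the reference itself (identically 1)


@dataclass
class QuantComparison:
    """External-standard vs single-marker result for one analyte."""

    analyte: str
    c_esm: float
    c_qams: float
    smd: float | None


def rcf_single(area_s: float, conc_s: float,
               area_x: float, conc_x: float) -> float:
    """Relative response factor from one level: (As/Cs) / (Ax/Cx)."""
    for label, v in (("area_s", area_s), ("conc_s", conc_s),
                     ("area_x", area_x), ("conc_x", conc_x)):
        if v <= 0:
            raise ValueError(f"{label} must be positive (got {v})")
    return (area_s / conc_s) / (area_x / conc_x)


def rcf_series(analyte: str,
               reference: str,
               levels: Sequence[tuple[float, float | None, float | None]]
               ) -> RcfEntry:
    """Average the per-level response factors into one calibration-free
    conversion factor.

    ``levels`` holds (concentration, analyte area, reference area) tuples;
    a missing (None or nonpositive) area drops that level with a warning.
    At least two surviving levels are required.
    """
    per_level: list[tuple[float, float]] = []
    for conc, area_x, area_s in levels:
        if (area_x is None or area_s is None
                or area_x <= 0 or area_s <= 0 or conc <= 0):
            warnings.warn(f"{analyte}: dropping level {conc} (missing peak)",
                          stacklevel=2)
            continue
        per_level.append((conc, rcf_single(area_s, conc, area_x, conc)))
    if len(per_level) < 2:
        raise ValueError(f"{analyte}: fewer than two usable levels")
    fx = [f for _, f in per_level]
    if analyte == reference:
        return RcfEntry(analyte, reference, per_level, 1.0, None)
    return RcfEntry(analyte, reference, per_level,
                    float(np.mean(fx)), rsd(fx))


def quantify_qams(area_x: float, area_s: float, conc_s: float,
                  fx: float) -> float:
    """Concentration of analyte x from its area, the reference's unit
    response As/Cs, and the relative response factor."""
    if area_s <= 0:
        raise ValueError("reference area must be positive")
    if conc_s <= 0 or fx <= 0 or area_x < 0:
        raise ValueError("inputs must be positive (area_x nonnegative)")
    return area_x / (area_s / conc_s) * fx


def smd(c_esm: float, c_qams: float) -> float:
    """Standard method difference in percent (absolute value)."""
    if c_esm <= 0:
        raise ValueError("c_esm must be positive")
    return float(100.0 * abs(c_esm - c_qams) / c_esm)


def rcf_robustness(variant_tables: Sequence[Mapping[str, tuple[float, float]]]
                   ) -> dict[str, dict[str, float]]:
    """Aggregate per-condition-variant (RCF, RT ratio) tables.

    Each variant maps analyte -> (mean RCF, relative retention time). The
    result maps analyte -> mean/RSD of both quantities across variants;
    analytes absent from any variant are dropped with a warning.
    """
    if len(variant_tables) < 2:
        raise ValueError("need at least two condition variants")
    names = set(variant_tables[0])
    for table in variant_tables[1:]:
        missing = names ^ set(table)
        for name in missing:
            warnings.warn(f"{name}: missing from a condition variant; dropped",
                          stacklevel=2)
        names &= set(table)
    out: dict[str, dict[str, float]] = {}
    for name in sorted(names):
        rcfs = [t[name][0] for t in variant_tables]
        rtrs = [t[name][1] for t in variant_tables]
        out[name] = {
            "rcf_mean": float(np.mean(rcfs)),
            "rcf_rsd": float(100.0 * np.std(rcfs, ddof=1) / np.mean(rcfs)),
            "rtr_mean": float(np.mean(rtrs)),
            "rtr_rsd": float(100.0 * np.std(rtrs, ddof=1) / np.mean(rtrs)),
        }
    return out
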