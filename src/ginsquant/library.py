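"""Built-in analyte library for the 25-ginsenoside UPLC-HRMS assay.

Two tables live here:

``STANDARD_LIBRARY``
    The 25 authentic standards used for quantification, each with molecular
    formula, retention time on the C18 gradient, aglycone class, the reported
    linear calibration law (peak area vs concentration in ug/mL) and its
    valid range, plus the canonical glycosidic neutral-loss sequence observed
    in negative-mode MS/MS.

``REFERENCE_COMPOUNDS``
    The 43-compound identification table for *Panax ginseng* root extracts:
    printed adduct m/z values ([M+HCOO]- and [M-H]-), MS/MS fragment ions,
    and the assigned aglycone class. Two rows carry known [M-H]- misprints
    (flagged ``mz_typo``); the Rh2 row's printed formula contradicted its
    printed m/z 621.4372 and is stored with the m/z-consistent C36H62O8.

Reported single-marker validation values (per-level relative response
factors against Rb2, and the ESM/QAMS method-comparison concentrations) are
kept in ``REPORTED_RCF_SERIES`` and ``REPORTED_METHOD_COMPARISON`` so that
the arithmetic of the published tables can be recomputed from this package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .masses import monoisotopic_mass, mz_mh

__all__ = [
    "AnalyteSpec",
    "ReferenceCompound",
    "STANDARD_LIBRARY",
    "REFERENCE_COMPOUNDS",
    "REPORTED_RCF_SERIES",
    "REPORTED_RCF_LEVELS_NG_ML",
    "REPORTED_METHOD_COMPARISON",
    "DEFAULT_REFERENCE",
    "get_analyte",
    "zero_intercept_library",
]

AGLYCONE_CLASSES = ("PPT", "PPD", "OA", "other")

#: QAMS internal reference marker
DEFAULT_REFERENCE = "Rb2"


@dataclass(frozen=True)
class AnalyteSpec:
    """One target ginsenoside standard.

    The calibration law is ``area = slope * conc + intercept`` with
    concentration in ug/mL and area in arbitrary detector counts x minutes.
    ``losses`` is the ordered glycosidic residue sequence lost from the
    [M-H]- precursor down to the aglycone ion in MS/MS.
    """

    name: str
    formula: str
    rt_min: float
    aglycone_class: str
    slope: float
    intercept: float
    cal_range: tuple[float, float]
    losses: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rt_min <= 0:
            raise ValueError(f"{self.name}: rt_min must be positive")
        if self.slope <= 0:
            raise ValueError(f"{self.name}: slope must be positive")
        low, high = self.cal_range
        if not low < high:
            raise ValueError(f"{self.name}: cal_range low must be < high")
        if self.aglycone_class not in AGLYCONE_CLASSES:
            raise ValueError(f"{self.name}: unknown class {self.aglycone_class!r}")
        monoisotopic_mass(self.formula)  # raises on junk

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def mz(self) -> float:
        """Theoretical [M-H]- m/z, the quantification channel."""
        return mz_mh(self.formula)

    def predicted_area(self, conc: float, *, zero_intercept: bool = False) -> float:
        """Peak area the calibration law predicts at *conc* ug/mL."""
        if zero_intercept:
            return self.slope * conc
        return self.slope * conc + self.intercept


@dataclass(frozen=True)
class ReferenceCompound:
    """One row of the 43-compound identification table."""

    number: int
    name: str
    formula: str
    rt_min: float
    mz_formate_printed: float | None
    mz_mh_printed: float
    fragments: tuple[float, ...]
    aglycone_class: str  # assigned class; "other" for dehydrated species
    is_aglycone: bool = False
    mz_typo: bool = False  # printed [M-H]- inconsistent with formula


def _a(name, formula, rt, cls, slope, intercept, lo, hi, losses) -> AnalyteSpec:
    return AnalyteSpec(name, formula, rt, cls, slope, intercept, (lo, hi),
                       tuple(losses))


# name, formula, RT (min), class, slope, intercept, cal range (ug/mL),
# MS/MS neutral-loss sequence down to the aglycone.
STANDARD_LIBRARY: tuple[AnalyteSpec, ...] = (
    _a("Rg1", "C42H72O14", 1.46, "PPT", 64984.0, 980287.0, 0.02, 2.0, ["Glc", "Glc"]),
    _a("Re", "C48H82O18", 1.46, "PPT", 41225.1, 688583.0, 0.02, 2.0, ["Rha", "Glc", "Glc"]),
    _a("Rf", "C42H72O14", 4.08, "PPT", 42146.9, -44017.1, 0.01, 0.5, ["Glc", "Glc"]),
    _a("Rh1", "C36H62O9", 5.02, "PPT", 238413.0, -153145.0, 0.002, 0.2, ["Glc"]),
    _a("Rg2", "C42H72O13", 5.08, "PPT", 52298.5, -612776.0, 0.05, 1.0, ["Rha", "Glc"]),
    _a("Rb1", "C54H92O23", 5.44, "PPD", 6240.95, 85602.4, 0.02, 2.0, ["Glc", "Glc", "Glc", "Glc"]),
    _a("Rc", "C53H90O22", 6.09, "PPD", 22275.0, -24796.1, 0.01, 1.0, ["Pen", "Glc", "Glc", "Glc"]),
    _a("F1", "C36H62O9", 6.73, "PPT", 292355.0, -175557.0, 0.002, 0.2, ["Glc"]),
    _a("Rb2", "C53H90O22", 7.13, "PPD", 20778.7, -36514.3, 0.01, 1.0, ["Pen", "Glc", "Glc", "Glc"]),
    _a("Rb3", "C53H90O22", 7.59, "PPD", 20695.1, 48835.8, 0.05, 2.0, ["Pen", "Glc", "Glc", "Glc"]),
    _a("Rd", "C48H82O18", 9.25, "PPD", 61029.8, -558838.0, 0.1, 2.0, ["Glc", "Glc", "Glc"]),
    _a("GXVII", "C48H82O18", 10.07, "PPD", 85248.5, -57819.7, 0.002, 0.2, ["Glc", "Glc", "Glc"]),
    _a("nFe", "C47H80O17", 10.8, "PPD", 29919.9, -7299.02, 0.002, 0.2, ["Pen", "Glc", "Glc"]),
    _a("CO", "C47H80O17", 11.61, "PPD", 31396.7, -13591.7, 0.001, 0.2, ["Pen", "Glc", "Glc"]),
    _a("nFd", "C47H80O17", 12.01, "PPD", 20835.8, -25094.8, 0.01, 0.2, ["Pen", "Glc", "Glc"]),
    _a("F2", "C42H72O13", 13.68, "PPD", 212189.0, -115446.0, 0.002, 0.2, ["Glc", "Glc"]),
    _a("PPT", "C30H52O4", 14.75, "PPT", 27249.2, -50845.3, 0.002, 0.05, []),
    _a("G75", "C42H72O13", 15.63, "PPD", 231218.0, -99660.6, 0.001, 0.2, ["Glc", "Glc"]),
    _a("Rg3", "C42H72O13", 15.89, "PPD", 149379.0, -82845.1, 0.002, 0.2, ["Glc", "Glc"]),
    _a("Mc", "C41H70O12", 17.29, "PPD", 58309.3, -14125.5, 0.001, 0.2, ["Pen", "Glc"]),
    _a("CY", "C41H70O12", 18.02, "PPD", 41233.6, 36194.0, 0.001, 0.2, ["Pen", "Glc"]),
    _a("CMx", "C41H70O12", 18.46, "PPD", 80902.7, -22662.5, 0.002, 0.2, ["Pen", "Glc"]),
    _a("CK", "C36H62O8", 19.31, "PPD", 140955.0, 96724.4, 0.001, 0.2, ["Glc"]),
    _a("Rh2", "C36H62O8", 19.6, "PPD", 316346.0, -188172.0, 0.002, 0.2, ["Glc"]),
    _a("PPD", "C30H52O3", 20.99, "PPD", 3099.89, -4843.21, 0.002, 0.2, []),
)


def _r(number, name, formula, rt, fmt, mh, frags, cls, **kw) -> ReferenceCompound:
    return ReferenceCompound(number, name, formula, rt, fmt, mh, tuple(frags),
                             cls, **kw)


REFERENCE_COMPOUNDS: tuple[ReferenceCompound, ...] = (
    _r(1, "20-Glc-Rf", "C48H82O19", 1.05, 1007.5447, 961.5384,
       (799.4883, 637.4325, 475.3785), "PPT"),
    _r(2, "nR1", "C47H80O18", 1.17, 977.5344, 931.5288,
       (799.4872, 637.4320, 475.3792), "PPT"),
    _r(3, "Rg1", "C42H72O14", 1.42, 845.4910, 799.4869,
       (637.4324, 475.3803), "PPT"),
    _r(4, "Re", "C48H82O18", 1.46, 991.5502, 945.5451,
       (799.4931, 783.4944, 637.4338, 475.3784), "PPT"),
    _r(5, "Rf", "C42H72O14", 4.05, 845.4898, 799.4855,
       (637.4332, 475.3791), "PPT"),
    _r(6, "Ra3", "C59H100O27", 4.33, 1285.6436, 1239.6372,
       (1107.6023, 945.5419, 783.4863, 621.4360), "PPD"),
    _r(7, "F3/F5", "C41H70O13", 4.48, 815.4810, 769.4754,
       (637.4333, 475.3789), "PPT"),
    _r(8, "Rh1", "C36H62O9", 4.96, 683.4381, 637.4322,
       (475.3778,), "PPT"),
    _r(9, "Rg2", "C42H72O13", 5.03, 829.4963, 783.4898,
       (637.4306, 475.3807), "PPT"),
    _r(10, "Ra2", "C58H98O26", 5.23, 1255.6328, 1209.6276,
       (1077.5858, 945.5414, 783.4915, 621.4380, 459.3847), "PPD"),
    _r(11, "Rb1", "C54H92O23", 5.40, 1153.6014, 1107.5956,
       (945.5421, 783.4899, 621.4374, 459.3840), "PPD"),
    _r(12, "Rc", "C53H90O22", 6.06, 1123.5912, 1077.5854,
       (945.5413, 783.4907, 621.4377, 459.3847), "PPD"),
    _r(13, "Ra2-isomer", "C58H98O26", 6.27, 1255.6329, 1209.6266,
       (1077.5870, 945.5418, 783.4917, 459.3863), "PPD"),
    _r(14, "Ro", "C48H76O19", 6.44, None, 955.4915,
       (793.4398, 631.3837, 455.3540), "OA"),
    _r(15, "F1", "C36H62O9", 6.64, 683.4385, 637.4288,
       (475.3827,), "PPT"),
    _r(16, "Ra1", "C58H98O26", 6.68, 1255.6334, 1209.6271,
       (1077.5790, 783.4831, 621.4320), "PPD"),
    _r(17, "Rb2", "C53H90O22", 7.09, 1123.5912, 1077.5859,
       (945.5415, 783.4908, 621.4387, 459.3847), "PPD"),
    _r(18, "Rb3", "C53H90O22", 7.48, 1123.5916, 1077.5838,
       (945.5406, 783.4916, 621.4372, 459.3855), "PPD"),
    _r(19, "Ra1-isomer", "C58H98O26", 8.03, 1255.6338, 1209.6284,
       (1077.5868, 945.5466, 783.4907, 621.4337, 459.3868), "PPD"),
    _r(20, "CS-IVa", "C42H66O14", 8.91, None, 793.4395,
       (631.3858, 455.3555), "OA"),
    _r(21, "Rd", "C48H82O18", 9.21, 991.5497, 945.5438,
       (783.4911, 621.4377, 459.3850), "PPD"),
    _r(22, "GXVII", "C48H82O18", 10.01, 991.5506, 945.5432,
       (783.4890, 621.4405), "PPD"),
    _r(23, "nFe", "C47H80O17", 10.74, 961.5374, 915.5348,
       (783.4901, 621.4399, 459.3845), "PPD"),
    _r(24, "CO", "C47H80O17", 11.17, 961.5401, 915.5327,
       (783.4915, 621.4379, 459.3847), "PPD"),
    _r(25, "nFd", "C47H80O17", 11.54, 961.5401, 915.5330,
       (783.4908, 621.4370, 459.3854), "PPD"),
    _r(26, "Rg6", "C42H70O12", 12.09, 811.4872, 765.4798,
       (619.4215,), "other"),
    _r(27, "Rk3", "C36H60O8", 12.51, 665.4287, 619.3349, (), "other",
       mz_typo=True),
    _r(28, "F4", "C42H70O12", 12.90, 811.4871, 765.4786,
       (619.4219, 457.3643), "other"),
    _r(29, "Rh4", "C36H60O8", 13.24, 665.4284, 619.3344, (), "other",
       mz_typo=True),
    _r(30, "F2", "C42H72O13", 13.62, 829.4974, 783.4861,
       (621.4400, 459.3816), "PPD"),
    _r(31, "PPT", "C30H52O4", 14.69, 521.3853, 475.3792, (), "PPT",
       is_aglycone=True),
    _r(32, "GD3a", "C42H66O14", 14.70, None, 793.4392,
       (613.3735, 455.3517), "OA"),
    _r(33, "G75", "C42H72O13", 15.51, 829.4975, 783.4913,
       (621.4393, 459.3844), "PPD"),
    _r(34, "Rg3", "C42H72O13", 15.79, 829.4951, 783.4912,
       (621.4393, 459.3845), "PPD"),
    _r(35, "20(R)-Rg3", "C42H72O13", 16.28, 829.4974, 783.4905,
       (621.4382, 459.3864), "PPD"),
    _r(36, "Mc", "C41H70O12", 17.31, 799.4866, 753.4793,
       (621.4371, 459.3869), "PPD"),
    _r(37, "CY", "C41H70O12", 17.94, 799.4868, 753.4804,
       (621.4374, 459.3866), "PPD"),
    _r(38, "CMx", "C41H70O12", 18.42, 799.4869, 753.4770,
       (621.4406, 459.3858), "PPD"),
    _r(39, "CK", "C36H62O8", 19.30, 667.4473, 621.4392,
       (459.3828,), "PPD"),
    _r(40, "Rk1", "C42H70O12", 19.46, 811.4865, 765.4803,
       (603.4224,), "other"),
    _r(41, "Rg5", "C42H70O12", 19.55, 811.4869, 765.4843,
       (603.4230,), "other"),
    # printed formula C53H90O22 contradicts printed m/z 621.4372; stored with
    # the m/z-consistent monoglucosyl-PPD formula
    _r(42, "Rh2", "C36H62O8", 19.59, 667.4438, 621.4372,
       (459.3831,), "PPD"),
    _r(43, "PPD", "C30H52O3", 20.99, 505.3909, 459.3843, (), "PPD",
       is_aglycone=True),
)


#: relative-response-factor working levels (ng/mL of each analyte)
REPORTED_RCF_LEVELS_NG_ML: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0, 200.0)

#: reported per-level relative response factors vs Rb2 (one value per level
#: above); the reference's own row is identically 1
REPORTED_RCF_SERIES: Mapping[str, tuple[float, ...]] = {
    "Rb2": (1.00, 1.00, 1.00, 1.00, 1.00),
    "Rg1": (0.32, 0.30, 0.31, 0.30, 0.30),
    "Re": (0.48, 0.46, 0.47, 0.48, 0.46),
    "Rf": (0.48, 0.48, 0.52, 0.48, 0.50),
    "Rb1": (3.45, 3.25, 3.05, 3.18, 3.22),
    "Rg2": (0.44, 0.43, 0.46, 0.42, 0.42),
    "Rh1": (0.09, 0.09, 0.09, 0.09, 0.08),
    "Rc": (0.93, 0.88, 0.94, 0.94, 0.92),
    "F1": (0.07, 0.08, 0.08, 0.08, 0.08),
    "Rb3": (0.97, 0.97, 0.98, 0.99, 0.98),
    "Rd": (0.36, 0.34, 0.35, 0.34, 0.34),
    "GXVII": (0.24, 0.24, 0.25, 0.23, 0.24),
    "nFe": (0.62, 0.67, 0.66, 0.69, 0.68),
    "CO": (0.60, 0.62, 0.63, 0.66, 0.65),
    "nFd": (1.05, 1.00, 1.05, 0.99, 1.05),
    "F2": (0.10, 0.10, 0.09, 0.10, 0.10),
    "G75": (0.09, 0.09, 0.09, 0.08, 0.09),
    "Rg3": (0.14, 0.14, 0.14, 0.13, 0.14),
    "PPT": (1.00, 0.97, 0.95, 0.99, 1.01),
    "Mc": (0.33, 0.34, 0.34, 0.36, 0.34),
    "CY": (0.47, 0.48, 0.50, 0.49, 0.47),
    "CMx": (0.24, 0.25, 0.25, 0.26, 0.25),
    "CK": (0.14, 0.13, 0.14, 0.15, 0.14),
    "Rh2": (0.06, 0.07, 0.07, 0.07, 0.07),
    "PPD": (6.48, 6.95, 6.67, 6.98, 6.45),
}

#: reported method comparison on ginseng root: analyte -> (ESM, QAMS, SMD%)
#: in mg/g dry root; the internal reference has no SMD entry
REPORTED_METHOD_COMPARISON: Mapping[str, tuple[float, float, float | None]] = {
    "Rg1": (53.85, 53.80, 0.10),
    "Re": (151.28, 143.83, 4.92),
    "Rf": (29.34, 29.47, 0.46),
    "Rb1": (324.15, 316.05, 2.50),
    "Rg2": (29.22, 30.21, 3.38),
    "Rh1": (1.39, 1.35, 2.54),
    "Rc": (97.77, 96.82, 0.97),
    "F1": (0.55, 0.57, 2.52),
    "Rb2": (112.03, 112.03, None),
    "Rb3": (17.94, 17.88, 0.38),
    "Rd": (97.66, 98.03, 0.38),
    "GXVII": (2.56, 2.54, 0.91),
    "nFe": (3.92, 3.71, 5.33),
    "CO": (2.22, 2.20, 0.52),
    "nFd": (1.75, 1.76, 0.50),
    "F2": (1.25, 1.24, 0.71),
    "G75": (0.11, 0.10, 5.45),
    "Rg3": (2.95, 2.86, 3.05),
    "PPT": (1.03, 1.01, 1.53),
    "Mc": (0.91, 0.88, 3.69),
    "CY": (2.42, 2.42, 0.21),
    "CMx": (0.38, 0.37, 1.40),
    "CK": (1.42, 1.41, 0.18),
    "Rh2": (0.33, 0.32, 4.12),
    "PPD": (0.47, 0.46, 2.09),
}


def get_analyte(name: str,
                library: Sequence[AnalyteSpec] = STANDARD_LIBRARY) -> AnalyteSpec:
    for spec in library:
        if spec.name == name:
            return spec
    raise KeyError(f"analyte {name!r} not in library")


def zero_intercept_library(
        library: Sequence[AnalyteSpec] = STANDARD_LIBRARY) -> tuple[AnalyteSpec, ...]:
    """The same library with all intercepts forced to zero.

    Single-marker quantification is exact only for proportional response, so
    identity round-trip tests run on this variant.
    """
    return tuple(replace(spec, intercept=0.0) for spec in library)
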