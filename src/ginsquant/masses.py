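"""Monoisotopic mass and adduct arithmetic for negative-mode saponin MS.

All masses are monoisotopic and in Da. Ion m/z values include the electron
mass: [M-H]- is M minus a proton (1.007276 Da), not M minus a hydrogen atom.
This distinction is ~0.001 Da and matters at Orbitrap mass accuracy.
"""

from __future__ import annotations

from pyteomics import mass as _ptmass

__all__ = [
    "PROTON",
    "ELECTRON",
    "monoisotopic_mass",
    "adduct_mz",
    "mz_mh",
    "mz_formate",
    "ADDUCTS",
]

ELECTRON = 0.00054857990907


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass of a neutral molecular formula (e.g. ``"C54H92O23"``).

    Raises
    ------
    ValueError
        If the formula cannot be parsed.
    """
    if not formula or not isinstance(formula, str):
        raise ValueError(f"unparseable formula: {formula!r}")
    try:
        return float(_ptmass.calculate_mass(formula=formula))
    except Exception as exc:  # pyteomics raises PyteomicsError subclasses
        raise ValueError(f"unparseable formula: {formula!r}") from exc


#: H atom minus electron, from the same atomic-mass table as the formulas so
#: that adduct identities hold exactly
PROTON = monoisotopic_mass("H") - ELECTRON

#: neutral-loss / adduct building blocks
MASS_H2O = monoisotopic_mass("H2O")
MASS_HCOOH = monoisotopic_mass("CH2O2")
#: formate anion HCOO- (radical mass plus one electron)
MASS_FORMATE_ANION = monoisotopic_mass("CHO2") + ELECTRON

ADDUCTS = ("[M-H]-", "[M+HCOO]-")


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged negative adduct of a neutral of given mass.

    Supported adducts: ``[M-H]-`` (deprotonation) and ``[M+HCOO]-``
    (formate attachment). Their difference is exactly the HCOOH mass.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    if adduct == "[M-H]-":
        return neutral_mass - PROTON
    if adduct == "[M+HCOO]-":
        return neutral_mass + MASS_FORMATE_ANION
    raise ValueError(f"unknown adduct: {adduct!r} (supported: {ADDUCTS})")


def mz_mh(formula: str) -> float:
    """Theoretical [M-H]- m/z of a formula."""
    return adduct_mz(monoisotopic_mass(formula), "[M-H]-")


def mz_formate(formula: str) -> float:
    """Theoretical [M+HCOO]- m/z of a formula."""
    return adduct_mz(monoisotopic_mass(formula), "[M+HCOO]-")


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative deviation of *observed* from *theoretical* in ppm."""
    return (observed - theoretical) / theoretical * 1e6
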