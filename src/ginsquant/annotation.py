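"""Rule-based ginsenoside identification from negative-mode HRMS data.

Ginsenosides are triterpene saponins: an aglycone backbone — protopanaxatriol
(PPT, C30H52O4), protopanaxadiol (PPD, C30H52O3) or oleanolic acid (OA,
C30H48O3) — carrying glycosyl residues. In negative-mode MS/MS the glycosidic
bonds cleave, shedding dehydrated sugar units (hexose 162 Da, deoxyhexose
146 Da, pentose 132 Da, glucuronosyl 176 Da) until the bare [aglycone-H]-
ion remains near m/z 475, 459 or 455. Identification therefore reduces to a
small integer decomposition problem: which multiset of residue masses
connects a precursor to an aglycone within tolerance?

The xylose/arabinopyranose/arabinofuranose pentoses are exactly isobaric and
are collapsed into a single "Pen" residue. Dehydrated ginsenosides (Rk1,
Rg5, Rg6, F4, Rh4, Rk3) carry a water-loss-modified aglycone; they match no
path unless the search is extended with one H2O loss (``allow_h2o``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .library import AnalyteSpec, ReferenceCompound
from .masses import MASS_H2O, monoisotopic_mass, mz_mh, ppm_error
from .synthetic import MsmsSpectrum, RESIDUE_FORMULAS

__all__ = [
    "RESIDUE_MASSES",
    "AGLYCONES",
    "AglyconeDef",
    "SugarLossPath",
    "Annotation",
    "decompose_losses",
    "classify_compound",
    "classify_library",
    "isomer_groups",
    "annotate_spectrum",
]

#: glycosidic residue neutral-loss masses (Da, monoisotopic)
RESIDUE_MASSES: Mapping[str, float] = {
    name: monoisotopic_mass(formula)
    for name, formula in RESIDUE_FORMULAS.items() if name != "H2O"
}


@dataclass(frozen=True)
class AglyconeDef:
    """One aglycone backbone and its deprotonated ion."""

    name: str
    formula: str

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def mz(self) -> float:
        return mz_mh(self.formula)


AGLYCONES: tuple[AglyconeDef, ...] = (
    AglyconeDef("PPT", "C30H52O4"),
    AglyconeDef("PPD", "C30H52O3"),
    AglyconeDef("OA", "C30H48O3"),
)

_AGLYCONE_MZ = {a.name: a.mz for a in AGLYCONES}


@dataclass(frozen=True)
class SugarLossPath:
    """A decomposition of a precursor into residue losses ending at an
    aglycone ion."""

    precursor_mz: float
    losses: tuple[str, ...]  # residue names, canonical order
    terminal_class: str
    ppm_error: float
    water_losses: int = 0

    @property
    def n_residues(self) -> int:
        return len(self.losses)

    @property
    def n_kinds(self) -> int:
        return len(set(self.losses))


@dataclass
class Annotation:
    """A scored candidate identity for one MS/MS spectrum."""

    candidate: str
    precursor_ppm: float
    ladder_coverage: float
    loss_path: tuple[str, ...]
    terminal_class: str
    rt_delta: float | None
    low_confidence: bool


_CANONICAL_RESIDUE_ORDER = ("Glc", "Rha", "Pen", "GlcA")


def decompose_losses(precursor_mz: float,
                     residues: Mapping[str, float] = RESIDUE_MASSES,
                     aglycones: Sequence[AglyconeDef] = AGLYCONES,
                     max_residues: int = 8,
                     ppm_tol: float = 5.0,
                     allow_h2o: bool = False) -> list[SugarLossPath]:
    """All residue multisets of size <= max_residues whose removal from the
    precursor lands on an aglycone [M-H]- within ppm_tol.

    Paths are ranked by |ppm error|, then fewer residues, then fewer distinct
    residue kinds, then aglycone name. An empty list is a valid outcome.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    if max_residues > 8:
        raise ValueError("max_residues capped at 8")
    names = sorted(residues, key=lambda r: (
        _CANONICAL_RESIDUE_ORDER.index(r)
        if r in _CANONICAL_RESIDUE_ORDER else 99, r))
    paths: list[SugarLossPath] = []
    for size in range(0, max_residues + 1):
        for combo in itertools.combinations_with_replacement(names, size):
            loss_total = sum(residues[r] for r in combo)
            for n_h2o in range(0, 2 if allow_h2o else 1):
                residual = precursor_mz - loss_total - n_h2o * MASS_H2O
                if residual <= 0:
                    continue
                for agly in aglycones:
                    dev = ppm_error(residual, agly.mz)
                    if abs(dev) <= ppm_tol:
                        paths.append(SugarLossPath(
                            precursor_mz=precursor_mz, losses=tuple(combo),
                            terminal_class=agly.name, ppm_error=dev,
                            water_losses=n_h2o))
    # rank on the absolute Da deviation (bucketed at 0.1 mDa) so that
    # formula-exact isobaric paths — identical in Da but not in ppm, which
    # is normalised by different aglycone masses — tie and fall through to
    # the structural tie-breaks
    def _key(p: SugarLossPath):
        abs_da = abs(p.ppm_error) * 1e-6 * _AGLYCONE_MZ[p.terminal_class]
        return (round(abs_da, 4), p.n_residues + p.water_losses,
                p.n_kinds, p.terminal_class)

    paths.sort(key=_key)
    return paths


def _ms2_supported(path: SugarLossPath, fragments: Sequence[float],
                   aglycone_mz: Mapping[str, float],
                   ppm_tol: float) -> bool:
    """Does the observed spectrum contain this path's terminal aglycone ion?"""
    target = aglycone_mz[path.terminal_class]
    return any(abs(ppm_error(f, target)) <= ppm_tol for f in fragments)


def classify_compound(formula: str,
                      fragments: Sequence[float] = (),
                      ppm_tol: float = 5.0,
                      fragment_ppm_tol: float = 10.0,
                      allow_h2o: bool = False) -> SugarLossPath | None:
    """Best sugar-loss decomposition of a formula's theoretical [M-H]-.

    Several aglycone/residue combinations are exactly isobaric (e.g.
    PPT + Glc + Rha vs PPD + 2 Glc), so precursor mass alone cannot always
    decide the backbone. Candidate paths whose terminal aglycone ion is
    actually present in the observed MS/MS fragments are preferred; remaining
    ties fall back to the decomposition ranking (fewest residues, then
    fewest residue kinds — saponin sugar chains are predominantly glucose).
    Returns None when nothing matches.
    """
    precursor = mz_mh(formula)
    paths = decompose_losses(precursor, ppm_tol=ppm_tol, allow_h2o=allow_h2o)
    if not paths:
        return None
    if fragments:
        agly_mz = {a.name: a.mz for a in AGLYCONES}
        supported = [p for p in paths
                     if _ms2_supported(p, fragments, agly_mz, fragment_ppm_tol)]
        if supported:
            return supported[0]
    return paths[0]


def classify_library(entries: Iterable[ReferenceCompound | tuple[str, str]],
                     ppm_tol: float = 5.0,
                     allow_h2o: bool = False) -> dict[str, object]:
    """Classify a compound table by aglycone backbone.

    Entries are ReferenceCompound records (whose MS/MS fragments help break
    isobaric ties) or bare (name, formula) pairs. Returns per-class name
    lists, bare-aglycone names, and glycoside counts that exclude the
    zero-residue (bare aglycone) matches. Unmatched entries land in
    ``"other"``. Order-independent and idempotent.
    """
    classes: dict[str, list[str]] = {"PPT": [], "PPD": [], "OA": [],
                                     "other": []}
    aglycone_entries: list[str] = []
    for entry in entries:
        if isinstance(entry, ReferenceCompound):
            name, formula, frags = entry.name, entry.formula, entry.fragments
        else:
            name, formula = entry
            frags = ()
        best = classify_compound(formula, frags, ppm_tol=ppm_tol,
                                 allow_h2o=allow_h2o)
        if best is None:
            classes["other"].append(name)
        elif best.n_residues == 0 and best.water_losses == 0:
            aglycone_entries.append(name)
        else:
            classes[best.terminal_class].append(name)
    return {
        "classes": classes,
        "aglycones": aglycone_entries,
        "counts": {cls: len(members) for cls, members in classes.items()},
    }


def isomer_groups(library: Sequence[AnalyteSpec]) -> list[list[str]]:
    """Partition the library by nominal (integer-rounded) [M-H]- m/z.

    Only groups of two or more co-nominal analytes are returned, ordered by
    m/z; members must have distinct retention times (they are expected to be
    chromatographically resolved)."""
    if not library:
        raise ValueError("empty library")
    names = [s.name for s in library]
    if len(set(names)) != len(names):
        raise ValueError("duplicate analyte names in library")
    buckets: dict[int, list[AnalyteSpec]] = {}
    for spec in library:
        buckets.setdefault(int(round(spec.mz)), []).append(spec)
    groups = []
    for nominal in sorted(buckets):
        members = buckets[nominal]
        if len(members) < 2:
            continue
        rts = [m.rt_min for m in members]
        if len(set(rts)) != len(rts):
            raise ValueError(
                f"isomer group at nominal m/z {nominal} has co-eluting "
                f"members: {[m.name for m in members]}")
        groups.append([m.name for m in sorted(members, key=lambda s: s.rt_min)])
    return groups


def _expected_ladder(spec: AnalyteSpec, ppm_tol: float) -> list[float]:
    """Fragment m/z ladder a candidate standard should produce, from its
    canonical loss sequence (or, failing that, its best decomposition)."""
    losses = spec.losses
    if not losses:
        path = classify_compound(spec.formula, ppm_tol=ppm_tol)
        losses = path.losses if path is not None else ()
    mz = mz_mh(spec.formula)
    ladder = []
    for res in losses:
        mz -= RESIDUE_MASSES[res]
        ladder.append(mz)
    return ladder


def annotate_spectrum(spectrum: MsmsSpectrum,
                      library: Sequence[AnalyteSpec],
                      ppm_tol: float = 10.0,
                      rt_tol_min: float | None = None) -> list[Annotation]:
    """Rank library candidates against one product-ion spectrum.

    Candidates must match the precursor within ppm_tol; they are scored by
    the fraction of their expected neutral-loss ladder found among the
    fragments (coverage), with ties broken by retention-time proximity when
    the spectrum carries one (isobaric ginsenosides share identical ladders
    and are only separable chromatographically), then by precursor mass
    error. Coverage below 0.5 flags the annotation low-confidence.
    """
    if spectrum.precursor_mz <= 0:
        raise ValueError("spectrum has no precursor")
    observed = spectrum.mz_values()
    results: list[Annotation] = []
    for spec in library:
        theo = mz_mh(spec.formula)
        prec_dev = ppm_error(spectrum.precursor_mz, theo)
        if abs(prec_dev) > ppm_tol:
            continue
        ladder = _expected_ladder(spec, ppm_tol)
        if ladder:
            hits = sum(1 for step in ladder
                       if any(abs(ppm_error(f, step)) <= ppm_tol
                              for f in observed))
            coverage = hits / len(ladder)
        else:
            # bare aglycone: nothing to fragment, precursor match suffices
            coverage = 1.0 if not observed else 0.0
        rt_delta = (abs(spectrum.rt_min - spec.rt_min)
                    if spectrum.rt_min is not None else None)
        if rt_tol_min is not None and rt_delta is not None \
                and rt_delta > rt_tol_min:
            continue
        results.append(Annotation(
            candidate=spec.name, precursor_ppm=prec_dev,
            ladder_coverage=coverage, loss_path=tuple(spec.losses),
            terminal_class=spec.aglycone_class, rt_delta=rt_delta,
            low_confidence=coverage < 0.5))
    results.sort(key=lambda a: (-a.ladder_coverage,
                                a.rt_delta if a.rt_delta is not None else 0.0,
                                abs(a.precursor_ppm)))
    return results
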