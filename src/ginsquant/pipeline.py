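"""End-to-end workflows tying generation, peak measurement, calibration,
single-marker quantification and validation together.

These are the functions the command-line interface and the reproduction
script call; each stage consumes the previous stage's in-memory products and
every quantity is measured from the chromatograms, never read from the truth
block (which exists only for oracle checks in the test-suite).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .chrom import PeakMeasurement, extract_xic, estimate_noise, integrate_peak
from .library import (AnalyteSpec, DEFAULT_REFERENCE,
                      REPORTED_METHOD_COMPARISON, REPORTED_RCF_LEVELS_NG_ML)
from .qams import (QuantComparison, RcfEntry, quantify_qams, rcf_series,
                   round_half_up, smd)
from .quant import CalibrationCurve, ValidationReport, fit_curve, quantify_esm
from .synthetic import SyntheticRun, SyntheticRunConfig, make_sample_run, \
    make_standard_series

__all__ = [
    "measure_run",
    "calibrate",
    "build_rcf_table",
    "compare_methods",
    "comparison_table",
    "validation_metrics",
    "scaled_sample_concs",
    "DEFAULT_CAL_LEVELS",
]

#: working-solution dilution levels of the mixed standard (ug/mL)
DEFAULT_CAL_LEVELS: tuple[float, ...] = (
    0.001, 0.002, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)

_WINDOW_SIGMAS = 4.0


def measure_run(run: SyntheticRun,
                library: Sequence[AnalyteSpec],
                ppm: float = 20.0) -> dict[str, PeakMeasurement]:
    """Integrate every library analyte's peak in *run*.

    Each analyte is read from its own [M-H]- channel in a +/-4 sigma window
    around its (condition-scaled) retention time; when the run carries
    baseline noise it is estimated per channel with all expected peak
    windows excluded, and feeds both bound detection and S/N.
    """
    config = run.config
    sigma = config.peak_sigma_min
    half = _WINDOW_SIGMAS * sigma
    # per channel: expected peak windows (noise exclusion) and apex times
    # (isobaric neighbours, for window clipping at the midpoint)
    windows_by_mz: dict[float, list[tuple[float, float]]] = {}
    apexes_by_mz: dict[float, list[float]] = {}
    for spec in library:
        rt = spec.rt_min * config.rt_scale
        key = round(spec.mz, 2)
        windows_by_mz.setdefault(key, []).append((rt - 2 * half, rt + 2 * half))
        apexes_by_mz.setdefault(key, []).append(rt)
    out: dict[str, PeakMeasurement] = {}
    for spec in library:
        xic = extract_xic(run, spec.mz, ppm)
        key = round(spec.mz, 2)
        noise = None
        if config.baseline_sd > 0:
            noise = estimate_noise(xic, windows_by_mz[key])
        rt = spec.rt_min * config.rt_scale
        t0, t1 = rt - half, rt + half
        # isobaric analytes are chromatographically resolved: never integrate
        # past the midpoint toward a neighbouring peak on the same channel
        for other in apexes_by_mz[key]:
            if other < rt:
                t0 = max(t0, (other + rt) / 2)
            elif other > rt:
                t1 = min(t1, (other + rt) / 2)
        out[spec.name] = integrate_peak(
            xic, (t0, t1), noise=noise, analyte=spec.name)
    return out


def _mean_measure(library: Sequence[AnalyteSpec],
                  make_run, config: SyntheticRunConfig,
                  n_injections: int, tag: str) -> dict[str, float]:
    """Average measured areas over replicate injections (the assay injects
    every solution in sextuplicate)."""
    sums = {s.name: 0.0 for s in library}
    for j in range(n_injections):
        run = make_run(f"{tag}-inj{j}")
        measured = measure_run(run, library)
        for name, peak in measured.items():
            sums[name] += peak.area
    return {name: total / n_injections for name, total in sums.items()}


def calibrate(library: Sequence[AnalyteSpec],
              config: SyntheticRunConfig,
              levels: Sequence[float] = DEFAULT_CAL_LEVELS,
              n_injections: int = 6,
              ) -> dict[str, CalibrationCurve]:
    """Fit one curve per analyte from a generated standard series.

    Each level is injected ``n_injections`` times and the mean area used.
    Levels outside an analyte's calibrated range are skipped for that
    analyte, as on the bench; with a proportional-response config the fit is
    constrained through the origin to match the generative model.
    """
    usable: dict[str, list[float]] = {
        s.name: [lv for lv in levels
                 if s.cal_range[0] <= lv <= s.cal_range[1]]
        for s in library}
    areas: dict[str, list[tuple[float, float]]] = {s.name: [] for s in library}
    for level in levels:
        concs = {s.name: level for s in library}
        mean_areas = _mean_measure(
            library,
            lambda lab, c=concs: make_sample_run(library, c, config, label=lab),
            config, n_injections, f"cal-{level:g}")
        for spec in library:
            if level in usable[spec.name]:
                areas[spec.name].append((level, mean_areas[spec.name]))
    proportional = config.zero_intercept or all(
        s.intercept == 0 for s in library)
    return {name: fit_curve(pts, analyte=name, through_origin=proportional)
            for name, pts in areas.items() if len(pts) >= 3}


def build_rcf_table(library: Sequence[AnalyteSpec],
                    config: SyntheticRunConfig,
                    reference: str = DEFAULT_REFERENCE,
                    levels_ng_ml: Sequence[float] = REPORTED_RCF_LEVELS_NG_ML,
                    ) -> dict[str, RcfEntry]:
    """Relative response factors of every analyte against the marker from a
    generated working-level series (levels in ng/mL)."""
    names = {s.name for s in library}
    if reference not in names:
        raise KeyError(f"reference {reference!r} not in library")
    levels_ug = [lv / 1000.0 for lv in levels_ng_ml]
    runs = make_standard_series(library, levels_ug, config)
    measured = [measure_run(run, library) for run in runs]
    table: dict[str, RcfEntry] = {}
    for spec in library:
        rows = []
        for lv, m in zip(levels_ug, measured):
            ax = m[spec.name].area
            as_ = m[reference].area
            rows.append((lv, ax if ax > 0 else None, as_ if as_ > 0 else None))
        table[spec.name] = rcf_series(spec.name, reference, rows)
    return table


def scaled_sample_concs(library: Sequence[AnalyteSpec],
                        contents: Mapping[str, Sequence[float]] | None = None,
                        divisor: float = 400.0) -> dict[str, float]:
    """Map reported root contents (mg/g) onto injectable concentrations.

    The assay's extract-to-injection dilution is not part of the method
    definition, so contents are scaled by a nominal *divisor* and clipped
    into each analyte's calibrated range (ug/mL).
    """
    if contents is None:
        contents = {k: v for k, v in REPORTED_METHOD_COMPARISON.items()}
    out = {}
    for spec in library:
        if spec.name not in contents:
            continue
        value = contents[spec.name][0]
        low, high = spec.cal_range
        out[spec.name] = float(min(max(value / divisor, low), high))
    return out


def compare_methods(library: Sequence[AnalyteSpec],
                    sample_concs: Mapping[str, float],
                    config: SyntheticRunConfig,
                    reference: str = DEFAULT_REFERENCE,
                    rcf_levels_ng_ml: Sequence[float] = REPORTED_RCF_LEVELS_NG_ML,
                    ref_level_ng_ml: float | None = None,
                    n_injections: int = 6,
                    ) -> list[QuantComparison]:
    """Quantify one sample both ways and report the per-analyte SMD.

    External-standard curves come from each analyte's own calibration
    levels; relative response factors from a generated working series at
    the ng/mL levels; the single-marker route then uses only the
    reference's peak in that series plus the factors. Every solution is
    injected ``n_injections`` times and mean areas are used, matching the
    assay's sextuplicate injection scheme.
    """
    levels_ug = [lv / 1000.0 for lv in rcf_levels_ng_ml]
    mean_series: list[dict[str, float]] = []
    for level in levels_ug:
        concs = {s.name: level for s in library}
        mean_series.append(_mean_measure(
            library,
            lambda lab, c=concs: make_sample_run(library, c, config, label=lab),
            config, n_injections, f"rcf-{level:g}"))

    curves = calibrate(library, config, n_injections=n_injections)

    rcf_table: dict[str, RcfEntry] = {}
    for spec in library:
        rows = [(lv, m[spec.name] or None, m[reference] or None)
                for lv, m in zip(levels_ug, mean_series)]
        rcf_table[spec.name] = rcf_series(spec.name, reference, rows)

    if ref_level_ng_ml is None:
        ref_level_ng_ml = max(rcf_levels_ng_ml)
    ref_idx = list(rcf_levels_ng_ml).index(ref_level_ng_ml)
    conc_s = levels_ug[ref_idx]
    area_s = mean_series[ref_idx][reference]

    sample_areas = _mean_measure(
        library,
        lambda lab: make_sample_run(library, sample_concs, config, label=lab),
        config, n_injections, "sample")

    out: list[QuantComparison] = []
    for spec in library:
        if spec.name not in sample_concs:
            continue
        area_x = sample_areas[spec.name]
        c_esm = quantify_esm(area_x, curves[spec.name])
        c_qams = quantify_qams(area_x, area_s, conc_s,
                               rcf_table[spec.name].mean_fx)
        delta = smd(c_esm, c_qams) if spec.name != reference else None
        out.append(QuantComparison(analyte=spec.name, c_esm=c_esm,
                                   c_qams=c_qams, smd=delta))
    return out


def comparison_table(comparisons: Sequence[QuantComparison],
                     rounded: bool = True) -> pd.DataFrame:
    """Method-comparison report (No., analyte, ESM, QAMS, SMD%)."""
    rows = []
    for i, comp in enumerate(comparisons, start=1):
        esm, qams_, delta = comp.c_esm, comp.c_qams, comp.smd
        if rounded:
            esm, qams_ = round_half_up(esm, 4), round_half_up(qams_, 4)
            delta = round_half_up(delta, 2) if delta is not None else None
        rows.append({"No.": i, "Ginsenoside": comp.analyte, "ESM": esm,
                     "QAMS": qams_, "SMD%": delta})
    return pd.DataFrame(rows)


def validation_metrics(library: Sequence[AnalyteSpec],
                       config: SyntheticRunConfig,
                       n_replicates: int = 6,
                       target_ug_ml: float = 0.2,
                       n_timepoints: int = 6) -> ValidationReport:
    """Assay validation on generated replicates.

    Precision/accuracy: *n* replicate injections of the mixed standard at
    the target level, back-calculated through each analyte's proportional
    response. Stability: areas across storage timepoints. Repeatability:
    areas across independent preparations. All RSDs use the n-1 estimator.
    """
    def replicate_areas(tag: str, count: int) -> dict[str, list[float]]:
        areas: dict[str, list[float]] = {s.name: [] for s in library}
        for i in range(count):
            run = make_sample_run(
                library, {s.name: target_ug_ml for s in library},
                config, label=f"{tag}-{i}")
            measured = measure_run(run, library)
            for name, peak in measured.items():
                areas[name].append(peak.area)
        return areas

    from .quant import precision_accuracy, rsd as _rsd

    prec_areas = replicate_areas("precision", n_replicates)
    stab_areas = replicate_areas("stability", n_timepoints)
    rept_areas = replicate_areas("repeatability", n_replicates)

    precision, accuracy, stability, repeatability = {}, {}, {}, {}
    for spec in library:
        # proportional response: concentration = area / slope
        concs = [a / spec.slope for a in prec_areas[spec.name]]
        p, re = precision_accuracy(concs, target_ug_ml)
        precision[spec.name] = p
        accuracy[spec.name] = re
        stability[spec.name] = _rsd(stab_areas[spec.name])
        repeatability[spec.name] = _rsd(rept_areas[spec.name])
    return ValidationReport(precision_rsd=precision, accuracy_re=accuracy,
                            stability_rsd=stability,
                            repeatability_rsd=repeatability)
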