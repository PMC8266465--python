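"""Readers and writers: runs as long-format CSV + JSON truth sidecar,
analyte library CSV, MS/MS spectra as MGF or two-column peak lists, peak
tables as CSV. All writers are deterministic (stable row order, fixed float
formats) so repeated runs with the same seed produce identical files."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .chrom import PeakMeasurement
from .library import AnalyteSpec
from .synthetic import Channel, MsmsSpectrum, SyntheticRun, SyntheticRunConfig

__all__ = [
    "write_run",
    "read_run",
    "write_library",
    "read_library",
    "write_spectra_mgf",
    "read_spectra_mgf",
    "read_peaklist_csv",
    "write_peak_table",
]

LIBRARY_COLUMNS = ["name", "formula", "rt_min", "class", "slope", "intercept",
                   "range_low", "range_high", "losses"]


def write_run(run: SyntheticRun, stem: Path | str) -> tuple[Path, Path]:
    """Write a run as ``<stem>.csv`` (channel_mz, time_min, intensity) and
    ``<stem>.json`` (truth block + config echo)."""
    stem = Path(stem)
    frames = []
    for ch in run.channels:
        frames.append(pd.DataFrame({
            "channel_mz": np.round(ch.mz, 4),
            "time_min": ch.time,
            "intensity": ch.intensity,
        }))
    table = pd.concat(frames, ignore_index=True)
    # suffixes are appended, not substituted: stems like "standard_0.001"
    # contain dots
    csv_path = stem.parent / (stem.name + ".csv")
    table.to_csv(csv_path, index=False, float_format="%.6f")
    sidecar = {
        "label": run.label,
        "truth": run.truth,
        "config": dataclasses.asdict(run.config),
    }
    json_path = stem.parent / (stem.name + ".json")
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return csv_path, json_path


def read_run(stem: Path | str) -> SyntheticRun:
    """Round-trip counterpart of :func:`write_run`."""
    stem = Path(stem)
    table = pd.read_csv(stem.parent / (stem.name + ".csv"))
    sidecar = json.loads((stem.parent / (stem.name + ".json")).read_text())
    channels = []
    for mz, grp in table.groupby("channel_mz", sort=True):
        channels.append(Channel(mz=float(mz),
                                time=grp["time_min"].to_numpy(),
                                intensity=grp["intensity"].to_numpy()))
    config = SyntheticRunConfig(**sidecar["config"])
    return SyntheticRun(channels=channels, truth=sidecar["truth"],
                        config=config, label=sidecar.get("label", ""))


def write_library(library: Sequence[AnalyteSpec], path: Path | str) -> Path:
    path = Path(path)
    rows = []
    for s in library:
        rows.append({
            "name": s.name, "formula": s.formula, "rt_min": s.rt_min,
            "class": s.aglycone_class, "slope": s.slope,
            "intercept": s.intercept, "range_low": s.cal_range[0],
            "range_high": s.cal_range[1], "losses": ";".join(s.losses),
        })
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(path, index=False)
    return path


def read_library(path: Path | str) -> tuple[AnalyteSpec, ...]:
    table = pd.read_csv(Path(path), keep_default_na=False)
    specs = []
    for row in table.to_dict("records"):
        losses = tuple(x for x in str(row["losses"]).split(";") if x)
        specs.append(AnalyteSpec(
            name=str(row["name"]), formula=str(row["formula"]),
            rt_min=float(row["rt_min"]), aglycone_class=str(row["class"]),
            slope=float(row["slope"]), intercept=float(row["intercept"]),
            cal_range=(float(row["range_low"]), float(row["range_high"])),
            losses=losses))
    return tuple(specs)


def write_spectra_mgf(spectra: Sequence[MsmsSpectrum], path: Path | str) -> Path:
    path = Path(path)
    entries = []
    for i, sp in enumerate(spectra):
        mzs = np.array([mz for mz, _ in sp.fragments], dtype=float)
        intens = np.array([inten for _, inten in sp.fragments], dtype=float)
        params = {"title": sp.analyte or f"spectrum-{i}",
                  "pepmass": (sp.precursor_mz, None),
                  "charge": "1-"}
        if sp.rt_min is not None:
            params["rtinseconds"] = sp.rt_min * 60.0
        entries.append({"params": params, "m/z array": mzs,
                        "intensity array": intens})
    _mgf.write(entries, str(path), file_mode="w")
    return path


def read_spectra_mgf(path: Path | str) -> list[MsmsSpectrum]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            rt_s = params.get("rtinseconds")
            spectra.append(MsmsSpectrum(
                precursor_mz=float(params["pepmass"][0]),
                fragments=list(zip(entry["m/z array"].tolist(),
                                   entry["intensity array"].tolist())),
                rt_min=float(rt_s) / 60.0 if rt_s is not None else None,
                analyte=params.get("title")))
    return spectra


def read_peaklist_csv(path: Path | str,
                      precursor_mz: float,
                      rt_min: float | None = None) -> MsmsSpectrum:
    """Two-column (m/z, intensity) CSV peak list for one precursor."""
    table = pd.read_csv(Path(path))
    mz_col, int_col = table.columns[:2]
    return MsmsSpectrum(precursor_mz=precursor_mz,
                        fragments=list(zip(table[mz_col].astype(float),
                                           table[int_col].astype(float))),
                        rt_min=rt_min)


def write_peak_table(peaks: Sequence[PeakMeasurement], path: Path | str) -> Path:
    path = Path(path)
    rows = [{"analyte": p.analyte, "rt_apex": round(p.rt_apex, 4),
             "area": p.area, "height": p.height, "snr": round(p.snr, 2)}
            for p in peaks]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
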