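"""Synthetic UPLC-HRMS run generation.

Emulates the statistical structure the downstream quantification assumes:
each analyte elutes as a Gaussian peak centred at its library retention time
on its own [M-H]- channel, with true peak area given by its calibration law,
multiplicative lognormal area dispersion (injection-to-injection RSD), and
additive Gaussian baseline noise on every channel. Isobaric analytes share a
channel and are separated in time, as on the real instrument.

Randomness is fully deterministic: one master seed, with per-analyte and
per-channel substreams derived from stable name hashes, so adding an analyte
to the library never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .library import AnalyteSpec
from .masses import mz_mh

__all__ = [
    "SyntheticRunConfig",
    "Channel",
    "SyntheticRun",
    "MsmsSpectrum",
    "make_standard_series",
    "make_sample_run",
    "make_msms_spectrum",
    "RESIDUE_FORMULAS",
]

SQRT_2PI = float(np.sqrt(2.0 * np.pi))

#: glycosidic residue losses (dehydrated sugar units) usable in spectra
RESIDUE_FORMULAS: Mapping[str, str] = {
    "Glc": "C6H10O5",
    "Rha": "C6H10O4",
    "Pen": "C5H8O4",
    "GlcA": "C6H8O6",
    "H2O": "H2O",
}


@dataclass(frozen=True)
class SyntheticRunConfig:
    """Generator settings.

    peak_sigma_min
        Gaussian chromatographic peak width (one sigma, minutes).
    baseline_sd
        Additive baseline noise standard deviation (intensity counts).
    baseline_level
        Constant baseline offset; defaults to 6 x baseline_sd so that
        clipping at zero never truncates the noise distribution.
    area_cv
        Coefficient of variation of the multiplicative lognormal factor
        applied to each true peak area.
    sampling_hz
        Acquisition rate in points per second.
    zero_intercept
        Force all calibration intercepts to zero (proportional response).
    rt_scale
        Uniform retention-time stretch, emulating flow-rate/temperature
        condition variants.
    """

    peak_sigma_min: float = 0.05
    baseline_sd: float = 0.0
    baseline_level: float | None = None
    area_cv: float = 0.0
    sampling_hz: float = 5.0
    seed: int = 0
    zero_intercept: bool = False
    rt_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.peak_sigma_min <= 0:
            raise ValueError("peak_sigma_min must be positive")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be nonnegative")
        if self.area_cv < 0:
            raise ValueError("area_cv must be nonnegative")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.rt_scale <= 0:
            raise ValueError("rt_scale must be positive")

    @property
    def effective_baseline(self) -> float:
        if self.baseline_level is not None:
            return self.baseline_level
        return 6.0 * self.baseline_sd


@dataclass
class Channel:
    """One targeted [M-H]- trace: time in minutes, intensity in counts."""

    mz: float
    time: np.ndarray
    intensity: np.ndarray


@dataclass
class SyntheticRun:
    """A generated run plus its ground truth.

    ``truth`` maps analyte name to ``{"conc": ug/mL, "area": true area,
    "rt": apex minutes, "mz": channel}``. The truth block is what identity
    round-trip tests quantify against.
    """

    channels: list[Channel]
    truth: dict[str, dict[str, float]]
    config: SyntheticRunConfig
    label: str = ""

    def channel_mzs(self) -> list[float]:
        return [c.mz for c in self.channels]


@dataclass
class MsmsSpectrum:
    """A centroided product-ion spectrum of one precursor."""

    precursor_mz: float
    fragments: list[tuple[float, float]]  # (m/z, intensity)
    rt_min: float | None = None
    analyte: str | None = None

    def mz_values(self) -> list[float]:
        return [mz for mz, _ in self.fragments]


def _substream(seed: int, name: str, salt: str = "") -> np.random.Generator:
    key = zlib.crc32(f"{salt}:{name}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _time_grid(library: Sequence[AnalyteSpec], config: SyntheticRunConfig) -> np.ndarray:
    rt_max = max(s.rt_min for s in library) * config.rt_scale
    t_end = rt_max + max(0.5, 8 * config.peak_sigma_min)
    n = int(np.ceil(t_end * 60.0 * config.sampling_hz)) + 1
    return np.linspace(0.0, t_end, n)


def _true_area(spec: AnalyteSpec, conc: float, config: SyntheticRunConfig,
               rng: np.random.Generator) -> float:
    area = spec.predicted_area(conc, zero_intercept=config.zero_intercept)
    if conc == 0.0 and config.zero_intercept:
        return 0.0
    if area <= 0:
        raise ValueError(
            f"{spec.name}: calibration law predicts nonpositive area "
            f"({area:.1f}) at {conc} ug/mL; cannot synthesise a peak")
    if config.area_cv > 0:
        sigma = np.sqrt(np.log1p(config.area_cv ** 2))
        # mean-one lognormal factor
        area *= rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma)
    return float(area)


def _build_run(library: Sequence[AnalyteSpec],
               concs: Mapping[str, float],
               config: SyntheticRunConfig,
               label: str) -> SyntheticRun:
    if not library:
        raise ValueError("empty analyte library")
    names = {s.name for s in library}
    for name in concs:
        if name not in names:
            raise KeyError(f"analyte {name!r} named in concentrations but "
                           "missing from library")
    for name, c in concs.items():
        if c < 0:
            raise ValueError(f"{name}: negative concentration {c}")

    time = _time_grid(library, config)
    # isobaric analytes share one channel keyed by rounded theoretical m/z
    channel_map: dict[float, np.ndarray] = {}
    truth: dict[str, dict[str, float]] = {}
    for spec in library:
        mz = round(mz_mh(spec.formula), 4)
        signal = channel_map.setdefault(mz, np.zeros_like(time))
        conc = float(concs.get(spec.name, 0.0))
        if spec.name in concs:
            rng = _substream(config.seed, spec.name, label)
            area = _true_area(spec, conc, config, rng)
            rt = spec.rt_min * config.rt_scale
            if area > 0:
                sigma = config.peak_sigma_min
                height = area / (sigma * SQRT_2PI)
                signal += height * np.exp(-0.5 * ((time - rt) / sigma) ** 2)
            truth[spec.name] = {"conc": conc, "area": area, "rt": rt, "mz": mz}

    channels = []
    for mz in sorted(channel_map):
        intensity = channel_map[mz] + config.effective_baseline
        if config.baseline_sd > 0:
            rng = _substream(config.seed, f"{mz:.4f}", f"noise:{label}")
            intensity = intensity + rng.normal(0.0, config.baseline_sd,
                                               size=time.size)
        intensity = np.clip(intensity, 0.0, None)
        channels.append(Channel(mz=mz, time=time.copy(), intensity=intensity))
    return SyntheticRun(channels=channels, truth=truth, config=config,
                        label=label)


def make_standard_series(library: Sequence[AnalyteSpec],
                         levels: Sequence[float],
                         config: SyntheticRunConfig) -> list[SyntheticRun]:
    """One mixed-standard run per concentration level (all analytes at the
    same nominal concentration, as in a serial dilution of a working mix)."""
    if not library:
        raise ValueError("empty analyte library")
    runs = []
    for i, level in enumerate(levels):
        if level < 0:
            raise ValueError(f"negative concentration level {level}")
        concs = {s.name: level for s in library}
        runs.append(_build_run(library, concs, config, label=f"std-{i}-{level:g}"))
    return runs


def make_sample_run(library: Sequence[AnalyteSpec],
                    true_concs: Mapping[str, float],
                    config: SyntheticRunConfig,
                    label: str = "sample") -> SyntheticRun:
    """A single run with per-analyte true concentrations (a 'sample')."""
    return _build_run(library, dict(true_concs), config, label=label)


def make_msms_spectrum(analyte: AnalyteSpec,
                       losses: Sequence[str] | None = None,
                       intensities: Sequence[float] | None = None) -> MsmsSpectrum:
    """Fragment ladder spectrum: precursor [M-H]- minus cumulative residues.

    ``losses`` defaults to the analyte's canonical loss sequence. Fragments
    get unit intensity unless ``intensities`` is given.
    """
    from .masses import monoisotopic_mass  # residue masses

    if losses is None:
        losses = analyte.losses
    precursor = mz_mh(analyte.formula)
    frags: list[tuple[float, float]] = []
    mz = precursor
    for i, res in enumerate(losses):
        if res not in RESIDUE_FORMULAS:
            raise KeyError(f"unknown residue {res!r}")
        mz -= monoisotopic_mass(RESIDUE_FORMULAS[res])
        if mz <= 0:
            raise ValueError(
                f"cumulative loss exceeds precursor mass at step {i + 1}")
        inten = 1.0 if intensities is None else float(intensities[i])
        frags.append((mz, inten))
    return MsmsSpectrum(precursor_mz=precursor, fragments=frags,
                        rt_min=analyte.rt_min, analyte=analyte.name)
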