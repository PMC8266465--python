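"""Extracted-ion chromatograms, peak integration, noise/SNR estimation and
relative-retention-time peak localisation.

Conventions: time in minutes throughout; areas in intensity x minutes;
windows are closed intervals. S/N is apex height over the baseline standard
deviation. Integration is trapezoidal on the baseline-subtracted trace
between bounds found by descending from the apex until the trace falls to
baseline + k*noise (or turns back up at a valley between adjacent peaks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as _spsignal

from .synthetic import SyntheticRun

__all__ = [
    "XIC",
    "PeakMeasurement",
    "RelativeRT",
    "EmptyXICError",
    "PeakNotFoundError",
    "extract_xic",
    "extract_xic_scans",
    "integrate_peak",
    "estimate_noise",
    "snr",
    "detect_peaks",
    "locate_peak_by_rtr",
]


class EmptyXICError(LookupError):
    """No channel / no signal within the requested m/z tolerance."""


class PeakNotFoundError(LookupError):
    """No candidate peak satisfied the relative-retention-time match."""


@dataclass
class XIC:
    """An extracted ion chromatogram for one target m/z."""

    target_mz: float
    ppm_window: float
    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.size != self.intensity.size or self.time.size < 2:
            raise ValueError("time and intensity must be equal length >= 2")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class PeakMeasurement:
    """One integrated chromatographic peak."""

    analyte: str
    rt_apex: float
    area: float
    height: float
    snr: float
    bounds: tuple[float, float]


@dataclass(frozen=True)
class RelativeRT:
    """Retention time of an analyte divided by the internal reference's."""

    value: float
    reference: str

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("relative retention time must be positive")


def extract_xic(run: SyntheticRun, mz: float, ppm: float) -> XIC:
    """Pull the channel of *run* whose m/z lies within *ppm* of *mz*.

    If several channels qualify, the nearest wins. Raises
    :class:`EmptyXICError` when none does.
    """
    if ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    best = None
    best_dev = ppm
    for channel in run.channels:
        dev = abs(channel.mz - mz) / mz * 1e6
        if dev <= best_dev:
            best, best_dev = channel, dev
    if best is None:
        raise EmptyXICError(
            f"no channel within {ppm} ppm of m/z {mz}; run has "
            f"{[round(c.mz, 4) for c in run.channels]}")
    return XIC(target_mz=mz, ppm_window=ppm, time=best.time,
               intensity=best.intensity)


def extract_xic_scans(scans: Iterable[Mapping], mz: float, ppm: float) -> XIC:
    """Build an XIC from centroided MS1 scans (pyteomics-style dicts with
    ``m/z array``, ``intensity array`` and a scan start time in minutes under
    ``rt_min`` or the mzML ``scanList`` layout), summing intensity inside the
    ppm window per scan."""
    if ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    half = mz * ppm * 1e-6
    times, intensities = [], []
    for scan in scans:
        if "rt_min" in scan:
            rt = float(scan["rt_min"])
        else:  # mzML layout
            rt = float(scan["scanList"]["scan"][0]["scan start time"])
        mz_arr = np.asarray(scan["m/z array"], dtype=float)
        int_arr = np.asarray(scan["intensity array"], dtype=float)
        mask = np.abs(mz_arr - mz) <= half
        times.append(rt)
        intensities.append(float(int_arr[mask].sum()))
    if len(times) < 2 or not any(i > 0 for i in intensities):
        raise EmptyXICError(f"no signal within {ppm} ppm of m/z {mz}")
    order = np.argsort(times)
    return XIC(target_mz=mz, ppm_window=ppm,
               time=np.asarray(times)[order],
               intensity=np.asarray(intensities)[order])


def estimate_noise(xic: XIC,
                   exclude: Sequence[tuple[float, float]] = ()) -> float:
    """Baseline noise: standard deviation of the trace outside the excluded
    windows, after median subtraction. Needs >= 20 baseline points."""
    mask = np.ones(xic.time.size, dtype=bool)
    for t0, t1 in exclude:
        mask &= ~((xic.time >= t0) & (xic.time <= t1))
    pts = xic.intensity[mask]
    if pts.size < 20:
        raise ValueError(
            f"only {pts.size} baseline points left after exclusion (need 20)")
    resid = pts - np.median(pts)
    return float(np.std(resid, ddof=1))


def snr(peak: PeakMeasurement, noise: float) -> float:
    """Signal-to-noise ratio: apex height over baseline noise."""
    if noise <= 0:
        raise ValueError("noise must be positive for a defined S/N")
    return peak.height / noise


def _baseline_of(xic: XIC, window: tuple[float, float]) -> float:
    outside = xic.intensity[(xic.time < window[0]) | (xic.time > window[1])]
    if outside.size >= 20:
        return float(np.median(outside))
    return float(np.median(xic.intensity))


def integrate_peak(xic: XIC, window: tuple[float, float], *,
                   noise: float | None = None, k: float = 3.0,
                   baseline: float | None = None,
                   analyte: str = "") -> PeakMeasurement:
    """Integrate the largest peak inside *window*.

    The apex is the intensity maximum in the window; bounds walk outward
    from the apex until the baseline-subtracted trace drops below k*noise or
    starts rising again (valley between neighbouring peaks). Area is the
    trapezoidal integral of the baseline-subtracted trace between bounds,
    floored at zero.
    """
    t0, t1 = window
    idx = np.where((xic.time >= t0) & (xic.time <= t1))[0]
    if idx.size == 0:
        raise ValueError(f"window {window} does not overlap the XIC time span")
    if baseline is None:
        baseline = _baseline_of(xic, window)
    sub = xic.intensity - baseline
    if noise is None:
        noise = 0.0
    threshold = k * noise

    win = sub[idx]
    apex_local = int(np.argmax(win))
    apex = idx[apex_local]
    # a short centred average tempers the selection bias of a raw argmax on
    # noisy traces (an apex-max estimator overstates height at low S/N)
    a0, a1 = max(apex - 2, 0), min(apex + 3, sub.size)
    height = float(np.mean(sub[a0:a1]))
    if height <= 0 or np.all(win <= threshold):
        rt = float(xic.time[idx[apex_local]])
        return PeakMeasurement(analyte=analyte, rt_apex=rt, area=0.0,
                               height=max(height, 0.0), snr=0.0,
                               bounds=(float(t0), float(t1)))

    def _walk(start: int, step: int, limit: int) -> int:
        cur = start
        while cur != limit:
            nxt = cur + step
            v = sub[nxt]
            if v <= threshold:
                cur = nxt  # include the first at/below-threshold point
                break
            if v > sub[cur] and sub[cur] < 0.05 * height:
                break  # valley before a neighbouring peak
            cur = nxt
        return cur

    lo = _walk(apex, -1, int(idx[0]))
    hi = _walk(apex, +1, int(idx[-1]))
    area = float(np.trapezoid(sub[lo:hi + 1], xic.time[lo:hi + 1]))
    ratio = height / noise if noise > 0 else 0.0
    return PeakMeasurement(analyte=analyte, rt_apex=float(xic.time[apex]),
                           area=max(area, 0.0), height=height, snr=ratio,
                           bounds=(float(xic.time[lo]), float(xic.time[hi])))


def detect_peaks(xic: XIC, *, noise: float | None = None, k: float = 3.0,
                 min_height: float | None = None,
                 analyte: str = "") -> list[PeakMeasurement]:
    """Find and integrate all local maxima rising min_height (default
    10*noise, or 0.1% of the trace maximum on noise-free traces) above
    baseline."""
    baseline = float(np.median(xic.intensity))
    sub = xic.intensity - baseline
    if min_height is None:
        if noise and noise > 0:
            min_height = 10.0 * noise
        else:
            min_height = 1e-3 * float(sub.max()) if sub.max() > 0 else np.inf
    peaks, _ = _spsignal.find_peaks(sub, height=min_height,
                                    prominence=min_height / 2)
    out = []
    dt = float(np.median(np.diff(xic.time)))
    for p in peaks:
        t_apex = float(xic.time[p])
        # generous window; integrate_peak trims at valleys/threshold
        window = (t_apex - 50 * dt, t_apex + 50 * dt)
        out.append(integrate_peak(xic, window, noise=noise, k=k,
                                  baseline=baseline, analyte=analyte))
    return out


def locate_peak_by_rtr(candidates: Sequence[PeakMeasurement],
                       reference_peak: PeakMeasurement,
                       expected: RelativeRT,
                       tol: float = 0.05) -> PeakMeasurement:
    """Pick the candidate whose RT ratio to the reference is nearest the
    expected relative retention time and within *tol* (a fraction of the
    expected value). Ties go to the larger area."""
    if not 0 < tol <= 0.2:
        raise ValueError("tol must be in (0, 0.2]")
    if reference_peak.rt_apex <= 0:
        raise ValueError("reference peak has nonpositive retention time")
    scored = []
    for peak in candidates:
        rtr = peak.rt_apex / reference_peak.rt_apex
        dev = abs(rtr - expected.value) / expected.value
        if dev <= tol:
            scored.append((dev, -peak.area, peak))
    if not scored:
        seen = [round(p.rt_apex / reference_peak.rt_apex, 4)
                for p in candidates]
        raise PeakNotFoundError(
            f"no candidate within {tol:.0%} of expected RT ratio "
            f"{expected.value:.4f} (candidates at ratios {seen})")
    scored.sort(key=lambda s: (s[0], s[1]))
    return scored[0][2]
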