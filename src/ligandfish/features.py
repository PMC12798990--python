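"""Chromatographic feature extraction from centroided MS1 runs.

A run is a time-ordered list of :class:`CentroidSpectrum`.  Centroids are
linked into ppm-bounded mass traces (extracted-ion chromatograms), peaks
are detected on each trace with the screen's S/N and minimum-intensity
thresholds, and peak areas are integrated by the trapezoidal rule with
time expressed in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chem import MassTolerance, neutral_from_mz

logger = logging.getLogger(__name__)

# Extraction thresholds used throughout the screen.
DEFAULT_SNR_MIN = 3.0
DEFAULT_MIN_HEIGHT = 100_000.0


@dataclass
class CentroidSpectrum:
    """One centroided MS1 scan: retention time (min) plus sorted m/z and
    intensity arrays of equal length."""

    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z array must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class MassTrace:
    """An extracted-ion chromatogram: time-ordered (rt, intensity) points
    whose centroids all lie within the linking tolerance of ``mz_center``
    (intensity-weighted mean m/z)."""

    mz_center: float
    rt: np.ndarray
    intensity: np.ndarray

    def __len__(self) -> int:
        return self.rt.size


@dataclass
class Feature:
    """A quantified chromatographic peak in a single run."""

    mz: float
    neutral_mass: float
    rt_apex: float
    rt_start: float
    rt_end: float
    height: float
    area: float
    snr: float
    run_id: str = ""


class _OpenTrace:
    __slots__ = ("mz_sum", "w_sum", "rts", "ints", "gap")

    def __init__(self, rt: float, mz: float, inten: float) -> None:
        w = max(inten, 1.0)
        self.mz_sum = mz * w
        self.w_sum = w
        self.rts = [rt]
        self.ints = [inten]
        self.gap = 0

    @property
    def center(self) -> float:
        return self.mz_sum / self.w_sum

    def add(self, rt: float, mz: float, inten: float) -> None:
        w = max(inten, 1.0)
        self.mz_sum += mz * w
        self.w_sum += w
        self.rts.append(rt)
        self.ints.append(inten)
        self.gap = 0


def build_mass_traces(
    run: list[CentroidSpectrum],
    tol: MassTolerance = MassTolerance(5.0),
    max_gap: int = 2,
    min_points: int = 3,
) -> list[MassTrace]:
    """Link centroids across scans into mass traces.

    Scan by scan, each centroid is assigned to the open trace whose
    intensity-weighted center is nearest in m/z within ``tol`` (one
    centroid per trace per scan); unmatched centroids open new traces.
    A trace is closed after ``max_gap`` consecutive scans without a
    match and emitted only if it collected at least ``min_points``
    points.
    """
    rts = [s.retention_time for s in run]
    if any(b < a for a, b in zip(rts, rts[1:])):
        raise ValueError("spectra must be in ascending retention-time order")

    open_traces: list[_OpenTrace] = []
    closed: list[MassTrace] = []

    def _close(tr: _OpenTrace) -> None:
        if len(tr.rts) >= min_points:
            closed.append(
                MassTrace(
                    mz_center=tr.center,
                    rt=np.asarray(tr.rts),
                    intensity=np.asarray(tr.ints),
                )
            )

    for spec in run:
        n_open = len(open_traces)
        if n_open:
            centers = np.array([t.center for t in open_traces])
            order = np.argsort(centers)
            centers_sorted = centers[order]
        taken = [False] * n_open
        matched_any = [False] * n_open
        for mz, inten in zip(spec.mz, spec.intensity):
            best = -1
            if n_open:
                half = tol.window(mz)
                j0 = np.searchsorted(centers_sorted, mz - half)
                j1 = np.searchsorted(centers_sorted, mz + half)
                best_d = half
                for j in range(j0, j1):
                    k = order[j]
                    if taken[k]:
                        continue
                    d = abs(centers[k] - mz)
                    if d <= best_d:
                        best_d = d
                        best = k
            if best >= 0:
                open_traces[best].add(spec.retention_time, mz, inten)
                taken[best] = True
                matched_any[best] = True
            else:
                open_traces.append(_OpenTrace(spec.retention_time, mz, inten))
        still_open: list[_OpenTrace] = []
        for k, tr in enumerate(open_traces):
            if k < len(matched_any) and not matched_any[k]:
                tr.gap += 1
                if tr.gap > max_gap:
                    _close(tr)
                    continue
            still_open.append(tr)
        open_traces = still_open

    for tr in open_traces:
        _close(tr)
    closed.sort(key=lambda t: (t.mz_center, t.rt[0]))
    return closed


def integrate_area(trace: MassTrace, rt_start: float, rt_end: float) -> float:
    """Trapezoidal peak area over [rt_start, rt_end], in counts x seconds.

    Retention times are stored in minutes; the integral converts to
    seconds so areas match instrument-software conventions.
    """
    if rt_start >= rt_end:
        raise ValueError("rt_start must be < rt_end")
    sel = (trace.rt >= rt_start) & (trace.rt <= rt_end)
    if sel.sum() < 2:
        raise ValueError("integration window contains fewer than two trace points")
    return float(np.trapezoid(trace.intensity[sel], trace.rt[sel] * 60.0))


def _local_peaks(y: np.ndarray) -> list[tuple[int, int, int]]:
    """(apex, left, right) index triples of all local maxima with
    boundaries at the flanking local minima (or trace ends)."""
    n = y.size
    if n < 3:
        return []
    apexes = [
        i
        for i in range(1, n - 1)
        if y[i] > 0 and y[i] >= y[i - 1] and y[i] > y[i + 1]
    ]
    peaks = []
    for i in apexes:
        left = i
        while left > 0 and y[left - 1] < y[left]:
            left -= 1
        right = i
        while right < n - 1 and y[right + 1] < y[right]:
            right += 1
        peaks.append((i, left, right))
    return peaks


def detect_peaks(
    trace: MassTrace,
    snr_min: float = DEFAULT_SNR_MIN,
    min_height: float = DEFAULT_MIN_HEIGHT,
    run_id: str = "",
) -> list[Feature]:
    """Detect chromatographic peaks on one mass trace.

    Peaks are local maxima with boundaries at the flanking minima (or
    baseline return / trace ends).  The noise level is the median
    absolute deviation of off-peak trace intensities scaled by 1.4826
    (Gaussian-consistent), floored at 1 count; S/N = apex height /
    noise.  Peaks below ``min_height`` or ``snr_min`` are suppressed,
    so loosening either threshold can only add features, never remove
    one.
    """
    y = trace.intensity
    if y.size < 3:
        return []
    candidates = _local_peaks(y)
    if not candidates:
        return []
    on_peak = np.zeros(y.size, dtype=bool)
    for _, left, right in candidates:
        on_peak[left : right + 1] = True
    off = y[~on_peak]
    if off.size >= 3:
        noise = 1.4826 * float(np.median(np.abs(off - np.median(off))))
    else:
        noise = 0.0
    noise = max(noise, 1.0)

    features = []
    for apex, left, right in candidates:
        height = float(y[apex])
        snr = height / noise
        if height < min_height or snr < snr_min:
            continue
        if right - left < 2:
            continue
        area = integrate_area(trace, trace.rt[left], trace.rt[right])
        features.append(
            Feature(
                mz=trace.mz_center,
                neutral_mass=neutral_from_mz(trace.mz_center),
                rt_apex=float(trace.rt[apex]),
                rt_start=float(trace.rt[left]),
                rt_end=float(trace.rt[right]),
                height=height,
                area=area,
                snr=snr,
                run_id=run_id,
            )
        )
    return features


def extract_features(
    run: list[CentroidSpectrum],
    tol: MassTolerance = MassTolerance(5.0),
    snr_min: float = DEFAULT_SNR_MIN,
    min_height: float = DEFAULT_MIN_HEIGHT,
    max_gap: int = 2,
    run_id: str = "",
) -> list[Feature]:
    """Full per-run extraction: traces, then peak detection on each."""
    features: list[Feature] = []
    for trace in build_mass_traces(run, tol=tol, max_gap=max_gap):
        features.extend(
            detect_peaks(trace, snr_min=snr_min, min_height=min_height, run_id=run_id)
        )
    features.sort(key=lambda f: (-f.height, f.mz))
    return features
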