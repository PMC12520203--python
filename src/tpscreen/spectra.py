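"""Centroided LC-MSn data model, peak-table I/O, EIC extraction, peak picking.

The format of record is a plain-text peak table (CSV) with one row per
centroid: ``scan_id, ms_level, rt_min, precursor_path, mz, intensity``.
``precursor_path`` is the chain of isolation m/z values leading to the scan
('|'-separated, empty for MS1), so an MS3 scan carries two ancestors.  MGF
export covers MS2 scans.

Extracted-ion chromatograms use a symmetric two-sided ppm window
(|delta| <= tol), defaulting to the 50 ppm screening tolerance.  Peak picking
is deliberately simple - local maxima above a threshold with trapezoidal
areas between flanking minima - because the synthetic chromatograms this
package screens are centroided, noise-controlled and well-sampled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "CentroidPeak",
    "MsnSpectrum",
    "LcMsRun",
    "Chromatogram",
    "PeakTableError",
    "read_peak_table",
    "write_peak_table",
    "write_mgf",
    "extract_eic",
    "pick_peaks",
    "base_peak_normalize",
]

PEAK_TABLE_COLUMNS = ("scan_id", "ms_level", "rt_min", "precursor_path", "mz", "intensity")


class PeakTableError(ValueError):
    """Structured parse error carrying the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


class CentroidPeak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class MsnSpectrum:
    """One centroided spectrum with its MS-level lineage.

    ``precursor_path`` lists the isolation m/z values from MS1 downwards, so
    ``ms_level == len(precursor_path) + 1`` always holds.
    """

    scan_id: str
    ms_level: int
    rt_min: float
    precursor_path: tuple[float, ...] = ()
    peaks: list[CentroidPeak] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ms_level != len(self.precursor_path) + 1:
            raise PeakTableError(
                f"scan {self.scan_id!r}: ms_level {self.ms_level} inconsistent "
                f"with precursor path of length {len(self.precursor_path)}"
            )
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def precursor_mz(self) -> float | None:
        return self.precursor_path[-1] if self.precursor_path else None

    def base_peak(self) -> CentroidPeak:
        if not self.peaks:
            raise PeakTableError(f"scan {self.scan_id!r} has no peaks")
        return max(self.peaks, key=lambda p: p.intensity)


@dataclass
class LcMsRun:
    """An ordered collection of spectra for one sample or time point."""

    label: str
    spectra: list[MsnSpectrum] = field(default_factory=list)
    polarity: str = "positive"

    def __post_init__(self) -> None:
        last_rt: dict[int, float] = {}
        for sp in self.spectra:
            prev = last_rt.get(sp.ms_level)
            if prev is not None and sp.rt_min < prev:
                raise PeakTableError(
                    f"retention times not monotone at MS{sp.ms_level} "
                    f"scan {sp.scan_id!r}"
                )
            last_rt[sp.ms_level] = sp.rt_min

    def ms1_scans(self) -> list[MsnSpectrum]:
        return [sp for sp in self.spectra if sp.ms_level == 1]

    def msn_scans(self, level: int | None = None) -> list[MsnSpectrum]:
        return [
            sp
            for sp in self.spectra
            if sp.ms_level > 1 and (level is None or sp.ms_level == level)
        ]


@dataclass
class Chromatogram:
    """Paired (rt, intensity) series for one target m/z window."""

    times: np.ndarray
    intensities: np.ndarray
    target_mz: float
    tol_ppm: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have the same length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("chromatogram times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def _format_path(path: tuple[float, ...]) -> str:
    return "|".join(f"{mz:.6f}" for mz in path)


def write_peak_table(run: LcMsRun, path: str | Path) -> None:
    """Write a run in the CSV peak-table dialect (6-decimal round trip)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PEAK_TABLE_COLUMNS)
        for sp in run.spectra:
            for peak in sp.peaks:
                writer.writerow(
                    [
                        sp.scan_id,
                        sp.ms_level,
                        f"{sp.rt_min:.6f}",
                        _format_path(sp.precursor_path),
                        f"{peak.mz:.6f}",
                        f"{peak.intensity:.6f}",
                    ]
                )


def read_peak_table(path: str | Path, label: str | None = None) -> LcMsRun:
    """Read the CSV peak-table dialect written by :func:`write_peak_table`."""
    path = Path(path)
    scans: dict[str, MsnSpectrum] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PeakTableError("empty peak table", line=1) from None
        if tuple(h.strip() for h in header) != PEAK_TABLE_COLUMNS:
            missing = set(PEAK_TABLE_COLUMNS) - set(header)
            raise PeakTableError(
                f"bad header; missing column(s) {sorted(missing)}", line=1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(PEAK_TABLE_COLUMNS):
                raise PeakTableError(
                    f"expected {len(PEAK_TABLE_COLUMNS)} fields, got {len(row)}",
                    line=lineno,
                )
            scan_id, level_s, rt_s, path_s, mz_s, int_s = row
            try:
                level = int(level_s)
                rt = float(rt_s)
                mz = float(mz_s)
                intensity = float(int_s)
                prec = tuple(float(x) for x in path_s.split("|")) if path_s else ()
            except ValueError as exc:
                raise PeakTableError(f"unparseable field: {exc}", line=lineno) from None
            if level != len(prec) + 1:
                raise PeakTableError(
                    f"scan {scan_id!r}: ms_level {level} does not match "
                    f"precursor path {path_s!r}",
                    line=lineno,
                )
            sp = scans.get(scan_id)
            if sp is None:
                scans[scan_id] = MsnSpectrum(
                    scan_id=scan_id,
                    ms_level=level,
                    rt_min=rt,
                    precursor_path=prec,
                    peaks=[CentroidPeak(mz, intensity)],
                )
            else:
                if sp.ms_level != level or sp.rt_min != rt:
                    raise PeakTableError(
                        f"scan {scan_id!r} has inconsistent level/rt across rows",
                        line=lineno,
                    )
                sp.peaks.append(CentroidPeak(mz, intensity))
                sp.peaks.sort(key=lambda p: p.mz)
    ordered = sorted(scans.values(), key=lambda s: (s.rt_min, s.ms_level, s.scan_id))
    return LcMsRun(label=label or path.stem, spectra=ordered)


def write_mgf(run: LcMsRun, path: str | Path) -> int:
    """Export MS2 scans to MGF; returns the number of spectra written."""
    from pyteomics import mgf as _mgf

    entries = []
    for sp in run.msn_scans(level=2):
        entries.append(
            {
                "m/z array": np.array([p.mz for p in sp.peaks]),
                "intensity array": np.array([p.intensity for p in sp.peaks]),
                "params": {
                    "title": sp.scan_id,
                    "pepmass": sp.precursor_mz,
                    "rtinseconds": sp.rt_min * 60.0,
                    "charge": "1+",
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")
    return len(entries)


def extract_eic(run: LcMsRun, target_mz: float, tol_ppm: float = 50.0) -> Chromatogram:
    """Extracted-ion chromatogram over the run's MS1 scans.

    Per scan, intensities of all peaks with |ppm(peak, target)| <= tol are
    summed; scans with no matching peak contribute zero.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    half_width = target_mz * tol_ppm * 1e-6
    lo, hi = target_mz - half_width, target_mz + half_width
    times, values = [], []
    for sp in run.ms1_scans():
        total = 0.0
        for peak in sp.peaks:
            if lo <= peak.mz <= hi:
                total += peak.intensity
        times.append(sp.rt_min)
        values.append(total)
    return Chromatogram(
        times=np.array(times), intensities=np.array(values),
        target_mz=target_mz, tol_ppm=tol_ppm,
    )


class PickedPeak(NamedTuple):
    rt: float
    apex_intensity: float
    area: float


def pick_peaks(
    chrom: Chromatogram, min_intensity: float = 0.0, min_points: int = 3
) -> list[PickedPeak]:
    """Local maxima above ``min_intensity`` with trapezoidal areas.

    A peak apex is a strict rise followed by a fall (plateaus are collapsed to
    their first point); its area integrates the trace between the flanking
    local minima.  Peaks spanning fewer than ``min_points`` samples are
    dropped.  Apexes are returned in retention-time order.
    """
    if len(chrom) == 0:
        raise ValueError("cannot pick peaks from an empty chromatogram")
    from scipy.signal import find_peaks

    y = chrom.intensities
    t = chrom.times
    n = y.size
    apexes, _ = find_peaks(y)
    picked = []
    for apex in apexes:
        if y[apex] <= 0 or y[apex] < min_intensity:
            continue
        left = apex
        while left > 0 and y[left - 1] < y[left]:
            left -= 1
        right = apex
        while right < n - 1 and y[right + 1] < y[right]:
            right += 1
        if right - left + 1 < min_points:
            continue
        area = float(np.trapezoid(y[left : right + 1], t[left : right + 1]))
        picked.append(PickedPeak(float(t[apex]), float(y[apex]), area))
    picked.sort(key=lambda p: p.rt)
    return picked


def base_peak_normalize(spectrum: MsnSpectrum) -> MsnSpectrum:
    """Return a copy with intensities rescaled so the base peak is 100."""
    if not spectrum.peaks:
        raise PeakTableError(f"scan {spectrum.scan_id!r} has no peaks")
    top = max(p.intensity for p in spectrum.peaks)
    if top <= 0:
        raise PeakTableError(
            f"scan {spectrum.scan_id!r} is all-zero; cannot normalize"
        )
    return MsnSpectrum(
        scan_id=spectrum.scan_id,
        ms_level=spectrum.ms_level,
        rt_min=spectrum.rt_min,
        precursor_path=spectrum.precursor_path,
        peaks=[CentroidPeak(p.mz, p.intensity / top * 100.0) for p in spectrum.peaks],
        annotations=dict(spectrum.annotations, normalized="base_peak_percent"),
    )
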