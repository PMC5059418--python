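"""Reading SWATH runs and extracting chromatograms (XICs).

A :class:`SpectrumRun` holds centroided MS1 and MS2 scans indexed by level and
isolation-window so that extracted ion chromatograms — summed intensity at a
target m/z ± ppm tolerance per scan, as a function of retention time — can be
pulled out cheaply. Peak areas are trapezoidal integrals over user-supplied
retention-time borders (minutes), matching targeted-quantification practice.
"""

from __future__ import annotations

import base64
import bisect
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from lxml import etree

from .chem import AcylPeptide, peptide_mono_mass, precursor_mz
from .swath import SwathWindowScheme, assign_window

__all__ = [
    "Scan",
    "SpectrumRun",
    "Chromatogram",
    "PeakArea",
    "read_run",
    "extract_xic",
    "integrate_peak",
    "ms1_isotope_areas",
]

#: Average mass difference between adjacent isotope peaks (Da).
ISOTOPE_SPACING = 1.00336


@dataclass
class Scan:
    ms_level: int
    rt: float  # minutes
    mz: np.ndarray  # sorted ascending
    intensity: np.ndarray
    window: int | None = None  # SWATH window index for MS2
    isolation: tuple[float, float] | None = None  # lower, upper m/z


class SpectrumRun:
    """An ordered collection of scans with per-(level, window) RT indexes."""

    def __init__(self, scans: list[Scan]):
        self.scans = scans
        self._index: dict[tuple[int, int | None], list[int]] = {}
        prev_rt = -np.inf
        for i, s in enumerate(self.scans):
            if s.rt < prev_rt - 1e-9:
                raise ValueError("scan retention times must be non-decreasing")
            prev_rt = s.rt
            key = (s.ms_level, s.window if s.ms_level == 2 else None)
            self._index.setdefault(key, []).append(i)

    @property
    def rt_range(self) -> tuple[float, float]:
        return (self.scans[0].rt, self.scans[-1].rt) if self.scans else (0.0, 0.0)

    @property
    def ms2_windows(self) -> list[int]:
        return sorted(w for lvl, w in self._index if lvl == 2 and w is not None)

    def select(
        self, level: int, window: int | None = None, rt_range: tuple[float, float] | None = None
    ) -> list[Scan]:
        idx = self._index.get((level, window if level == 2 else None), [])
        scans = [self.scans[i] for i in idx]
        if rt_range is not None:
            lo, hi = rt_range
            rts = [s.rt for s in scans]
            a = bisect.bisect_left(rts, lo)
            b = bisect.bisect_right(rts, hi)
            scans = scans[a:b]
        return scans


@dataclass
class Chromatogram:
    """An extracted ion chromatogram for one target m/z."""

    target_mz: float
    ppm_tol: float
    rt: np.ndarray  # minutes
    intensity: np.ndarray
    source: str  # "MS1" or "MS2@<window>"
    empty_range: bool = False  # RT range had no scans


@dataclass
class PeakArea:
    """A trapezoid-integrated peak area with QC metadata."""

    area: float  # intensity * minutes
    rt_borders: tuple[float, float]
    n_points: int
    apex_rt: float | None
    low_points: bool = False


# ---------------------------------------------------------------------------
# reading


def _window_from_isolation(
    lower: float, upper: float, scheme: SwathWindowScheme | None
) -> int | None:
    if scheme is None:
        return None
    return assign_window((lower + upper) / 2.0, scheme)


def _decode_binary(text: str, dtype: str, compressed: bool, big_endian: bool = False) -> np.ndarray:
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    count = len(raw) // struct.calcsize(dtype)
    order = ">" if big_endian else "<"
    return np.array(struct.unpack(f"{order}{count}{dtype}", raw), dtype=float)


def _parse_mzml_spectrum(el) -> tuple[int, float, np.ndarray, np.ndarray, tuple | None]:
    def cv(parent, accession, default=None):
        for p in parent.iter("{*}cvParam"):
            if p.get("accession") == accession:
                return p
        return default

    level_p = cv(el, "MS:1000511")
    level = int(level_p.get("value")) if level_p is not None else 1
    rt = 0.0
    for scan in el.iter("{*}scan"):
        p = cv(scan, "MS:1000016")
        if p is not None:
            rt = float(p.get("value"))
            if p.get("unitName", "minute") in ("second", "seconds"):
                rt /= 60.0
        break
    bounds = None
    for iso in el.iter("{*}isolationWindow"):
        t = cv(iso, "MS:1000827")
        lo = cv(iso, "MS:1000828")
        hi = cv(iso, "MS:1000829")
        if t is not None:
            target = float(t.get("value"))
            lo_off = float(lo.get("value")) if lo is not None else 0.0
            hi_off = float(hi.get("value")) if hi is not None else 0.0
            bounds = (target - lo_off, target + hi_off)
        break
    mz = inten = np.array([])
    for bda in el.iter("{*}binaryDataArray"):
        dtype = "d" if cv(bda, "MS:1000523") is not None else "f"
        compressed = cv(bda, "MS:1000574") is not None
        is_mz = cv(bda, "MS:1000514") is not None
        is_int = cv(bda, "MS:1000515") is not None
        btext = ""
        for b in bda.iter("{*}binary"):
            btext = b.text or ""
        arr = _decode_binary(btext, dtype, compressed) if btext else np.array([])
        if is_mz:
            mz = arr
        elif is_int:
            inten = arr
    return level, rt, mz, inten, bounds


def _iter_mzml(path: Path):
    for _, el in etree.iterparse(str(path), events=("end",), tag="{*}spectrum"):
        yield _parse_mzml_spectrum(el)
        el.clear()


def _iter_mzxml(path: Path):
    for _, el in etree.iterparse(str(path), events=("end",), tag="{*}scan"):
        level = int(el.get("msLevel", "1"))
        rt_attr = el.get("retentionTime", "PT0S")  # e.g. PT123.4S
        rt = float(rt_attr.strip("PTS")) / 60.0
        bounds = None
        mz = inten = np.array([])
        for pm in el.iter("{*}precursorMz"):
            target = float(pm.text)
            width = float(pm.get("windowWideness", "0"))
            bounds = (target - width / 2.0, target + width / 2.0)
            break
        for peaks in el.iter("{*}peaks"):
            dtype = "d" if peaks.get("precision", "32") == "64" else "f"
            compressed = peaks.get("compressionType", "none") == "zlib"
            if peaks.text:
                pairs = _decode_binary(peaks.text, dtype, compressed, big_endian=True)
                mz, inten = pairs[0::2], pairs[1::2]
            break
        yield level, rt, mz, inten, bounds
        el.clear()


def read_run(path: str | Path, scheme: SwathWindowScheme | None = None) -> SpectrumRun:
    """Read an mzML (or mzXML) SWATH run into a :class:`SpectrumRun`.

    MS2 scans are attributed to isolation windows from their isolation-window
    metadata when present (via the scheme if supplied, else by order of first
    appearance); without metadata, windows are assigned by cycle order against
    the scheme. RTs are converted to minutes.
    """
    path = Path(path)
    scans: list[Scan] = []
    seen_bounds: dict[tuple[float, float], int] = {}
    cycle_pos = 0
    source = _iter_mzxml(path) if path.suffix.lower() == ".mzxml" else _iter_mzml(path)
    try:
        for level, rt, mz, inten, bounds in source:
            window = None
            if level == 1:
                cycle_pos = 0
            else:
                if bounds is not None:
                    window = _window_from_isolation(*bounds, scheme)
                    if window is None:
                        if bounds not in seen_bounds:
                            seen_bounds[bounds] = len(seen_bounds)
                        window = seen_bounds[bounds]
                elif scheme is not None:
                    window = cycle_pos
                else:
                    raise ValueError(
                        f"{path.name}: MS2 scan without isolation metadata and "
                        "no window scheme supplied"
                    )
                cycle_pos += 1
            order = np.argsort(mz, kind="stable")
            scans.append(
                Scan(level, rt, np.asarray(mz)[order], np.asarray(inten)[order],
                     window, bounds)
            )
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    return SpectrumRun(scans)


# ---------------------------------------------------------------------------
# extraction / integration


def extract_xic(
    run: SpectrumRun,
    target_mz: float,
    ppm_tol: float = 20.0,
    rt_range: tuple[float, float] | None = None,
    level: Literal[1, 2] = 2,
    window: int | None = None,
) -> Chromatogram:
    """Summed intensity within ``target_mz * ppm_tol * 1e-6`` per qualifying scan."""
    if level == 2 and window is None:
        raise ValueError("MS2 extraction requires a window index")
    scans = run.select(level, window, rt_range)
    tol = target_mz * ppm_tol * 1e-6
    rts = np.empty(len(scans))
    vals = np.empty(len(scans))
    for i, s in enumerate(scans):
        a = np.searchsorted(s.mz, target_mz - tol, side="left")
        b = np.searchsorted(s.mz, target_mz + tol, side="right")
        rts[i] = s.rt
        vals[i] = s.intensity[a:b].sum() if b > a else 0.0
    return Chromatogram(
        target_mz, ppm_tol, rts, vals,
        source="MS1" if level == 1 else f"MS2@{window}",
        empty_range=len(scans) == 0,
    )


def integrate_peak(chrom: Chromatogram, rt_borders: tuple[float, float]) -> PeakArea:
    """Trapezoidal integral of the XIC restricted to [lo, hi] (inclusive)."""
    lo, hi = rt_borders
    if lo > hi:
        raise ValueError("rt borders must be ordered")
    mask = (chrom.rt >= lo) & (chrom.rt <= hi)
    rt, inten = chrom.rt[mask], chrom.intensity[mask]
    if len(rt) < 2:
        return PeakArea(0.0, rt_borders, len(rt), rt[0] if len(rt) else None, low_points=True)
    area = float(np.trapezoid(inten, rt))
    apex = float(rt[int(np.argmax(inten))])
    return PeakArea(area, rt_borders, len(rt), apex)


def ms1_isotope_areas(
    run: SpectrumRun,
    peptide: AcylPeptide,
    n_isotopes: int = 3,
    ppm_tol: float = 20.0,
    rt_borders: tuple[float, float] | None = None,
) -> list[PeakArea]:
    """MS1 areas for the M, M+1, ... isotopes of a peptide precursor.

    Isotopes are spaced by ``1.00336 / charge`` m/z; the monoisotopic (M) peak
    is the highest-ranked precursor ion used for MS1-level quantification.
    """
    if n_isotopes < 1:
        raise ValueError("n_isotopes must be >= 1")
    if rt_borders is None:
        rt_borders = run.rt_range
    mono = precursor_mz(peptide_mono_mass(peptide), peptide.charge)
    out = []
    for k in range(n_isotopes):
        mz = mono + k * ISOTOPE_SPACING / peptide.charge
        chrom = extract_xic(run, mz, ppm_tol, rt_borders, level=1)
        out.append(integrate_peak(chrom, rt_borders))
    return out
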