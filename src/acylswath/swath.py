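"""SWATH (DIA) isolation-window schemes and precursor-to-window assignment.

Variable-width isolation windows usually overlap by ~1 m/z (vendor default).
For quantification each precursor must be attributed to exactly one window, so
the scheme de-overlaps neighbours by splitting the overlap equally and uses
half-open effective intervals [lo, hi); an m/z exactly on a boundary goes to
the higher-index window.

The co-isolation check — light and heavy precursors of a pair landing in the
same window, so their fragments appear in the same MS2 scans — is a hard
prerequisite for fragment-level L/(L+H) ratios.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "SwathWindow",
    "SwathWindowScheme",
    "load_window_scheme",
    "write_window_scheme",
    "assign_window",
    "co_isolated",
]


@dataclass(frozen=True)
class SwathWindow:
    index: int
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"window {self.index}: lower {self.lower} >= upper {self.upper}")


class SwathWindowScheme:
    """Ordered isolation windows plus de-overlapped effective bounds."""

    def __init__(self, windows: list[SwathWindow], overlap: float | None = None):
        if not windows:
            raise ValueError("empty window scheme")
        ws = sorted(windows, key=lambda w: w.lower)
        if overlap is None:
            gaps = [ws[i].upper - ws[i + 1].lower for i in range(len(ws) - 1)]
            overlap = max(0.0, statistics.median(gaps)) if gaps else 0.0
        self.windows = [SwathWindow(i, w.lower, w.upper) for i, w in enumerate(ws)]
        self.overlap = overlap
        half = overlap / 2.0
        self.effective: list[tuple[float, float]] = []
        for i, w in enumerate(self.windows):
            lo = w.lower + (half if i > 0 else 0.0)
            hi = w.upper - (half if i < len(self.windows) - 1 else 0.0)
            self.effective.append((lo, hi))
        for i in range(len(self.effective) - 1):
            hi = self.effective[i][1]
            lo = self.effective[i + 1][0]
            if abs(hi - lo) > 1e-6:
                raise ValueError(
                    f"windows {i} and {i+1} leave a gap/overlap after de-overlap "
                    f"({hi:.4f} vs {lo:.4f})"
                )

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def range(self) -> tuple[float, float]:
        return self.effective[0][0], self.effective[-1][1]


def load_window_scheme(path: str | Path) -> SwathWindowScheme:
    """Parse a two-column (lower upper) window definition text file.

    Whitespace- or tab-separated; one optional header line is skipped.
    """
    windows: list[SwathWindow] = []
    lines = Path(path).read_text().splitlines()
    for ln, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) < 2:
            raise ValueError(f"line {ln}: expected two columns, got {line!r}")
        try:
            lo, hi = float(parts[0]), float(parts[1])
        except ValueError:
            if ln == 1:  # header
                continue
            raise ValueError(f"line {ln}: non-numeric window bounds {line!r}") from None
        if not lo < hi:
            raise ValueError(f"line {ln}: inverted bounds {lo} >= {hi}")
        windows.append(SwathWindow(len(windows), lo, hi))
    if not windows:
        raise ValueError(f"{path}: no windows parsed")
    prev = None
    for w in sorted(windows, key=lambda w: w.lower):
        if prev is not None and w.lower < prev.lower:
            raise ValueError("windows not sortable by lower bound")
        prev = w
    return SwathWindowScheme(windows)


def write_window_scheme(scheme: SwathWindowScheme, path: str | Path) -> None:
    """Write the scheme in the same two-column dialect the loader reads."""
    with open(path, "w") as fh:
        fh.write("lower_mz\tupper_mz\n")
        for w in scheme.windows:
            fh.write(f"{w.lower:.2f}\t{w.upper:.2f}\n")


def assign_window(mz: float, scheme: SwathWindowScheme) -> int | None:
    """Index of the effective half-open window containing ``mz``; None if outside."""
    lo0, hiN = scheme.range
    if mz < lo0 or mz >= hiN:
        return None
    # windows are contiguous after de-overlap: binary search on effective lows
    lo, hi = 0, len(scheme.effective) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if mz >= scheme.effective[mid][1]:
            lo = mid + 1
        else:
            hi = mid
    wlo, whi = scheme.effective[lo]
    return lo if wlo <= mz < whi else None


def co_isolated(
    light_mz: float, heavy_mz: float, scheme: SwathWindowScheme
) -> tuple[bool, int | None, int | None]:
    """Whether a light/heavy precursor pair falls in the same isolation window."""
    i = assign_window(light_mz, scheme)
    j = assign_window(heavy_mz, scheme)
    return (i is not None and i == j), i, j
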