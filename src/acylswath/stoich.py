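"""Site-specific acyl occupancy from SWATH fragment ions.

The estimator: after exhaustive chemical acylation, every lysine carries
either the endogenous light acyl group or the isotope-labeled heavy one, so
the site occupancy is the intensity fraction L/(L+H). Fragment ions that
contain the modified lysine ("differentiating" ions) shift in m/z between the
light and heavy forms and measure the ratio free of the precursor-level
interferences that plague MS1 quantification; fragments without the site are
common to both forms and carry no ratio information.

Workflow per target site:

1. compute light and heavy precursor m/z and confirm the pair co-isolates in
   one SWATH window;
2. enumerate the differentiating fragments for the site;
3. extract light and heavy fragment XICs from that window at ppm tolerance,
   integrate within the target's retention-time borders;
4. keep fragments whose heavy area — or, for near-saturated sites, light
   area — clears a minimum-area threshold;
5. report the median ratio over passing fragments and the rank-1 ratio (the
   passing fragment with the largest light+heavy area).

Peptides with two lysines are resolved with the b-ion run for the first site
and the y-ion run for the second; a middle (third) lysine is estimated in
extended mode from multi-site fragment label-ladders under a per-site
independence model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .chem import (
    LABEL_DELTA,
    AcylPeptide,
    FragmentIon,
    fragment_ions,
    label_pair,
    peptide_mono_mass,
    precursor_mz,
)
from .swath import SwathWindowScheme, assign_window, co_isolated
from .xic import SpectrumRun, extract_xic, integrate_peak, ms1_isotope_areas

__all__ = [
    "TargetEntry",
    "FragmentRatio",
    "SiteStoichiometryResult",
    "differentiating_ions",
    "quantify_site",
    "quantify_multisite",
    "ms1_stoichiometry",
    "read_targets",
    "results_to_frames",
]

DEFAULT_PPM_TOL = 20.0
DEFAULT_MIN_HEAVY_AREA = 1000.0


@dataclass(frozen=True)
class TargetEntry:
    """One quantification task from the target table."""

    sequence: str
    protein: str
    site_numbers: tuple[int, ...]  # protein coordinates (reporting only)
    peptide_positions: tuple[int, ...]  # 1-based within the peptide
    family: str  # acetyl | succinyl
    charge: int
    rt_borders: tuple[float, float]
    run_file: str = ""

    def __post_init__(self) -> None:
        if len(self.site_numbers) != len(self.peptide_positions):
            raise ValueError("site_numbers and peptide_positions must align")
        for pos in self.peptide_positions:
            if self.sequence[pos - 1] != "K":
                raise ValueError(f"peptide position {pos} is not a lysine")

    def peptide(self, states: Sequence[str]) -> AcylPeptide:
        """Build the peptide with the given per-site label states.

        Carbamidomethyl is applied to every cysteine (fixed modification).
        """
        light, _ = label_pair(self.family)
        return AcylPeptide(
            sequence=self.sequence,
            charge=self.charge,
            acyl_sites=tuple(
                (pos, light.name, st) for pos, st in zip(self.peptide_positions, states)
            ),
            fixed_mods=tuple(
                (i, "carbamidomethyl")
                for i, c in enumerate(self.sequence, 1)
                if c == "C"
            ),
        )


@dataclass
class FragmentRatio:
    fragment: str  # e.g. "b3"
    series: str
    index: int
    charge: int
    light_mz: float
    heavy_mz: float
    light_area: float
    heavy_area: float
    passes: bool
    ratio: float | None = None  # L/(L+H); None when both channels fail
    rank: int | None = None


@dataclass
class SiteStoichiometryResult:
    target: TargetEntry
    site_number: int
    peptide_position: int
    fragments: list[FragmentRatio] = field(default_factory=list)
    median_ratio: float | None = None
    rank1_ratio: float | None = None
    co_isolated: bool = False
    window: int | None = None
    qc_notes: list[str] = field(default_factory=list)
    ms1_ratio: float | None = None
    ms1_isotope_areas: list[float] | None = None


# ---------------------------------------------------------------------------
# fragment selection


def differentiating_ions(
    peptide: AcylPeptide,
    site: int,
    mode: Literal["strict", "extended"] = "strict",
    fragment_charges: Sequence[int] = (1,),
) -> list[FragmentIon]:
    """Fragments that can distinguish light from heavy at ``site``.

    Strict mode returns fragments whose contained acyl sites are exactly
    ``{site}`` — their light/heavy m/z difference reflects that site alone.
    Extended mode adds multi-site fragments containing ``site`` (to be
    interpreted through their label-count ladders).
    """
    if site not in peptide.site_positions:
        raise ValueError(f"position {site} is not an acyl site of this peptide")
    out = []
    for frag in fragment_ions(peptide, ("b", "y"), fragment_charges):
        if site not in frag.contained_sites:
            continue
        if mode == "strict" and frag.contained_sites != (site,):
            continue
        out.append(frag)
    return out


def _fragment_mz_for_states(
    target: TargetEntry, series: str, index: int, charge: int, states: Sequence[str]
) -> float:
    pep = target.peptide(states)
    for f in fragment_ions(pep, (series,), (charge,)):
        if f.index == index:
            return f.mz
    raise ValueError(f"no {series}{index} fragment")


def _median_lower(values: list[float]) -> float:
    """Median; at even counts the lower of the two central values."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


# ---------------------------------------------------------------------------
# single-site quantification


def quantify_site(
    run: SpectrumRun,
    scheme: SwathWindowScheme,
    target: TargetEntry,
    site: int | None = None,
    ppm_tol: float = DEFAULT_PPM_TOL,
    min_heavy_area: float = DEFAULT_MIN_HEAVY_AREA,
    mode: Literal["strict", "extended"] = "strict",
    fragment_charges: Sequence[int] = (1,),
    series_filter: str | None = None,
) -> SiteStoichiometryResult:
    """Quantify one acyl site of a target from SWATH MS2 fragment XICs."""
    positions = target.peptide_positions
    if site is None:
        if len(positions) != 1:
            raise ValueError("site must be given for multi-lysine targets")
        site = positions[0]
    site_idx = positions.index(site)
    site_number = target.site_numbers[site_idx]
    result = SiteStoichiometryResult(target, site_number, site)

    # co-isolation of the all-light / all-heavy precursor pair
    light_pep = target.peptide(["light"] * len(positions))
    heavy_pep = target.peptide(["heavy"] * len(positions))
    lmz = precursor_mz(peptide_mono_mass(light_pep), target.charge)
    hmz = precursor_mz(peptide_mono_mass(heavy_pep), target.charge)
    ok, wi, wj = co_isolated(lmz, hmz, scheme)
    result.co_isolated = ok
    result.window = wi
    if not ok:
        result.qc_notes.append(
            f"co-isolation failure: light window {wi}, heavy window {wj}"
        )
        return result

    frags = differentiating_ions(light_pep, site, "strict", fragment_charges)
    if series_filter:
        frags = [f for f in frags if f.series == series_filter]
    for frag in frags:
        states_l = ["light"] * len(positions)
        states_h = list(states_l)
        states_h[site_idx] = "heavy"
        fl = _fragment_mz_for_states(target, frag.series, frag.index, frag.charge, states_l)
        fh = _fragment_mz_for_states(target, frag.series, frag.index, frag.charge, states_h)
        la = integrate_peak(
            extract_xic(run, fl, ppm_tol, target.rt_borders, level=2, window=wi),
            target.rt_borders,
        ).area
        ha = integrate_peak(
            extract_xic(run, fh, ppm_tol, target.rt_borders, level=2, window=wi),
            target.rt_borders,
        ).area
        # minimum-area filter: heavy first, light as the high-occupancy fallback
        passes = ha >= min_heavy_area or la >= min_heavy_area
        fr = FragmentRatio(
            fragment=frag.name, series=frag.series, index=frag.index,
            charge=frag.charge, light_mz=fl, heavy_mz=fh,
            light_area=la, heavy_area=ha, passes=passes,
        )
        if passes:
            fr.ratio = la / (la + ha)
        result.fragments.append(fr)

    passing = [f for f in result.fragments if f.passes]
    if not passing:
        result.qc_notes.append("no fragments above threshold")
        return result
    for rank, f in enumerate(
        sorted(passing, key=lambda f: f.light_area + f.heavy_area, reverse=True), 1
    ):
        f.rank = rank
    result.median_ratio = _median_lower([f.ratio for f in passing])
    result.rank1_ratio = next(f.ratio for f in passing if f.rank == 1)
    return result


# ---------------------------------------------------------------------------
# multi-lysine targets


def _ladder_model(thetas: Sequence[float]) -> np.ndarray:
    """Expected label-count ladder fractions for independent per-site states.

    ``thetas[s]`` is the light probability of site s; rung k is the total
    probability that exactly k of the contained sites are heavy.
    """
    k = len(thetas)
    out = np.zeros(k + 1)
    for heavy_set in itertools.product([0, 1], repeat=k):
        p = 1.0
        for th, h in zip(thetas, heavy_set):
            p *= (1.0 - th) if h else th
        out[sum(heavy_set)] += p
    return out


def quantify_multisite(
    run: SpectrumRun,
    scheme: SwathWindowScheme,
    target: TargetEntry,
    ppm_tol: float = DEFAULT_PPM_TOL,
    min_heavy_area: float = DEFAULT_MIN_HEAVY_AREA,
) -> list[SiteStoichiometryResult]:
    """Resolve per-site occupancies for a 2- or 3-lysine peptide.

    The first site is quantified from its strict b-ion run, the last from its
    strict y-ion run. For three lysines the middle site — which no strict
    single-site fragment isolates — is estimated in extended mode: every
    multi-site fragment's label-count ladder is modeled as independent
    per-site Bernoulli label states and the middle occupancy is the
    least-squares fit given the flanking b-/y-derived values.
    """
    positions = target.peptide_positions
    if len(positions) not in (2, 3):
        raise ValueError("quantify_multisite handles 2 or 3 acyl sites")

    # all label-permutation precursors must share one window
    windows = set()
    for states in itertools.product(["light", "heavy"], repeat=len(positions)):
        pep = target.peptide(states)
        windows.add(assign_window(precursor_mz(peptide_mono_mass(pep), target.charge), scheme))
    if len(windows) != 1 or None in windows:
        out = []
        for pos, num in zip(positions, target.site_numbers):
            r = SiteStoichiometryResult(target, num, pos)
            r.qc_notes.append(
                f"label permutations split across windows {sorted(windows, key=str)}"
            )
            out.append(r)
        return out

    first = quantify_site(
        run, scheme, target, positions[0], ppm_tol, min_heavy_area, series_filter="b"
    )
    last = quantify_site(
        run, scheme, target, positions[-1], ppm_tol, min_heavy_area, series_filter="y"
    )
    results = [first, last]

    if len(positions) == 3:
        mid = _estimate_middle_site(
            run, scheme, target, ppm_tol,
            theta_first=first.median_ratio, theta_last=last.median_ratio,
        )
        results.insert(1, mid)
    return results


def _estimate_middle_site(
    run: SpectrumRun,
    scheme: SwathWindowScheme,
    target: TargetEntry,
    ppm_tol: float,
    theta_first: float | None,
    theta_last: float | None,
) -> SiteStoichiometryResult:
    positions = target.peptide_positions
    mid_pos = positions[1]
    result = SiteStoichiometryResult(
        target, target.site_numbers[1], mid_pos, co_isolated=True
    )
    result.qc_notes.append("extended-mode: independence-model ladder fit")
    if theta_first is None or theta_last is None:
        result.qc_notes.append("flanking site estimates unavailable")
        return result

    light_pep = target.peptide(["light"] * 3)
    window = assign_window(
        precursor_mz(peptide_mono_mass(light_pep), target.charge), scheme
    )
    result.window = window
    delta = LABEL_DELTA[target.family]
    flank = {positions[0]: theta_first, positions[-1]: theta_last}

    ladders = []  # (contained sites, measured rung areas)
    for frag in differentiating_ions(light_pep, mid_pos, "extended"):
        if len(frag.contained_sites) < 2:
            continue
        base = frag.mz  # all-light rung
        areas = []
        for k in range(len(frag.contained_sites) + 1):
            mz = base + k * delta / frag.charge
            areas.append(
                integrate_peak(
                    extract_xic(run, mz, ppm_tol, target.rt_borders, 2, window),
                    target.rt_borders,
                ).area
            )
        total = sum(areas)
        if total > 0:
            ladders.append((frag.contained_sites, np.array(areas) / total))
    if not ladders:
        result.qc_notes.append("no usable multi-site fragment ladders")
        return result

    def loss(theta_mid: float) -> float:
        sse = 0.0
        for sites, measured in ladders:
            thetas = [flank.get(s, theta_mid) for s in sites]
            sse += float(np.sum((measured - _ladder_model(thetas)) ** 2))
        return sse

    fit = minimize_scalar(loss, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-10})
    result.median_ratio = float(fit.x)
    result.rank1_ratio = float(fit.x)
    return result


# ---------------------------------------------------------------------------
# MS1 comparison value


def ms1_stoichiometry(
    run: SpectrumRun,
    target: TargetEntry,
    ppm_tol: float = DEFAULT_PPM_TOL,
    n_isotopes: int = 3,
) -> SiteStoichiometryResult:
    """Precursor-level L/(L+H) for a single-lysine target.

    Uses the monoisotopic (highest-ranked) precursor areas; the top
    ``n_isotopes`` light-channel areas are retained in the report. Multi-site
    peptides are refused: their mixed label permutations share precursor m/z
    and cannot be resolved at MS1.
    """
    if len(target.peptide_positions) != 1:
        raise ValueError(
            "MS1 quantification cannot resolve multi-lysine targets: mixed "
            "light/heavy permutations share precursor m/z; use fragment-level "
            "quantification"
        )
    pos = target.peptide_positions[0]
    result = SiteStoichiometryResult(target, target.site_numbers[0], pos)
    light = target.peptide(["light"])
    heavy = target.peptide(["heavy"])
    la = ms1_isotope_areas(run, light, n_isotopes, ppm_tol, target.rt_borders)
    ha = ms1_isotope_areas(run, heavy, 1, ppm_tol, target.rt_borders)
    result.ms1_isotope_areas = [a.area for a in la]
    l0, h0 = la[0].area, ha[0].area
    if l0 + h0 <= 0:
        result.qc_notes.append("no MS1 signal in either channel")
        return result
    result.ms1_ratio = l0 / (l0 + h0)
    return result


# ---------------------------------------------------------------------------
# tables


TARGET_COLUMNS = [
    "sequence", "protein", "site_numbers", "peptide_positions", "family",
    "charge", "rt_start", "rt_end", "run_file",
]


def read_targets(path: str | Path) -> list[TargetEntry]:
    """Read the TSV target table (one row per peptide quantification task)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"target table missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            TargetEntry(
                sequence=row["sequence"],
                protein=str(row["protein"]),
                site_numbers=tuple(int(x) for x in str(row["site_numbers"]).split(";")),
                peptide_positions=tuple(
                    int(x) for x in str(row["peptide_positions"]).split(";")
                ),
                family=row["family"],
                charge=int(row["charge"]),
                rt_borders=(float(row["rt_start"]), float(row["rt_end"])),
                run_file=str(row["run_file"]),
            )
        )
    return out


def results_to_frames(
    results: list[SiteStoichiometryResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten results into (fragment-level, site-level) DataFrames."""
    frag_rows, site_rows = [], []
    for r in results:
        for f in r.fragments:
            frag_rows.append(
                dict(
                    sequence=r.target.sequence, protein=r.target.protein,
                    site_number=r.site_number, fragment=f.fragment,
                    light_mz=round(f.light_mz, 4), heavy_mz=round(f.heavy_mz, 4),
                    light_area=f.light_area, heavy_area=f.heavy_area,
                    passes=f.passes, ratio=f.ratio, rank=f.rank,
                )
            )
        site_rows.append(
            dict(
                sequence=r.target.sequence, protein=r.target.protein,
                site_number=r.site_number, peptide_position=r.peptide_position,
                median_ratio=r.median_ratio, rank1_ratio=r.rank1_ratio,
                ms1_ratio=r.ms1_ratio, co_isolated=r.co_isolated,
                window=r.window, qc_notes="; ".join(r.qc_notes),
            )
        )
    return pd.DataFrame(frag_rows), pd.DataFrame(site_rows)
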