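"""Synthetic SWATH run generator with known ground-truth occupancies.

Emulates a DIA acquisition of light/heavy acyl peptide pairs: each cycle is
one MS1 survey scan followed by MS2 scans for the isolation windows, on a
fixed cycle-time grid. Peptides elute as Gaussians in retention time; spectra
are centroided sticks. Per peptide the generator enumerates the label
*species* implied by the chemistry:

- a site is endogenously light with probability θ (the true occupancy);
- otherwise the heavy reagent labels it with the chemical completeness c;
- a labeled site carries the full heavy-isotope complement with the reagent
  purity p — with probability 1-p it is mass-identical to light, which is the
  mechanism behind the purity floor on apparent occupancy.

MS1 scans carry 4-isotope precursor envelopes (averagine-style Poisson
approximation) for every species; MS2 scans carry the species' b/y fragment
ladders in the species' isolation window. Optional Poisson shot noise and
injected interference peaks complete the picture. All randomness derives from
the scenario seed; with noise disabled every peak intensity is an exact
closed-form expectation, which the test-suite exploits.

The bundle written per run (mzML + window scheme + target table + ground-truth
JSON) feeds directly into the quantification pipeline.
"""

from __future__ import annotations

import base64
import json
import math
import struct
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from .chem import AcylPeptide, fragment_ions, label_pair, peptide_mono_mass, precursor_mz
from .swath import SwathWindow, SwathWindowScheme, assign_window, write_window_scheme
from .xic import Scan

__all__ = [
    "SimPeptideSpec",
    "InterferenceSpec",
    "SimScenario",
    "SimBundle",
    "simulate_run",
    "bsa_mixture_scenario",
    "default_variable_scheme",
    "averagine_envelope",
    "write_mzml",
    "random_gluc_peptides",
]

#: Mean isotope-rate per Da for an averagine-like composition.
_LAMBDA_PER_DA = 5.3e-4


def averagine_envelope(neutral_mass: float, n_isotopes: int = 4) -> np.ndarray:
    """Approximate relative isotope abundances M..M+(n-1), normalised to sum 1.

    Poisson approximation with rate proportional to mass; adequate for
    quadrupole-TOF style resolutions where isotopes are resolved but fine
    structure is not.
    """
    lam = neutral_mass * _LAMBDA_PER_DA
    probs = np.array([math.exp(-lam) * lam**k / math.factorial(k) for k in range(n_isotopes)])
    return probs / probs.sum()


def default_variable_scheme(
    n_windows: int = 64,
    mz_lo: float = 400.0,
    mz_hi: float = 1250.0,
    overlap: float = 1.0,
) -> SwathWindowScheme:
    """A variable-width window scheme: narrow where precursors are dense.

    Window density follows a bell over the precursor m/z range (most tryptic/
    Glu-C peptides fall mid-range), with effective widths clipped to stay
    within instrument-realistic bounds; widths span roughly 5–90 m/z.
    """
    centers = np.linspace(0, 1, n_windows)
    density = 0.15 + np.exp(-((centers - 0.35) ** 2) / 0.045)
    widths = 1.0 / density
    widths = widths / widths.sum() * (mz_hi - mz_lo)
    widths = np.clip(widths, 5.0, 89.0)
    widths = widths / widths.sum() * (mz_hi - mz_lo)
    edges = np.concatenate([[mz_lo], mz_lo + np.cumsum(widths)])
    edges[-1] = mz_hi
    windows = []
    for i in range(n_windows):
        lo = edges[i] - (overlap / 2 if i > 0 else 0.0)
        hi = edges[i + 1] + (overlap / 2 if i < n_windows - 1 else 0.0)
        windows.append(SwathWindow(i, lo, hi))
    return SwathWindowScheme(windows, overlap=overlap)


# ---------------------------------------------------------------------------
# scenario types


@dataclass
class SimPeptideSpec:
    """One simulated peptide with per-site true (light) occupancies."""

    sequence: str
    sites: tuple[int, ...]  # 1-based K positions
    occupancies: tuple[float, ...]  # fraction light, per site
    family: str = "acetyl"
    charge: int = 2
    abundance: float = 2.0e5  # apex amplitude (counts) before splitting
    apex_rt: float = 10.0  # minutes
    rt_sd: float = 0.08  # minutes
    fragment_rel: dict[str, float] | None = None  # e.g. {"b3": 1.0}; None = default

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.occupancies):
            raise ValueError("one occupancy per site required")
        for th in self.occupancies:
            if not 0.0 <= th <= 1.0:
                raise ValueError("occupancies must lie in [0, 1]")
        if self.abundance <= 0 or self.rt_sd <= 0:
            raise ValueError("abundance and rt_sd must be positive")


@dataclass
class InterferenceSpec:
    """A co-eluting or RT-offset interferent stick."""

    level: int  # 1 or 2
    mz: float
    apex_rt: float
    rt_sd: float
    intensity: float
    window: int | None = None  # required for MS2


@dataclass
class SimScenario:
    peptides: list[SimPeptideSpec]
    scheme: SwathWindowScheme | None = None  # None -> default 64-window scheme
    cycle_time: float = 3.2  # seconds
    noise: float = 0.0  # 0 = noise-free; >0 enables Poisson shot noise
    purity: float = 1.0  # heavy-reagent isotopic purity p
    completeness: float = 1.0  # chemical labeling completeness c
    interferences: list[InterferenceSpec] = field(default_factory=list)
    seed: int = 0
    rt_range: tuple[float, float] | None = None  # None -> inferred from peptides
    emit_all_windows: bool = False  # also write empty MS2 windows

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness must be in (0, 1]")


@dataclass
class SimBundle:
    mzml_path: Path
    scheme_path: Path
    targets_path: Path
    truth_path: Path
    truth: dict


# ---------------------------------------------------------------------------
# species enumeration

# per-site states: endogenous light, heavy label, light-mass impure label,
# or unlabeled (incomplete chemistry). Impure-heavy is mass-identical to
# light, so it is merged into the light-mass state.
def _site_states(theta: float, p: float, c: float) -> list[tuple[str, float]]:
    light_mass = theta + (1.0 - theta) * c * (1.0 - p)
    heavy = (1.0 - theta) * c * p
    unmod = (1.0 - theta) * (1.0 - c)
    out = [("light", light_mass), ("heavy", heavy)]
    if unmod > 0:
        out.append(("none", unmod))
    return [(s, w) for s, w in out if w > 1e-12]


def _species_peptide(spec: SimPeptideSpec, states: tuple[str, ...]) -> AcylPeptide:
    light, _ = label_pair(spec.family)
    return AcylPeptide(
        sequence=spec.sequence,
        charge=spec.charge,
        acyl_sites=tuple(
            (pos, light.name, st)
            for pos, st in zip(spec.sites, states)
            if st != "none"
        ),
        fixed_mods=tuple(
            (i, "carbamidomethyl") for i, ch in enumerate(spec.sequence, 1) if ch == "C"
        ),
    )


def _default_fragment_rel(n: int) -> dict[str, float]:
    rel = {}
    for series in "by":
        for i in range(1, n):
            rel[f"{series}{i}"] = 0.25 + 0.75 * math.exp(-((i - n / 2) ** 2) / (2 * (n / 3) ** 2))
    return rel


# ---------------------------------------------------------------------------
# mzML writing

_CV = "MS"


def _cv(el, acc, name, value="", unit=None):
    p = etree.SubElement(el, "cvParam", cvRef=_CV, accession=acc, name=name)
    if value != "":
        p.set("value", str(value))
    if unit:
        p.set("unitCvRef", "UO"), p.set("unitAccession", unit[0]), p.set("unitName", unit[1])


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{len(arr)}d", *arr)).decode()


def write_mzml(path: str | Path, scans: list[Scan]) -> None:
    """Write centroided scans as mzML (64-bit float arrays, no compression)."""
    NS = "http://psi.hupo.org/ms/mzml"
    root = etree.Element(f"{{{NS}}}mzML", version="1.1.0", nsmap={None: NS})
    cvlist = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(cvlist, "cv", id="MS", fullName="PSI-MS", URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    etree.SubElement(cvlist, "cv", id="UO", fullName="UNIT-ONTOLOGY", URI="http://ontologies.berkeleybop.org/uo.obo")
    run = etree.SubElement(root, "run", id="simulated_run")
    slist = etree.SubElement(run, "spectrumList", count=str(len(scans)))
    for i, s in enumerate(scans):
        sp = etree.SubElement(
            slist, "spectrum", index=str(i), id=f"scan={i+1}",
            defaultArrayLength=str(len(s.mz)),
        )
        _cv(sp, "MS:1000511", "ms level", s.ms_level)
        _cv(sp, "MS:1000127", "centroid spectrum")
        scl = etree.SubElement(sp, "scanList", count="1")
        _cv(scl, "MS:1000795", "no combination")
        scan = etree.SubElement(scl, "scan")
        _cv(scan, "MS:1000016", "scan start time", f"{s.rt:.6f}",
            unit=("UO:0000031", "minute"))
        if s.ms_level == 2 and s.isolation is not None:
            lo, hi = s.isolation
            target = (lo + hi) / 2.0
            plist = etree.SubElement(sp, "precursorList", count="1")
            prec = etree.SubElement(plist, "precursor")
            iso = etree.SubElement(prec, "isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z", f"{target:.4f}",
                unit=("MS:1000040", "m/z"))
            _cv(iso, "MS:1000828", "isolation window lower offset",
                f"{target - lo:.4f}", unit=("MS:1000040", "m/z"))
            _cv(iso, "MS:1000829", "isolation window upper offset",
                f"{hi - target:.4f}", unit=("MS:1000040", "m/z"))
            sel = etree.SubElement(prec, "selectedIonList", count="1")
            si = etree.SubElement(sel, "selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z", f"{target:.4f}",
                unit=("MS:1000040", "m/z"))
            etree.SubElement(prec, "activation")
        bdal = etree.SubElement(sp, "binaryDataArrayList", count="2")
        for acc, name, arr, unit in (
            ("MS:1000514", "m/z array", s.mz, ("MS:1000040", "m/z")),
            ("MS:1000515", "intensity array", s.intensity,
             ("MS:1000131", "number of detector counts")),
        ):
            enc = _b64(np.asarray(arr, dtype=float))
            bda = etree.SubElement(bdal, "binaryDataArray", encodedLength=str(len(enc)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, acc, name, unit=unit)
            b = etree.SubElement(bda, "binary")
            b.text = enc
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# the generator


def simulate_run(
    scenario: SimScenario, outdir: str | Path, basename: str = "sim"
) -> SimBundle:
    """Generate one SWATH run bundle from a scenario.

    Returns paths to the mzML file, window-scheme file, target-table TSV and
    ground-truth JSON, plus the in-memory ground-truth record.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = scenario.scheme or default_variable_scheme()
    rng = np.random.default_rng(scenario.seed)

    # retention-time cycle grid
    if scenario.rt_range is not None:
        rt_lo, rt_hi = scenario.rt_range
    elif scenario.peptides:
        rt_lo = min(p.apex_rt - 5 * p.rt_sd for p in scenario.peptides)
        rt_hi = max(p.apex_rt + 5 * p.rt_sd for p in scenario.peptides)
    else:
        rt_lo, rt_hi = 0.0, 1.0
    step = scenario.cycle_time / 60.0
    cycle_rts = np.arange(rt_lo, rt_hi + step / 2, step)

    truth: dict = {
        "seed": scenario.seed,
        "purity": scenario.purity,
        "completeness": scenario.completeness,
        "noise": scenario.noise,
        "cycle_time_s": scenario.cycle_time,
        "cycle_rt_min": [round(float(t), 6) for t in cycle_rts],
        "peptides": [],
        "excluded": [],
    }

    # per-window fragment sticks and MS1 sticks, built species by species
    ms1_sticks: list[list[tuple[float, float]]] = [[] for _ in cycle_rts]
    ms2_sticks: dict[int, list[list[tuple[float, float]]]] = {}
    target_rows = []
    import itertools as _it

    for pi, pep in enumerate(scenario.peptides):
        per_site = [
            _site_states(th, scenario.purity, scenario.completeness)
            for th in pep.occupancies
        ]
        rel = pep.fragment_rel or _default_fragment_rel(len(pep.sequence))
        profile = np.exp(-((cycle_rts - pep.apex_rt) ** 2) / (2 * pep.rt_sd**2))
        species_records = []
        excluded = False
        combos = list(_it.product(*per_site))
        for states_w in combos:
            states = tuple(s for s, _ in states_w)
            weight = float(np.prod([w for _, w in states_w]))
            sp_pep = _species_peptide(pep, states)
            mono = peptide_mono_mass(sp_pep)
            pmz = precursor_mz(mono, pep.charge)
            window = assign_window(pmz, scheme)
            if window is None:
                excluded = True
                continue
            env = averagine_envelope(mono)
            frags = fragment_ions(sp_pep, ("b", "y"), (1,))
            for ci, g in enumerate(profile):
                amp = pep.abundance * weight * g
                if amp <= 1e-9:
                    continue
                for k, e in enumerate(env):
                    ms1_sticks[ci].append((pmz + k * 1.00336 / pep.charge, amp * e))
                wl = ms2_sticks.setdefault(window, [[] for _ in cycle_rts])
                for f in frags:
                    r = rel.get(f.name, 0.0)
                    if r > 0:
                        wl[ci].append((f.mz, amp * r))
            species_records.append(
                dict(states=list(states), weight=weight,
                     precursor_mz=round(pmz, 5), window=window)
            )
        if excluded:
            truth["excluded"].append(pep.sequence)
        rt_borders = (
            max(rt_lo, pep.apex_rt - 4 * pep.rt_sd),
            min(rt_hi, pep.apex_rt + 4 * pep.rt_sd),
        )
        truth["peptides"].append(
            dict(
                sequence=pep.sequence, sites=list(pep.sites),
                occupancies=list(pep.occupancies), family=pep.family,
                charge=pep.charge, abundance=pep.abundance,
                apex_rt=pep.apex_rt, rt_sd=pep.rt_sd,
                rt_borders=list(rt_borders),
                fragment_rel={k: v for k, v in rel.items()},
                species=species_records,
            )
        )
        target_rows.append(
            dict(
                sequence=pep.sequence, protein=f"SIM{pi:03d}",
                site_numbers=";".join(str(s) for s in pep.sites),
                peptide_positions=";".join(str(s) for s in pep.sites),
                family=pep.family, charge=pep.charge,
                rt_start=round(rt_borders[0], 4), rt_end=round(rt_borders[1], 4),
                run_file=f"{basename}.mzML",
            )
        )

    # interference sticks
    for spec in scenario.interferences:
        prof = spec.intensity * np.exp(
            -((cycle_rts - spec.apex_rt) ** 2) / (2 * spec.rt_sd**2)
        )
        if spec.level == 1:
            for ci, v in enumerate(prof):
                if v > 1e-9:
                    ms1_sticks[ci].append((spec.mz, v))
        else:
            w = spec.window if spec.window is not None else assign_window(spec.mz, scheme)
            if w is None:
                raise ValueError("MS2 interference outside scheme; give a window")
            wl = ms2_sticks.setdefault(w, [[] for _ in cycle_rts])
            for ci, v in enumerate(prof):
                if v > 1e-9:
                    wl[ci].append((spec.mz, v))

    windows_emitted = (
        list(range(len(scheme))) if scenario.emit_all_windows else sorted(ms2_sticks)
    )

    def finish(sticks: list[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
        if not sticks:
            return np.array([]), np.array([])
        mz = np.array([m for m, _ in sticks])
        inten = np.array([v for _, v in sticks])
        order = np.argsort(mz)
        mz, inten = mz[order], inten[order]
        if scenario.noise > 0:
            inten = rng.poisson(inten).astype(float)
            keep = inten > 0
            mz, inten = mz[keep], inten[keep]
        return mz, inten

    scans: list[Scan] = []
    eps = step / (len(windows_emitted) + 2)  # keep RTs strictly ordered in a cycle
    for ci, t in enumerate(cycle_rts):
        mz, inten = finish(ms1_sticks[ci])
        scans.append(Scan(1, float(t), mz, inten, None, None))
        for wj, w in enumerate(windows_emitted):
            mz, inten = finish(ms2_sticks.get(w, [[] for _ in cycle_rts])[ci])
            lo, hi = scheme.windows[w].lower, scheme.windows[w].upper
            scans.append(Scan(2, float(t + (wj + 1) * eps), mz, inten, w, (lo, hi)))

    mzml_path = outdir / f"{basename}.mzML"
    scheme_path = outdir / f"{basename}_windows.tsv"
    targets_path = outdir / f"{basename}_targets.tsv"
    truth_path = outdir / f"{basename}_truth.json"
    write_mzml(mzml_path, scans)
    write_window_scheme(scheme, scheme_path)
    import pandas as pd

    pd.DataFrame(
        target_rows,
        columns=["sequence", "protein", "site_numbers", "peptide_positions",
                 "family", "charge", "rt_start", "rt_end", "run_file"],
    ).to_csv(targets_path, sep="\t", index=False)
    truth_path.write_text(json.dumps(truth, indent=1))
    return SimBundle(mzml_path, scheme_path, targets_path, truth_path, truth)


# ---------------------------------------------------------------------------
# scenario builders


def random_gluc_peptides(
    n: int,
    rng: np.random.Generator,
    n_sites: int = 1,
    length_range: tuple[int, int] = (8, 13),
    charge: int = 2,
    family: str = "acetyl",
    scheme: SwathWindowScheme | None = None,
) -> list[tuple[str, tuple[int, ...]]]:
    """Deterministic random Glu-C-like peptides (end in E, internal K sites).

    Sequences avoid internal D/E (fully cleaved products) and place lysines
    away from the termini so both b- and y-differentiating runs exist. When a
    ``scheme`` is given, only peptides whose light/heavy precursor
    permutations all co-isolate in one window are kept (the quantifiable
    subset — pairs split across windows cannot be measured at the fragment
    level and would simply be flagged downstream).
    """
    alphabet = list("AGILPSTVFYNQHRMW")  # no K/C/D/E; K added explicitly
    light, _ = label_pair(family)
    out: list[tuple[str, tuple[int, ...]]] = []
    attempts = 0
    while len(out) < n and attempts < 200 * n:
        attempts += 1
        ln = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = [alphabet[i] for i in rng.integers(0, len(alphabet), ln)]
        seq[-1] = "E"
        positions = sorted(
            rng.choice(np.arange(2, ln - 1), size=n_sites, replace=False).tolist()
        )
        for p in positions:
            seq[p - 1] = "K"
        pep = "".join(seq)
        if scheme is not None:
            import itertools as _it

            windows = set()
            for states in _it.product(["light", "heavy"], repeat=n_sites):
                ap = AcylPeptide(
                    pep, charge,
                    tuple((p, light.name, s) for p, s in zip(positions, states)),
                )
                windows.add(
                    assign_window(precursor_mz(peptide_mono_mass(ap), charge), scheme)
                )
            if len(windows) != 1 or None in windows:
                continue
        out.append((pep, tuple(positions)))
    if len(out) < n:
        raise RuntimeError("could not generate enough co-isolating peptides")
    return out


def bsa_mixture_scenario(
    light_fractions: list[float],
    n_peptides: int = 18,
    family: str = "succinyl",
    purity: float = 0.98,
    noise: float = 1.0,
    seed: int = 0,
) -> list[SimScenario]:
    """Dilution-series scenarios: one sample per defined light fraction.

    Mirrors a standard-protein validation design in which separate samples
    are prepared at defined percentages of light modification and each is
    acquired as its own SWATH run over the same peptide panel. The peptide
    panel is synthetic (seeded random Glu-C-like sequences standing in for a
    digest of a carrier protein such as BSA).
    """
    for f in light_fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError("light fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    panel = random_gluc_peptides(
        n_peptides, rng, family=family, scheme=default_variable_scheme()
    )
    apexes = np.linspace(8.0, 8.0 + 0.45 * (n_peptides - 1), n_peptides)
    scenarios = []
    for si, frac in enumerate(light_fractions):
        peptides = [
            SimPeptideSpec(
                sequence=seq, sites=sites, occupancies=(frac,) * len(sites),
                family=family, apex_rt=float(apexes[i]),
                abundance=2.0e5 * float(rng.uniform(0.5, 2.0)),
            )
            for i, (seq, sites) in enumerate(panel)
        ]
        scenarios.append(
            SimScenario(
                peptides=peptides, purity=purity, noise=noise,
                seed=seed * 1000 + si,
            )
        )
    return scenarios
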