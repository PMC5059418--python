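"""Monoisotopic mass bookkeeping for acyl-labeled peptides.

This module owns the chemistry needed for light/heavy acyl stoichiometry:
standard residue masses, the fixed and isotope-paired acyl modifications
(endogenous "light" acetyl/succinyl vs chemically installed heavy acetyl-d3 /
succinyl-d4), Glu-C in-silico digestion, and b-/y-fragment m/z computation for
any per-site label state of a peptide.

Masses are standard monoisotopic values (Unimod / IUPAC 2021 atomic masses) as
shipped by :mod:`pyteomics.mass`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Literal, Sequence

from pyteomics import fasta as _fasta
from pyteomics import mass as _pmass

__all__ = [
    "WATER",
    "PROTON",
    "RESIDUE_MASS",
    "ModificationSpec",
    "MODIFICATIONS",
    "label_pair",
    "AcylPeptide",
    "FragmentIon",
    "digest_gluc",
    "peptide_mono_mass",
    "precursor_mz",
    "fragment_ions",
    "read_fasta",
]

#: Monoisotopic mass of water (Da).
WATER: float = 18.010565
#: Mass of a proton (Da), used for charge-state arithmetic.
PROTON: float = 1.007276

#: One-letter residue code -> monoisotopic residue mass (Da).
RESIDUE_MASS: dict[str, float] = {
    aa: m for aa, m in _pmass.std_aa_mass.items() if len(aa) == 1 and aa.isupper()
}

LabelState = Literal["light", "heavy"]


@dataclass(frozen=True)
class ModificationSpec:
    """A named modification with its monoisotopic mass shift.

    ``label_partner`` names the isotopic counterpart for light/heavy pairs
    (e.g. light acetyl <-> acetyl-d3); ``None`` for unpaired mods such as
    carbamidomethyl.
    """

    name: str
    target: str  # residue one-letter code
    delta_mass: float  # Da
    label_partner: str | None = None


#: Built-in modifications used throughout the workflow.
MODIFICATIONS: dict[str, ModificationSpec] = {
    m.name: m
    for m in [
        ModificationSpec("carbamidomethyl", "C", 57.021464),
        ModificationSpec("acetyl", "K", 42.010565, "acetyl-d3"),
        ModificationSpec("acetyl-d3", "K", 45.029395, "acetyl"),
        ModificationSpec("succinyl", "K", 100.016044, "succinyl-d4"),
        ModificationSpec("succinyl-d4", "K", 104.041152, "succinyl"),
    ]
}

#: Light/heavy mass difference per labeled site, by family.
LABEL_DELTA: dict[str, float] = {
    "acetyl": MODIFICATIONS["acetyl-d3"].delta_mass - MODIFICATIONS["acetyl"].delta_mass,
    "succinyl": MODIFICATIONS["succinyl-d4"].delta_mass - MODIFICATIONS["succinyl"].delta_mass,
}


def label_pair(family: str) -> tuple[ModificationSpec, ModificationSpec]:
    """Return the (light, heavy) modification pair for ``family``.

    ``family`` is ``"acetyl"`` or ``"succinyl"``.
    """
    try:
        light = MODIFICATIONS[family]
    except KeyError:
        raise ValueError(f"unknown modification family: {family!r}") from None
    if light.label_partner is None:
        raise ValueError(f"{family!r} has no isotopic partner")
    return light, MODIFICATIONS[light.label_partner]


@dataclass(frozen=True)
class AcylPeptide:
    """A peptide with fixed modifications and per-site acyl label states.

    ``acyl_sites`` maps 1-based peptide positions (lysines) to
    ``(modification name, label state)``; ``fixed_mods`` maps positions to
    modification names (e.g. carbamidomethyl on a cysteine).
    """

    sequence: str
    charge: int = 2
    acyl_sites: tuple[tuple[int, str, LabelState], ...] = ()
    fixed_mods: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence or not self.sequence.isupper():
            raise ValueError("peptide sequence must be non-empty and uppercase")
        bad = [i for i, c in enumerate(self.sequence, 1) if c not in RESIDUE_MASS]
        if bad:
            raise ValueError(f"non-residue character at position {bad[0]}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        positions = [p for p, _, _ in self.acyl_sites]
        if positions != sorted(set(positions)):
            raise ValueError("acyl site positions must be strictly increasing")
        n = len(self.sequence)
        for pos, name, state in self.acyl_sites:
            if not 1 <= pos <= n:
                raise ValueError(f"acyl site {pos} outside peptide 1..{n}")
            if self.sequence[pos - 1] != "K":
                raise ValueError(f"acyl site {pos} is {self.sequence[pos-1]!r}, not K")
            mod = MODIFICATIONS.get(name)
            if mod is None or mod.target != "K":
                raise ValueError(f"not a lysine acyl modification: {name!r}")
            if state not in ("light", "heavy"):
                raise ValueError(f"label state must be light|heavy, got {state!r}")
        for pos, name in self.fixed_mods:
            mod = MODIFICATIONS.get(name)
            if mod is None:
                raise ValueError(f"unknown modification {name!r}")
            if self.sequence[pos - 1] != mod.target:
                raise ValueError(
                    f"fixed mod {name} targets {mod.target}, position {pos} is "
                    f"{self.sequence[pos-1]!r}"
                )

    # -- helpers -----------------------------------------------------------

    @property
    def site_positions(self) -> tuple[int, ...]:
        return tuple(p for p, _, _ in self.acyl_sites)

    def with_label_states(self, states: Sequence[LabelState]) -> "AcylPeptide":
        """Return a copy with the given label state per acyl site (in order)."""
        if len(states) != len(self.acyl_sites):
            raise ValueError("one label state per acyl site required")
        new_sites = tuple(
            (pos, _light_name(name), st)
            for (pos, name, _), st in zip(self.acyl_sites, states)
        )
        return replace(self, acyl_sites=new_sites)

    def mod_mass_at(self, pos: int) -> float:
        """Total modification mass carried by position ``pos``."""
        total = 0.0
        for p, name in self.fixed_mods:
            if p == pos:
                total += MODIFICATIONS[name].delta_mass
        for p, name, state in self.acyl_sites:
            if p == pos:
                light, heavy = label_pair(_light_name(name))
                total += (light if state == "light" else heavy).delta_mass
        return total


def _light_name(name: str) -> str:
    """Map either member of a label pair to the light (family) name."""
    mod = MODIFICATIONS[name]
    if mod.label_partner is not None and mod.delta_mass > MODIFICATIONS[mod.label_partner].delta_mass:
        return mod.label_partner
    return name


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-ion of an :class:`AcylPeptide`.

    ``contained_sites`` are the acyl-site positions that fall inside the
    fragment's residue span; only fragments with a non-empty set differ in m/z
    between the light and heavy peptide forms ("differentiating" ions).
    """

    series: Literal["b", "y"]
    index: int
    charge: int
    mz: float
    contained_sites: tuple[int, ...]
    label_state_vector: tuple[LabelState, ...]

    @property
    def name(self) -> str:
        z = "" if self.charge == 1 else f"^{self.charge}+"
        return f"{self.series}{self.index}{z}"


# ---------------------------------------------------------------------------
# digestion


def digest_gluc(
    protein_sequence: str, max_missed_cleavages: int = 0
) -> list[tuple[str, int, int]]:
    """In-silico Glu-C digestion (cleavage C-terminal to E and D).

    Returns ``(peptide, start, end)`` tuples with 1-based inclusive protein
    coordinates. With ``max_missed_cleavages=k`` every contiguous join of up
    to ``k+1`` fully cleaved peptides is returned, in N- to C-terminal order.
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    seq = protein_sequence
    for i, c in enumerate(seq, 1):
        if c not in RESIDUE_MASS:
            raise ValueError(f"non-residue character {c!r} at position {i}")

    # fully cleaved segments
    segments: list[tuple[int, int]] = []  # 0-based [start, end)
    start = 0
    for i, c in enumerate(seq):
        if c in "ED":
            segments.append((start, i + 1))
            start = i + 1
    if start < len(seq):
        segments.append((start, len(seq)))

    out: list[tuple[str, int, int]] = []
    for i in range(len(segments)):
        for j in range(i, min(i + max_missed_cleavages + 1, len(segments))):
            lo, hi = segments[i][0], segments[j][1]
            out.append((seq[lo:hi], lo + 1, hi))
    out.sort(key=lambda t: (t[1], t[2]))
    return out


# ---------------------------------------------------------------------------
# masses


def peptide_mono_mass(peptide: AcylPeptide) -> float:
    """Monoisotopic neutral mass (Da): residues + water + all modifications."""
    m = sum(RESIDUE_MASS[c] for c in peptide.sequence) + WATER
    m += sum(peptide.mod_mass_at(p) for p in range(1, len(peptide.sequence) + 1))
    return m


def precursor_mz(neutral_mass: float, charge: int) -> float:
    """(M + z·H+) / z."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON) / charge


def fragment_ions(
    peptide: AcylPeptide,
    series_set: Iterable[str] = ("b", "y"),
    fragment_charges: Sequence[int] = (1,),
) -> list[FragmentIon]:
    """Enumerate b/y fragment ions with per-site label-state bookkeeping.

    Full-length b_n / y_n ions are excluded. A b_i ion carries the mods of
    positions 1..i; a y_j ion carries those of positions n-j+1..n plus water.
    """
    n = len(peptide.sequence)
    seq = peptide.sequence
    site_state = {p: st for p, _, st in peptide.acyl_sites}

    # cumulative residue+mod masses from the N terminus
    permod = [RESIDUE_MASS[seq[i]] + peptide.mod_mass_at(i + 1) for i in range(n)]
    prefix = [0.0]
    for m in permod:
        prefix.append(prefix[-1] + m)

    out: list[FragmentIon] = []
    for z in fragment_charges:
        if z < 1:
            raise ValueError("fragment charge must be >= 1")
        for series in series_set:
            if series not in ("b", "y"):
                raise ValueError(f"unknown ion series {series!r}")
            for idx in range(1, n):
                if series == "b":
                    neutral = prefix[idx]
                    span = range(1, idx + 1)
                else:
                    neutral = prefix[n] - prefix[n - idx] + WATER
                    span = range(n - idx + 1, n + 1)
                sites = tuple(p for p in peptide.site_positions if p in span)
                out.append(
                    FragmentIon(
                        series=series,  # type: ignore[arg-type]
                        index=idx,
                        charge=z,
                        mz=(neutral + z * PROTON) / z,
                        contained_sites=sites,
                        label_state_vector=tuple(site_state[p] for p in sites),
                    )
                )
    return out


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (identifier, sequence) pairs."""
    records = []
    with _fasta.read(str(path)) as rd:
        for descr, seq in rd:
            records.append((descr.split()[0], seq.upper()))
    return records
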