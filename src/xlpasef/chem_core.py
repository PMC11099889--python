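"""Masses and fragment ions for linear and DSBU cross-linked peptides.

Cross-linking with MS-cleavable reagents such as DSBU (disuccinimidyl
dibutyric urea) joins two peptides through an amine-reactive linker that
fragments in the gas phase at its central urea bond.  Cleavage distributes
the linker between the two peptides as two complementary modifications —
conventionally called Bu (C4H7NO) and BuUr (C5H5NO2) — so every fragment
ion that spans the link site appears as a characteristic doublet.  This
module computes neutral monoisotopic masses, precursor and isotope m/z,
and the a/b/y fragment ion series (including the cleavable doublet
variants) for such cross-linked peptide pairs.

Monoisotopic element and residue masses come from :mod:`pyteomics.mass`
(NIST values); the proton mass and the isotope spacing constant are fixed
here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "ISOTOPE_SPACING",
    "WATER_MASS",
    "CO_MASS",
    "CARBAMIDOMETHYL_MASS",
    "OXIDATION_MASS",
    "ElementComposition",
    "Peptide",
    "LinkerSpec",
    "CrossLink",
    "FragmentIon",
    "DSBU",
    "monoisotopic_mass",
    "peptide_mass",
    "crosslink_mass",
    "precursor_mz",
    "isotope_mz",
    "fragment_ions",
    "linker_from_dict",
]

# Charge carrier and isotope-envelope conventions.
PROTON_MASS = 1.00727646  # Da, mass of H+
ISOTOPE_SPACING = 1.0033548  # Da, 13C-12C spacing (averagine convention)

WATER_MASS = _pmass.calculate_mass(formula="H2O")
CO_MASS = _pmass.calculate_mass(formula="CO")

# Built-in modification deltas (Da).
CARBAMIDOMETHYL_MASS = 57.02146  # iodoacetamide alkylation, fixed on Cys
OXIDATION_MASS = 15.99491  # variable on Met

_CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


class ChemistryError(ValueError):
    """Raised for invalid compositions, residues, or link positions."""


@dataclass(frozen=True)
class ElementComposition:
    """Chemical formula as non-negative counts per element symbol."""

    counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for symbol, n in self.counts.items():
            if n < 0:
                raise ChemistryError(f"negative count for element {symbol}")
            if symbol not in _pmass.nist_mass:
                raise ChemistryError(f"unknown element symbol: {symbol}")

    @classmethod
    def from_formula(cls, formula: str) -> "ElementComposition":
        try:
            comp = _pmass.Composition(formula=formula)
        except Exception as exc:  # pyteomics raises PyteomicsError
            raise ChemistryError(f"unparsable formula {formula!r}: {exc}") from exc
        return cls(dict(comp))

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self.counts)
        for symbol, n in other.counts.items():
            merged[symbol] = merged.get(symbol, 0) + n
        return ElementComposition(merged)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def monoisotopic_mass(composition: ElementComposition) -> float:
    """Neutral monoisotopic mass of a composition in Da.

    Sum over elements of count x monoisotopic atomic mass; unknown element
    symbols are rejected by name at construction time.
    """
    return float(
        _pmass.calculate_mass(composition=_pmass.Composition(composition.counts))
    )


@dataclass(frozen=True)
class Peptide:
    """A linear peptide with fixed (per-residue) and variable (positional) mods.

    ``fixed_mods`` maps a residue letter to a mass delta applied at every
    occurrence; ``variable_mods`` is a list of ``(position, delta)`` with
    1-based positions.  Carbamidomethyl-Cys is applied as a fixed mod by
    default, matching common sample preparation.
    """

    sequence: str
    fixed_mods: Tuple[Tuple[str, float], ...] = (("C", CARBAMIDOMETHYL_MASS),)
    variable_mods: Tuple[Tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _CANONICAL_RESIDUES
        if bad:
            raise ChemistryError(
                f"unknown residue letter(s): {''.join(sorted(bad))}"
            )
        if not self.sequence:
            raise ChemistryError("empty peptide sequence")
        for pos, _ in self.variable_mods:
            if not 1 <= pos <= len(self.sequence):
                raise ChemistryError(
                    f"variable mod position {pos} outside 1..{len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_masses(self) -> List[float]:
        """Per-residue monoisotopic masses with all mods applied."""
        fixed = dict(self.fixed_mods)
        masses = [
            _pmass.std_aa_mass[res] + fixed.get(res, 0.0) for res in self.sequence
        ]
        for pos, delta in self.variable_mods:
            masses[pos - 1] += delta
        return masses

    @property
    def mass(self) -> float:
        return peptide_mass(self)


def peptide_mass(p: Peptide) -> float:
    """Neutral monoisotopic mass: residue masses + water + mod deltas."""
    return float(sum(p.residue_masses()) + WATER_MASS)


@dataclass(frozen=True)
class LinkerSpec:
    """An MS-cleavable cross-linker that splits into two signature fragments.

    ``intact_mass`` is the delta added to the sum of the two peptide masses;
    for a cleavable urea linker it must equal the sum of the two fragment
    modification masses (conservation, checked to 1e-4 Da).
    """

    name: str
    fragment_a_name: str
    fragment_a: ElementComposition
    fragment_b_name: str
    fragment_b: ElementComposition
    reactive_residues: frozenset = frozenset("KSTY")
    reacts_with_nterm: bool = True
    intact_mass: Optional[float] = None

    def __post_init__(self) -> None:
        frag_sum = self.fragment_a.mass + self.fragment_b.mass
        if self.intact_mass is None:
            object.__setattr__(self, "intact_mass", frag_sum)
        elif abs(self.intact_mass - frag_sum) > 1e-4:
            raise ChemistryError(
                f"linker {self.name}: intact mass {self.intact_mass:.5f} != "
                f"{self.fragment_a_name}+{self.fragment_b_name} sum {frag_sum:.5f}"
            )

    def is_reactive(self, peptide: Peptide, position: int, n_terminal: bool = False) -> bool:
        if n_terminal and position == 1 and self.reacts_with_nterm:
            return True
        return peptide.sequence[position - 1] in self.reactive_residues


#: The default linker: DSBU, cleaving into Bu (C4H7NO) and BuUr (C5H5NO2).
DSBU = LinkerSpec(
    name="DSBU",
    fragment_a_name="Bu",
    fragment_a=ElementComposition.from_formula("C4H7NO"),
    fragment_b_name="BuUr",
    fragment_b=ElementComposition.from_formula("C5H5NO2"),
    reactive_residues=frozenset("KSTY"),
    reacts_with_nterm=True,
)


def linker_from_dict(spec: dict) -> LinkerSpec:
    """Build a LinkerSpec from a config mapping.

    Expected keys: ``name``, ``fragment_a`` / ``fragment_b`` (each with
    ``name`` and ``formula``), ``reactive_residues`` (string of letters),
    ``reacts_with_nterm`` (bool, default true).
    """
    return LinkerSpec(
        name=spec["name"],
        fragment_a_name=spec["fragment_a"]["name"],
        fragment_a=ElementComposition.from_formula(spec["fragment_a"]["formula"]),
        fragment_b_name=spec["fragment_b"]["name"],
        fragment_b=ElementComposition.from_formula(spec["fragment_b"]["formula"]),
        reactive_residues=frozenset(spec.get("reactive_residues", "KSTY")),
        reacts_with_nterm=bool(spec.get("reacts_with_nterm", True)),
    )


@dataclass(frozen=True)
class CrossLink:
    """Two peptides joined by a linker at 1-based residue positions.

    Protein-N-terminal linkage is represented as position 1 with the
    corresponding ``nterm_*`` flag set.
    """

    alpha: Peptide
    beta: Peptide
    link_pos_alpha: int
    link_pos_beta: int
    linker: LinkerSpec = DSBU
    nterm_alpha: bool = False
    nterm_beta: bool = False

    def __post_init__(self) -> None:
        for pep, pos, ntm, label in (
            (self.alpha, self.link_pos_alpha, self.nterm_alpha, "alpha"),
            (self.beta, self.link_pos_beta, self.nterm_beta, "beta"),
        ):
            if not 1 <= pos <= len(pep):
                raise ChemistryError(
                    f"{label} link position {pos} outside peptide of length {len(pep)}"
                )
            if not self.linker.is_reactive(pep, pos, n_terminal=ntm):
                raise ChemistryError(
                    f"{label} link position {pos} ({pep.sequence[pos - 1]}) is not "
                    f"in the {self.linker.name} reactive set"
                )

    @property
    def mass(self) -> float:
        return crosslink_mass(self)

    def swapped(self) -> "CrossLink":
        return CrossLink(
            alpha=self.beta,
            beta=self.alpha,
            link_pos_alpha=self.link_pos_beta,
            link_pos_beta=self.link_pos_alpha,
            linker=self.linker,
            nterm_alpha=self.nterm_beta,
            nterm_beta=self.nterm_alpha,
        )


def crosslink_mass(xl: CrossLink) -> float:
    """Neutral mass of the cross-linked pair: both peptides + intact linker."""
    return peptide_mass(xl.alpha) + peptide_mass(xl.beta) + float(xl.linker.intact_mass)


def precursor_mz(neutral_mass: float, z: int) -> float:
    """m/z of the [M+zH]z+ species."""
    if z < 1:
        raise ChemistryError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * PROTON_MASS) / z


def isotope_mz(mono_mz: float, z: int, k: int) -> float:
    """m/z of the k-th isotope peak above the monoisotopic peak."""
    if z < 1:
        raise ChemistryError(f"charge must be >= 1, got {z}")
    if k < 0:
        raise ChemistryError(f"isotope index must be >= 0, got {k}")
    return mono_mz + k * ISOTOPE_SPACING / z


LinkerState = Literal["none", "intact", "retains_Bu", "retains_BuUr"]

_SERIES_ORDER = {"a": 0, "b": 1, "y": 2}
_STATE_ORDER = {"none": 0, "intact": 1, "retains_Bu": 2, "retains_BuUr": 3}


@dataclass(frozen=True)
class FragmentIon:
    """One a/b/y fragment ion of a cross-linked pair.

    ``linker_state`` records whether the fragment spans the link site and, if
    so, which part of the cleaved linker (plus partner peptide, for
    ``intact``) it retains.
    """

    series: str
    ordinal: int
    source_peptide: str  # "alpha" | "beta"
    linker_state: str
    charge: int
    mz: float

    def sort_key(self):
        return (
            0 if self.source_peptide == "alpha" else 1,
            _SERIES_ORDER[self.series],
            self.ordinal,
            _STATE_ORDER[self.linker_state],
            self.charge,
        )


def _neutral_series_masses(residues: Sequence[float]) -> Dict[str, List[float]]:
    """Neutral fragment masses for a/b/y, ordinals 1..n-1."""
    n = len(residues)
    prefix = list(itertools.accumulate(residues))
    b = [prefix[i - 1] for i in range(1, n)]
    a = [m - CO_MASS for m in b]
    total = prefix[-1]
    y = [total - prefix[n - i - 1] + WATER_MASS for i in range(1, n)]
    return {"a": a, "b": b, "y": y}


def _spans_link(series: str, ordinal: int, n: int, link_pos: int) -> bool:
    # a/b fragments cover residues 1..ordinal; y fragments cover n-ordinal+1..n
    if series in ("a", "b"):
        return link_pos <= ordinal
    return link_pos >= n - ordinal + 1


def fragment_ions(
    xl: CrossLink,
    max_frag_charge: int = 2,
    series: Iterable[str] = ("a", "b", "y"),
) -> List[FragmentIon]:
    """Enumerate a/b/y fragment ions of both peptides of a cross-link.

    Fragments that do not span the link site are plain peptide fragments
    (``linker_state="none"``).  Fragments spanning the site are emitted in
    three variants: ``intact`` (carrying the whole linker plus the partner
    peptide), and the cleavable doublet ``retains_Bu`` / ``retains_BuUr``.
    Output is deterministically ordered by (peptide, series, ordinal,
    linker state, charge).
    """
    if max_frag_charge < 1:
        raise ChemistryError("max_frag_charge must be >= 1")
    bu = xl.linker.fragment_a.mass
    buur = xl.linker.fragment_b.mass
    out: List[FragmentIon] = []
    sides = (
        ("alpha", xl.alpha, xl.link_pos_alpha, peptide_mass(xl.beta)),
        ("beta", xl.beta, xl.link_pos_beta, peptide_mass(xl.alpha)),
    )
    for label, pep, link_pos, partner_mass in sides:
        n = len(pep)
        neutral = _neutral_series_masses(pep.residue_masses())
        for ser in series:
            for ordinal in range(1, n):
                base = neutral[ser][ordinal - 1]
                if _spans_link(ser, ordinal, n, link_pos):
                    variants = (
                        ("intact", base + float(xl.linker.intact_mass) + partner_mass),
                        ("retains_Bu", base + bu),
                        ("retains_BuUr", base + buur),
                    )
                else:
                    variants = (("none", base),)
                for state, m in variants:
                    for z in range(1, max_frag_charge + 1):
                        out.append(
                            FragmentIon(
                                series=ser,
                                ordinal=ordinal,
                                source_peptide=label,
                                linker_state=state,
                                charge=z,
                                mz=(m + z * PROTON_MASS) / z,
                            )
                        )
    out.sort(key=FragmentIon.sort_key)
    return out
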