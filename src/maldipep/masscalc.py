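"""Monoisotopic mass bookkeeping for amidated/acid peptides and their fragment ions.

All ions are singly protonated, as produced by MALDI of small peptides. Masses
follow the hydrogen-atom convention used by the classic peptide fragmentation
calculators: a b-type ion is the residue-sum plus 1.00782 Da, a y-type ion adds
the terminal group on top of that. Internal arithmetic never rounds; comparison
with values printed at one decimal is done by the caller.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RESIDUE_MASSES",
    "HYDROGEN",
    "AMIDE_TERM",
    "ACID_TERM",
    "A_MINUS_B",
    "IMMONIUM_OFFSET",
    "PROLYL_SIDE_CHAIN",
    "CTerm",
    "IonType",
    "Modification",
    "MODIFICATION_REGISTRY",
    "Peptide",
    "TheoreticalIon",
    "AlphabetError",
    "InputError",
    "peptide_mh",
    "residue_masses_of",
    "fragment_ions",
    "fragment_ions_from_masses",
    "classify_mass_shift",
    "ModificationMatch",
    "free_amine_count",
    "write_modification_registry",
    "ions_to_tsv",
]

# Monoisotopic residue masses (Da) of the 20 standard amino acids, plus the
# Xle ambiguity code 'J' for the isobaric Ile/Leu pair.
RESIDUE_MASSES: Mapping[str, float] = MappingProxyType(
    {
        "G": 57.02146,
        "A": 71.03711,
        "S": 87.03203,
        "P": 97.05276,
        "V": 99.06841,
        "T": 101.04768,
        "C": 103.00919,
        "L": 113.08406,
        "I": 113.08406,
        "J": 113.08406,
        "N": 114.04293,
        "D": 115.02694,
        "Q": 128.05858,
        "K": 128.09496,
        "E": 129.04259,
        "M": 131.04049,
        "H": 137.05891,
        "F": 147.06841,
        "R": 156.10111,
        "Y": 163.06333,
        "W": 186.07931,
    }
)

#: Charge-carrier/backbone hydrogen (H-atom convention of peptide calculators).
HYDROGEN = 1.00782
#: C-terminal amide terminus constant: MH+ = sum(residues) + AMIDE_TERM.
AMIDE_TERM = 18.03437
#: C-terminal free-acid terminus constant.
ACID_TERM = 19.01839
#: a ion = b ion - CO.
A_MINUS_B = 27.99491
#: immonium ion = residue mass - IMMONIUM_OFFSET.
IMMONIUM_OFFSET = 26.98709
#: neutral loss of the proline side chain (C3H6) from C-terminal-Pro precursors.
PROLYL_SIDE_CHAIN = 42.04695


class AlphabetError(ValueError):
    """A residue letter outside the supported amino-acid alphabet."""


class InputError(ValueError):
    """Structurally invalid input (empty sequence, bad ion type, ...)."""


class CTerm(str, enum.Enum):
    """C-terminal chemistry: post-translationally amidated or free acid."""

    amide = "amide"
    acid = "acid"


class IonType(str, enum.Enum):
    a = "a"
    b = "b"
    y = "y"
    internal_b = "internal_b"
    internal_a = "internal_a"
    immonium = "immonium"
    precursor = "precursor"
    precursor_loss = "precursor_loss"


#: Ion types enumerated by default: the full sequence-ion set used when a
#: candidate sequence is verified against its spectrum.
FULL_ION_SET = frozenset(
    {IonType.a, IonType.b, IonType.y, IonType.internal_b, IonType.immonium}
)


@dataclass(frozen=True)
class Modification:
    """A chemical modification with its monoisotopic mass shift.

    ``site_class`` names where the modification can occur: a free amine
    (N-terminus or Lys) for acetylation, Met/Trp for oxidation, the
    glycine-extended C-terminus for the amidation intermediate, or the
    C-terminal proline side chain for the characteristic -42 neutral loss.
    """

    name: str
    delta: float
    site_class: str


MODIFICATION_REGISTRY: tuple[Modification, ...] = (
    Modification("acetyl", 42.01057, "free amine"),
    Modification("oxidation", 15.99491, "M/W"),
    Modification("dioxidation", 31.98983, "W"),
    Modification("glycine-extension", 58.00548, "C-terminal G extension"),
    Modification("prolyl side-chain loss", -42.04695, "C-terminal P side chain"),
)

_REGISTRY_BY_NAME = {m.name: m for m in MODIFICATION_REGISTRY}


def get_modification(name: str) -> Modification:
    try:
        return _REGISTRY_BY_NAME[name]
    except KeyError:
        raise InputError(f"unknown modification: {name!r}") from None


@dataclass(frozen=True)
class Peptide:
    """A peptide: residue string, C-terminal form, and attached modifications.

    ``mods`` is a sequence of ``(Modification, site)`` pairs where ``site`` is a
    1-based residue index or the string ``"N-term"``; at most one modification
    per site.
    """

    sequence: str
    c_term: CTerm = CTerm.amide
    mods: tuple = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError("peptide sequence must be non-empty")
        bad = set(self.sequence) - set(RESIDUE_MASSES)
        if bad:
            raise AlphabetError(f"unknown residue letter(s): {sorted(bad)}")
        if not isinstance(self.c_term, CTerm):
            object.__setattr__(self, "c_term", CTerm(self.c_term))
        object.__setattr__(self, "mods", tuple(self.mods))
        sites = [site for _, site in self.mods]
        if len(sites) != len(set(sites)):
            raise InputError("at most one modification per site")
        for _, site in self.mods:
            if site == "N-term":
                continue
            if not (isinstance(site, int) and 1 <= site <= len(self.sequence)):
                raise InputError(f"modification site out of bounds: {site!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TheoreticalIon:
    """One predicted fragment ion: type, residue span (1-based, inclusive), m/z."""

    ion_type: IonType
    span: tuple[int, int]
    mz: float


def residue_masses_of(peptide: Peptide) -> list[float]:
    """Per-residue masses including any site-attached modification deltas.

    An N-terminal modification is folded into residue 1, which places it in
    every prefix (a/b) ion, as the chemistry dictates.
    """
    masses = [RESIDUE_MASSES[aa] for aa in peptide.sequence]
    for mod, site in peptide.mods:
        idx = 0 if site == "N-term" else site - 1
        masses[idx] += mod.delta
    return masses


def _terminal_constant(c_term: CTerm) -> float:
    return AMIDE_TERM if c_term is CTerm.amide else ACID_TERM


def peptide_mh(peptide: Peptide) -> float:
    """Singly protonated monoisotopic m/z (MH+) of a peptide.

    MH+ = sum of residue masses + 18.03437 (amide) or 19.01839 (free acid),
    plus all modification deltas.
    """
    return sum(residue_masses_of(peptide)) + _terminal_constant(peptide.c_term)


def mh_from_masses(masses: Sequence[float], c_term: CTerm) -> float:
    return sum(masses) + _terminal_constant(c_term)


def fragment_ions_from_masses(
    masses: Sequence[float],
    c_term: CTerm,
    types: Iterable[IonType],
    c_terminal_pro: bool = False,
) -> list[TheoreticalIon]:
    """Enumerate theoretical ions for an explicit residue-mass sequence.

    The mass-sequence form exists so that de novo candidates carrying residue
    ambiguity classes (which have a class mass but no single letter) can be
    scored with the same ion arithmetic as ordinary peptides.
    """
    types = {IonType(t) for t in types}
    if not types:
        raise InputError("types must be non-empty")
    n = len(masses)
    term = _terminal_constant(c_term)
    mh = sum(masses) + term
    prefix = list(itertools.accumulate(masses))
    ions: list[TheoreticalIon] = []

    if IonType.b in types or IonType.a in types:
        for k in range(1, n):
            b = prefix[k - 1] + HYDROGEN
            if IonType.b in types:
                ions.append(TheoreticalIon(IonType.b, (1, k), b))
            if IonType.a in types:
                ions.append(TheoreticalIon(IonType.a, (1, k), b - A_MINUS_B))
    if IonType.y in types:
        for k in range(1, n):
            y = (prefix[n - 1] - prefix[n - k - 1]) + term
            ions.append(TheoreticalIon(IonType.y, (n - k + 1, n), y))
    if IonType.internal_b in types or IonType.internal_a in types:
        # internal fragments contain neither terminus: spans within 2..n-1
        for i in range(2, n):
            for j in range(i + 1, n):
                frag = prefix[j - 1] - prefix[i - 2] + HYDROGEN
                if IonType.internal_b in types:
                    ions.append(TheoreticalIon(IonType.internal_b, (i, j), frag))
                if IonType.internal_a in types:
                    ions.append(
                        TheoreticalIon(IonType.internal_a, (i, j), frag - A_MINUS_B)
                    )
    if IonType.immonium in types:
        for i, m in enumerate(masses, start=1):
            ions.append(TheoreticalIon(IonType.immonium, (i, i), m - IMMONIUM_OFFSET))
    if IonType.precursor in types:
        ions.append(TheoreticalIon(IonType.precursor, (1, n), mh))
    if IonType.precursor_loss in types and c_terminal_pro:
        ions.append(
            TheoreticalIon(IonType.precursor_loss, (1, n), mh - PROLYL_SIDE_CHAIN)
        )
    return ions


def fragment_ions(peptide: Peptide, types: Iterable[IonType]) -> list[TheoreticalIon]:
    """Enumerate the requested theoretical fragment ions of a peptide.

    b/y (and a) indices run 1..n-1; internal fragments have spans of length >= 2
    containing neither terminus; C-terminal-proline peptides additionally yield
    the precursor minus 42.047 (side-chain neutral loss) when
    ``precursor_loss`` is requested.
    """
    return fragment_ions_from_masses(
        residue_masses_of(peptide),
        peptide.c_term,
        types,
        c_terminal_pro=peptide.sequence.endswith("P"),
    )


@dataclass(frozen=True)
class ModificationMatch:
    """A registry modification (possibly a small multiple) explaining a shift."""

    modification: Modification
    count: int
    delta: float
    error: float

    @property
    def name(self) -> str:
        if self.count == 1:
            return self.modification.name
        return f"{self.count}x {self.modification.name}"


# Shifts observed in MS1 are magnitudes of either gains or losses; repeated
# acetylation/oxidation up to this multiplicity is considered.
_MAX_MULTIPLE = 4
_MULTIPLIABLE = ("acetyl", "oxidation")


def classify_mass_shift(delta: float, tol: float) -> list[ModificationMatch]:
    """Explain an observed mass difference by registry modifications.

    Both signs are considered (a +42 gain and a -42 neutral loss are the same
    magnitude at MS1 reading precision); small integer multiples of acetylation
    and oxidation are included. Matches are ordered by absolute error; an empty
    list means no modification explains the shift.
    """
    if tol <= 0:
        raise InputError("tol must be positive")
    magnitude = abs(delta)
    out: list[ModificationMatch] = []
    for mod in MODIFICATION_REGISTRY:
        counts = range(1, _MAX_MULTIPLE + 1) if mod.name in _MULTIPLIABLE else (1,)
        for k in counts:
            expected = abs(mod.delta) * k
            err = magnitude - expected
            if abs(err) <= tol:
                out.append(ModificationMatch(mod, k, mod.delta * k, err))
    out.sort(key=lambda m: (abs(m.error), m.modification.name, m.count))
    return out


def free_amine_count(peptide: Peptide) -> int:
    """Number of free primary amines: the N-terminal alpha-amine plus Lys side
    chains (an N-terminally acetylated peptide loses the alpha-amine)."""
    n_term_blocked = any(site == "N-term" for _, site in peptide.mods)
    return (0 if n_term_blocked else 1) + peptide.sequence.count("K")


def write_modification_registry(path) -> None:
    """Serialize the modification registry as a plain-text TSV table."""
    with open(path, "w") as fh:
        fh.write("name\tdelta\tsite_class\n")
        for mod in MODIFICATION_REGISTRY:
            fh.write(f"{mod.name}\t{mod.delta:.5f}\t{mod.site_class}\n")


def ions_to_tsv(ions: Sequence[TheoreticalIon], path) -> None:
    """Export an ion enumeration as TSV (ion_type, span, m/z)."""
    with open(path, "w") as fh:
        fh.write("ion_type\tspan\tmz\n")
        for ion in sorted(ions, key=lambda i: (i.ion_type.value, i.span)):
            fh.write(f"{ion.ion_type.value}\t{ion.span[0]}-{ion.span[1]}\t{ion.mz:.6f}\n")
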