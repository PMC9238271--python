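"""Peptide masses, b/y fragment ions, and MRM transition sets.

Masses are computed from the standard monoisotopic residue table.  A
peptide may carry intramolecular disulfide bridges; forming one bridge
removes two hydrogens (2.01565 Da).  The correction is applied to the
intact peptide once per bridge, and to a fragment ion only when *both*
cysteines of a bridge fall inside the fragment — a fragment that cuts
through a bridge is reported uncorrected with ``contains_disulfide``
False, because the open/closed state of a severed bridge is not defined
by the sequence alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "RESIDUE_MONO_MASS",
    "WATER_MONO",
    "PROTON",
    "DISULFIDE_MASS_LOSS",
    "Peptide",
    "FragmentIon",
    "Transition",
    "TransitionSet",
    "ENTF",
    "ENTF_STAR",
    "CXCL12_ACTIVE_DOMAIN",
    "monoisotopic_mass",
    "fragment_mz",
    "fragment_ion",
    "builtin_transition_sets",
    "read_fasta_peptides",
]

#: Monoisotopic masses of the 20 standard amino-acid residues (Da).
RESIDUE_MONO_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
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

WATER_MONO = 18.01056
PROTON = 1.00728
#: Mass lost when a Cys-Cys disulfide bridge forms (two hydrogens).
DISULFIDE_MASS_LOSS = 2.01565


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with optional intramolecular disulfide bridges.

    ``disulfide_pairs`` uses 1-based residue indices; every index must
    point at a cysteine and no cysteine may take part in two bridges.
    """

    name: str
    sequence: str
    disulfide_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for ch in self.sequence:
            if ch not in RESIDUE_MONO_MASS:
                raise ValueError(
                    f"non-standard residue {ch!r} in peptide {self.name!r}"
                )
        pairs = tuple(tuple(sorted(p)) for p in self.disulfide_pairs)
        object.__setattr__(self, "disulfide_pairs", pairs)
        seen: set[int] = set()
        for i, j in pairs:
            for idx in (i, j):
                if not 1 <= idx <= len(self.sequence):
                    raise ValueError(f"disulfide index {idx} out of range")
                if self.sequence[idx - 1] != "C":
                    raise ValueError(
                        f"disulfide index {idx} does not point at a cysteine"
                    )
                if idx in seen:
                    raise ValueError(f"residue {idx} appears in two disulfide pairs")
                seen.add(idx)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentIon:
    series: Literal["b", "y"]
    index: int
    charge: int
    mz: float
    contains_disulfide: bool


@dataclass(frozen=True)
class Transition:
    product_mz: float
    collision_energy_ev: float
    role: Literal["quantifier", "qualifier"]


@dataclass(frozen=True)
class TransitionSet:
    """MRM precursor plus quantifier/qualifier product ions.

    Precursor m/z values are stored as instrument-method constants, not
    recomputed from the sequence.
    """

    peptide_name: str
    precursor_mz: float
    products: tuple[Transition, ...]

    def __post_init__(self) -> None:
        roles = [t.role for t in self.products]
        if roles.count("quantifier") != 1:
            raise ValueError("a transition set needs exactly one quantifier")
        for t in self.products:
            if t.product_mz >= 2 * self.precursor_mz:
                raise ValueError("product m/z must be below twice the precursor m/z")

    @property
    def quantifier(self) -> Transition:
        return next(t for t in self.products if t.role == "quantifier")

    @property
    def qualifiers(self) -> tuple[Transition, ...]:
        return tuple(t for t in self.products if t.role == "qualifier")


#: Mature quorum-sensing peptide of Enterococcus faecium.
ENTF = Peptide("EntF", "AGTKPQGKPASNLVECVFSLFKKCN", ((16, 24),))
#: 15-mer C-terminal metabolite of EntF; Cys6-Cys14 bridged by default.
ENTF_STAR = Peptide("EntF*", "SNLVECVFSLFKKCN", ((6, 14),))
#: N-terminal CXCR4-activating stretch of CXCL12 (residues 22-30).
CXCL12_ACTIVE_DOMAIN = Peptide("CXCL12-domain", "KPVSLSYRC")


def monoisotopic_mass(peptide: Peptide) -> float:
    """Neutral monoisotopic mass in Da, including disulfide corrections."""
    total = sum(RESIDUE_MONO_MASS[ch] for ch in peptide.sequence) + WATER_MONO
    return total - DISULFIDE_MASS_LOSS * len(peptide.disulfide_pairs)


def _fragment_residue_span(series: str, index: int, length: int) -> tuple[int, int]:
    # 1-based inclusive residue span covered by the fragment
    if series == "b":
        return 1, index
    return length - index + 1, length


def fragment_ion(
    peptide: Peptide, series: Literal["b", "y"], index: int, charge: int = 1
) -> FragmentIon:
    """b- or y-ion of a peptide as a :class:`FragmentIon`.

    b_k = (sum of the first k residues + z*proton) / z;
    y_k = (sum of the last k residues + water + z*proton) / z.
    The disulfide correction (−2.01565 Da) applies only when both
    cysteines of a bridge lie inside the fragment.
    """
    if series not in ("b", "y"):
        raise ValueError(f"unknown ion series {series!r}")
    if not 1 <= index < len(peptide):
        raise ValueError(
            f"fragment index {index} out of range for length {len(peptide)}"
        )
    if charge < 1:
        raise ValueError("charge must be >= 1")
    lo, hi = _fragment_residue_span(series, index, len(peptide))
    residues = peptide.sequence[lo - 1 : hi]
    neutral = sum(RESIDUE_MONO_MASS[ch] for ch in residues)
    if series == "y":
        neutral += WATER_MONO
    contains = False
    for i, j in peptide.disulfide_pairs:
        if lo <= i <= hi and lo <= j <= hi:
            neutral -= DISULFIDE_MASS_LOSS
            contains = True
    mz = (neutral + charge * PROTON) / charge
    return FragmentIon(series=series, index=index, charge=charge, mz=mz,
                       contains_disulfide=contains)


def fragment_mz(
    peptide: Peptide, series: Literal["b", "y"], index: int, charge: int = 1
) -> float:
    """m/z (Th) of the requested b/y fragment ion."""
    return fragment_ion(peptide, series, index, charge).mz


def builtin_transition_sets() -> dict[str, TransitionSet]:
    """The EntF* and EntF MRM transition sets used by the detection rules.

    EntF*: precursor m/z 865.7 -> b2 202.08 (quantifier, 36 eV) and
    b3 315.17 (qualifier, 31 eV).  EntF: precursor m/z 667.1 -> y17
    949.4 (quantifier, 22 eV), b2 129.0 and b25 662.6 (qualifiers).
    """
    return {
        "EntF*": TransitionSet(
            "EntF*",
            865.7,
            (
                Transition(202.08, 36.0, "quantifier"),
                Transition(315.17, 31.0, "qualifier"),
            ),
        ),
        "EntF": TransitionSet(
            "EntF",
            667.1,
            (
                Transition(949.4, 22.0, "quantifier"),
                Transition(129.0, 30.0, "qualifier"),
                Transition(662.6, 22.0, "qualifier"),
            ),
        ),
    }


def get_transition_set(name: str) -> TransitionSet:
    sets = builtin_transition_sets()
    if name not in sets:
        raise KeyError(
            f"no built-in transition set for {name!r}; available: {sorted(sets)}"
        )
    return sets[name]


def _parse_disulfide_field(description: str) -> tuple[tuple[int, int], ...]:
    # description may carry e.g. "disulfide=6-14" or "disulfide=6-14,1-3"
    for token in description.split():
        if token.startswith("disulfide="):
            pairs = []
            for chunk in token.removeprefix("disulfide=").split(","):
                i, j = chunk.split("-")
                pairs.append((int(i), int(j)))
            return tuple(pairs)
    return ()


def read_fasta_peptides(path: str | Path) -> list[Peptide]:
    """Read peptides from FASTA; the header may carry ``disulfide=i-j``."""
    from Bio import SeqIO

    peptides = []
    for rec in SeqIO.parse(str(path), "fasta"):
        pairs = _parse_disulfide_field(rec.description)
        peptides.append(Peptide(rec.id, str(rec.seq).upper(), pairs))
    if not peptides:
        raise ValueError(f"no FASTA records found in {path}")
    return peptides
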