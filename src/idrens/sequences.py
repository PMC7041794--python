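"""Registry of the studied C-terminal peptide, its alanine variants and
residue-level annotations.

The wild-type construct is the 22-residue acidic C-terminal region of the
magnetosome protein Mms6 (absolute residue numbering 38-59).  Variants are
expressed as alanine substitutions at absolute positions; the registry is
hard-coded and can also be round-tripped through FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Side-chain formal charge at pH 7.4.  Termini of the internal fragment are
#: treated as capped/neutral; His is treated as neutral.
FORMAL_CHARGE_PH74: Mapping[str, int] = {
    "D": -1,
    "E": -1,
    "K": +1,
    "R": +1,
}

#: Relative helix-forming weight per residue type (dimensionless, >= 0).
#: Loosely ranked after experimental helix-propensity scales (Ala high,
#: Gly/Pro low); the absolute scale is calibrated so that the default sampler
#: produces 10-15% transient C-terminal helicity for the wild type.
HELIX_PROPENSITY: Mapping[str, float] = {
    "A": 1.00,
    "L": 0.79,
    "R": 0.79,
    "M": 0.73,
    "K": 0.73,
    "Q": 0.61,
    "E": 0.61,
    "I": 0.57,
    "W": 0.49,
    "S": 0.50,
    "Y": 0.47,
    "F": 0.54,
    "H": 0.39,
    "V": 0.44,
    "N": 0.39,
    "T": 0.39,
    "C": 0.42,
    "D": 0.46,
    "G": 0.18,
    "P": 0.05,
}

#: Effective steric radius (Angstrom) of the single side-chain bead, a
#: coarse volume-ranked scale.
STERIC_RADIUS: Mapping[str, float] = {
    "G": 1.0,
    "A": 1.6,
    "S": 1.7,
    "C": 1.8,
    "T": 1.9,
    "P": 1.9,
    "D": 2.0,
    "N": 2.0,
    "V": 2.0,
    "E": 2.2,
    "Q": 2.2,
    "I": 2.2,
    "L": 2.2,
    "M": 2.3,
    "H": 2.3,
    "K": 2.4,
    "F": 2.5,
    "R": 2.6,
    "Y": 2.6,
    "W": 2.9,
}


class UnknownVariantError(KeyError):
    """Raised when a variant name is not in the registry."""


@dataclass(frozen=True)
class PeptideSequence:
    """One-letter residue string with an absolute numbering offset.

    Absolute position of residue ``i`` (0-based) is ``start_number + i``.
    """

    residues: str
    start_number: int = 38
    name: str = ""

    def __post_init__(self) -> None:
        bad = set(self.residues) - CANONICAL_AA
        if bad:
            raise ValueError(f"non-canonical residue codes: {sorted(bad)}")
        if len(self.residues) < 2:
            raise ValueError("sequence must contain at least 2 residues")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> range:
        """Absolute residue numbers."""
        return range(self.start_number, self.start_number + len(self.residues))

    def residue_at(self, absolute_position: int) -> str:
        i = absolute_position - self.start_number
        if not 0 <= i < len(self.residues):
            raise IndexError(
                f"position {absolute_position} outside "
                f"[{self.start_number}, {self.start_number + len(self.residues) - 1}]"
            )
        return self.residues[i]

    def charges(self) -> list[int]:
        """Per-residue side-chain formal charge at pH 7.4."""
        return [FORMAL_CHARGE_PH74.get(r, 0) for r in self.residues]

    def helix_propensities(self) -> list[float]:
        return [HELIX_PROPENSITY[r] for r in self.residues]

    def steric_radii(self) -> list[float]:
        return [STERIC_RADIUS[r] for r in self.residues]


@dataclass(frozen=True)
class VariantSpec:
    """A named set of point substitutions against the wild type."""

    name: str
    substitutions: tuple[tuple[int, str, str], ...] = field(default_factory=tuple)

    def apply(self, wt: PeptideSequence) -> PeptideSequence:
        residues = list(wt.residues)
        for pos, frm, to in self.substitutions:
            i = pos - wt.start_number
            if not 0 <= i < len(residues):
                raise ValueError(f"{self.name}: position {pos} outside sequence range")
            if residues[i] != frm:
                raise ValueError(
                    f"{self.name}: wild type has {residues[i]} at {pos}, expected {frm}"
                )
            residues[i] = to
        return PeptideSequence("".join(residues), wt.start_number, self.name)


WT_SEQUENCE = PeptideSequence("MKSRDIESAQSDEEVELRDALA", start_number=38, name="WT")

# "EE50AA" mutates the two adjacent glutamates 50 and 51; "MM" is the triple
# alanine substitution of E44, E50 and R55.
VARIANTS: Mapping[str, VariantSpec] = {
    "WT": VariantSpec("WT"),
    "D42A": VariantSpec("D42A", ((42, "D", "A"),)),
    "E44A": VariantSpec("E44A", ((44, "E", "A"),)),
    "D49A": VariantSpec("D49A", ((49, "D", "A"),)),
    "E50A": VariantSpec("E50A", ((50, "E", "A"),)),
    "E51A": VariantSpec("E51A", ((51, "E", "A"),)),
    "EE50AA": VariantSpec("EE50AA", ((50, "E", "A"), (51, "E", "A"))),
    "E53A": VariantSpec("E53A", ((53, "E", "A"),)),
    "R55A": VariantSpec("R55A", ((55, "R", "A"),)),
    "D56A": VariantSpec("D56A", ((56, "D", "A"),)),
    "MM": VariantSpec("MM", ((44, "E", "A"), (50, "E", "A"), (55, "R", "A"))),
}

VARIANT_NAMES: tuple[str, ...] = tuple(VARIANTS)


def get_variant(name: str) -> PeptideSequence:
    """Return the peptide for a registered construct label.

    Raises :class:`UnknownVariantError` listing the valid names otherwise.
    """
    try:
        spec = VARIANTS[name]
    except KeyError:
        raise UnknownVariantError(
            f"unknown variant {name!r}; valid names: {', '.join(VARIANTS)}"
        ) from None
    return spec.apply(WT_SEQUENCE)


def net_charge(seq: PeptideSequence) -> int:
    """Net side-chain formal charge at pH 7.4, termini excluded."""
    return sum(seq.charges())


def to_fasta(names: Iterable[str] | None = None) -> str:
    """FASTA text with one record per construct (record ID = variant name)."""
    names = list(names) if names is not None else list(VARIANTS)
    records = []
    for name in names:
        seq = get_variant(name)
        records.append(f">{name} positions {seq.start_number}-{seq.positions[-1]}")
        records.append(seq.residues)
    return "\n".join(records) + "\n"


def from_fasta(text: str, start_number: int = 38) -> dict[str, PeptideSequence]:
    """Parse variant records back out of FASTA text."""
    out: dict[str, PeptideSequence] = {}
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                out[name] = PeptideSequence("".join(chunks), start_number, name)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line)
    if name is not None:
        out[name] = PeptideSequence("".join(chunks), start_number, name)
    return out
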