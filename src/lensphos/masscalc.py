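"""Peptide chemistry core.

Monoisotopic residue masses, variable modifications (phosphorylation,
methionine oxidation), peptide mass and m/z arithmetic, in-silico tryptic
digestion with the proline rule, and mapping of within-peptide positions to
protein-level site designations such as ``Ser-19``.

All masses are monoisotopic and in daltons; m/z values are in thomson (Th).
Coordinates are 1-based inclusive, the convention used for peptide fragment
ranges like ``12-22`` in phosphosite catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

# Monoisotopic residue (amino-acid minus water) masses, Da.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
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

WATER_MONO = 18.010565
PROTON_MASS = 1.007276

THREE_LETTER = {
    "G": "Gly", "A": "Ala", "S": "Ser", "P": "Pro", "V": "Val",
    "T": "Thr", "C": "Cys", "L": "Leu", "I": "Ile", "N": "Asn",
    "D": "Asp", "Q": "Gln", "K": "Lys", "E": "Glu", "M": "Met",
    "H": "His", "F": "Phe", "R": "Arg", "Y": "Tyr", "W": "Trp",
}


@dataclass(frozen=True)
class ModificationSpec:
    """A variable mass modification restricted to certain residues."""

    name: str
    delta: float
    residues: frozenset[str]
    terminal: bool = False  # True for protein-terminus mods (unused by default set)

    def __post_init__(self) -> None:
        if not self.delta or self.delta != self.delta:
            raise ValueError(f"modification {self.name!r}: delta must be finite and nonzero")
        if not self.residues:
            raise ValueError(f"modification {self.name!r}: empty residue set")

    def allows(self, residue: str) -> bool:
        return residue in self.residues


PHOSPHO = ModificationSpec("Phospho", 79.966331, frozenset("STY"))
OXIDATION = ModificationSpec("Oxidation", 15.994915, frozenset("M"))


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with positioned modifications and a charge state.

    ``modifications`` holds ``(position, spec)`` pairs with 1-based positions
    within the peptide.
    """

    sequence: str
    modifications: tuple[tuple[int, ModificationSpec], ...] = ()
    charge: int = 2

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for aa in self.sequence:
            if aa not in MONOISOTOPIC_RESIDUE_MASS:
                raise ValueError(f"unknown residue code {aa!r} in {self.sequence!r}")
        for pos, spec in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside peptide of length {len(self.sequence)}"
                )
            residue = self.sequence[pos - 1]
            if not spec.allows(residue):
                raise ValueError(
                    f"{spec.name} not allowed on residue {residue!r} at position {pos}"
                )
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")

    @property
    def key(self) -> str:
        """Stable identity string: sequence, sorted mod positions, charge."""
        mods = ";".join(f"{p}:{s.name}" for p, s in sorted(self.modifications))
        return f"{self.sequence}|{mods}|{self.charge}"


def peptide_monoisotopic_mass(peptide: ModifiedPeptide | str,
                              modifications: Iterable[tuple[int, ModificationSpec]] = ()) -> float:
    """Neutral monoisotopic mass of a (modified) peptide in Da.

    Sum of residue masses plus one water plus modification deltas; the
    charge state plays no role here.
    """
    if isinstance(peptide, str):
        peptide = ModifiedPeptide(peptide, tuple(modifications), charge=1)
    mass = WATER_MONO
    for aa in peptide.sequence:
        mass += MONOISOTOPIC_RESIDUE_MASS[aa]
    for _, spec in peptide.modifications:
        mass += spec.delta
    return mass


def compute_mz(mass: float, charge: int) -> float:
    """m/z of an [M + zH]^z+ ion."""
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


def mass_from_mz(mz: float, charge: int) -> float:
    """Neutral mass back-computed from an observed m/z; inverse of compute_mz."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON_MASS


def peptide_mz(sequence: str, charge: int, n_phospho: int = 0) -> float:
    """Convenience: m/z of a peptide carrying ``n_phospho`` phosphate groups.

    The phospho positions do not affect the mass, so none need be given; this
    is the calculation used to check catalog m/z values where each row lists a
    single phosphosite.
    """
    mass = peptide_monoisotopic_mass(ModifiedPeptide(sequence, (), charge=1))
    mass += n_phospho * PHOSPHO.delta
    return compute_mz(mass, charge)


@dataclass(frozen=True)
class DigestFragment:
    """A tryptic fragment with 1-based inclusive coordinates in its parent."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("fragment coordinates inconsistent with sequence length")
        if self.missed_cleavages < 0:
            raise ValueError("missed cleavage count must be >= 0")


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices *after* which trypsin cleaves: K/R not followed by P."""
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            sites.append(i)
    return sites


def tryptic_digest(protein_sequence: str, max_missed_cleavages: int = 2) -> list[DigestFragment]:
    """In-silico tryptic digestion.

    Cleaves C-terminal to K/R except before proline. Returns every fragment
    with 0..max_missed_cleavages internal missed cleavage sites; the
    zero-missed-cleavage fragments tile the protein exactly. The N-terminal
    methionine is retained (catalog numbering counts it).
    """
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    # Boundaries of the fully-cleaved peptides, as 0-based start indices.
    cuts = [i + 1 for i in cleavage_sites(protein_sequence)]
    starts = [0] + cuts
    ends = cuts + [len(protein_sequence)]  # exclusive
    fragments: list[DigestFragment] = []
    n = len(starts)
    for i in range(n):
        for j in range(i, min(i + max_missed_cleavages + 1, n)):
            s, e = starts[i], ends[j]
            fragments.append(
                DigestFragment(protein_sequence[s:e], s + 1, e, missed_cleavages=j - i)
            )
    return fragments


def annotate_site_position(fragment: DigestFragment, position_in_peptide: int) -> str:
    """Protein-level site designation, e.g. ``Ser-19``, for a peptide position."""
    if not 1 <= position_in_peptide <= len(fragment.sequence):
        raise ValueError(
            f"position {position_in_peptide} outside peptide of length {len(fragment.sequence)}"
        )
    residue = fragment.sequence[position_in_peptide - 1]
    protein_pos = fragment.start + position_in_peptide - 1
    return f"{THREE_LETTER[residue]}-{protein_pos}"


def parse_designation(designation: str) -> tuple[str, int]:
    """Split a designation like ``Ser-19`` into its one-letter code and position."""
    name, _, pos = designation.partition("-")
    one = {v: k for k, v in THREE_LETTER.items()}.get(name)
    if one is None or not pos.isdigit():
        raise ValueError(f"malformed site designation {designation!r}")
    return one, int(pos)


def read_fasta(path) -> dict[str, str]:
    """Protein sequences keyed by accession (header token up to first whitespace)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
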