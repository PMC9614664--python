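"""Core record types shared across the package.

The package works with candidate surrogate-light-chain (SLC) proteins —
VpreB1, VpreB2, VpreB3, IGLL1 (lambda5) and PTCRA — one record per species.
VpreB proteins carry a C-terminal unique region ("tail"); IGLL1 carries an
N-terminal one. Tail boundaries are 0-based half-open internally and 1-based
inclusive in user-facing tables.
"""

from __future__ import annotations

from dataclasses import dataclass

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_ALPHABET = frozenset(AMINO_ACIDS + "X")

BASIC_RESIDUES = frozenset("RKH")
ACIDIC_RESIDUES = frozenset("DE")
CHARGED_RESIDUES = BASIC_RESIDUES | ACIDIC_RESIDUES

GENE_FAMILIES = ("VpreB1", "VpreB2", "VpreB3", "IGLL1", "PTCRA")


class RecordError(ValueError):
    """Invalid record content (alphabet, empty sequence, duplicate id)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One species' candidate protein.

    Parameters
    ----------
    id : str
        Stable identifier, unique within a dataset.
    species : str
        Binomial or common name.
    clade : str
        Branch label (e.g. "glires", "artiodactyla"); free text.
    gene_label : str
        Claimed or assigned family; "" when unassigned.
    sequence : str
        Uppercase amino acids, 20 canonical letters plus X.
    """

    id: str
    species: str
    sequence: str
    clade: str = ""
    gene_label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise RecordError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise RecordError(
                f"record {self.id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TailAnnotation:
    """A delineated unique-region (tail) annotation.

    ``boundary`` is the 0-based index of the first tail residue for a
    C-terminal tail, or one-past-the-last tail residue for an N-terminal
    tail; either way ``tail_length == len(tail_sequence)`` and the tail is
    ``sequence[boundary:]`` (C-terminal) or ``sequence[:boundary]``
    (N-terminal).
    """

    record_id: str
    side: str  # "C" or "N"
    boundary: int
    tail_sequence: str
    tail_length: int
    n_basic: int
    n_acidic: int
    tail_pi: float | None
    full_pi: float | None
    pka_set: str = ""

    def __post_init__(self) -> None:
        if self.side not in ("C", "N"):
            raise ValueError(f"side must be 'C' or 'N', got {self.side!r}")
        if self.tail_length != len(self.tail_sequence):
            raise ValueError("tail_length inconsistent with tail_sequence")
        if self.n_basic + self.n_acidic > self.tail_length:
            raise ValueError("charged counts exceed tail length")
        for name, pi in (("tail_pi", self.tail_pi), ("full_pi", self.full_pi)):
            if pi is not None and not (0.0 < pi < 14.0):
                raise ValueError(f"{name} out of (0, 14): {pi}")

    @property
    def n_charged(self) -> int:
        return self.n_basic + self.n_acidic


@dataclass(frozen=True)
class CuratedReference:
    """A curated family reference with an annotated tail boundary.

    ``boundary`` follows the TailAnnotation convention for ``side``.
    ``conserved_sites`` lists (0-based position, residue) pairs that must be
    conserved in family members (used for PTCRA validation).
    """

    family: str
    sequence: str
    boundary: int
    side: str = "C"
    conserved_sites: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.side not in ("C", "N"):
            raise ValueError(f"side must be 'C' or 'N', got {self.side!r}")
        if not (0 <= self.boundary <= len(self.sequence)):
            raise ValueError("boundary outside sequence")
        for pos, res in self.conserved_sites:
            if not (0 <= pos < len(self.sequence)):
                raise ValueError(f"conserved site {pos} outside sequence")
            if self.sequence[pos] != res:
                raise ValueError(
                    f"conserved site {pos}: reference has "
                    f"{self.sequence[pos]!r}, expected {res!r}"
                )

    @property
    def tail_sequence(self) -> str:
        if self.side == "C":
            return self.sequence[self.boundary:]
        return self.sequence[: self.boundary]


def check_unique_ids(records: list[ProteinRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise RecordError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
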