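"""Unique-region ("tail") delineation, charged-residue counts, and
isoelectric points.

VpreB1/VpreB2 carry a C-terminal unique region and IGLL1 an N-terminal one.
The tail boundary of a query is obtained by projecting a curated reference
boundary through a global pairwise alignment onto the query — the reference
column carrying the boundary is located in the alignment and mapped to the
corresponding query coordinate.

The isoelectric point is the pH at which the Henderson–Hasselbalch net
charge

    Q(pH) = sum_basic 1 / (1 + 10^(pH - pKa))
          - sum_acidic 1 / (1 + 10^(pKa - pH))

crosses zero. Q is strictly decreasing in pH whenever the peptide has at
least one ionizable group, so the root is unique and is found by bisection
on [0, 14]. Two pKa scales ship with the package (Bjellqvist, the default,
and EMBOSS); the scale used is recorded in every annotation because the
point values — though not the ranks — depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .phylo import global_align
from .records import (ACIDIC_RESIDUES, BASIC_RESIDUES, CuratedReference,
                      ProteinRecord, TailAnnotation)


class UnalignableError(ValueError):
    """Query/reference alignment identity below the configured floor."""


class NoIsoelectricPointError(ValueError):
    """Sequence has no ionizable group (or no root in (0, 14))."""


@dataclass(frozen=True)
class PkaSet:
    """A named pKa scale: side-chain pKa for D, E, C, Y, H, K, R plus the
    free termini."""

    name: str
    side_chain: dict[str, float]
    n_term: float
    c_term: float

    def __post_init__(self) -> None:
        for res in "DECYHKR":
            if res not in self.side_chain:
                raise ValueError(f"pKa set {self.name!r} missing {res}")
        for value in (*self.side_chain.values(), self.n_term, self.c_term):
            if not (0.0 < value < 14.0):
                raise ValueError(f"pKa {value} outside (0, 14)")


BJELLQVIST = PkaSet(
    name="bjellqvist",
    side_chain={"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
                "H": 5.98, "K": 10.0, "R": 12.0},
    n_term=7.5,
    c_term=3.55,
)

EMBOSS = PkaSet(
    name="emboss",
    side_chain={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
                "H": 6.5, "K": 10.8, "R": 12.5},
    n_term=8.6,
    c_term=3.6,
)

PKA_SETS = {s.name: s for s in (BJELLQVIST, EMBOSS)}

_ACIDIC_GROUPS = "DECY"
_BASIC_GROUPS = "HKR"


def count_charged(tail_sequence: str) -> tuple[int, int]:
    """(n_basic, n_acidic) = (# of R/K/H, # of D/E). X counts for neither."""
    n_basic = sum(1 for c in tail_sequence if c in BASIC_RESIDUES)
    n_acidic = sum(1 for c in tail_sequence if c in ACIDIC_RESIDUES)
    return n_basic, n_acidic


def net_charge(sequence: str, ph: float, pka: PkaSet = BJELLQVIST,
               termini: bool = True) -> float:
    """Henderson–Hasselbalch net charge of a free peptide at a given pH."""
    basic_pkas = [pka.side_chain[c] for c in sequence if c in _BASIC_GROUPS]
    acidic_pkas = [pka.side_chain[c] for c in sequence if c in _ACIDIC_GROUPS]
    if termini:
        basic_pkas.append(pka.n_term)
        acidic_pkas.append(pka.c_term)
    q = sum(1.0 / (1.0 + 10.0 ** (ph - k)) for k in basic_pkas)
    q -= sum(1.0 / (1.0 + 10.0 ** (k - ph)) for k in acidic_pkas)
    return q


def compute_pi(sequence: str, pka: PkaSet = BJELLQVIST,
               termini: bool = True, tol: float = 1e-4) -> float:
    """Isoelectric point by bisection of the net-charge function.

    Raises NoIsoelectricPointError if the sequence has no ionizable group
    (possible only with ``termini=False``) or if the net charge does not
    change sign on [0, 14].
    """
    if not sequence:
        raise ValueError("empty sequence")
    has_group = termini or any(
        c in _BASIC_GROUPS or c in _ACIDIC_GROUPS for c in sequence)
    if not has_group:
        raise NoIsoelectricPointError("no ionizable groups")
    lo, hi = 0.0, 14.0
    q_lo = net_charge(sequence, lo, pka, termini)
    q_hi = net_charge(sequence, hi, pka, termini)
    if q_lo <= 0.0 or q_hi >= 0.0:
        raise NoIsoelectricPointError("net charge does not cross zero in (0, 14)")
    # converge on interval width: |Q| can stay tiny over a wide pH range
    # when the root sits far from every pKa, so a charge-based early exit
    # would be less accurate than the bracket itself
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka, termini) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def project_position(aligned_ref: str, aligned_query: str,
                     ref_index: int) -> int:
    """Map a 0-based reference coordinate to the query through an alignment.

    Returns the number of query residues preceding the alignment column at
    which the reference reaches ``ref_index`` residues; ``ref_index`` equal
    to the reference length maps to the query length.
    """
    if len(aligned_ref) != len(aligned_query):
        raise ValueError("aligned rows differ in length")
    r = q = 0
    for cr, cq in zip(aligned_ref, aligned_query):
        if r == ref_index and cr != "-":
            return q
        if cr != "-":
            r += 1
        if cq != "-":
            q += 1
    if ref_index == r:  # one-past-end
        return q
    raise ValueError(f"reference index {ref_index} beyond reference length {r}")


def delineate_tail(
    record: ProteinRecord,
    reference: CuratedReference,
    pka: PkaSet = BJELLQVIST,
    identity_floor: float = 0.2,
) -> TailAnnotation:
    """Project a curated reference tail boundary onto a query record.

    The reference and query are globally aligned (BLOSUM62, affine gaps);
    an alignment whose column identity falls below ``identity_floor``
    raises UnalignableError. The annotated tail's charge counts and the
    tail/full-protein isoelectric points are computed on the fly.
    """
    aln = global_align(reference.sequence, record.sequence)
    if aln.identity_columns < identity_floor:
        raise UnalignableError(
            f"record {record.id!r} vs {reference.family} reference: identity "
            f"{aln.identity_columns:.2f} below floor {identity_floor:.2f}")
    boundary = project_position(aln.aligned_query, aln.aligned_subject,
                                reference.boundary)
    if reference.side == "C":
        tail = record.sequence[boundary:]
    else:
        tail = record.sequence[:boundary]
    n_basic, n_acidic = count_charged(tail)

    def _pi(seq: str) -> float | None:
        try:
            return compute_pi(seq, pka=pka, termini=True)
        except (NoIsoelectricPointError, ValueError):
            return None

    return TailAnnotation(
        record_id=record.id,
        side=reference.side,
        boundary=boundary,
        tail_sequence=tail,
        tail_length=len(tail),
        n_basic=n_basic,
        n_acidic=n_acidic,
        tail_pi=_pi(tail),
        full_pi=_pi(record.sequence),
        pka_set=pka.name,
    )


def feature_table(records: Iterable[ProteinRecord],
                  annotations: Iterable[TailAnnotation]) -> pd.DataFrame:
    """One row per annotated record: id, species, clade, gene_label, side,
    tail_length, n_basic, n_acidic, tail_pi, full_pi, pka_set. Boundaries
    are reported 1-based inclusive (column ``tail_start``/``tail_end``)."""
    by_id = {r.id: r for r in records}
    rows = []
    for ann in annotations:
        rec = by_id[ann.record_id]
        if ann.side == "C":
            start, end = ann.boundary + 1, len(rec.sequence)
        else:
            start, end = 1, ann.boundary
        rows.append({
            "id": rec.id, "species": rec.species, "clade": rec.clade,
            "gene_label": rec.gene_label, "side": ann.side,
            "tail_start": start, "tail_end": end,
            "tail_length": ann.tail_length, "n_basic": ann.n_basic,
            "n_acidic": ann.n_acidic, "tail_pi": ann.tail_pi,
            "full_pi": ann.full_pi, "pka_set": ann.pka_set,
        })
    return pd.DataFrame(rows, columns=[
        "id", "species", "clade", "gene_label", "side", "tail_start",
        "tail_end", "tail_length", "n_basic", "n_acidic", "tail_pi",
        "full_pi", "pka_set"])
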