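"""Pairwise global alignment, identity matrices, similarity shading, and
neighbor-joining trees with bootstrap support.

Alignment is global (Needleman–Wunsch with Gotoh affine gaps) under BLOSUM62
with gap open 11 and gap extend 1 by default: a gap of length k costs
``gap_open + k * gap_extend``. Two percent-identity conventions are reported
for every alignment, because "% of residues shared" is ambiguous:

* ``identity_columns`` — identical columns / columns with a residue in both
  rows (gapped columns excluded from the denominator);
* ``identity_shorter`` — identical columns / length of the shorter sequence.

Trees are built by neighbor joining on distance matrices (1 - identity by
default); support values come from resampling alignment columns with
replacement and counting, for each internal bipartition of the point
estimate, the fraction of replicate trees that contain it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .records import ProteinRecord

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: float
    identity_columns: float
    identity_shorter: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned rows differ in length")


@dataclass(frozen=True)
class TreeResult:
    """An unrooted NJ tree; ``support`` maps each internal bipartition
    (frozenset of leaf ids on one side) to a bootstrap percentage."""

    tree: TreeNode
    support: dict[frozenset, float] | None = None
    n_replicates: int = 0
    clamped_negative_total: float = 0.0

    def newick(self) -> str:
        return str(self.tree).strip()


def _make_aligner(matrix: str | None, gap_open: float,
                  gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    # Biopython charges open_gap_score at the first gap residue; our
    # convention is gap_open + k*gap_extend for a gap of length k.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _identities(row_a: str, row_b: str) -> tuple[float, float]:
    both = ident = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                ident += 1
    id_cols = ident / both if both else 0.0
    shorter = min(len(row_a.replace("-", "")), len(row_b.replace("-", "")))
    id_short = ident / shorter if shorter else 0.0
    return id_cols, id_short


def global_align(
    a: str | ProteinRecord,
    b: str | ProteinRecord,
    matrix: str | None = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    ``matrix=None`` scores match=+1 / mismatch=-1 (useful with toy
    alphabets); otherwise a named substitution matrix is used.
    """
    id_a, seq_a = (a.id, a.sequence) if isinstance(a, ProteinRecord) else ("query", a)
    id_b, seq_b = (b.id, b.sequence) if isinstance(b, ProteinRecord) else ("subject", b)
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    if matrix is None:
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
    alignments = aligner.align(seq_a, seq_b)
    best = alignments[0]  # deterministic first optimum
    row_a, row_b = str(best[0]), str(best[1])
    id_cols, id_short = _identities(row_a, row_b)
    return AlignmentResult(
        query_id=id_a,
        subject_id=id_b,
        aligned_query=row_a,
        aligned_subject=row_b,
        score=float(best.score),
        identity_columns=id_cols,
        identity_shorter=id_short,
    )


def percent_identity_matrix(
    records: list[ProteinRecord],
    matrix: str | None = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    convention: str = "columns",
) -> tuple[np.ndarray, list[str]]:
    """Symmetric identity-fraction matrix over all record pairs.

    Returns (matrix, ids); diagonal is 1. ``convention`` selects
    "columns" (identical / co-residue columns) or "shorter".
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    n = len(records)
    ids = [r.id for r in records]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(records[i], records[j], matrix, gap_open,
                               gap_extend)
            frac = (res.identity_columns if convention == "columns"
                    else res.identity_shorter)
            out[i, j] = out[j, i] = frac
    return out, ids


# ---------------------------------------------------------------------------
# similarity shading (alignment-figure style)

_SHADE_BANDS = (
    (1.0, "identical"),
    (0.8, "high"),
    (0.6, "medium"),
    (0.0, "low"),
)


def similarity_shading(
    rows: list[str],
    matrix: str = DEFAULT_MATRIX,
    threshold: float = 1.0,
) -> list[str]:
    """Per-column similarity category for a set of aligned rows.

    For each column, the fraction of non-gap residues scoring at least
    ``threshold`` (BLOSUM62 by default) against the column's modal residue
    is banded: 1.0 → identical, [0.8, 1.0) → high, [0.6, 0.8) → medium,
    below → low. Gaps are excluded from numerator and denominator;
    boundary fractions fall in the higher band. All-gap columns are "low".
    """
    if len(rows) < 2:
        raise ValueError("need at least two rows")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows must be aligned (equal length)")
    subs = substitution_matrices.load(matrix)
    cats: list[str] = []
    for col in zip(*rows):
        residues = [c for c in col if c != "-"]
        if not residues:
            cats.append("low")
            continue
        modal = Counter(residues).most_common(1)[0][0]
        similar = sum(1 for c in residues if subs[modal, c] >= threshold)
        frac = similar / len(residues)
        if frac >= 1.0:
            cats.append("identical")
        elif frac >= 0.8:
            cats.append("high")
        elif frac >= 0.6:
            cats.append("medium")
        else:
            cats.append("low")
    return cats


# ---------------------------------------------------------------------------
# neighbor joining + bootstrap

def nj_tree(distances: np.ndarray, ids: list[str]) -> TreeResult:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch lengths are clamped to zero; the total clamped deficit
    is recorded on the result.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(distances, distances.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if len(ids) != distances.shape[0]:
        raise ValueError("ids do not match matrix size")
    if len(ids) < 3:
        raise ValueError("need at least three taxa")
    dm = DistanceMatrix(distances, ids)
    tree = nj(dm)
    clamped = 0.0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            clamped += -node.length
            node.length = 0.0
    return TreeResult(tree=tree, clamped_negative_total=clamped)


def _bipartitions(tree: TreeNode, leaf_set: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalised as
    the lexicographically smaller side."""
    parts: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaf_set - side
        if len(side) < 2 or len(other) < 2:
            continue
        parts.add(min(side, other, key=lambda s: sorted(s)))
    return parts


def _pdistance_matrix(columns: np.ndarray) -> np.ndarray:
    """Normalised Hamming distance between rows of a character matrix,
    ignoring columns where either row has a gap."""
    n = columns.shape[0]
    out = np.zeros((n, n))
    gap = columns == "-"
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            total = int(ok.sum())
            diff = int((columns[i, ok] != columns[j, ok]).sum())
            out[i, j] = out[j, i] = diff / total if total else 1.0
    return out


def alignment_column_matrix(rows: list[str], ids: list[str]) -> tuple[np.ndarray, list[str]]:
    """Character matrix (taxa x columns) from aligned rows."""
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows must be aligned (equal length)")
    return np.array([list(r) for r in rows]), list(ids)


def bootstrap_support(
    rows: list[str],
    ids: list[str],
    n_replicates: int = 200,
    seed: int = 0,
) -> TreeResult:
    """NJ tree with bootstrap support from aligned sequence rows.

    Columns are resampled with replacement ``n_replicates`` times; support
    for each internal bipartition of the point-estimate tree is the
    percentage of replicate trees containing it. Distances are p-distances
    on the (resampled) columns.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    # canonical leaf order so support is invariant to input order
    order = np.argsort(ids)
    ids = [ids[i] for i in order]
    rows = [rows[i] for i in order]
    cols, ids = alignment_column_matrix(rows, ids)
    point = nj_tree(_pdistance_matrix(cols), ids)
    leaf_set = frozenset(ids)
    target = _bipartitions(point.tree, leaf_set)
    counts: dict[frozenset, int] = {p: 0 for p in target}
    rng = np.random.default_rng(seed)
    n_cols = cols.shape[1]
    for _ in range(n_replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        rep = nj_tree(_pdistance_matrix(cols[:, idx]), ids)
        rep_parts = _bipartitions(rep.tree, leaf_set)
        for p in target:
            if p in rep_parts:
                counts[p] += 1
    support = {p: 100.0 * c / n_replicates for p, c in counts.items()}
    return TreeResult(tree=point.tree, support=support,
                      n_replicates=n_replicates,
                      clamped_negative_total=point.clamped_negative_total)


def clade_support(result: TreeResult, leaves: set[str]) -> float | None:
    """Bootstrap percentage for the bipartition isolating ``leaves``,
    or None if the point-estimate tree lacks that bipartition."""
    if result.support is None:
        return None
    all_leaves = frozenset(t.name for t in result.tree.tips())
    key = min(frozenset(leaves), all_leaves - frozenset(leaves),
              key=lambda s: sorted(s))
    return result.support.get(key)
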