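"""Gene-neighborhood models and microsynteny comparison.

Neighborhoods are ordered, stranded gene lists on one scaffold, anchored for
comparison by a 5' gene (MIF in the SLC locus) and a 3' gene (TOP3B). Shared
syntenic blocks are maximal runs of consecutive shared genes: same order
with matching strands ("same") or reversed order with flipped strands
("inverted"). Distances are ordinal — gene counts, never base pairs.

Gene names are normalised to uppercase symbols through an editable alias
table; the defaults encode known misannotations of surrogate-light-chain
genes (Ig Iota for VPREB1, Om / Ig Omega for VPREB2, IGLL3/5/7 for IGLL1
candidates).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

DEFAULT_ALIASES = {
    "IG IOTA": "VPREB1",
    "IGIOTA": "VPREB1",
    "OM": "VPREB2",
    "IG OMEGA": "VPREB2",
    "IGOMEGA": "VPREB2",
    "IGLL3": "IGLL1",
    "IGLL5": "IGLL1",
    "IGLL7": "IGLL1",
}


class AnchorNotFoundError(KeyError):
    """A synteny anchor gene is absent from the neighborhood."""


class SplitLocusError(ValueError):
    """The two anchors lie on different scaffolds."""


def normalize_name(name: str, aliases: dict[str, str] | None = None) -> str:
    table = DEFAULT_ALIASES if aliases is None else aliases
    key = name.strip().upper()
    return table.get(key, key)


def load_aliases(path: str | Path) -> dict[str, str]:
    """Load an alias mapping (YAML: alias -> symbol), upper-cased."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {str(k).upper(): str(v).upper() for k, v in raw.items()}


@dataclass(frozen=True)
class Gene:
    name: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.name!r}: need 1 <= start <= end "
                f"(got {self.start}, {self.end})")

    def flipped(self) -> "Gene":
        return replace(self, strand="-" if self.strand == "+" else "+")


@dataclass(frozen=True)
class GeneNeighborhood:
    species: str
    scaffold_id: str
    genes: tuple[Gene, ...]
    orientation_note: str = "forward"

    def __post_init__(self) -> None:
        if self.orientation_note == "forward":
            starts = [g.start for g in self.genes]
            if starts != sorted(starts):
                raise ValueError("genes must be sorted by start coordinate")

    def names(self, aliases: dict[str, str] | None = None) -> list[str]:
        return [normalize_name(g.name, aliases) for g in self.genes]

    def index_of(self, name: str,
                 aliases: dict[str, str] | None = None) -> list[int]:
        target = normalize_name(name, aliases)
        return [i for i, n in enumerate(self.names(aliases)) if n == target]

    def reversed_view(self) -> "GeneNeighborhood":
        note = "reverse" if self.orientation_note == "forward" else "forward"
        return GeneNeighborhood(
            species=self.species, scaffold_id=self.scaffold_id,
            genes=tuple(g.flipped() for g in reversed(self.genes)),
            orientation_note=note)

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# I/O: tab-separated gene-order tables

TABLE_COLUMNS = ["species", "scaffold", "gene", "start", "end", "strand"]


def read_gene_table(path: str | Path) -> list[GeneNeighborhood]:
    """Read a gene-order TSV (species, scaffold, gene, start, end, strand;
    1-based inclusive coordinates) into one neighborhood per
    (species, scaffold), genes sorted by start."""
    df = pd.read_csv(path, sep="\t", dtype={"start": int, "end": int})
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    out = []
    for (species, scaffold), grp in df.groupby(["species", "scaffold"],
                                               sort=True):
        grp = grp.sort_values("start")
        genes = tuple(Gene(str(r.gene), int(r.start), int(r.end),
                           str(r.strand)) for r in grp.itertuples())
        out.append(GeneNeighborhood(str(species), str(scaffold), genes))
    return out


def write_gene_table(neighborhoods: list[GeneNeighborhood],
                     path: str | Path) -> None:
    rows = [
        {"species": n.species, "scaffold": n.scaffold_id, "gene": g.name,
         "start": g.start, "end": g.end, "strand": g.strand}
        for n in neighborhoods for g in n.genes
    ]
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)


# ---------------------------------------------------------------------------
# anchored intervals

def anchored_interval(n: GeneNeighborhood, five_anchor: str,
                      three_anchor: str,
                      aliases: dict[str, str] | None = None
                      ) -> GeneNeighborhood:
    """Restrict a neighborhood to the inclusive span between the anchors,
    reported in 5'->3' (five-anchor-first) orientation; strand labels are
    flipped when the stored orientation is reversed."""
    five_idx = n.index_of(five_anchor, aliases)
    three_idx = n.index_of(three_anchor, aliases)
    for name, idx in ((five_anchor, five_idx), (three_anchor, three_idx)):
        if not idx:
            raise AnchorNotFoundError(name)
    i5, i3 = five_idx[0], three_idx[0]
    if i5 <= i3:
        genes = n.genes[i5:i3 + 1]
        note = "forward"
    else:
        genes = tuple(g.flipped() for g in reversed(n.genes[i3:i5 + 1]))
        note = "reverse"
    return GeneNeighborhood(species=n.species, scaffold_id=n.scaffold_id,
                            genes=genes, orientation_note=note)


def find_anchored(neighborhoods: list[GeneNeighborhood], five_anchor: str,
                  three_anchor: str,
                  aliases: dict[str, str] | None = None) -> GeneNeighborhood:
    """Locate the scaffold carrying both anchors; raise SplitLocusError if
    the anchors lie on different scaffolds."""
    with_five = [n for n in neighborhoods if n.index_of(five_anchor, aliases)]
    with_three = [n for n in neighborhoods if n.index_of(three_anchor, aliases)]
    both = [n for n in with_five if n in with_three]
    if both:
        return anchored_interval(both[0], five_anchor, three_anchor, aliases)
    if with_five and with_three:
        raise SplitLocusError(
            f"{five_anchor} on {with_five[0].scaffold_id}, "
            f"{three_anchor} on {with_three[0].scaffold_id}")
    missing = five_anchor if not with_five else three_anchor
    raise AnchorNotFoundError(missing)


# ---------------------------------------------------------------------------
# shared blocks

@dataclass(frozen=True)
class Block:
    """A run of shared genes. Spans are inclusive 0-based gene-index
    intervals in each neighborhood's stored order."""

    ref_span: tuple[int, int]
    query_span: tuple[int, int]
    orientation: str  # "same" | "inverted"
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SyntenyCall:
    species_pair: tuple[str, str]
    blocks: tuple[Block, ...]
    singletons: tuple[Block, ...]
    unplaced: dict[str, tuple[str, ...]]  # side -> names
    duplications: dict[str, tuple[int, int]]  # name -> (ref, query) counts


def _matches(ref: GeneNeighborhood, query: GeneNeighborhood,
             aliases: dict[str, str] | None):
    """Order-paired occurrences of genes shared by both sides.

    Duplicate copies are paired by occurrence order; surplus copies are
    excluded from the permutation (they surface via ``duplications``).
    """
    ref_names, q_names = ref.names(aliases), query.names(aliases)
    ref_pos: dict[str, list[int]] = {}
    q_pos: dict[str, list[int]] = {}
    for i, nm in enumerate(ref_names):
        ref_pos.setdefault(nm, []).append(i)
    for i, nm in enumerate(q_names):
        q_pos.setdefault(nm, []).append(i)
    pairs = []
    for nm in ref_pos:
        if nm in q_pos:
            for ri, qi in zip(ref_pos[nm], q_pos[nm]):
                pairs.append((ri, qi, nm))
    pairs.sort()
    return pairs, ref_pos, q_pos


def shared_blocks(ref: GeneNeighborhood, query: GeneNeighborhood,
                  min_block: int = 2,
                  aliases: dict[str, str] | None = None) -> SyntenyCall:
    """Maximal runs of consecutive shared genes between two neighborhoods.

    Runs extend while matched genes are adjacent on both sides in the same
    direction with consistent strand relation: equal strands for "same"
    runs, flipped strands with descending query order for "inverted" runs.
    Runs of at least ``min_block`` genes are blocks; shorter runs are
    singletons. Genes present on one side only are unplaced; genes with
    more copies on either side are listed under duplications.
    """
    pairs, ref_pos, q_pos = _matches(ref, query, aliases)
    blocks: list[Block] = []
    singletons: list[Block] = []

    def emit(run: list[tuple[int, int, str]]) -> None:
        ref_idx = [p[0] for p in run]
        q_idx = [p[1] for p in run]
        if len(run) == 1:
            rel = ref.genes[run[0][0]].strand == query.genes[run[0][1]].strand
            orient = "same" if rel else "inverted"
        else:
            orient = "same" if q_idx[1] > q_idx[0] else "inverted"
        blk = Block(ref_span=(ref_idx[0], ref_idx[-1]),
                    query_span=(min(q_idx), max(q_idx)),
                    orientation=orient,
                    genes=tuple(p[2] for p in run))
        (blocks if len(run) >= min_block else singletons).append(blk)

    run: list[tuple[int, int, str]] = []
    for pair in pairs:
        if not run:
            run = [pair]
            continue
        pr, pq, _ = run[-1]
        r, q, _ = pair
        same_strand_prev = ref.genes[pr].strand == query.genes[pq].strand
        same_strand_cur = ref.genes[r].strand == query.genes[q].strand
        forward = (r == pr + 1 and q == pq + 1
                   and same_strand_prev and same_strand_cur)
        inverted = (r == pr + 1 and q == pq - 1
                    and not same_strand_prev and not same_strand_cur)
        if len(run) >= 2:
            direction = run[1][1] - run[0][1]
            if direction > 0:
                inverted = False
            else:
                forward = False
        if forward or inverted:
            run.append(pair)
        else:
            emit(run)
            run = [pair]
    if run:
        emit(run)

    shared = set(ref_pos) & set(q_pos)
    unplaced = {
        "ref_only": tuple(sorted(set(ref_pos) - shared)),
        "query_only": tuple(sorted(set(q_pos) - shared)),
    }
    duplications = {
        nm: (len(ref_pos.get(nm, [])), len(q_pos.get(nm, [])))
        for nm in sorted(set(ref_pos) | set(q_pos))
        if max(len(ref_pos.get(nm, [])), len(q_pos.get(nm, []))) > 1
    }
    return SyntenyCall(
        species_pair=(ref.species, query.species),
        blocks=tuple(blocks), singletons=tuple(singletons),
        unplaced=unplaced, duplications=duplications)


# ---------------------------------------------------------------------------
# proximity (context rules)

def proximity(n: GeneNeighborhood, subject: str, target: str,
              side: str = "either", k: int = 5,
              aliases: dict[str, str] | None = None
              ) -> tuple[bool, int | None]:
    """Is ``target`` within ``k`` genes of ``subject`` on the given side
    ("5prime", "3prime", "either"), in neighborhood orientation? Returns
    (hit, ordinal distance of the nearest qualifying copy)."""
    if side not in ("5prime", "3prime", "either"):
        raise ValueError(f"invalid side {side!r}")
    subj_idx = n.index_of(subject, aliases)
    if not subj_idx:
        raise KeyError(f"subject gene {subject!r} absent")
    targ_idx = n.index_of(target, aliases)
    best: int | None = None
    for s in subj_idx:
        for t in targ_idx:
            delta = t - s
            if delta == 0:
                continue
            if side == "5prime" and delta > 0:
                continue
            if side == "3prime" and delta < 0:
                continue
            dist = abs(delta)
            if dist <= k and (best is None or dist < best):
                best = dist
    return best is not None, best


# ---------------------------------------------------------------------------
# edit inference (used to verify planted rearrangements)

@dataclass(frozen=True)
class InferredEdit:
    kind: str  # inversion | translocation | duplication | deletion
    ref_span: tuple[int, int] | None = None
    gene: str | None = None
    copies: tuple[int, int] | None = None


def infer_edits(ref: GeneNeighborhood, edited: GeneNeighborhood,
                aliases: dict[str, str] | None = None) -> list[InferredEdit]:
    """Reconstruct whole-gene rearrangements between a reference and an
    edited neighborhood: inversions from inverted runs, duplications and
    deletions from copy counts, and translocations as blocks whose removal
    restores monotone query order."""
    call = shared_blocks(ref, edited, min_block=1, aliases=aliases)
    edits: list[InferredEdit] = []
    for blk in (*call.blocks, *call.singletons):
        if blk.orientation == "inverted":
            edits.append(InferredEdit(kind="inversion", ref_span=blk.ref_span))
    for nm, (rc, qc) in call.duplications.items():
        if qc > rc:
            edits.append(InferredEdit(kind="duplication", gene=nm,
                                      copies=(rc, qc)))
    for nm in call.unplaced["ref_only"]:
        edits.append(InferredEdit(kind="deletion", gene=nm))
    # translocation: a block whose removal restores monotone query order.
    # Moving X past Y is indistinguishable from moving Y past X, so by
    # convention the *smallest* removable block is called the moved one
    # (ties report every minimal candidate).
    ordered = sorted((*call.blocks, *call.singletons),
                     key=lambda b: b.ref_span[0])
    q_order = [b.query_span[0] for b in ordered]
    if q_order != sorted(q_order):
        candidates = []
        for i, blk in enumerate(ordered):
            rest = q_order[:i] + q_order[i + 1:]
            if rest == sorted(rest) and blk.orientation == "same":
                candidates.append(blk)
        if candidates:
            smallest = min(len(b) for b in candidates)
            for blk in candidates:
                if len(blk) == smallest:
                    edits.append(InferredEdit(kind="translocation",
                                              ref_span=blk.ref_span))
    return edits
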