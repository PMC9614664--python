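"""Synthetic data generation for every pipeline stage.

This module emulates the structures the analysis consumes, so the whole
pipeline is testable without genome downloads:

* protein families with an immunoglobulin-like core, an optional diagnostic
  motif (GPRC for IGLL1, VFPGQ for VpreB3, conserved Cys/Trp sites for
  PTCRA) and a charged tail, evolved along a Newick tree by per-site
  substitutions, with ground-truth tail boundaries;
* gene neighborhoods with planted inversions, translocations, duplications
  and deletions plus an edit log;
* rearranged heavy-chain junctions with conserved anchors (2nd-CYS and the
  J-region [WF]-G-x-G motif) around CDR H3 segments of known length;
* two-column feature tables with a prescribed Spearman rank correlation,
  drawn through a Gaussian copula.

Substitutions never touch motif or conserved-site positions unless
``motif_decay`` is set, and tail substitutions replace charged residues
within their charge class — generated tails therefore satisfy their spec's
charged-count ranges as a hard constraint, not merely in expectation.
Identical (spec, seed) inputs give identical outputs.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .records import (ACIDIC_RESIDUES, AMINO_ACIDS, BASIC_RESIDUES,
                      CuratedReference, ProteinRecord, TailAnnotation)
from .synteny import Gene, GeneNeighborhood

_UNCHARGED = "".join(sorted(set(AMINO_ACIDS) - set("RKHDE")))
_BASIC = "".join(sorted(BASIC_RESIDUES))
_ACIDIC = "".join(sorted(ACIDIC_RESIDUES))


class SpecError(ValueError):
    """Infeasible or inconsistent generator specification."""


# ---------------------------------------------------------------------------
# protein families

@dataclass(frozen=True)
class FamilySpec:
    """Generative parameters for one gene family.

    ``motif`` is (motif string, 0-based anchor); the anchor is a core
    coordinate when ``motif_region == "core"`` and a tail coordinate when
    ``"tail"`` (IGLL1's GPRC motif sits inside its N-terminal tail).
    ``tail_bias`` is the target fraction of basic residues among the tail's
    charged residues. ``side`` places the tail at the C- or N-terminus.
    ``conserved_sites`` are (core position, residue) pairs protected from
    substitution, like the PTCRA cysteine/tryptophan scaffold.
    """

    label: str
    core_length: int
    tail_length_range: tuple[int, int]
    tail_charged_range: tuple[int, int]
    tail_bias: float = 0.5
    substitution_rate: float = 0.05
    motif: tuple[str, int] | None = None
    motif_region: str = "core"
    side: str = "C"
    conserved_sites: tuple[tuple[int, str], ...] = ()
    motif_decay: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.tail_length_range
        clo, chi = self.tail_charged_range
        if not (0 <= lo <= hi):
            raise SpecError(f"bad tail_length_range {self.tail_length_range}")
        if not (0 <= clo <= chi):
            raise SpecError(f"bad tail_charged_range {self.tail_charged_range}")
        if chi > hi:
            raise SpecError("tail_charged_range max exceeds tail_length_range max")
        if clo > lo:
            raise SpecError("tail_charged_range min exceeds tail_length_range min")
        if not (0.0 <= self.tail_bias <= 1.0):
            raise SpecError("tail_bias outside [0, 1]")
        if self.side not in ("C", "N"):
            raise SpecError("side must be 'C' or 'N'")
        if self.motif_region not in ("core", "tail"):
            raise SpecError("motif_region must be 'core' or 'tail'")
        if self.motif is not None:
            m, anchor = self.motif
            if self.motif_region == "core" and anchor + len(m) > self.core_length:
                raise SpecError("motif does not fit in core")
            if self.motif_region == "tail" and anchor + len(m) > lo:
                raise SpecError("motif does not fit in shortest tail")
        for pos, _ in self.conserved_sites:
            if not (0 <= pos < self.core_length):
                raise SpecError(f"conserved site {pos} outside core")


# Default family specs — the study conditions. Tail-length and charged-count
# ranges for VpreB1/VpreB2 follow the reported per-species ranges (VpreB1
# tails 16-38 aa with 11-15 charged residues; VpreB2 tails 6-35 aa with 7-12);
# VpreB3 carries the VFPGQ motif near its N-terminus and essentially no tail;
# IGLL1 carries GPRC inside a basic-biased N-terminal tail; PTCRA carries the
# two disulfide cysteines and the Ig-fold tryptophan as conserved sites.
DEFAULT_FAMILY_SPECS: dict[str, FamilySpec] = {
    "VpreB1": FamilySpec(
        label="VpreB1", core_length=115, tail_length_range=(16, 38),
        tail_charged_range=(11, 15), tail_bias=0.4),
    "VpreB2": FamilySpec(
        label="VpreB2", core_length=115, tail_length_range=(13, 35),
        tail_charged_range=(7, 12), tail_bias=0.4),
    "VpreB3": FamilySpec(
        label="VpreB3", core_length=115, tail_length_range=(0, 4),
        tail_charged_range=(0, 0), motif=("VFPGQ", 10)),
    "IGLL1": FamilySpec(
        label="IGLL1", core_length=105, tail_length_range=(30, 50),
        tail_charged_range=(8, 16), tail_bias=0.7, side="N",
        motif=("GPRC", 20), motif_region="tail"),
    "PTCRA": FamilySpec(
        label="PTCRA", core_length=140, tail_length_range=(0, 4),
        tail_charged_range=(0, 0),
        conserved_sites=((27, "C"), (42, "W"), (87, "C"))),
}


def parse_tree(newick: str) -> TreeNode:
    # keep underscores verbatim in leaf names
    return TreeNode.read(_io.StringIO(newick), convert_underscores=False)


def balanced_tree(n_leaves: int, branch_length: float = 0.1,
                  prefix: str = "sp") -> str:
    """A simple caterpillar Newick tree with uniform branch lengths and
    leaves ``<prefix>1..<prefix>n``."""
    if n_leaves < 2:
        raise SpecError("need at least 2 leaves")
    tree = f"{prefix}1:{branch_length}"
    for i in range(2, n_leaves + 1):
        tree = f"({tree},{prefix}{i}:{branch_length}):{branch_length}"
    return tree + ";"


def _root_sequence(spec: FamilySpec, rng: np.random.Generator
                   ) -> tuple[str, str, set[int]]:
    """Returns (core, tail, protected tail offsets)."""
    core = list(rng.choice(list(AMINO_ACIDS), size=spec.core_length))
    protected_tail: set[int] = set()
    if spec.motif is not None and spec.motif_region == "core":
        m, anchor = spec.motif
        core[anchor:anchor + len(m)] = list(m)
    for pos, res in spec.conserved_sites:
        core[pos] = res

    lo, hi = spec.tail_length_range
    tail_len = int(rng.integers(lo, hi + 1))
    clo, chi = spec.tail_charged_range
    chi = min(chi, tail_len)
    clo = min(clo, chi)
    target_charged = int(rng.integers(clo, chi + 1))

    tail = list(rng.choice(list(_UNCHARGED), size=tail_len))
    motif_charged = 0
    motif_offsets: set[int] = set()
    if spec.motif is not None and spec.motif_region == "tail":
        m, anchor = spec.motif
        if anchor + len(m) > tail_len:
            anchor = tail_len - len(m)
        tail[anchor:anchor + len(m)] = list(m)
        motif_offsets = set(range(anchor, anchor + len(m)))
        motif_charged = sum(1 for c in m if c in "RKHDE")
        protected_tail |= motif_offsets
    n_extra = max(0, target_charged - motif_charged)
    free = [i for i in range(tail_len) if i not in motif_offsets]
    n_extra = min(n_extra, len(free))
    charged_pos = rng.choice(free, size=n_extra, replace=False) if n_extra else []
    for i in charged_pos:
        if rng.random() < spec.tail_bias:
            tail[i] = str(rng.choice(list(_BASIC)))
        else:
            tail[i] = str(rng.choice(list(_ACIDIC)))
    return "".join(core), "".join(tail), protected_tail


def _substitute(seq: list[str], protected: set[int], tail_range: range,
                p: float, rng: np.random.Generator) -> None:
    """In-place per-site substitution; tail positions stay in their charge
    class so planted charged counts are preserved exactly."""
    if p <= 0:
        return
    hits = np.flatnonzero(rng.random(len(seq)) < p)
    for i in hits:
        if i in protected:
            continue
        cur = seq[i]
        if i in tail_range:
            if cur in BASIC_RESIDUES:
                pool = _BASIC.replace(cur, "")
            elif cur in ACIDIC_RESIDUES:
                pool = _ACIDIC.replace(cur, "")
            else:
                pool = _UNCHARGED.replace(cur, "")
        else:
            pool = AMINO_ACIDS.replace(cur, "")
        seq[i] = str(rng.choice(list(pool)))


def make_family(
    spec: FamilySpec,
    tree: str | TreeNode,
    seed: int,
    clade: str = "",
) -> tuple[list[ProteinRecord], dict[str, TailAnnotation]]:
    """Evolve one family along a tree; one record per leaf.

    Returns (records, ground truth): per-leaf TailAnnotation carrying the
    true boundary, tail sequence and charge counts (pI fields are left
    unset — they are the feature stage's job).
    """
    if isinstance(tree, str):
        tree = parse_tree(tree)
    leaves = list(tree.tips())
    if len(leaves) < 2:
        raise SpecError("tree must have at least 2 leaves")
    rng = np.random.default_rng(seed)
    core, tail, protected_tail = _root_sequence(spec, rng)

    if spec.side == "C":
        root = list(core + tail)
        tail_range = range(len(core), len(root))
        boundary = len(core)
        tail_off = len(core)
    else:
        root = list(tail + core)
        tail_range = range(0, len(tail))
        boundary = len(tail)
        tail_off = 0

    protected: set[int] = set()
    if not spec.motif_decay:
        protected |= {tail_off + i for i in protected_tail}
        if spec.motif is not None and spec.motif_region == "core":
            m, anchor = spec.motif
            base = anchor if spec.side == "C" else len(tail) + anchor
            protected |= set(range(base, base + len(m)))
        for pos, _ in spec.conserved_sites:
            protected.add(pos if spec.side == "C" else len(tail) + pos)

    # deterministic pre-order traversal carrying sequences down the tree
    seqs: dict[int, list[str]] = {id(tree): root}
    records: list[ProteinRecord] = []
    truth: dict[str, TailAnnotation] = {}
    for node in tree.preorder(include_self=False):
        parent_seq = seqs[id(node.parent)]
        child = list(parent_seq)
        bl = node.length or 0.0
        p = 1.0 - float(np.exp(-spec.substitution_rate * bl))
        _substitute(child, protected, tail_range, p, rng)
        seqs[id(node)] = child
        if node.is_tip():
            name = node.name
            rec_id = f"{spec.label}_{name}"
            seq = "".join(child)
            records.append(ProteinRecord(
                id=rec_id, species=name, clade=clade,
                gene_label=spec.label, sequence=seq))
            tail_seq = (seq[boundary:] if spec.side == "C"
                        else seq[:boundary])
            nb = sum(1 for c in tail_seq if c in BASIC_RESIDUES)
            na = sum(1 for c in tail_seq if c in ACIDIC_RESIDUES)
            truth[rec_id] = TailAnnotation(
                record_id=rec_id, side=spec.side, boundary=boundary,
                tail_sequence=tail_seq, tail_length=len(tail_seq),
                n_basic=nb, n_acidic=na, tail_pi=None, full_pi=None)
    records.sort(key=lambda r: r.id)
    return records, truth


def family_seed(label: str, seed: int,
                specs: dict[str, FamilySpec] | None = None) -> int:
    """Stable per-family sub-seed (sorted-label offset from the base seed)."""
    specs = DEFAULT_FAMILY_SPECS if specs is None else specs
    return seed + sorted(specs).index(label)


def family_reference(spec: FamilySpec, seed: int) -> CuratedReference:
    """The curated-reference view of a family's root sequence: the exact
    sequence ``make_family(spec, tree, seed)`` evolves from, with its true
    tail boundary and conserved sites.

    A synthetic stand-in for a curated reference protein; it carries no
    real biological sequence.
    """
    rng = np.random.default_rng(seed)
    core, tail, _ = _root_sequence(spec, rng)
    if spec.side == "C":
        seq, boundary = core + tail, len(core)
        sites = spec.conserved_sites
    else:
        seq, boundary = tail + core, len(tail)
        sites = tuple((len(tail) + p, r) for p, r in spec.conserved_sites)
    return CuratedReference(family=spec.label, sequence=seq,
                            boundary=boundary, side=spec.side,
                            conserved_sites=sites)


def synthetic_references(
    seed: int = 20,
    specs: dict[str, FamilySpec] | None = None,
) -> dict[str, CuratedReference]:
    """Synthetic curated references, one per family, built from the same
    roots that ``make_family`` uses under ``family_seed(label, seed)``."""
    specs = DEFAULT_FAMILY_SPECS if specs is None else specs
    return {label: family_reference(spec, family_seed(label, seed, specs))
            for label, spec in specs.items()}


# ---------------------------------------------------------------------------
# gene neighborhoods

@dataclass(frozen=True)
class Edit:
    kind: str  # inversion | translocation | duplication | deletion
    span: tuple[int, int]  # inclusive 0-based reference gene indices
    destination: int | None = None  # translocation target (reference index)

    def __post_init__(self) -> None:
        if self.kind not in ("inversion", "translocation", "duplication",
                             "deletion"):
            raise SpecError(f"unknown edit kind {self.kind!r}")
        if self.span[0] > self.span[1]:
            raise SpecError(f"degenerate span {self.span}")
        if self.kind == "translocation" and self.destination is None:
            raise SpecError("translocation needs a destination")


@dataclass(frozen=True)
class NeighborhoodSpec:
    gene_order: tuple[tuple[str, str], ...]  # (name, strand)
    anchors: tuple[str, str]  # (five_prime, three_prime)
    edits: tuple[Edit, ...] = ()
    species: str = "synthetic"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.gene_order]
        five, three = self.anchors
        if names.count(five) != 1 or names.count(three) != 1:
            raise SpecError("anchors must occur exactly once each")
        if names.index(five) >= names.index(three):
            raise SpecError("five-prime anchor must precede three-prime")
        n = len(self.gene_order)
        spans = []
        for e in self.edits:
            if not (0 <= e.span[0] <= e.span[1] < n):
                raise SpecError(f"edit span {e.span} out of bounds")
            if e.destination is not None and not (0 <= e.destination <= n):
                raise SpecError(f"destination {e.destination} out of bounds")
            if e.destination is not None and \
                    e.span[0] <= e.destination <= e.span[1] + 1:
                raise SpecError("translocation destination inside its span")
            spans.append(e.span)
        spans.sort()
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise SpecError("overlapping edit spans")


def make_neighborhood(
    spec: NeighborhoodSpec, seed: int
) -> tuple[GeneNeighborhood, GeneNeighborhood, list[dict]]:
    """Build a reference neighborhood and an edited copy differing from it
    by exactly the listed edits, plus a machine-readable edit log."""
    rng = np.random.default_rng(seed)
    lengths = rng.integers(500, 5000, size=len(spec.gene_order))
    gaps = rng.integers(100, 10_000, size=len(spec.gene_order))

    def coordinates(items: list[tuple[str, str, int]]) -> tuple[Gene, ...]:
        genes, pos = [], 1
        for name, strand, orig in items:
            ln = int(lengths[orig])
            genes.append(Gene(name=name, start=pos, end=pos + ln - 1,
                              strand=strand))
            pos += ln + int(gaps[orig])
        return tuple(genes)

    # working representation: (name, strand, original index)
    work = [(n, s, i) for i, (n, s) in enumerate(spec.gene_order)]
    ref = GeneNeighborhood(species=spec.species, scaffold_id="scf_ref",
                           genes=coordinates(work))

    log: list[dict] = []
    current = list(work)

    def locate(orig: int) -> int:
        for pos, (_, _, o) in enumerate(current):
            if o == orig:
                return pos
        raise SpecError(f"gene with original index {orig} was deleted")

    for e in spec.edits:
        i = locate(e.span[0])
        j = locate(e.span[1])
        if e.kind == "inversion":
            flipped = [(n, "-" if s == "+" else "+", o)
                       for n, s, o in reversed(current[i:j + 1])]
            current[i:j + 1] = flipped
        elif e.kind == "duplication":
            current[j + 1:j + 1] = [(n, s, o) for n, s, o in current[i:j + 1]]
        elif e.kind == "deletion":
            del current[i:j + 1]
        else:  # translocation
            chunk = current[i:j + 1]
            del current[i:j + 1]
            if e.destination >= len(spec.gene_order):
                dest = len(current)
            else:
                dest = locate(e.destination)
            current[dest:dest] = chunk
        log.append({"kind": e.kind, "span": list(e.span),
                    "destination": e.destination,
                    "genes": [spec.gene_order[k][0]
                              for k in range(e.span[0], e.span[1] + 1)]})

    edited = GeneNeighborhood(species=spec.species, scaffold_id="scf_edit",
                              genes=coordinates(current))
    return ref, edited, log


# ---------------------------------------------------------------------------
# rank-correlated feature tables (Gaussian copula)

_MARGINALS = {
    "uniform": lambda p: stats.uniform(loc=p[0], scale=p[1] - p[0]),
    "normal": lambda p: stats.norm(loc=p[0], scale=p[1]),
    "lognormal": lambda p: stats.lognorm(s=p[0], scale=p[1]),
    "gamma": lambda p: stats.gamma(a=p[0], scale=p[1]),
    "expon": lambda p: stats.expon(scale=p[0]),
}


@dataclass(frozen=True)
class CopulaSpec:
    n_species: int
    target_rho: float
    marginals: tuple[tuple[str, tuple[float, ...]],
                     tuple[str, tuple[float, ...]]] = (
        ("uniform", (0.0, 1.0)), ("uniform", (0.0, 1.0)))
    seed: int = 0
    col_names: tuple[str, str] = ("x", "y")

    def __post_init__(self) -> None:
        if abs(self.target_rho) > 1.0:
            raise SpecError("|target_rho| must be <= 1")
        if self.n_species < 3:
            raise SpecError("n_species must be >= 3")
        for name, _ in self.marginals:
            if name not in _MARGINALS:
                raise SpecError(f"unknown marginal {name!r}")


def make_correlated_table(spec: CopulaSpec) -> pd.DataFrame:
    """Two columns with a prescribed population Spearman correlation.

    The latent Gaussian correlation is r = 2 sin(pi * rho_s / 6), the exact
    inverse of the normal-copula Spearman map; the normal CDF then feeds
    each named marginal's quantile function. |rho| = 1 short-circuits to a
    co-/anti-monotone transform of a single latent draw, so sample Spearman
    rho is exactly +-1.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_species
    rho = spec.target_rho
    if abs(rho) >= 1.0:
        z1 = rng.standard_normal(n)
        z2 = np.sign(rho) * z1
    else:
        r = 2.0 * np.sin(np.pi * rho / 6.0)
        cov = np.array([[1.0, r], [1.0 * r, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n,
                                    method="cholesky")
        z1, z2 = z[:, 0], z[:, 1]
    u1, u2 = stats.norm.cdf(z1), stats.norm.cdf(z2)
    d1 = _MARGINALS[spec.marginals[0][0]](spec.marginals[0][1])
    d2 = _MARGINALS[spec.marginals[1][0]](spec.marginals[1][1])
    species = [f"sp{i + 1}" for i in range(n)]
    return pd.DataFrame({spec.col_names[0]: d1.ppf(u1),
                         spec.col_names[1]: d2.ppf(u2)}, index=species)


# ---------------------------------------------------------------------------
# rearranged heavy-chain junctions

_CDR_ALPHABET = "".join(sorted(set(AMINO_ACIDS) - set("CWF")))
_V_ALPHABET = "".join(sorted(set(AMINO_ACIDS) - set("WF")))


def make_junction(cdr_length: int, rng: np.random.Generator,
                  v_context: int = 10, j_context: int = 8) -> str:
    """One rearranged junction: V context ending in the anchor Cys, a CDR of
    the requested length (free of C/W/F so the anchors are unambiguous), and
    a J region starting [WF]-G-x-G."""
    v = "".join(rng.choice(list(_V_ALPHABET), size=v_context)) + "C"
    cdr = "".join(rng.choice(list(_CDR_ALPHABET), size=cdr_length))
    wf = str(rng.choice(["W", "F"]))
    x = str(rng.choice(list(_CDR_ALPHABET)))
    j = wf + "G" + x + "G" + "".join(
        rng.choice(list(_V_ALPHABET), size=max(0, j_context - 4)))
    return v + cdr + j


def make_repertoire(
    species_lengths: dict[str, list[int]], seed: int
) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Per-species junction reads with planted CDR H3 lengths.

    Returns (records, ground truth mapping record id -> CDR length).
    """
    rng = np.random.default_rng(seed)
    records, truth = [], {}
    for species in sorted(species_lengths):
        for k, ln in enumerate(species_lengths[species]):
            rec_id = f"{species}_read{k + 1}"
            records.append(ProteinRecord(
                id=rec_id, species=species,
                sequence=make_junction(int(ln), rng)))
            truth[rec_id] = int(ln)
    return records, truth


# ---------------------------------------------------------------------------
# spec loading

def load_family_specs(path) -> dict[str, FamilySpec]:
    """Load family specs from YAML: a mapping of label -> FamilySpec
    fields (list values are converted to the tuple types the dataclass
    expects)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, FamilySpec] = {}
    for label, kwargs in raw.items():
        kwargs = dict(kwargs)
        kwargs.setdefault("label", label)
        for key in ("tail_length_range", "tail_charged_range", "motif"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if "conserved_sites" in kwargs:
            kwargs["conserved_sites"] = tuple(
                (int(p), str(r)) for p, r in kwargs["conserved_sites"])
        out[label] = FamilySpec(**kwargs)
    return out


# ---------------------------------------------------------------------------
# composite scenarios

def make_duplicate_pair_scenario(seed: int = 0, rate: float = 2.0):
    """Emulates the glires situation: a recently duplicated VpreB1 pair
    (nearly identical) inside a VpreB1 ortholog clade, with a distant
    VpreB2 clade. Returns (records, duplicate pair ids, VpreB1-clade ids).
    """
    newick = ("((human_B1:0.15,dog_B1:0.15):0.05,(cow_B1:0.18,"
              "(rabbit_B1a:0.005,rabbit_B1b:0.005):0.17):0.02):0.6,"
              "(human_B2:0.2,(dog_B2:0.18,cow_B2:0.18):0.04):0.6")
    spec = replace(DEFAULT_FAMILY_SPECS["VpreB1"], substitution_rate=rate)
    records, _ = make_family(spec, f"({newick});", seed)
    pair = {"VpreB1_rabbit_B1a", "VpreB1_rabbit_B1b"}
    clade1 = {r.id for r in records if r.species.endswith("_B1")} | pair
    return records, pair, clade1
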