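"""Rule-based assignment of candidate proteins to the five gene families.

The rule table mechanises the validity criteria used when curating
surrogate-light-chain candidates:

* VpreB1 — an elongated C-terminal tail with 11-15 charged residues, and
  (when genomic context is available) TOP3B within a few genes;
* VpreB2 — an elongated C-terminal tail with 7-12 charged residues, near
  solute-carrier genes (SLC5A4) or the lambda locus (IGL);
* IGLL1 — the Gly-Pro-Arg-Cys (GPRC) motif inside the N-terminal tail
  region;
* VpreB3 — the Val-Phe-Pro-Gly-Gln (VFPGQ) motif near the N-terminus and
  *no* elongated tail;
* PTCRA — the two disulfide-bridge cysteines with the Ig-fold tryptophan
  between them, at reference-projected positions.

Charged-count ranges are soft: counts missing a range by at most
``soft_margin`` downgrade the rule to a warning (tails "often", not always,
carry the stated counts). A record passing the mandatory rules of exactly
one family gets that label; ties and all-fail give "unknown" with the full
evidence trail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .records import CuratedReference, ProteinRecord, TailAnnotation
from .synteny import GeneNeighborhood, proximity
from .phylo import global_align
from .features import project_position


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    position: int
    matched: str
    max_mismatches: int


@dataclass(frozen=True)
class ClassifierConfig:
    vpreb1_charged: tuple[int, int] = (11, 15)
    vpreb2_charged: tuple[int, int] = (7, 12)
    soft_margin: int = 2
    short_tail_threshold: int = 10  # "elongated tail" = at least this long
    n_term_window: int = 40        # "near the N-terminus" for VFPGQ
    proximity_k: int = 5
    max_mismatches: int = 0
    igll1_motif: str = "GPRC"
    vpreb3_motif: str = "VFPGQ"
    identity_floor: float = 0.2
    site_tolerance: int = 3


DEFAULT_CONFIG = ClassifierConfig()


@dataclass(frozen=True)
class ClassificationResult:
    record_id: str
    label: str
    evidence: tuple[tuple[str, str, str], ...]  # (rule, status, detail)
    score: int

    def rules(self, status: str) -> list[str]:
        return [name for name, st, _ in self.evidence if st == status]


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def scan_motif(sequence: str, motif: str,
               window: tuple[int, int] | None = None,
               max_mismatches: int = 0,
               motif_name: str | None = None) -> list[MotifHit]:
    """All window positions whose substring is within ``max_mismatches``
    of the motif, sorted by position. A window outside the sequence emits
    a warning and an empty result."""
    if len(motif) < 3:
        raise ValueError("motif must be at least 3 residues")
    name = motif_name or motif
    lo, hi = (0, len(sequence)) if window is None else window
    if lo >= len(sequence) or hi <= 0:
        warnings.warn(f"motif window {window} outside sequence bounds",
                      stacklevel=2)
        return []
    lo, hi = max(0, lo), min(hi, len(sequence))
    hits = []
    for pos in range(lo, hi - len(motif) + 1):
        sub = sequence[pos:pos + len(motif)]
        if _hamming(sub, motif) <= max_mismatches:
            hits.append(MotifHit(motif_name=name, position=pos, matched=sub,
                                 max_mismatches=max_mismatches))
    return hits


def validate_ptcra(
    record: ProteinRecord | str,
    reference: CuratedReference,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> tuple[bool, list[tuple[str, str, str]]]:
    """Check the PTCRA scaffold: two cysteines with an intervening
    tryptophan at reference-projected positions (± a few columns)."""
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    if not reference.conserved_sites:
        raise ValueError("PTCRA reference carries no conserved sites")
    aln = global_align(reference.sequence, seq)
    evidence: list[tuple[str, str, str]] = []
    if aln.identity_columns < config.identity_floor:
        evidence.append(("ptcra_alignable", "fail",
                         f"identity {aln.identity_columns:.2f} below floor"))
        return False, evidence
    evidence.append(("ptcra_alignable", "pass",
                     f"identity {aln.identity_columns:.2f}"))
    ok = True
    tol = config.site_tolerance
    for pos, res in reference.conserved_sites:
        q = project_position(aln.aligned_query, aln.aligned_subject, pos)
        lo, hi = max(0, q - tol), min(len(seq), q + tol + 1)
        found = res in seq[lo:hi]
        status = "pass" if found else "fail"
        evidence.append((f"ptcra_site_{res}{pos + 1}", status,
                         f"projected to {q}, window {lo}-{hi}"))
        ok = ok and found
    return ok, evidence


def _range_rule(count: int, bounds: tuple[int, int], margin: int
                ) -> tuple[str, str]:
    lo, hi = bounds
    if lo <= count <= hi:
        return "pass", f"{count} charged in [{lo},{hi}]"
    if lo - margin <= count <= hi + margin:
        return "warn", f"{count} charged just outside [{lo},{hi}]"
    return "fail", f"{count} charged outside [{lo},{hi}]"


def classify(
    record: ProteinRecord,
    tail: TailAnnotation | None = None,
    context: GeneNeighborhood | None = None,
    references: dict[str, CuratedReference] | None = None,
    subject_gene: str | None = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> ClassificationResult:
    """Assign a family label with itemized rule evidence.

    ``tail`` is a prior tail annotation (its absence degrades the
    tail-based rules); ``context`` is the record's gene neighborhood, in
    which ``subject_gene`` (default: the record's claimed label or
    "CANDIDATE") locates the candidate; ``references`` supplies the curated
    PTCRA reference for scaffold validation.

    Decision procedure: sequence-only rules first rank each family as a
    "strict" candidate (all rules pass), a "soft" candidate (passes with
    warnings, e.g. a charged count just outside its range) or a
    non-candidate. A unique best-tier candidate is the provisional label.
    Genomic context then acts purely as a veto — it can eliminate
    candidates (resolving a strict tie such as the VpreB1/VpreB2
    charged-count overlap) or overturn the provisional label to "unknown",
    but it never substitutes a different family, so removing context can
    only move labels to or from "unknown".
    """
    ev: list[tuple[str, str, str]] = []
    candidates: dict[str, str] = {}  # label -> "strict" | "soft"
    vetoed: set[str] = set()

    has_c_tail = (tail is not None and tail.side == "C"
                  and tail.tail_length >= config.short_tail_threshold)
    if tail is None:
        ev.append(("c_tail_elongated", "not-evaluated", "no tail annotation"))
    else:
        ev.append(("c_tail_elongated", "pass" if has_c_tail else "fail",
                   f"side {tail.side}, length {tail.tail_length}"))

    def context_rule(rule: str, target: str, targets: tuple[str, ...] = ()
                     ) -> bool | None:
        """True/False when evaluable, None when context is unavailable."""
        if context is None:
            ev.append((rule, "not-evaluated", "no genomic context"))
            return None
        subject = subject_gene or record.gene_label or "CANDIDATE"
        try:
            for t in (target, *targets):
                hit, dist = proximity(context, subject, t,
                                      side="either", k=config.proximity_k)
                if hit:
                    ev.append((rule, "pass", f"{t} within {dist} genes"))
                    return True
            ev.append((rule, "fail",
                       f"none of {(target, *targets)} within "
                       f"{config.proximity_k} genes"))
            return False
        except KeyError:
            ev.append((rule, "not-evaluated",
                       f"subject {subject!r} absent from context"))
            return None

    # VpreB1 / VpreB2: tail charge, then genomic context as a veto
    if has_c_tail:
        assert tail is not None
        charged = tail.n_basic + tail.n_acidic
        for label, bounds, target in (
                ("VpreB1", config.vpreb1_charged, ("TOP3B",)),
                ("VpreB2", config.vpreb2_charged, ("SLC5A4", "IGL"))):
            status, detail = _range_rule(charged, bounds, config.soft_margin)
            ev.append((f"{label.lower()}_charged", status, detail))
            if status == "pass":
                candidates[label] = "strict"
            elif status == "warn":
                candidates[label] = "soft"
            if label in candidates:
                ctx = context_rule(f"{label.lower()}_context", *target)
                if ctx is False:
                    vetoed.add(label)

    # IGLL1: GPRC inside the N-terminal tail window
    if tail is not None and tail.side == "N":
        window = (0, tail.boundary + len(config.igll1_motif) + 1)
    else:
        window = (0, min(60, len(record.sequence)))
    gprc = scan_motif(record.sequence, config.igll1_motif, window=window,
                      max_mismatches=config.max_mismatches)
    ev.append(("igll1_gprc_motif", "pass" if gprc else "fail",
               f"{len(gprc)} hit(s) in window {window}"))
    if gprc and not has_c_tail:
        candidates["IGLL1"] = "strict"

    # VpreB3: VFPGQ near N-terminus, no elongated tail
    vfpgq = scan_motif(record.sequence, config.vpreb3_motif,
                       window=(0, config.n_term_window),
                       max_mismatches=config.max_mismatches)
    ev.append(("vpreb3_vfpgq_motif", "pass" if vfpgq else "fail",
               f"{len(vfpgq)} hit(s) in first {config.n_term_window} aa"))
    short_tail = tail is None or tail.tail_length < config.short_tail_threshold
    ev.append(("vpreb3_no_elongated_tail", "pass" if short_tail else "fail",
               "no tail" if tail is None else f"tail {tail.tail_length} aa"))
    if vfpgq and short_tail:
        candidates["VpreB3"] = "strict"

    # PTCRA: conserved scaffold versus the curated reference
    ptcra_ref = (references or {}).get("PTCRA")
    if ptcra_ref is None:
        ev.append(("ptcra_scaffold", "not-evaluated", "no PTCRA reference"))
    elif has_c_tail or "IGLL1" in candidates or "VpreB3" in candidates:
        # records already carrying SLC hallmarks are never PTCRA candidates
        ev.append(("ptcra_scaffold", "not-evaluated",
                   "record already carries SLC hallmarks"))
    else:
        ok, sub_ev = validate_ptcra(record, ptcra_ref, config)
        ev.extend(sub_ev)
        if ok:
            candidates["PTCRA"] = "strict"

    def unique_best(pool: dict[str, str]) -> str | None:
        strict = [l for l, tier in pool.items() if tier == "strict"]
        if strict:
            return strict[0] if len(strict) == 1 else None
        soft = list(pool)
        return soft[0] if len(soft) == 1 else None

    provisional = unique_best(candidates)
    surviving = {l: t for l, t in candidates.items() if l not in vetoed}
    if provisional is not None:
        label = provisional if provisional in surviving else "unknown"
    else:
        label = unique_best(surviving) or "unknown"
    score = sum(1 for _, st, _ in ev if st == "pass")
    return ClassificationResult(record_id=record.id, label=label,
                                evidence=tuple(ev), score=score)
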