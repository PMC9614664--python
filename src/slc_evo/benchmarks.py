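"""Desk-scale validation benchmarks.

Each routine regenerates its inputs from a seed, runs one pipeline
capability against an independent oracle or planted ground truth, and
returns the measured quantity:

* isoelectric-point bisection vs an exhaustive pH-grid scan;
* the affine-gap global aligner vs enumeration of every alignment;
* exact permutation Spearman p-values vs the t approximation, and the
  exact test's type-I error under the permutation null;
* the family classifier on generated benchmark families;
* rearrangement recovery on neighborhoods with planted edits;
* bootstrap support for a recently duplicated gene pair;
* Spearman-rho recovery from the Gaussian-copula generator.
"""

from __future__ import annotations

import dataclasses
from math import factorial

import numpy as np
from scipy import stats as sps

from .classifier import classify
from .features import BJELLQVIST, PkaSet, compute_pi, delineate_tail
from .phylo import bootstrap_support, clade_support, global_align
from .records import AMINO_ACIDS
from .stats import _exact_distribution, exact_p_value, spearman, \
    t_approx_p_value
from .synteny import infer_edits, normalize_name
from .synthetic import (CopulaSpec, DEFAULT_FAMILY_SPECS, Edit,
                        NeighborhoodSpec, balanced_tree, family_reference,
                        family_seed, make_correlated_table,
                        make_duplicate_pair_scenario, make_family,
                        make_neighborhood)

# ---------------------------------------------------------------------------
# isoelectric point vs grid oracle


def grid_pi_oracle(seq: str, pka: PkaSet = BJELLQVIST,
                   step: float = 0.0005) -> float:
    """Brute force: argmin |Q(pH)| over a uniform grid on [0, 14]."""
    basic = [pka.side_chain[c] for c in seq if c in "HKR"] + [pka.n_term]
    acidic = [pka.side_chain[c] for c in seq if c in "DECY"] + [pka.c_term]
    grid = np.arange(0.0, 14.0 + step, step)
    q = np.zeros_like(grid)
    for k in basic:
        q += 1.0 / (1.0 + 10.0 ** (grid - k))
    for k in acidic:
        q -= 1.0 / (1.0 + 10.0 ** (k - grid))
    return float(grid[np.argmin(np.abs(q))])


def pi_solver_benchmark(n_peptides: int = 1000, seed: int = 0,
                        length: int = 30) -> dict[str, float]:
    """Max |bisection - grid oracle| and monotone-perturbation violations
    (appending K must never lower pI, appending D never raise it)."""
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    violations = 0
    for _ in range(n_peptides):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        pi = compute_pi(seq)
        max_dev = max(max_dev, abs(pi - grid_pi_oracle(seq)))
        if compute_pi(seq + "K") < pi - 1e-9:
            violations += 1
        if compute_pi(seq + "D") > pi + 1e-9:
            violations += 1
    return {"max_abs_deviation": max_dev, "monotone_violations": violations}


# ---------------------------------------------------------------------------
# aligner vs exhaustive enumeration


def enumerate_alignment_optimum(a: str, b: str, match: float = 1.0,
                                mismatch: float = -1.0,
                                gap_open: float = 2.0,
                                gap_extend: float = 1.0) -> float:
    """Best score over every global alignment, enumerated recursively.
    A gap run of length k costs gap_open + k * gap_extend."""
    best = [-np.inf]

    def rec(i: int, j: int, score: float, state: str) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            rec(i + 1, j,
                score - gap_extend - (gap_open if state != "D" else 0.0),
                "D")
        if j < len(b):
            rec(i, j + 1,
                score - gap_extend - (gap_open if state != "I" else 0.0),
                "I")

    rec(0, 0, 0.0, "M")
    return best[0]


def aligner_oracle_benchmark(n_pairs: int = 300, seed: int = 0,
                             max_len: int = 6) -> dict[str, float]:
    """Score mismatches between the DP aligner and the enumeration oracle
    on random pairs of length <= max_len over a 4-letter alphabet."""
    rng = np.random.default_rng(seed)
    alphabet = list("ACGT")
    mismatches = 0
    for _ in range(n_pairs):
        a = "".join(rng.choice(alphabet, size=rng.integers(1, max_len + 1)))
        b = "".join(rng.choice(alphabet, size=rng.integers(1, max_len + 1)))
        dp = global_align(a, b, matrix=None, gap_open=2.0,
                          gap_extend=1.0).score
        if abs(dp - enumerate_alignment_optimum(a, b)) > 1e-9:
            mismatches += 1
    return {"score_mismatches": mismatches, "n_pairs": n_pairs}


# ---------------------------------------------------------------------------
# Spearman calibration


def spearman_calibration_benchmark(n_draws: int = 500, seed: int = 0,
                                   n: int = 9) -> dict[str, float]:
    """Max |exact - t approximation| two-sided p over untied draws."""
    rng = np.random.default_rng(seed)
    diff = 0.0
    for _ in range(n_draws):
        r = spearman(rng.permutation(n), rng.permutation(n))
        diff = max(diff, abs(r.p_value - t_approx_p_value(r.rho, n)))
    return {"max_abs_p_difference": diff, "n": n}


def exact_type_one_error(n: int = 7, alpha: float = 0.05) -> float:
    """P(p <= alpha) under the permutation null, by full enumeration."""
    values, counts = _exact_distribution(n)
    scale = n * (n * n - 1)
    rhos = 1.0 - 6.0 * values / scale
    rejected = sum(int(c) for v, c in zip(rhos, counts)
                   if exact_p_value(float(v), n) <= alpha)
    return rejected / factorial(n)


# ---------------------------------------------------------------------------
# classifier benchmark

_CONTEXT_GENES = {
    "VpreB1": (("MIF", "+"), ("CANDIDATE", "-"), ("IGLL1", "-"),
               ("TOP3B", "+")),
    "VpreB2": (("SLC5A1", "+"), ("SLC5A4", "+"), ("CANDIDATE", "-"),
               ("IGL", "+")),
}


def classifier_benchmark(seed: int = 0, n_leaves: int = 20,
                         rate: float = 0.1) -> dict[str, float]:
    """Macro-averaged accuracy over 5 families x n_leaves records, with
    genomic context supplied for the context-dependent families. Records
    missed outside the VpreB1/VpreB2 charged-count overlap zone are
    counted separately."""
    tree = balanced_tree(n_leaves, 0.05)
    contexts = {}
    for label, genes in _CONTEXT_GENES.items():
        spec = NeighborhoodSpec(gene_order=genes,
                                anchors=(genes[0][0], genes[-1][0]))
        _, contexts[label], _ = make_neighborhood(spec, 0)
    references = {
        label: family_reference(
            dataclasses.replace(spec, substitution_rate=rate),
            family_seed(label, seed))
        for label, spec in DEFAULT_FAMILY_SPECS.items()}
    per_family = {}
    outside_overlap_misses = 0
    for label, spec in DEFAULT_FAMILY_SPECS.items():
        spec = dataclasses.replace(spec, substitution_rate=rate)
        records, truth = make_family(spec, tree, family_seed(label, seed))
        hits = 0
        for rec in records:
            ann = delineate_tail(rec, references[label])
            res = classify(rec, tail=ann, context=contexts.get(label),
                           references=references, subject_gene="CANDIDATE")
            if res.label == label:
                hits += 1
            else:
                charged = truth[rec.id].n_charged
                in_overlap = (label in ("VpreB1", "VpreB2")
                              and 10 <= charged <= 13)
                outside_overlap_misses += not in_overlap
        per_family[label] = hits / len(records)
    return {
        "macro_accuracy": sum(per_family.values()) / len(per_family),
        "outside_overlap_misses": outside_overlap_misses,
        "per_family": per_family,
    }


# ---------------------------------------------------------------------------
# synteny edit recovery


def synteny_recovery_benchmark(n_draws: int = 100,
                               seed: int = 0) -> dict[str, float]:
    """Fraction of planted edits recovered exactly over seeded draws that
    cycle through inversion / translocation / duplication / deletion."""
    rng = np.random.default_rng(seed)
    kinds = ("inversion", "translocation", "duplication", "deletion")
    recovered = 0
    for draw in range(n_draws):
        kind = kinds[draw % 4]
        n = 14
        genes = tuple((f"G{i}", "+" if rng.random() < 0.5 else "-")
                      for i in range(n))
        start = int(rng.integers(2, n - 5))
        span = (start, start + int(rng.integers(1, 3)))
        dest = None
        if kind == "translocation":
            choices = [d for d in range(1, n - 1)
                       if d <= span[0] - 5 or d >= span[1] + 5]
            dest = int(rng.choice(choices))
        spec = NeighborhoodSpec(gene_order=genes,
                                anchors=("G0", f"G{n - 1}"),
                                edits=(Edit(kind=kind, span=span,
                                            destination=dest),))
        ref, edited, log = make_neighborhood(spec, seed + draw)
        inferred = infer_edits(ref, edited)
        matches = [e for e in inferred if e.kind == kind]
        planted_names = {normalize_name(g) for g in log[0]["genes"]}
        if len(inferred) != len(matches):
            continue
        if kind in ("inversion", "translocation"):
            ok = (len(matches) == 1
                  and matches[0].ref_span == tuple(log[0]["span"]))
        else:
            ok = {e.gene for e in matches} == planted_names
        recovered += ok
    return {"recovery_rate": recovered / n_draws, "n_draws": n_draws}


# ---------------------------------------------------------------------------
# duplicate-pair bootstrap support


def duplicate_pair_benchmark(n_replicates: int = 200,
                             seed: int = 0) -> dict[str, float]:
    """Bootstrap support for the duplicated-pair cherry and for its
    membership in the source clade (the glires-style scenario)."""
    records, pair, clade1 = make_duplicate_pair_scenario(seed=seed)
    rows = [r.sequence for r in records]
    ids = [r.id for r in records]
    res = bootstrap_support(rows, ids, n_replicates=n_replicates, seed=seed)
    return {
        "pair_support": clade_support(res, pair) or 0.0,
        "clade_support": clade_support(res, clade1) or 0.0,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# copula recovery


def copula_recovery_benchmark(seed: int = 0, n: int = 1000,
                              targets: tuple[float, ...] = (-0.3, 0.6, 0.8)
                              ) -> dict[float, float]:
    """Sample Spearman rho recovered for each target."""
    out = {}
    for k, rho in enumerate(targets):
        df = make_correlated_table(CopulaSpec(
            n_species=n, target_rho=rho, seed=seed + k,
            marginals=(("normal", (0.0, 1.0)), ("gamma", (2.0, 1.0)))))
        out[rho] = float(sps.spearmanr(df.x, df.y).statistic)
    return out
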