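"""CDR H3 length extraction and the Spearman correlation battery.

CDR H3 is delimited IMGT-style: the residues strictly between the conserved
2nd-CYS of the V region and the conserved Trp/Phe of the J region's
[WF]-G-x-G motif. On a rearranged junction the anchors are located as the
first [WF]-G-x-G match downstream of a cysteine, with the last cysteine
before that match taken as the 2nd-CYS.

Spearman's rho is Pearson's correlation on average (tie-corrected) ranks.
The two-sided p-value is exact — full enumeration of the n! rank
permutations — when n is at most ``exact_threshold`` (default 9) and the
data carry no ties; otherwise the usual t approximation
t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom is used. The
exact null distribution for each n is enumerated once and cached.

The battery runs the fixed set of tail-feature/repertoire analyses
(VpreB tail length vs DH and CDR H3 lengths; tail and whole-protein pI vs
tail length; IGLL1 tail pI vs maximum CDR H3), each also in a
drop-cattle variant where the ultralong-antibody species dominates the
relationship.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import ProteinRecord

J_ANCHOR = re.compile(r"[WF]G.G")


class AnchorlessError(ValueError):
    """Junction lacks the cysteine anchor or the [WF]-G-x-G J anchor."""


def cdrh3_length(junction: str) -> int:
    """Residue count strictly between the anchor Cys and the J-region
    Trp/Phe of a rearranged heavy-chain junction."""
    for m in J_ANCHOR.finditer(junction):
        cys = junction.rfind("C", 0, m.start())
        if cys != -1:
            return m.start() - cys - 1
    raise AnchorlessError("no [WF]G.G J anchor downstream of a cysteine")


def repertoire_lengths(records: list[ProteinRecord]
                       ) -> tuple[dict[str, int], list[str]]:
    """Per-read CDR H3 lengths; anchorless reads are skipped and returned
    separately."""
    lengths: dict[str, int] = {}
    skipped: list[str] = []
    for rec in records:
        try:
            lengths[rec.id] = cdrh3_length(rec.sequence)
        except AnchorlessError:
            skipped.append(rec.id)
    return lengths, skipped


def species_cdrh3_summary(records: list[ProteinRecord]) -> pd.DataFrame:
    """Average and maximum CDR H3 length per species."""
    lengths, _ = repertoire_lengths(records)
    by_id = {r.id: r.species for r in records}
    rows: dict[str, list[int]] = {}
    for rid, ln in lengths.items():
        rows.setdefault(by_id[rid], []).append(ln)
    return pd.DataFrame(
        [{"species": sp, "cdrh3_avg": float(np.mean(v)),
          "cdrh3_max": int(np.max(v)), "n_reads": len(v)}
         for sp, v in sorted(rows.items())]).set_index("species")


# ---------------------------------------------------------------------------
# Spearman with exact small-n p-values

@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    n: int
    rho: float
    p_value: float
    method: str  # "exact" | "t_approx" | "skipped"
    ties_present: bool
    dropped_species: tuple[str, ...] = ()


@lru_cache(maxsize=None)
def _exact_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Counts of the sum-of-squared-rank-difference statistic D over all
    n! permutations (untied data); rho = 1 - 6 D / (n (n^2 - 1))."""
    base = np.arange(n)
    perms = np.array(list(permutations(range(n))), dtype=np.int64)
    d = ((perms - base) ** 2).sum(axis=1)
    values, counts = np.unique(d, return_counts=True)
    return values, counts


def exact_p_value(rho: float, n: int) -> float:
    """Two-sided exact p: probability under the permutation null that
    |rho| is at least the observed |rho|."""
    values, counts = _exact_distribution(n)
    scale = n * (n * n - 1)
    rhos = 1.0 - 6.0 * values / scale
    mask = np.abs(rhos) >= abs(rho) - 1e-12
    return float(counts[mask].sum()) / factorial(n)


def t_approx_p_value(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def spearman(x, y, exact_threshold: int = 9,
             x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Missing values are deleted pairwise. Raises on constant input (rho
    undefined). Exact enumeration applies only to untied samples of size
    at most ``exact_threshold``; ties always route to the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: rho undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    if not ties and n <= exact_threshold:
        return CorrelationResult(x_name, y_name, n, rho,
                                 exact_p_value(rho, n), "exact", False)
    return CorrelationResult(x_name, y_name, n, rho,
                             t_approx_p_value(rho, n), "t_approx", ties)


# ---------------------------------------------------------------------------
# the correlation battery

FEATURE_COLUMNS = [
    "vpreb1_tail_len", "vpreb2_tail_len", "igll1_tail_len",
    "vpreb1_tail_pi", "vpreb2_tail_pi", "igll1_tail_pi",
    "vpreb1_full_pi", "vpreb2_full_pi",
    "cdrh3_avg", "cdrh3_max", "dh_avg", "dh_max",
]

BATTERY = [
    ("vpreb2_tail_len", "dh_max", False),
    ("vpreb2_tail_len", "dh_max", True),
    ("vpreb1_tail_len", "cdrh3_avg", False),
    ("vpreb1_tail_len", "cdrh3_max", False),
    ("vpreb2_tail_len", "cdrh3_avg", False),
    ("vpreb2_tail_len", "cdrh3_max", False),
    ("vpreb1_full_pi", "vpreb1_tail_len", False),
    ("vpreb1_tail_pi", "vpreb1_tail_len", False),
    ("vpreb2_full_pi", "vpreb2_tail_len", False),
    ("vpreb2_tail_pi", "vpreb2_tail_len", False),
    ("igll1_tail_pi", "cdrh3_max", False),
    ("igll1_tail_pi", "cdrh3_max", True),
]


def correlation_battery(table: pd.DataFrame,
                        drop_species: tuple[str, ...] = ("cattle",),
                        exact_threshold: int = 9
                        ) -> list[CorrelationResult]:
    """Run the fixed analysis battery on a per-species feature table.

    ``drop_species`` names the rows removed in the sensitivity variants
    (the ultralong-CDR-H3 species, cattle, by default). Analyses with
    fewer than 3 complete pairs are emitted as skipped entries rather than
    dropped silently.
    """
    results = []
    for x_name, y_name, drop in BATTERY:
        sub = table.drop(index=[s for s in drop_species if s in table.index]
                         ) if drop else table
        dropped = tuple(s for s in drop_species if s in table.index) if drop else ()
        if x_name not in sub.columns or y_name not in sub.columns:
            results.append(CorrelationResult(
                x_name, y_name, 0, float("nan"), float("nan"),
                "skipped", False, dropped))
            continue
        x = sub[x_name].to_numpy(dtype=float)
        y = sub[y_name].to_numpy(dtype=float)
        n_complete = int((~(np.isnan(x) | np.isnan(y))).sum())
        if n_complete < 3:
            results.append(CorrelationResult(
                x_name, y_name, n_complete, float("nan"), float("nan"),
                "skipped", False, dropped))
            continue
        try:
            res = spearman(x, y, exact_threshold, x_name, y_name)
        except ValueError:
            # constant column: rho undefined for this analysis
            results.append(CorrelationResult(
                x_name, y_name, n_complete, float("nan"), float("nan"),
                "degenerate", False, dropped))
            continue
        results.append(CorrelationResult(
            res.x_name, res.y_name, res.n, res.rho, res.p_value,
            res.method, res.ties_present, dropped))
    return results


def battery_report(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "x": r.x_name, "y": r.y_name, "n": r.n, "rho": r.rho,
        "p": r.p_value, "method": r.method,
        "dropped_species": ";".join(r.dropped_species),
    } for r in results])
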