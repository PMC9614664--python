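"""Alignment, shading, neighbor joining and bootstrap support."""

import itertools

import numpy as np
import pytest

from slc_evo.phylo import (bootstrap_support, clade_support, global_align,
                           nj_tree, percent_identity_matrix,
                           similarity_shading)
from slc_evo.records import ProteinRecord
from slc_evo.synthetic import make_duplicate_pair_scenario


def enumerate_alignment_optimum(a, b, match=1.0, mismatch=-1.0,
                                gap_open=2.0, gap_extend=1.0):
    """Brute-force oracle: the best score over *every* global alignment,
    enumerated recursively. A gap run of length k costs gap_open +
    k * gap_extend; gaps in either sequence open separate runs."""
    best = [-np.inf]

    def rec(i, j, score, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):  # gap in b
            cost = gap_extend + (gap_open if state != "D" else 0.0)
            rec(i + 1, j, score - cost, "D")
        if j < len(b):  # gap in a
            cost = gap_extend + (gap_open if state != "I" else 0.0)
            rec(i, j + 1, score - cost, "I")

    rec(0, 0, 0.0, "M")
    return best[0]


class TestGlobalAlign:
    def test_self_alignment_is_identity(self):
        res = global_align("MKVLA", "MKVLA")
        assert res.identity_columns == 1.0
        assert res.aligned_query == res.aligned_subject == "MKVLA"

    def test_degapping_recovers_inputs(self):
        res = global_align("MKVLAGW", "MKLAW")
        assert res.aligned_query.replace("-", "") == "MKVLAGW"
        assert res.aligned_subject.replace("-", "") == "MKLAW"
        assert len(res.aligned_query) == len(res.aligned_subject)

    def test_identity_is_symmetric(self, rng):
        for _ in range(10):
            a = "".join(rng.choice(list("ACDEFGHIKL"), size=12))
            b = "".join(rng.choice(list("ACDEFGHIKL"), size=9))
            ab = global_align(a, b)
            ba = global_align(b, a)
            assert ab.identity_columns == pytest.approx(ba.identity_columns)
            assert ab.score == pytest.approx(ba.score)

    def test_matches_exhaustive_enumeration(self, rng):
        """DP optimum equals the enumerated optimum over all global
        alignments, on random pairs of length <= 6 over a 4-letter
        alphabet (toy match/mismatch scoring, affine gaps)."""
        alphabet = list("ACGT")
        for _ in range(60):
            a = "".join(rng.choice(alphabet,
                                   size=rng.integers(1, 7)))
            b = "".join(rng.choice(alphabet,
                                   size=rng.integers(1, 7)))
            got = global_align(a, b, matrix=None, gap_open=2.0,
                               gap_extend=1.0).score
            assert got == pytest.approx(enumerate_alignment_optimum(a, b))

    def test_dp_dominates_trivial_alignment(self, rng):
        """Optimal score is at least the no-gap diagonal score."""
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")
        for _ in range(10):
            n = int(rng.integers(5, 20))
            a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
            b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
            diag = sum(blosum[x, y] for x, y in zip(a, b))
            assert global_align(a, b).score >= diag - 1e-9


class TestIdentityMatrix:
    def test_duplicates_give_unit_offdiagonal(self):
        recs = [ProteinRecord(id=f"r{i}", species="s", sequence="MKVLAGW")
                for i in range(3)]
        m, ids = percent_identity_matrix(recs)
        assert np.allclose(m, 1.0)
        assert ids == ["r0", "r1", "r2"]

    def test_symmetry_and_unit_diagonal(self, benchmark_families):
        recs = benchmark_families["VpreB1"][0][:5]
        m, _ = percent_identity_matrix(recs)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_identity_decreases_with_tree_distance(self):
        """Across a generated family, pairwise identity rank-correlates
        negatively with patristic distance."""
        from scipy import stats as sps
        from slc_evo.synthetic import (DEFAULT_FAMILY_SPECS, make_family,
                                       parse_tree)
        newick = ("((a:0.02,b:0.02):0.5,(c:0.02,d:0.02):0.5,"
                  "(e:0.3,f:0.3):0.2);")
        tree = parse_tree(newick)
        recs, _ = make_family(DEFAULT_FAMILY_SPECS["VpreB1"], newick, seed=8)
        by = {r.species: r for r in recs}
        tips = sorted(by)
        dm = tree.tip_tip_distances()
        idents, dists = [], []
        for x, y in itertools.combinations(tips, 2):
            idents.append(global_align(by[x], by[y]).identity_columns)
            dists.append(dm[x, y])
        assert sps.spearmanr(idents, dists).statistic < 0


class TestSimilarityShading:
    def test_identical_column(self):
        assert similarity_shading(["L", "L", "L"]) == ["identical"]

    def test_conservative_substitutions_stay_identical_band(self):
        # L, I, V all score >= 1 against modal L in BLOSUM62
        assert similarity_shading(["L", "I", "V"]) == ["identical"]

    def test_dissimilar_column_is_low(self):
        assert similarity_shading(["L", "D"]) == ["low"]

    def test_gaps_excluded_and_all_gap_flagged(self):
        assert similarity_shading(["L-", "L-"]) == ["identical", "low"]

    def test_band_boundaries_go_up(self):
        # 4/5 = 0.8 similar -> high band (boundary assigned upward)
        col = ["L", "L", "L", "L", "D"]
        assert similarity_shading(col) == ["high"]


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 3.0, 4.0],
                      [3.0, 0.0, 5.0],
                      [4.0, 5.0, 0.0]])
        res = nj_tree(d, ["a", "b", "c"])
        dm = res.tree.tip_tip_distances()
        assert dm["a", "b"] == pytest.approx(3.0)
        assert dm["a", "c"] == pytest.approx(4.0)
        assert dm["b", "c"] == pytest.approx(5.0)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> additive distances
        d = np.array([
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0]], dtype=float)
        ids = ["A", "B", "C", "D"]
        res = nj_tree(d, ids)
        dm = res.tree.tip_tip_distances()
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i < j:
                    assert dm[x, y] == pytest.approx(d[i, j])

    def test_ultrametric_matches_upgma_topology(self):
        d = np.array([
            [0, 2, 6, 6],
            [2, 0, 6, 6],
            [6, 6, 0, 2],
            [6, 6, 2, 0]], dtype=float)
        res = nj_tree(d, ["A", "B", "C", "D"])
        # UPGMA pairs (A,B) and (C,D); NJ must produce the same split
        sides = [frozenset(t.name for t in n.tips())
                 for n in res.tree.non_tips(include_self=False)]
        assert frozenset("AB") in sides or frozenset("CD") in sides

    def test_rejects_asymmetry(self):
        d = np.array([[0, 1.0, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(d, list("abc"))

    def test_negative_lengths_clamped(self):
        d = np.array([
            [0.0, 0.1, 0.4, 0.5],
            [0.1, 0.0, 0.45, 0.55],
            [0.4, 0.45, 0.0, 0.05],
            [0.5, 0.55, 0.05, 0.0]])
        res = nj_tree(d, list("abcd"))
        assert all((n.length or 0) >= 0 for n in res.tree.traverse())


class TestBootstrap:
    def test_identical_clades_get_full_support(self):
        rows = ["AAAAAAAAAA"] * 2 + ["CCCCCCCCCC"] * 2
        ids = ["a1", "a2", "c1", "c2"]
        res = bootstrap_support(rows, ids, n_replicates=30, seed=1)
        assert clade_support(res, {"a1", "a2"}) == 100.0

    def test_support_invariant_to_input_order(self):
        recs, pair, _ = make_duplicate_pair_scenario(seed=3)
        rows = [r.sequence for r in recs]
        ids = [r.id for r in recs]
        res1 = bootstrap_support(rows, ids, n_replicates=50, seed=7)
        res2 = bootstrap_support(rows[::-1], ids[::-1], n_replicates=50,
                                 seed=7)
        assert res1.support == res2.support

    def test_duplicate_pair_is_supported_cherry(self):
        """The recently duplicated pair forms a strongly supported cherry
        inside its source clade (the glires-style scenario)."""
        recs, pair, clade1 = make_duplicate_pair_scenario(seed=2)
        rows = [r.sequence for r in recs]
        ids = [r.id for r in recs]
        res = bootstrap_support(rows, ids, n_replicates=200, seed=0)
        assert clade_support(res, pair) >= 90.0
        assert clade_support(res, clade1) >= 90.0
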