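"""Anchored intervals, shared-block calling, proximity, edit inference."""

import numpy as np
import pytest

from slc_evo.synteny import (AnchorNotFoundError, Gene, GeneNeighborhood,
                             SplitLocusError, anchored_interval,
                             find_anchored, infer_edits, normalize_name,
                             proximity, read_gene_table, shared_blocks,
                             write_gene_table)
from slc_evo.synthetic import Edit, NeighborhoodSpec, make_neighborhood


def neighborhood(names, species="sp", scaffold="scf", strands=None):
    strands = strands or ["+"] * len(names)
    genes = tuple(Gene(name=n, start=1 + i * 10, end=5 + i * 10, strand=s)
                  for i, (n, s) in enumerate(zip(names, strands)))
    return GeneNeighborhood(species=species, scaffold_id=scaffold,
                            genes=genes)


class TestNormalization:
    @pytest.mark.parametrize("alias,symbol", [
        ("Ig Iota", "VPREB1"), ("Om", "VPREB2"), ("IGLL5", "IGLL1"),
        ("top3b", "TOP3B")])
    def test_known_aliases(self, alias, symbol):
        assert normalize_name(alias) == symbol


class TestAnchoredInterval:
    def test_adjacent_anchors_give_two_genes(self):
        n = neighborhood(["A", "MIF", "TOP3B", "B"])
        sub = anchored_interval(n, "MIF", "TOP3B")
        assert [g.name for g in sub.genes] == ["MIF", "TOP3B"]

    def test_reversed_storage_is_normalized(self):
        fwd = neighborhood(["MIF", "X", "Y", "TOP3B"],
                           strands=["+", "-", "+", "+"])
        rev = fwd.reversed_view()
        # re-sort reversed genes by coordinate to emulate storage 3'->5'
        stored = neighborhood([g.name for g in rev.genes],
                              strands=[g.strand for g in rev.genes])
        a = anchored_interval(fwd, "MIF", "TOP3B")
        b = anchored_interval(stored, "MIF", "TOP3B")
        assert [(g.name, g.strand) for g in a.genes] == \
               [(g.name, g.strand) for g in b.genes]

    def test_missing_anchor_named_in_error(self):
        n = neighborhood(["A", "MIF", "B"])
        with pytest.raises(AnchorNotFoundError, match="TOP3B"):
            anchored_interval(n, "MIF", "TOP3B")

    def test_split_locus_detected(self):
        n1 = neighborhood(["MIF", "A"], scaffold="s1")
        n2 = neighborhood(["B", "TOP3B"], scaffold="s2")
        with pytest.raises(SplitLocusError):
            find_anchored([n1, n2], "MIF", "TOP3B")

    def test_planted_interval_matches_generator(self):
        spec = NeighborhoodSpec(
            gene_order=tuple((f"G{i}", "+") for i in range(10)),
            anchors=("G2", "G7"))
        ref, _, _ = make_neighborhood(spec, seed=0)
        sub = anchored_interval(ref, "G2", "G7")
        assert [g.name for g in sub.genes] == [f"G{i}" for i in range(2, 8)]


class TestSharedBlocks:
    def test_identical_neighborhoods_one_block(self):
        n = neighborhood(["A", "B", "C", "D", "E"])
        call = shared_blocks(n, n)
        assert len(call.blocks) == 1
        blk = call.blocks[0]
        assert blk.ref_span == (0, 4) and blk.orientation == "same"
        assert not call.unplaced["ref_only"]

    def test_planted_inversion_called(self):
        spec = NeighborhoodSpec(
            gene_order=tuple((f"G{i}", "+") for i in range(12)),
            anchors=("G0", "G11"),
            edits=(Edit(kind="inversion", span=(3, 7)),))
        ref, edited, _ = make_neighborhood(spec, seed=1)
        call = shared_blocks(ref, edited)
        inv = [b for b in call.blocks if b.orientation == "inverted"]
        assert len(inv) == 1
        assert inv[0].ref_span == (3, 7)
        same = [b for b in call.blocks if b.orientation == "same"]
        assert {b.ref_span for b in same} == {(0, 2), (8, 11)}

    def test_gene_missing_from_query_is_unplaced(self):
        ref = neighborhood(["A", "B", "C", "D", "E"])
        query = neighborhood(["A", "B", "D", "E"])
        call = shared_blocks(ref, query)
        assert call.unplaced["ref_only"] == ("C",)
        assert {b.ref_span for b in call.blocks} == {(0, 1), (3, 4)}

    def test_label_symmetry(self):
        spec = NeighborhoodSpec(
            gene_order=tuple((f"G{i}", "+") for i in range(10)),
            anchors=("G0", "G9"),
            edits=(Edit(kind="inversion", span=(2, 5)),))
        ref, edited, _ = make_neighborhood(spec, seed=2)
        fwd = shared_blocks(ref, edited)
        rev = shared_blocks(edited, ref)
        assert {(b.query_span, b.ref_span, b.orientation)
                for b in rev.blocks} == \
               {(b.ref_span, b.query_span, b.orientation)
                for b in fwd.blocks}

    def test_inversion_involution(self):
        """Re-inverting the inverted span restores one same-orientation
        block covering everything."""
        spec = NeighborhoodSpec(
            gene_order=tuple((f"G{i}", "+") for i in range(10)),
            anchors=("G0", "G9"),
            edits=(Edit(kind="inversion", span=(2, 5)),))
        _, edited, _ = make_neighborhood(spec, seed=3)
        genes = list(edited.genes)
        undone = genes[:2] + [g.flipped() for g in reversed(genes[2:6])] \
            + genes[6:]
        starts = [g.start for g in edited.genes]
        undone = [Gene(g.name, s, s + 4, g.strand)
                  for g, s in zip(undone, starts)]
        restored = GeneNeighborhood(species="sp", scaffold_id="scf",
                                    genes=tuple(undone))
        ref, _, _ = make_neighborhood(
            NeighborhoodSpec(gene_order=spec.gene_order,
                             anchors=spec.anchors), seed=3)
        call = shared_blocks(ref, restored)
        assert len(call.blocks) == 1
        assert call.blocks[0].orientation == "same"

    def test_duplication_counts(self):
        ref = neighborhood(["A", "B", "C"])
        query = neighborhood(["A", "B", "B", "C"])
        call = shared_blocks(ref, query)
        assert call.duplications == {"B": (1, 2)}


class TestProximity:
    def test_adjacent_three_prime(self):
        n = neighborhood(["A", "SUBJ", "TARG", "B"])
        hit, dist = proximity(n, "SUBJ", "TARG", side="3prime", k=1)
        assert hit and dist == 1

    def test_beyond_window_is_false(self):
        n = neighborhood(["SUBJ", "A", "B", "C", "D", "E", "TARG"])
        hit, dist = proximity(n, "SUBJ", "TARG", k=5)
        assert not hit and dist is None

    def test_side_filtering(self):
        n = neighborhood(["TARG", "SUBJ", "A"])
        assert proximity(n, "SUBJ", "TARG", side="5prime", k=2)[0]
        assert not proximity(n, "SUBJ", "TARG", side="3prime", k=2)[0]

    def test_absent_subject_raises(self):
        n = neighborhood(["A", "B"])
        with pytest.raises(KeyError):
            proximity(n, "NOPE", "A")


class TestEditRecovery:
    def random_spec(self, rng, kind):
        n = 14
        genes = tuple((f"G{i}", "+" if rng.random() < 0.5 else "-")
                      for i in range(n))
        start = int(rng.integers(2, n - 5))
        span = (start, start + int(rng.integers(1, 3)))
        dest = None
        if kind == "translocation":
            # the jumped-over segment must be strictly larger than the
            # moved span, so the minimal-moved-block convention resolves
            # the move direction unambiguously
            choices = [d for d in range(1, n - 1)
                       if d <= span[0] - 5 or d >= span[1] + 5]
            dest = int(rng.choice(choices))
        return NeighborhoodSpec(
            gene_order=genes, anchors=("G0", f"G{n - 1}"),
            edits=(Edit(kind=kind, span=span, destination=dest),))

    @pytest.mark.parametrize("kind", ["inversion", "translocation",
                                      "duplication", "deletion"])
    def test_planted_edits_recovered_exactly(self, kind, rng):
        for draw in range(25):
            spec = self.random_spec(rng, kind)
            ref, edited, log = make_neighborhood(spec, seed=draw)
            inferred = infer_edits(ref, edited)
            planted = log[0]
            matches = [e for e in inferred if e.kind == kind]
            planted_names = {normalize_name(g) for g in planted["genes"]}
            if kind in ("inversion", "translocation"):
                assert len(matches) == 1, (kind, draw, inferred)
                assert matches[0].ref_span == tuple(planted["span"])
            elif kind == "duplication":
                assert {e.gene for e in matches} == planted_names
                assert all(e.copies == (1, 2) for e in matches)
            else:
                assert {e.gene for e in matches} == planted_names
            # nothing else is called
            assert len(inferred) == len(matches), (kind, draw, inferred)


class TestTableIO:
    def test_round_trip(self, tmp_path):
        n = neighborhood(["MIF", "VPREB1", "TOP3B"], species="human")
        path = tmp_path / "genes.tsv"
        write_gene_table([n], path)
        back = read_gene_table(path)
        assert len(back) == 1
        assert [(g.name, g.start, g.end, g.strand)
                for g in back[0].genes] == \
               [(g.name, g.start, g.end, g.strand) for g in n.genes]
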