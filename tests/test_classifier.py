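"""Motif scanning, family rule table, and PTCRA scaffold validation."""

import dataclasses

import pytest

from slc_evo.classifier import (ClassifierConfig, classify, scan_motif,
                                validate_ptcra)
from slc_evo.features import delineate_tail
from slc_evo.records import ProteinRecord, TailAnnotation
from slc_evo.synthetic import (DEFAULT_FAMILY_SPECS, balanced_tree,
                               family_reference, family_seed, make_family)


def tailed_record(rec_id, n_basic, n_acidic, tail_len=25):
    """A record plus a C-tail annotation with the given charge counts."""
    tail = ("K" * n_basic + "D" * n_acidic
            + "G" * (tail_len - n_basic - n_acidic))
    seq = "M" + "A" * 99 + tail
    rec = ProteinRecord(id=rec_id, species=rec_id, sequence=seq)
    ann = TailAnnotation(record_id=rec_id, side="C", boundary=100,
                         tail_sequence=tail, tail_length=tail_len,
                         n_basic=n_basic, n_acidic=n_acidic,
                         tail_pi=None, full_pi=None)
    return rec, ann


class TestScanMotif:
    def test_absent_motif_gives_empty(self):
        assert scan_motif("MKVLAGW" * 3, "GPRC") == []

    def test_exact_hit_position(self):
        seq = "A" * 12 + "VFPGQ" + "A" * 10
        hits = scan_motif(seq, "VFPGQ")
        assert [h.position for h in hits] == [12]
        assert hits[0].matched == "VFPGQ"

    def test_one_mismatch_tolerated_when_allowed(self):
        seq = "A" * 12 + "VFPGA" + "A" * 10  # Q->A substitution
        assert scan_motif(seq, "VFPGQ", max_mismatches=0) == []
        hits = scan_motif(seq, "VFPGQ", max_mismatches=1)
        assert [h.position for h in hits] == [12]

    def test_window_restricts_search(self):
        seq = "GPRC" + "A" * 20 + "GPRC"
        assert [h.position for h in scan_motif(seq, "GPRC",
                                               window=(0, 10))] == [0]

    def test_out_of_bounds_window_warns_not_raises(self):
        with pytest.warns(UserWarning):
            assert scan_motif("MKVLA", "GPRC", window=(50, 60)) == []

    def test_planted_igll1_motif_found_in_tail(self, references):
        spec = DEFAULT_FAMILY_SPECS["IGLL1"]
        records, truth = make_family(spec, balanced_tree(6, 0.1),
                                     family_seed("IGLL1", 5))
        for rec in records:
            boundary = truth[rec.id].boundary
            hits = scan_motif(rec.sequence, "GPRC", window=(0, boundary + 4))
            assert any(h.matched == "GPRC" for h in hits)


class TestValidatePtcra:
    def test_reference_validates_itself(self, references):
        ref = references["PTCRA"]
        ok, ev = validate_ptcra(ref.sequence, ref)
        assert ok
        assert ("ptcra_alignable", "pass") in [(n, s) for n, s, _ in ev]

    def test_cysteine_knockout_fails_with_named_evidence(self, references):
        ref = references["PTCRA"]
        pos = ref.conserved_sites[0][0]
        mutant = ref.sequence[:pos] + "S" + ref.sequence[pos + 1:]
        # remove every other C/W nearby ambiguity by exact projection
        ok, ev = validate_ptcra(mutant, ref,
                                ClassifierConfig(site_tolerance=0))
        assert not ok
        failed = [n for n, s, _ in ev if s == "fail"]
        assert f"ptcra_site_C{pos + 1}" in failed

    def test_unalignable_sequence_fails(self, references):
        ok, ev = validate_ptcra("GAVLIPSTNQ" * 12, references["PTCRA"])
        assert not ok
        assert ev[0][0] == "ptcra_alignable" and ev[0][1] == "fail"

    def test_evolved_family_members_pass(self):
        """PTCRA leaves at substitution rate 0.05 with protected sites
        validate in >= 95% of 100 draws."""
        spec = dataclasses.replace(DEFAULT_FAMILY_SPECS["PTCRA"],
                                   substitution_rate=0.05)
        passed = total = 0
        for seed in range(25):
            ref = family_reference(spec, seed)
            records, _ = make_family(spec, balanced_tree(4, 0.5), seed)
            for rec in records:
                ok, _ = validate_ptcra(rec, ref)
                passed += ok
                total += 1
        assert total == 100
        assert passed / total >= 0.95


class TestClassify:
    def test_no_tail_no_motifs_is_unknown(self):
        rec = ProteinRecord(id="x", species="x", sequence="MAVLIG" * 20)
        res = classify(rec)
        assert res.label == "unknown"
        assert res.evidence  # every evaluated rule leaves a trace

    def test_overlap_zone_without_context_is_unknown(self):
        """12 charged residues satisfy both VpreB1 and VpreB2 ranges;
        without genomic context the tie stands, with both candidacies in
        evidence."""
        rec, ann = tailed_record("amb", n_basic=6, n_acidic=6)
        res = classify(rec, tail=ann)
        assert res.label == "unknown"
        rules = dict((n, s) for n, s, _ in res.evidence)
        assert rules["vpreb1_charged"] == "pass"
        assert rules["vpreb2_charged"] == "pass"

    def test_overlap_zone_resolved_by_context(self, family_contexts):
        rec, ann = tailed_record("amb", n_basic=6, n_acidic=6)
        res = classify(rec, tail=ann, context=family_contexts["VpreB1"],
                       subject_gene="CANDIDATE")
        assert res.label == "VpreB1"
        res2 = classify(rec, tail=ann, context=family_contexts["VpreB2"],
                        subject_gene="CANDIDATE")
        assert res2.label == "VpreB2"

    def test_distinct_counts_classified_without_context(self):
        rec, ann = tailed_record("b1", n_basic=7, n_acidic=7)  # 14: VpreB1
        assert classify(rec, tail=ann).label == "VpreB1"
        rec, ann = tailed_record("b2", n_basic=4, n_acidic=4)  # 8: VpreB2
        assert classify(rec, tail=ann).label == "VpreB2"

    def test_context_never_flips_between_families(self, family_contexts):
        """Context may move a label to or from unknown, never from one
        concrete family to another."""
        for nb, na in [(7, 7), (4, 4), (6, 6), (5, 4)]:
            rec, ann = tailed_record(f"r{nb}{na}", nb, na)
            bare = classify(rec, tail=ann).label
            for ctx in family_contexts.values():
                with_ctx = classify(rec, tail=ann, context=ctx,
                                    subject_gene="CANDIDATE").label
                if bare != with_ctx:
                    assert "unknown" in (bare, with_ctx)

    def test_synthetic_benchmark_macro_accuracy(
            self, benchmark_families, family_contexts, references):
        """5 families x 20 leaves at rate 0.1: macro accuracy >= 0.95,
        confusion confined to the VpreB1/VpreB2 charged-count overlap."""
        per_family = {}
        for label, (records, truth) in benchmark_families.items():
            ref = references[label]
            ctx = family_contexts.get(label)
            hits = 0
            for rec in records:
                ann = delineate_tail(rec, ref)
                res = classify(rec, tail=ann, context=ctx,
                               references=references,
                               subject_gene="CANDIDATE")
                if res.label == label:
                    hits += 1
                else:
                    assert label in ("VpreB1", "VpreB2")
                    charged = truth[rec.id].n_charged
                    assert 11 - 1 <= charged <= 12 + 1
            per_family[label] = hits / len(records)
        macro = sum(per_family.values()) / len(per_family)
        assert macro >= 0.95

    def test_classification_is_order_independent(self, benchmark_families,
                                                 references):
        records, _ = benchmark_families["VpreB3"]
        labels_fwd = [classify(r, references=references).label
                      for r in records]
        labels_rev = [classify(r, references=references).label
                      for r in reversed(records)]
        assert labels_fwd == labels_rev[::-1]
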