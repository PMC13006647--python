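import numpy as np
import pytest
from Bio.Seq import Seq

from osckit.indel_engine import (
    Construct,
    DELETION,
    FRAME_DISRUPTED,
    FUNCTIONAL_RESTORED,
    INSERTION,
    IndelEvent,
    PREMATURE_STOP,
    apply_indel,
    classify_outcome,
    fraction_forbidden,
    normalize_event,
    read_events_tsv,
    reconstruct_in_host,
    summarize_spectrum,
    write_events_tsv,
)
from osckit.sequence_core import CodingSequence, OscKitError


def oracle_classify(mutant_nt: str) -> str:
    """Independent full-translation classification via Biopython."""
    length = len(mutant_nt)
    net = length % 3
    prot = str(Seq(mutant_nt[: length - net]).translate(table=11))
    i = prot.find("*")
    if i == -1:
        return FRAME_DISRUPTED
    if net == 0 and 3 * i == length - 3:
        return FUNCTIONAL_RESTORED
    if 3 * i < length - 3:
        return PREMATURE_STOP
    return FRAME_DISRUPTED


def all_events(length, ins_lengths=(1, 2), del_lengths=(1, 2)):
    events = []
    for n in ins_lengths:
        for pos in range(0, length + 1):
            for payload in ("A", "T", "GA", "AT", "GC"):
                if len(payload) == n:
                    events.append(IndelEvent(INSERTION, pos, payload))
    for n in del_lengths:
        for pos in range(1, length - n + 2):
            events.append(IndelEvent(DELETION, pos, n))
    return events


class TestIndelEvent:
    def test_validation(self):
        with pytest.raises(OscKitError):
            IndelEvent("dup", 1, "A")
        with pytest.raises(OscKitError):
            IndelEvent(INSERTION, 1, "")
        with pytest.raises(OscKitError):
            IndelEvent(DELETION, 1, 0)
        with pytest.raises(OscKitError):
            IndelEvent(DELETION, 0, 1)

    def test_delta(self):
        assert IndelEvent(INSERTION, 3, "GA").delta == 2
        assert IndelEvent(DELETION, 3, 4).delta == -4


class TestApplyIndel:
    def test_hand_insertion(self):
        cds = CodingSequence("t", "ATGCAAAAT")
        out = apply_indel(cds, IndelEvent(INSERTION, 6, "T"))
        assert out.nt == "ATGCAATAAT"

    def test_hand_deletion(self):
        cds = CodingSequence("t", "ATGCAAAAT")
        out = apply_indel(cds, IndelEvent(DELETION, 2, 4))
        assert out.nt == "AAAAT"  # positions 2-5 removed

    def test_insert_then_inverse(self):
        cds = CodingSequence("t", "ATGCAAAAT")
        ins = IndelEvent(INSERTION, 4, "GG")
        mutant = apply_indel(cds, ins)
        back = apply_indel(mutant, IndelEvent(DELETION, 5, 2))
        assert back.nt == cds.nt

    def test_delete_then_inverse(self):
        cds = CodingSequence("t", "ATGCAAAAT")
        deleted = cds.nt[3:5]
        mutant = apply_indel(cds, IndelEvent(DELETION, 4, 2))
        back = apply_indel(mutant, IndelEvent(INSERTION, 3, deleted))
        assert back.nt == cds.nt

    def test_deletion_past_end(self):
        cds = CodingSequence("t", "ATGCAA")
        with pytest.raises(OscKitError):
            apply_indel(cds, IndelEvent(DELETION, 5, 3))

    def test_length_bookkeeping(self, toy_pair):
        plus, _, _ = toy_pair
        for event in all_events(len(plus.cds.nt)):
            mutant = apply_indel(plus, event)
            assert len(mutant.nt) == len(plus.cds.nt) + event.delta


class TestClassifyOutcome:
    def test_fresh_plus_construct_is_premature_ochre(self, toy_pair):
        plus, _, _ = toy_pair
        out = classify_outcome(plus, plus.cds)
        assert out.classification == PREMATURE_STOP
        assert out.first_stop_codon_index == 7
        assert plus.cds.nt[18:21] == "TAA"

    def test_restoring_deletion_no_loop_change(self, toy_pair):
        plus, minus, _ = toy_pair
        for c in (plus, minus):
            out = classify_outcome(c, apply_indel(c, IndelEvent(DELETION, 16, 1)))
            assert out.classification == FUNCTIONAL_RESTORED
            assert out.net_frame_shift == 0
            assert out.loop_delta_aa == 0

    def test_shift_exposing_hidden_stop(self, toy_pair):
        # -1 upstream of the +1-frame TGA reads it in frame in +OSC only
        plus, minus, _ = toy_pair
        event = IndelEvent(DELETION, 8, 1)
        out_plus = classify_outcome(plus, apply_indel(plus, event))
        out_minus = classify_outcome(minus, apply_indel(minus, event))
        assert out_plus.classification == PREMATURE_STOP
        assert out_minus.classification == FUNCTIONAL_RESTORED

    def test_plus_one_insertion_forms_ochre_in_unshifted_gene(self, toy_wt):
        construct = Construct(toy_wt)  # frame 0, ends in natural TAA
        mutant = apply_indel(construct, IndelEvent(INSERTION, 18, "T"))
        out = classify_outcome(construct, mutant)
        assert out.classification == PREMATURE_STOP
        assert mutant.nt[18:21] == "TAA"
        assert out.first_stop_codon_index == 7

    def test_two_base_insertion_lengthens_loop(self, toy_pair):
        _, minus, _ = toy_pair
        out = classify_outcome(minus, apply_indel(minus, IndelEvent(INSERTION, 16, "GA")))
        assert out.classification == FUNCTIONAL_RESTORED
        assert out.loop_delta_aa == 1

    def test_readthrough_is_frame_disrupted(self, toy_wt):
        construct = Construct(toy_wt)
        # delete 3 nt spanning the natural stop: frame kept, stop destroyed
        mutant = apply_indel(construct, IndelEvent(DELETION, 37, 3))
        out = classify_outcome(construct, mutant)
        assert out.classification == FRAME_DISRUPTED
        assert out.first_stop_codon_index is None

    def test_matches_independent_oracle_exhaustively(self, toy_pair):
        plus, minus, _ = toy_pair
        for construct in (plus, minus):
            for event in all_events(len(construct.cds.nt)):
                mutant = apply_indel(construct, event)
                assert (
                    classify_outcome(construct, mutant).classification
                    == oracle_classify(mutant.nt)
                ), event

    def test_net_frame_shift_formula(self, toy_pair):
        plus, _, _ = toy_pair
        for event in all_events(len(plus.cds.nt)):
            out = classify_outcome(plus, apply_indel(plus, event))
            assert out.net_frame_shift == (plus.frameshift_offset + event.delta) % 3
            if out.classification == FUNCTIONAL_RESTORED:
                assert out.net_frame_shift == 0


class TestNormalizeEvent:
    def test_deletion_left_aligned_in_run(self):
        nt = "ATGCAAAACT"
        for pos in (5, 6, 7, 8):
            norm = normalize_event(nt, IndelEvent(DELETION, pos, 1))
            assert norm.position == 5

    def test_insertion_left_aligned_in_run(self):
        nt = "ATGCAAAACT"
        norm = normalize_event(nt, IndelEvent(INSERTION, 8, "A"))
        assert norm.position == 4
        assert norm.payload == "A"

    def test_same_mutant_same_outcome(self, toy_pair):
        plus, _, _ = toy_pair
        nt = plus.cds.nt
        for pos in range(1, len(nt)):
            event = IndelEvent(DELETION, pos, 1)
            norm = normalize_event(nt, event)
            assert apply_indel(plus, event).nt == apply_indel(plus, norm).nt

    def test_non_repeat_untouched(self):
        event = IndelEvent(DELETION, 4, 1)
        assert normalize_event("ATGCAT", event) == event


class TestReconstruction:
    def test_identity_host_reproduces_mutant(self, toy_pair):
        plus, _, _ = toy_pair
        event = IndelEvent(DELETION, 16, 1)
        res = reconstruct_in_host(event, plus, plus)
        assert res.permitted
        assert res.outcome.classification == FUNCTIONAL_RESTORED

    def test_event_forbidden_only_in_plus(self, toy_pair):
        plus, minus, _ = toy_pair
        event = IndelEvent(DELETION, 8, 1)
        assert reconstruct_in_host(event, minus, minus).permitted
        assert not reconstruct_in_host(event, minus, plus).permitted

    def test_event_permitted_in_both(self, toy_pair):
        plus, minus, _ = toy_pair
        event = IndelEvent(DELETION, 16, 1)
        assert reconstruct_in_host(event, minus, plus).permitted
        assert reconstruct_in_host(event, plus, minus).permitted

    def test_length_mismatch_rejected(self, toy_pair, toy_wt):
        plus, _, _ = toy_pair
        with pytest.raises(OscKitError):
            reconstruct_in_host(IndelEvent(DELETION, 1, 1), plus, Construct(toy_wt))

    def test_minus_permits_superset(self, toy_pair):
        plus, minus, _ = toy_pair
        events = all_events(len(plus.cds.nt))
        permitted_plus = {
            e.label for e in events if reconstruct_in_host(e, plus, plus).permitted
        }
        permitted_minus = {
            e.label for e in events if reconstruct_in_host(e, minus, minus).permitted
        }
        assert permitted_plus < permitted_minus


class TestFractionForbidden:
    def test_empty_rejected(self, toy_pair):
        plus, minus, _ = toy_pair
        with pytest.raises(OscKitError):
            fraction_forbidden([], minus, plus)

    def test_all_permitted_is_zero(self, toy_pair):
        plus, minus, _ = toy_pair
        events = [IndelEvent(DELETION, 16, 1), IndelEvent(INSERTION, 16, "GA")]
        assert fraction_forbidden(events, minus, plus) == 0.0

    def test_matches_bruteforce_on_exhaustive_insertions(self, toy_pair):
        plus, minus, _ = toy_pair
        events = [
            IndelEvent(INSERTION, pos, base)
            for pos in range(0, len(minus.cds.nt) + 1)
            for base in "ACGT"
        ]
        frac = fraction_forbidden(events, minus, plus)
        oracle = sum(
            oracle_classify(apply_indel(plus, e).nt) != FUNCTIONAL_RESTORED
            for e in events
        ) / len(events)
        assert frac == oracle


class TestSummarizeSpectrum:
    def test_insertion_percentage(self):
        mutants = [("s", IndelEvent(INSERTION, i + 1, "A")) for i in range(4)]
        mutants += [("s", IndelEvent(DELETION, i + 10, 1)) for i in range(6)]
        spectra, _ = summarize_spectrum(mutants)
        assert spectra["s"].pct_insertions == pytest.approx(40.0)
        assert spectra["s"].pct_deletions == pytest.approx(60.0)
        assert spectra["s"].n_total == 10

    def test_site_set_arithmetic(self):
        mutants = [
            ("A", IndelEvent(DELETION, 3, 1)),
            ("A", IndelEvent(DELETION, 7, 1)),
            ("B", IndelEvent(DELETION, 7, 1)),
            ("B", IndelEvent(DELETION, 9, 1)),
            ("B", IndelEvent(DELETION, 11, 1)),
        ]
        _, cmp = summarize_spectrum(mutants)
        assert cmp.unique_to_a == {3}
        assert cmp.unique_to_b == {9, 11}
        assert cmp.shared == {7}

    def test_percent_occurrence(self):
        mutants = [("s", IndelEvent(DELETION, 5, 1))] * 2
        mutants += [("s", IndelEvent(INSERTION, i + 1, "G")) for i in range(19)]
        spectra, _ = summarize_spectrum(mutants)
        spec = spectra["s"]
        entry = next(e for e in spec.entries if e.kind == "deletion")
        assert round(spec.percent(entry), 1) == 9.5

    def test_unknown_strain_in_comparison(self):
        mutants = [("A", IndelEvent(DELETION, 3, 1))]
        with pytest.raises(OscKitError, match="unknown strain"):
            summarize_spectrum(mutants, compare=("A", "Z"))

    def test_left_alignment_merges_ambiguous_sites(self, toy_pair):
        plus, _, _ = toy_pair
        # deletions at equivalent positions of the same A-run
        mutants = [
            ("s", IndelEvent(DELETION, 13, 1)),
            ("s", IndelEvent(DELETION, 14, 1)),
        ]
        spectra, _ = summarize_spectrum(mutants, {"s": plus.cds})
        assert len(spectra["s"].entries) == 1
        assert spectra["s"].entries[0].count == 2


class TestEventsTsv:
    def test_round_trip(self, tmp_path):
        mutants = [
            ("plus", IndelEvent(INSERTION, 16, "GA", "+2GA")),
            ("minus", IndelEvent(DELETION, 8, 1, "-1A")),
        ]
        p = tmp_path / "events.tsv"
        write_events_tsv(mutants, p)
        assert read_events_tsv(p) == mutants

    def test_missing_columns(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("strain_id\tkind\nx\ty\n")
        with pytest.raises(OscKitError, match="missing event columns"):
            read_events_tsv(p)
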