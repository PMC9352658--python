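"""Junction caller: anchor matching, reconstruction, exclusion filters."""

import numpy as np
import pytest

from tmejkit.calling import (
    CallStatus,
    JunctionCall,
    call_junction,
    call_read,
    demultiplex,
    filter_ambiguous,
    filter_substitution_artifact,
    tabulate_junctions,
    trim_read,
)
from tmejkit.locus import LocusReference, ReadLayout, ReadRecord
from tmejkit.simulate import simulate_reads, simulate_substitution_artifact_reads

from conftest import random_event_case
from oracles import brute_force_call


@pytest.fixture(scope="module")
def toy_ref():
    # 12 nt arm + TAG + AAAA + TAG + 12 nt arm; blunt cut between the AA pairs
    return LocusReference("toy", "ACGTACGTACGT" + "TAG" + "AAAA" + "TAG" + "CATGCATGCATG", 17)


class TestCallJunction:
    def test_microhomology_deletion(self, toy_ref):
        """A deletion spanning the cut whose boundaries share the TAG repeat."""
        read = ReadRecord("r", "ACGTACGTACGT" + "TAG" + "CATGCATGCATG")
        call = call_junction(read, toy_ref)
        assert call.status is CallStatus.PASS
        assert call.deletion_length == 7
        assert (call.del_left, call.del_right) == (5, 2)
        assert call.insertion == ""
        assert (call.microhomology_length, call.microhomology_seq) == (3, "TAG")

    def test_plus_one_insertion(self, toy_ref):
        """The +1 nt insertion NHEJ signature: no deletion, no microhomology."""
        s = toy_ref.sequence
        read = ReadRecord("r", s[:17] + "G" + s[17:])
        call = call_junction(read, toy_ref)
        assert call.status is CallStatus.PASS
        assert call.deletion_length == 0
        assert call.insertion == "G"
        assert call.microhomology_length == 0

    def test_intact_read(self, toy_ref):
        call = call_junction(ReadRecord("r", toy_ref.sequence), toy_ref)
        assert call.status is CallStatus.INTACT
        assert call.deletion_length == 0 and call.insertion == ""

    def test_unrelated_read_unalignable(self, toy_ref):
        call = call_junction(ReadRecord("r", "TTTTGGGGTTTTGGGGTTTTGGGG"), toy_ref)
        assert call.status is CallStatus.UNALIGNABLE

    def test_seven_nt_deletion_minimality(self, toy_ref):
        """Anchors must flank the deleted segment at the minimal total deletion."""
        s = toy_ref.sequence
        read = ReadRecord("r", s[:14] + s[21:])  # delete 3 left + 4 right of the cut
        call = call_junction(read, toy_ref)
        oracle = brute_force_call(read.sequence, s, toy_ref.cut_site)
        assert call.deletion_length == 7
        assert oracle is not None and oracle[1] + oracle[2] == 7
        assert (call.del_left, call.del_right, call.insertion, call.microhomology_length) == oracle[1:]


class TestAgainstBruteForce:
    def test_matches_enumeration_on_random_cases(self, rng):
        """Implementation equals the naive minimal-deletion enumeration."""
        for _ in range(120):
            read_seq, ref_seq, c, _kind = random_event_case(rng)
            ref = LocusReference("t", ref_seq, c)
            got = call_junction(ReadRecord("r", read_seq), ref)
            expected = brute_force_call(read_seq, ref_seq, c)
            if expected is None:
                assert got.status is CallStatus.UNALIGNABLE
            else:
                assert (
                    got.status.value,
                    got.del_left,
                    got.del_right,
                    got.insertion,
                    got.microhomology_length,
                ) == expected

    def test_idempotent_on_reconstructed_reads(self, rng):
        """Re-calling a read rebuilt from its own call reproduces the call."""
        for _ in range(60):
            read_seq, ref_seq, c, _ = random_event_case(rng)
            ref = LocusReference("t", ref_seq, c)
            call = call_junction(ReadRecord("r", read_seq), ref)
            if call.status not in (CallStatus.PASS, CallStatus.INTACT):
                continue
            rebuilt = ref_seq[: c - call.del_left] + call.insertion + ref_seq[c + call.del_right :]
            again = call_junction(ReadRecord("r2", rebuilt), ref)
            assert (
                again.status,
                again.del_left,
                again.del_right,
                again.insertion,
                again.microhomology_length,
            ) == (
                call.status,
                call.del_left,
                call.del_right,
                call.insertion,
                call.microhomology_length,
            )

    def test_microhomology_bounds(self, rng):
        """MH never exceeds the deletion length or the anchor length; MH = 0
        whenever nothing is deleted or an insertion is present."""
        for _ in range(120):
            read_seq, ref_seq, c, _ = random_event_case(rng)
            call = call_junction(ReadRecord("r", read_seq), LocusReference("t", ref_seq, c))
            if call.status is CallStatus.UNALIGNABLE:
                continue
            assert call.microhomology_length <= min(call.deletion_length, 10)
            if call.deletion_length == 0 or call.insertion:
                assert call.microhomology_length == 0


class TestFilters:
    @pytest.mark.parametrize("code", list("NWSRK"))
    def test_ambiguity_codes_excluded(self, toy_ref, code):
        s = toy_ref.sequence
        read = ReadRecord("r", s[:17] + code + s[17:])  # ambiguity inside the junction
        call = call_read(read, toy_ref)
        assert call.status is CallStatus.AMBIGUOUS_BASE

    def test_clean_junction_not_flagged_ambiguous(self, toy_ref):
        read = ReadRecord("r", "ACGTACGTACGT" + "TAG" + "CATGCATGCATG")
        call = call_read(read, toy_ref)
        assert call.status is CallStatus.PASS

    @pytest.mark.parametrize("side,dist", [("left", 5), ("right", 3), ("left", 10)])
    def test_single_substitution_near_cut_is_artifact(self, locus, side, dist):
        s, c = locus.sequence, locus.cut_site
        p = c - dist if side == "left" else c + dist - 1
        mutated = s[:p] + ("C" if s[p] != "C" else "G") + s[p + 1 :]
        call = call_read(ReadRecord("r", mutated[locus.read_start :]), locus)
        assert call.status is CallStatus.SUBSTITUTION_ARTIFACT

    def test_adjacent_double_substitution_kept(self, locus):
        """Two adjacent mismatches fail the matching-neighbor condition."""
        s, c = locus.sequence, locus.cut_site
        p = c - 6  # mismatches at distances 5 and 6
        sub = "".join("C" if b != "C" else "G" for b in s[p : p + 2])
        mutated = s[:p] + sub + s[p + 2 :]
        call = call_read(ReadRecord("r", mutated[locus.read_start :]), locus)
        assert call.status is CallStatus.PASS

    def test_substitution_outside_window_kept(self, locus):
        s, c = locus.sequence, locus.cut_site
        p = c - 2  # distance 2: inside the junction but outside the 3-10 window
        mutated = s[:p] + ("C" if s[p] != "C" else "G") + s[p + 1 :]
        call = call_read(ReadRecord("r", mutated[locus.read_start :]), locus)
        assert call.status is CallStatus.PASS
        assert call.deletion_length > 0  # misattributed indel is retained

    def test_intact_read_untouched_by_filters(self, toy_ref):
        read = ReadRecord("r", toy_ref.sequence)
        call = call_junction(read, toy_ref)
        assert filter_ambiguous(call, read, toy_ref).status is CallStatus.INTACT
        assert filter_substitution_artifact(call, read, toy_ref).status is CallStatus.INTACT

    def test_filter_order_independence(self, locus, layout):
        """Final status is the same whichever filter runs first."""
        reads, _ = simulate_substitution_artifact_reads(locus, 40, seed=9)
        for raw in reads:
            trimmed = trim_read(raw, layout)
            call = call_junction(trimmed, locus)
            ab_first = filter_substitution_artifact(
                filter_ambiguous(call, trimmed, locus), trimmed, locus
            )
            art_first = filter_ambiguous(
                filter_substitution_artifact(call, trimmed, locus), trimmed, locus
            )
            assert ab_first.status == art_first.status


class TestTrimming:
    def test_layout_example(self):
        primer = "GATTACAGATTACAGATTAC"
        layout = ReadLayout(primer=primer)
        insert = "ACGTTGCAACGTTGCAACGT"
        raw = ReadRecord("r", "ACGTAC" + "GG" + primer + insert)
        trimmed = trim_read(raw, layout)
        assert trimmed is not None
        assert trimmed.sequence == insert
        assert trimmed.barcode == "ACGTAC"

    def test_missing_primer_unalignable(self):
        layout = ReadLayout(primer="GATTACAGATTACAGATTAC")
        assert trim_read(ReadRecord("r", "A" * 60), layout) is None

    def test_simulated_reads_trim_exactly(self, locus, layout, clean_config):
        """Trimming recovers the planted insert for every error-free read."""
        reads, truth = simulate_reads(clean_config, locus, condition="wt")
        truth = truth.set_index("read_id")
        R, c, o = locus.sequence, locus.cut_site, locus.read_start
        n_checked = 0
        for raw in reads:
            row = truth.loc[raw.read_id]
            variant = R[: c - row.del_left] + row.insertion + R[c + row.del_right :]
            trimmed = trim_read(raw, layout)
            assert trimmed is not None
            assert trimmed.sequence == variant[o : o + clean_config.read_length]
            assert trimmed.barcode == "ACGTCA"
            n_checked += 1
        assert n_checked == clean_config.n_reads

    def test_demultiplex_exact_barcode(self):
        reads = [
            ReadRecord("a", "ACGT", barcode="AAAAAA"),
            ReadRecord("b", "ACGT", barcode="CCCCCC"),
            ReadRecord("c", "ACGT", barcode="AAAAAT"),  # one mismatch: discarded
        ]
        out = demultiplex(reads, {"AAAAAA": "s1", "CCCCCC": "s2"})
        assert [(r.read_id, r.sample_id) for r in out] == [("a", "s1"), ("b", "s2")]


class TestTabulate:
    def test_counts_and_denominator(self):
        mk = lambda i, **kw: JunctionCall(f"r{i}", **kw)
        calls = [
            mk(1, status=CallStatus.PASS, del_left=5, del_right=2),
            mk(2, status=CallStatus.PASS, del_left=5, del_right=2),
            mk(3, status=CallStatus.PASS, del_left=5, del_right=2),
            mk(4, status=CallStatus.INTACT),
            mk(5, status=CallStatus.INTACT),
            mk(6, status=CallStatus.AMBIGUOUS_BASE, del_left=1, del_right=0),
            mk(7, status=CallStatus.UNALIGNABLE),
        ]
        table = tabulate_junctions(calls, "s")
        assert table.repair_total == 3
        assert table.intact_count == 2
        assert dict(zip(table.df.junction_key, table.df["count"])) == {"5|2|": 3}
        assert table.attrition["AMBIGUOUS_BASE"] == 1
        assert table.attrition["UNALIGNABLE"] == 1

    def test_empty_input(self):
        table = tabulate_junctions([], "s")
        assert table.repair_total == 0 and table.df.empty
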