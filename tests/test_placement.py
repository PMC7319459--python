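import random

import pytest

from becorrect.placement import SnvRecord, enumerate_placements, simulate_edit
from becorrect.fixtures import random_snv_record
from becorrect.seqcore import SequenceError, reverse_complement
from naive_oracle import naive_placements, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def placement_keys(placements):
    return sorted(
        (p.editor.name, p.strand, p.protospacer_start, p.snv_window, p.snv_distance_from_pam)
        for p in placements
    )


class TestSnvRecord:
    def test_variant_base_must_match_sequence(self):
        with pytest.raises(SequenceError):
            SnvRecord(id="x", sequence="AAAA", snv_pos=2, ref_base="G", var_base="C")

    def test_ref_must_differ_from_var(self):
        with pytest.raises(SequenceError):
            SnvRecord(id="x", sequence="AAAA", snv_pos=2, ref_base="A", var_base="A")

    def test_position_bounds(self):
        with pytest.raises(SequenceError):
            SnvRecord(id="x", sequence="AAAA", snv_pos=5, ref_base="G", var_base="A")

    def test_reference_sequence_swaps_the_variant(self):
        r = SnvRecord(id="x", sequence="AACA", snv_pos=3, ref_base="G", var_base="C")
        assert r.reference_sequence == "AAGA"


class TestEnumeratePlacements:
    def make_single_pam_record(self, snv_idx):
        """A/T background with one NGG ('AGG') at index 40: the only BE3 PAM
        site on either strand, so placements depend only on the SNV distance
        d = 40 - snv_idx."""
        seq = list("ATTA" * 15)
        seq[40:43] = "AGG"
        seq[snv_idx] = "A" if seq[snv_idx] != "A" else "T"
        var = seq[snv_idx]
        return SnvRecord(
            id="t", sequence="".join(seq), snv_pos=snv_idx + 1,
            ref_base="C", var_base=var,
        )

    @pytest.mark.parametrize(
        "snv_idx,expected_window",
        [
            (25, "major"),  # d=15, inside 13-17
            (23, "major"),  # d=17 boundary
            (27, "major"),  # d=13 boundary
            (28, "minor"),  # d=12, inside 10-12
            (30, "minor"),  # d=10 boundary
            (22, "minor"),  # d=18, inside 18-19
            (20, None),     # d=20, outside every window
            (31, None),     # d=9
            (35, None),     # d=5
        ],
    )
    def test_single_pam_window_membership(self, be3_only, snv_idx, expected_window):
        snv = self.make_single_pam_record(snv_idx)
        placements = enumerate_placements(snv, be3_only)
        if expected_window is None:
            assert placements == []
        else:
            assert len(placements) == 1
            p = placements[0]
            assert p.strand == "+"
            assert p.snv_window == expected_window
            assert p.snv_distance_from_pam == 40 - snv_idx
            assert p.protospacer_start == 21
            assert p.pam_site == "AGG"

    def test_placement_is_positional_even_without_editable_base(self, be3_only):
        # 20xA protospacer + AGG, SNV at distance 15: BE3 edits C, the window
        # holds no C — the placement is still returned; the edit is a no-op.
        seq = "A" * 20 + "AGG" + "A" * 7
        snv = SnvRecord(id="t", sequence=seq, snv_pos=6, ref_base="G", var_base="A")
        placements = enumerate_placements(snv, be3_only)
        majors = [p for p in placements if p.strand == "+" and p.snv_window == "major"]
        assert any(p.snv_distance_from_pam == 15 for p in majors)
        p = next(p for p in majors if p.snv_distance_from_pam == 15)
        outcome = simulate_edit(p, snv)
        assert outcome.edited_sequence == seq
        assert outcome.changed_positions == ()

    def test_all_t_sequence_has_no_placements(self, registry):
        snv = SnvRecord(id="t", sequence="T" * 60, snv_pos=30, ref_base="C", var_base="T")
        assert enumerate_placements(snv, registry) == []

    def test_matches_naive_oracle_on_random_fixtures(self, registry):
        rng = random.Random(20260925)
        for _ in range(60):
            snv = random_snv_record(rng, length=60)
            got = placement_keys(enumerate_placements(snv, registry))
            assert got == sorted(naive_placements(snv, registry))

    def test_truncated_flanks_skip_rather_than_pad(self, be3_only):
        # PAM would extend past the right end: no placement.
        seq = "A" * 18 + "CAG"  # 21 nt; a BE3 protospacer fits, its PAM cannot
        snv = SnvRecord(id="t", sequence=seq, snv_pos=19, ref_base="T", var_base="C")
        assert enumerate_placements(snv, be3_only) == []


class TestSimulateEdit:
    def run_single(self, registry_one, seq, pos, ref, var, strand="+", window="major"):
        snv = SnvRecord(id="t", sequence=seq, snv_pos=pos, ref_base=ref, var_base=var)
        placements = [
            p for p in enumerate_placements(snv, registry_one)
            if p.strand == strand and p.snv_window == window
        ]
        assert placements, "expected at least one placement"
        return snv, [simulate_edit(p, snv) for p in placements]

    def test_all_window_cytosines_convert(self, be3_only):
        seq = "AAACCCCCAAAAAAAAAAAA" + "AGG"
        snv, outcomes = self.run_single(be3_only, seq, 4, "T", "C")
        by_changed = {o.changed_positions: o for o in outcomes}
        # the distance-17 placement puts protospacer positions 4-8 in the window
        assert (4, 5, 6, 7, 8) in by_changed
        o = by_changed[(4, 5, 6, 7, 8)]
        assert o.edited_sequence == "AAATTTTTAAAAAAAAAAAA" + "AGG"

    def test_ea3a_requires_tc_context(self, registry):
        ea3a = registry.subset(["eA3A-BE3"])
        # preceded by A: nothing converts
        seq = "AAACCCCCAAAAAAAAAAAA" + "AGG"
        snv, outcomes = self.run_single(ea3a, seq, 4, "T", "C")
        assert all(o.changed_positions == () for o in outcomes)
        # preceded by T at position 4 only: exactly that C converts
        seq2 = "AATCCCCCAAAAAAAAAAAA" + "AGG"
        snv2, outcomes2 = self.run_single(ea3a, seq2, 4, "T", "C")
        changed = {o.changed_positions for o in outcomes2}
        assert changed == {(4,)}
        edited = {o.edited_sequence for o in outcomes2}
        assert edited == {"AATTCCCCAAAAAAAAAAAA" + "AGG"}

    def test_ea3a_agrees_with_base_by_base_scan(self, registry):
        from naive_oracle import naive_ea3a_edit

        ea3a = registry.subset(["eA3A-BE3"])
        rng = random.Random(11)
        for _ in range(25):
            snv = random_snv_record(rng, length=60)
            for p in enumerate_placements(snv, ea3a):
                o = simulate_edit(p, snv)
                work = snv.sequence if p.strand == "+" else revcomp(snv.sequence)
                n = len(work)
                if p.strand == "+":
                    proto_end = p.protospacer_end  # 0-based exclusive == 1-based end
                else:
                    proto_end = n - p.protospacer_start + 1
                lo, hi = p.editor.major_window
                window = range(proto_end - hi, proto_end - lo + 1)
                expect = naive_ea3a_edit(work, window)
                got = o.edited_sequence if p.strand == "+" else revcomp(o.edited_sequence)
                assert got == expect

    def test_minus_strand_abe_maps_t_to_c(self, abe710_only):
        # ABE on the minus strand over a plus-strand T in the window: the
        # edited plus strand shows C at that position.
        seq = list("GAT" * 20)
        seq[30:33] = "TGG"
        seq[29] = "C"
        seq[13:16] = "CCA"  # minus-strand NGG; SNV lands at distance 15
        seq = "".join(seq)
        snv = SnvRecord(id="t", sequence=seq, snv_pos=31, ref_base="A", var_base="T")
        placements = [
            p for p in enumerate_placements(snv, abe710_only)
            if p.strand == "-" and p.snv_window == "major"
        ]
        assert placements
        outcome = simulate_edit(placements[0], snv)
        assert outcome.edited_sequence[30] == "C"
        assert 31 in outcome.changed_positions

    def test_conversion_purity(self, registry):
        # each outcome applies one chemistry on one strand
        rng = random.Random(99)
        pure = {("C", "T"), ("G", "A"), ("A", "G"), ("T", "C")}
        for _ in range(40):
            snv = random_snv_record(rng, length=60)
            for p in enumerate_placements(snv, registry):
                o = simulate_edit(p, snv)
                changes = {
                    (snv.sequence[pos - 1], o.edited_sequence[pos - 1])
                    for pos in o.changed_positions
                }
                assert len(changes) <= 1
                assert changes <= pure

    @staticmethod
    def distance_of(p, pos):
        """Distance-from-PAM of a 1-based input position under a placement."""
        three_prime = p.editor.pam_side == "three_prime"
        pam_adjacent_at_end = three_prime == (p.strand == "+")
        if pam_adjacent_at_end:
            return p.protospacer_end - pos + 1
        return pos - p.protospacer_start + 1

    def test_changes_only_inside_major_window(self, registry):
        rng = random.Random(5)
        for _ in range(40):
            snv = random_snv_record(rng, length=60)
            for p in enumerate_placements(snv, registry):
                o = simulate_edit(p, snv)
                for pos in o.changed_positions:
                    assert p.protospacer_start <= pos <= p.protospacer_end
                    assert p.editor.in_major(self.distance_of(p, pos))


def mirror_record(snv):
    n = len(snv.sequence)
    return SnvRecord(
        id=snv.id,
        sequence=reverse_complement(snv.sequence),
        snv_pos=n - snv.snv_pos + 1,
        ref_base=_COMP[snv.ref_base],
        var_base=_COMP[snv.var_base],
        frame_offset=0,
    )


def outcome_signature(snv, outcome, mirrored):
    n = len(snv.sequence)
    p = outcome.placement
    if not mirrored:
        return (
            p.editor.name, p.strand, p.protospacer_start, p.snv_window,
            outcome.edited_sequence, outcome.changed_positions,
        )
    strand = "-" if p.strand == "+" else "+"
    start = n - p.protospacer_end + 1
    return (
        p.editor.name, strand, start, p.snv_window,
        reverse_complement(outcome.edited_sequence),
        tuple(sorted(n - pos + 1 for pos in outcome.changed_positions)),
    )


def test_strand_symmetry(registry):
    """The full pipeline on the reverse complement with mirrored coordinates
    yields the same outcomes with strands swapped and sequences flipped."""
    rng = random.Random(42)
    for _ in range(30):
        snv = random_snv_record(rng, length=60)
        mirrored = mirror_record(snv)
        orig = sorted(
            outcome_signature(snv, simulate_edit(p, snv), mirrored=False)
            for p in enumerate_placements(snv, registry)
        )
        flipped = sorted(
            outcome_signature(mirrored, simulate_edit(p, mirrored), mirrored=True)
            for p in enumerate_placements(mirrored, registry)
        )
        assert orig == flipped
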