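"""TBM scanning, correspondence classification and the presence matrix."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tbmevo import simulate as sim
from tbmevo.seq_io import AA20, AlignedSequence, Alignment, SequenceRecord
from tbmevo.tbm import (
    CANONICAL,
    DEFAULT_PATTERNS,
    RX4,
    RX5,
    CuratedBinderTable,
    PresenceCall,
    ReferenceTBM,
    best_verdict,
    classify,
    presence_matrix,
    scan,
    scan_all,
)

from conftest import make_record, regex_scan_oracle


@pytest.fixture(scope="module")
def binder_table():
    return CuratedBinderTable.load_packaged()


class TestCuratedTable:
    def test_entry_and_partner_counts(self, binder_table):
        assert len(binder_table.entries) == 26
        assert len(binder_table.partners) == 22

    def test_single_truncated_seven_mer(self, binder_table):
        trunc = [e for e in binder_table.entries if e.truncated]
        assert len(trunc) == 1
        assert trunc[0].partner == "USP25"
        assert len(trunc[0].expected_seq) == 7

    def test_all_motifs_start_with_arginine(self, binder_table):
        assert all(e.expected_seq.startswith("R") for e in binder_table.entries)

    def test_multi_motif_partners(self, binder_table):
        multi = {
            p for p in binder_table.partners
            if len(binder_table.for_partner(p)) == 2
        }
        assert multi == {"MERIT40", "PEX14", "SH3BP5", "SOX9"}


class TestScan:
    def test_canonical_example(self):
        hits = scan(make_record("RGCADGRD"))
        assert len(hits) == 1
        assert hits[0].start == 1
        assert hits[0].configuration == "canonical"

    def test_relaxed_rx4_example(self):
        # position 4 is V, outside [ACGP], so only the relaxed grammar fits
        hits = scan(make_record("RPPVPGEE"))
        assert [h.configuration for h in hits] == ["rx4"]

    def test_no_arginine_no_hits(self):
        assert scan(make_record("AAAAAAAA")) == []

    def test_concatenated_motifs_give_two_hits(self):
        hits = scan(make_record("RGCADGRD" + "RPPVPGEE"))
        assert [(h.start, h.configuration) for h in hits] == [
            (1, "canonical"),
            (9, "rx4"),
        ]

    def test_same_start_can_anchor_both_lengths(self):
        # R at 1 with G at 6 and at 7: an 8-mer rx4 hit and a 9-mer rx5 hit
        hits = scan(make_record("RVVVVGGVV"))
        assert [(h.length, h.configuration) for h in hits] == [
            (8, "rx4"),
            (9, "rx5"),
        ]

    def test_x_fails_constrained_positions_but_matches_wildcards(self):
        assert scan(make_record("XAAAAGAA")) == []  # X cannot play the R
        assert scan(make_record("RAAAAXAA")) == []  # X cannot play the G
        hits = scan(make_record("RXXXXGXX"))  # wildcards may be X; pos 4 is X
        assert [h.configuration for h in hits] == ["rx4"]

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = random.Random(77)
        alphabet = AA20 + "X"
        for _ in range(200):
            seq = "".join(
                rng.choice(alphabet) for _ in range(rng.randint(9, 120))
            )
            got = [(h.start, h.length, h.configuration) for h in scan(make_record(seq))]
            assert got == regex_scan_oracle(seq), seq

    @given(st.text(alphabet="RAGPC", min_size=8, max_size=40))
    @settings(max_examples=60, derandomize=True)
    def test_canonical_hits_are_a_subset_of_rx4_windows(self, seq):
        rec = SequenceRecord(id="s", residues=seq)
        canonical_starts = {
            h.start for h in scan(rec) if h.configuration == "canonical"
        }
        rx4_starts = {
            h.start for h in scan(rec, patterns=(RX4,))
        }
        assert canonical_starts <= rx4_starts

    def test_scan_all_equals_scan(self):
        rec = make_record("RGCADGRDAAARPPVPGEE")
        assert scan_all(rec) == scan(rec)


def _aln(*rows):
    return Alignment(
        rows=tuple(
            AlignedSequence(id=i, residues=r, species=i) for i, r in rows
        )
    )


class TestClassify:
    # human-like reference: motif RGCADGRD at residues 4-11
    REF = "MKL" + "RGCADGRD" + "AADE"

    def _ref_tbm(self):
        return ReferenceTBM(partner="p", arg_residue=4, expected_seq="RGCADGRD")

    def test_identical_ortholog_is_canonical_aligned(self):
        aln = _aln(("human", self.REF), ("orth", self.REF))
        call = classify("orth", aln, "human", self._ref_tbm())
        assert call.verdict == "canonical_aligned"

    def test_relaxed_motif_at_site_is_relaxed_aligned(self):
        orth = "MKL" + "RGCVDGRD" + "AADE"  # position 4 V: rx4 only
        aln = _aln(("human", self.REF), ("orth", orth))
        call = classify("orth", aln, "human", self._ref_tbm())
        assert call.verdict == "relaxed_aligned"

    def test_deleted_motif_is_absent(self):
        orth = "MKL" + "AGCADARD" + "AADE"  # R and motif G removed
        aln = _aln(("human", self.REF), ("orth", orth))
        call = classify("orth", aln, "human", self._ref_tbm())
        assert call.verdict == "absent"

    def test_offset_motif_depends_on_nearby_window(self):
        # ortholog motif shifted 5 columns downstream of the human site
        orth = "MKLAAAAA" + "RGCADGRD" + "AAAA"
        aln = _aln(("human", self.REF + "AAAAA"), ("orth", orth))
        tbm_ref = self._ref_tbm()
        assert classify("orth", aln, "human", tbm_ref, nearby_window=0).verdict == "absent"
        assert (
            classify("orth", aln, "human", tbm_ref, nearby_window=30).verdict
            == "nearby_unaligned"
        )

    def test_row_order_does_not_change_verdict(self):
        aln1 = _aln(("human", self.REF), ("orth", self.REF))
        aln2 = _aln(("orth", self.REF), ("human", self.REF))
        v1 = classify("orth", aln1, "human", self._ref_tbm()).verdict
        v2 = classify("orth", aln2, "human", self._ref_tbm()).verdict
        assert v1 == v2

    def test_enlarging_window_never_worsens_verdict(self):
        rng = random.Random(13)
        order = {"canonical_aligned": 0, "relaxed_aligned": 1,
                 "nearby_unaligned": 2, "absent": 3}
        for _ in range(20):
            n = 40
            human = "MKL" + "RGCADGRD" + "".join(
                rng.choice(AA20) for _ in range(n)
            )
            orth = "".join(rng.choice(AA20) for _ in range(len(human)))
            aln = _aln(("human", human), ("orth", orth))
            prev = None
            for w in (0, 5, 15, 40):
                v = classify("orth", aln, "human", self._ref_tbm(), nearby_window=w).verdict
                if prev is not None:
                    assert order[v] <= order[prev]
                prev = v

    def test_missing_row_errors(self):
        aln = _aln(("human", self.REF), ("orth", self.REF))
        with pytest.raises(KeyError):
            classify("nope", aln, "human", self._ref_tbm())

    def test_reference_residue_beyond_row_errors(self):
        aln = _aln(("human", "MKLR"), ("orth", "MKLR"))
        bad = ReferenceTBM(partner="p", arg_residue=99, expected_seq="RGCADGRD")
        with pytest.raises(ValueError, match="beyond"):
            classify("orth", aln, "human", bad)


class TestBestVerdict:
    def test_ordering(self):
        assert best_verdict(["absent", "relaxed_aligned"]) == "relaxed_aligned"
        assert best_verdict(["nearby_unaligned", "canonical_aligned"]) == "canonical_aligned"


class TestPresenceMatrix:
    def test_single_partner_single_species(self):
        table = CuratedBinderTable(
            entries=(ReferenceTBM(partner="p", arg_residue=4, expected_seq="RGCADGRD"),)
        )
        ref = "MKL" + "RGCADGRD" + "AADE"
        aln = _aln(("human", ref), ("mouse", ref))
        m = presence_matrix(table, {"p": aln}, ["human"])
        assert m.shape == (1, 1)
        assert m.loc[("p", 4), "human"] == "canonical_aligned"

    def test_species_without_row_is_no_ortholog(self):
        table = CuratedBinderTable(
            entries=(ReferenceTBM(partner="p", arg_residue=4, expected_seq="RGCADGRD"),)
        )
        ref = "MKL" + "RGCADGRD" + "AADE"
        aln = _aln(("human", ref), ("mouse", ref))
        m = presence_matrix(table, {"p": aln}, ["human", "sponge"])
        assert m.loc[("p", 4), "sponge"] == "no_ortholog"

    def test_partner_without_alignment_warns_no_ortholog(self):
        table = CuratedBinderTable(
            entries=(ReferenceTBM(partner="p", arg_residue=4, expected_seq="RGCADGRD"),)
        )
        with pytest.warns(UserWarning, match="no ortholog alignment"):
            m = presence_matrix(table, {}, ["human"])
        assert m.loc[("p", 4), "human"] == "no_ortholog"

    def test_two_motif_partner_gets_two_subrows(self):
        table = CuratedBinderTable(
            entries=(
                ReferenceTBM(partner="m", arg_residue=1, expected_seq="RSNPEGAE"),
                ReferenceTBM(partner="m", arg_residue=21, expected_seq="RSEGEGEA"),
            )
        )
        ref = "RSNPEGAE" + "AAAAAAAAAAAA" + "RSEGEGEA"
        aln = _aln(("human", ref), ("mouse", ref))
        m = presence_matrix(table, {"m": aln}, ["human", "mouse"])
        assert list(m.index) == [("m", 1), ("m", 21)]
        assert (m == "canonical_aligned").all().all()

    def test_recovers_simulator_truth_pattern(self):
        cfg = sim.SimulationConfig(
            n_taxa=6,
            seed=404,
            motifs=(
                sim.PlantedMotif(
                    block=0, offset=20, configuration="canonical",
                    taxa=("sp1", "sp2", "sp3", "sp4"),
                ),
            ),
        )
        res = sim.simulate_family(cfg)
        truth = res.truth
        ref_pos = truth.loc[truth.taxon == "sp1", "residue_position"].item()
        ref_seq = res.records[0].residues[ref_pos - 1 : ref_pos + 7]
        table = CuratedBinderTable(
            entries=(
                ReferenceTBM(partner="fam", arg_residue=ref_pos, expected_seq=ref_seq),
            )
        )
        m = presence_matrix(
            table, {"fam": res.alignment}, list(res.alignment.ids),
            ref_species="sp1", nearby_window=0,
        )
        for taxon in res.alignment.ids:
            expected = (
                "canonical_aligned"
                if truth.loc[truth.taxon == taxon, "present"].item()
                else "absent"
            )
            assert m.loc[("fam", ref_pos), taxon] == expected
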