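"""Read translation, QC filtering, tallying and replicate merging."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from psermkit.errors import ConfigError, DataError
from psermkit.reads import (
    CloneTable,
    extract_mutation_string,
    merge_replicates,
    qc_filter,
    tally,
    tally_reads,
    translate_read,
)
from psermkit.simulate import ReadLayout

from ._reference import ref_pipeline


class TestTranslateRead:
    @pytest.mark.parametrize(
        "nt, offset, expected",
        [
            ("ATGGCT", 0, "MA"),
            ("TATGGCT", 1, "MA"),  # identical after the one-base shift
            ("ATGGCTA", 0, "MA"),  # trailing partial codon ignored
        ],
    )
    def test_in_frame_translation(self, nt, offset, expected):
        assert translate_read(nt, offset) == expected

    def test_premature_stop_rejects(self):
        assert translate_read("ATGTAAGCT", 0, expected_codons=3) is None

    def test_stop_beyond_expected_span_truncates(self):
        # stop after the 2-codon expected span ends translation, not the read
        assert translate_read("ATGGCTTAAGCT", 0, expected_codons=2) == "MA"

    def test_n_codon_rejects(self):
        assert translate_read("ATGNCT", 0) is None

    def test_unknown_symbol_raises(self):
        with pytest.raises(DataError):
            translate_read("ATGXCT", 0)

    def test_too_short_raises(self):
        with pytest.raises(DataError):
            translate_read("AT", 0)


class TestQcFilter:
    ANCHOR = "DIQMTQ"

    @pytest.mark.parametrize(
        "seq, keep",
        [
            ("DIQMTQSPAS", True),  # exact anchor, correct length
            ("DIQATQSPAS", True),  # one mismatch in the first six residues
            ("DAQATQSPAS", False),  # two mismatches
            ("DIQMTQSPA", False),  # one residue short
            ("DIQMTQSPASF", False),  # one residue long
        ],
    )
    def test_anchor_and_length_rule(self, seq, keep):
        assert qc_filter(seq, 10, self.ANCHOR) is keep

    def test_mismatch_only_counted_in_first_six(self):
        # residues beyond the anchor are not compared to any template
        assert qc_filter("DIQMTQXXXX".replace("X", "W"), 10, self.ANCHOR)


class TestExtractMutationString:
    def test_direct_indexing(self):
        seq = "QSVSASFYYATYIK"
        positions = [2, 4, 6, 8, 12]
        assert extract_mutation_string(seq, positions) == "VAFYI"

    def test_identity_case(self):
        assert extract_mutation_string("ACDEF", list(range(5))) == "ACDEF"

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            extract_mutation_string("ACDEF", [0, 7])

    def test_non_increasing_positions_rejected(self):
        with pytest.raises(ConfigError):
            extract_mutation_string("ACDEF", [2, 1])


class TestTally:
    def test_direct_count(self):
        assert tally(["AA", "AB", "AA"]) == Counter({"AA": 2, "AB": 1})

    def test_empty(self):
        assert tally([]) == Counter()

    def test_worked_example_observations(self):
        counts = tally(["SASFYYATYI"] * 8)
        assert counts == Counter({"SASFYYATYI": 8})

    def test_mixed_lengths_rejected(self):
        with pytest.raises(DataError):
            tally(["AA", "ABC"])


class TestMergeReplicates:
    ROUNDS = ["R1", "R2"]

    def test_common_in_one_round_kept_with_zero_elsewhere(self):
        tallies = {
            ("R1", 1): Counter({"WT": 9, "AB": 1}),
            ("R1", 2): Counter({"WT": 10}),
            ("R2", 1): Counter({"WT": 8, "AB": 2}),
            ("R2", 2): Counter({"WT": 9, "AB": 1}),
        }
        table = merge_replicates(tallies, self.ROUNDS, wt_string="WT")
        assert "AB" in table.clones  # common to both replicates in R2
        assert table.frequency("AB", "R1") == pytest.approx((1 / 10 + 0) / 2)

    def test_single_replicate_clone_dropped(self):
        tallies = {
            ("R1", 1): Counter({"WT": 9, "AB": 1}),
            ("R1", 2): Counter({"WT": 10}),
            ("R2", 1): Counter({"WT": 8, "AB": 2}),
            ("R2", 2): Counter({"WT": 10}),
        }
        table = merge_replicates(tallies, self.ROUNDS)
        assert "AB" not in table.clones

    def test_required_rounds_frequency_hand_case(self):
        tallies = {
            ("R1", 1): Counter({"WT": 99, "AB": 1}),
            ("R1", 2): Counter({"WT": 99, "AB": 1}),
            ("R5", 1): Counter({"WT": 90, "AB": 10}),
            ("R5", 2): Counter({"WT": 90, "AB": 10}),
        }
        table = merge_replicates(
            tallies, ["R1", "R5"], mode="common-required-rounds",
            required_rounds=["R5"],
        )
        assert table.frequency("AB", "R5") == pytest.approx(0.10)

    def test_required_rounds_subset_of_any_round(self, rng):
        from .conftest import random_tallies

        _, tallies = random_tallies(rng, 30, 3, ["R1", "R2", "R3"])
        permissive = merge_replicates(tallies, ["R1", "R2", "R3"])
        strict = merge_replicates(
            tallies, ["R1", "R2", "R3"], mode="common-required-rounds",
            required_rounds=["R1", "R2"], allow_absent_rounds=["R3"],
        )
        assert set(strict.clones) <= set(permissive.clones)

    def test_unknown_required_round_rejected(self):
        tallies = {
            ("R1", 1): Counter({"A": 1}),
            ("R1", 2): Counter({"A": 1}),
        }
        with pytest.raises(ConfigError):
            merge_replicates(
                tallies, ["R1"], mode="common-required-rounds",
                required_rounds=["R9"],
            )

    def test_missing_replicate_rejected(self):
        with pytest.raises(ConfigError):
            merge_replicates({("R1", 1): Counter({"A": 1})}, ["R1"])

    def test_frequencies_bounded(self, tiny_table):
        assert ((tiny_table.freqs >= 0) & (tiny_table.freqs <= 1)).all().all()


class TestCloneTableRoundTrip:
    def test_tsv_round_trip(self, tiny_table, tmp_path):
        path = tmp_path / "table.tsv"
        tiny_table.to_tsv(path)
        back = CloneTable.from_tsv(path)
        assert back.counts.equals(tiny_table.counts)
        assert np.allclose(back.freqs, tiny_table.freqs, rtol=1e-12, atol=0)
        assert back.totals == tiny_table.totals
        assert back.wt_string == tiny_table.wt_string
        assert back.rounds == tiny_table.rounds


class TestPipelineOracle:
    def test_tally_matches_brute_force_on_synthetic_reads(self, rng):
        """Full reads pipeline vs an independent hand-rule reference."""
        layout = ReadLayout()
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        reads = []
        for _ in range(100):
            s = "".join(rng.choice(aa, 10))
            nt = layout.nucleotides(s)
            roll = rng.random()
            if roll < 0.1:
                nt = nt[:-3]  # wrong length
            elif roll < 0.2:
                nt = "TGGTGG" + nt[6:]  # anchor ruined (2+ mismatches)
            elif roll < 0.3:
                nt = nt[:12] + "TAA" + nt[15:]  # premature stop
            elif roll < 0.4:
                nt = nt[:20] + "N" + nt[21:]  # ambiguous base
            reads.append(nt)
        counts, stats = tally_reads(
            reads, frame_offset=0, anchor=layout.anchor,
            expected_length=layout.expected_length, positions=layout.positions,
        )
        expected = ref_pipeline(
            reads, 0, layout.anchor, layout.expected_length, layout.positions
        )
        assert counts == expected
        assert stats.kept == sum(expected.values())
        assert stats.seen == 100

    @given(st.integers(0, 2**31 - 1))
    def test_conservation_kept_plus_rejected_is_seen(self, seed):
        rng = np.random.default_rng(seed)
        layout = ReadLayout()
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        reads = []
        for _ in range(20):
            nt = layout.nucleotides("".join(rng.choice(aa, 10)))
            if rng.random() < 0.3:
                nt = nt[: int(rng.integers(3, len(nt)))]
            reads.append(nt)
        counts, stats = tally_reads(
            reads, frame_offset=0, anchor=layout.anchor,
            expected_length=layout.expected_length, positions=layout.positions,
        )
        assert stats.kept + stats.rejected_translation + stats.rejected_qc == 20
        assert sum(counts.values()) == stats.kept
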