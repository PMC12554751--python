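"""Clone scoring, ranking, selection rules and CDR net charge."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from psermkit.alphabet import AA_INDEX, AMINO_ACIDS
from psermkit.errors import ConfigError, DataError
from psermkit.matrices import LogScoreMatrix
from psermkit.selection import (
    ChargeModel,
    cysteine_filter,
    enrichment_metrics,
    net_charge,
    overlap_selection,
    rank_top_k,
    score_clone,
    score_clones,
    select_clones,
)

from ._reference import ref_score
from .test_matrices import table_from_counts


def matrix_from_entries(entries: dict[tuple[str, int], float], length: int,
                        kind: str = "pserm") -> LogScoreMatrix:
    values = np.zeros((20, length))
    for (residue, j), v in entries.items():
        values[AA_INDEX[residue], j] = v
    return LogScoreMatrix(values, kind, 0.05, round_pair=("R7", "R6"))


class TestScoreClone:
    def test_zero_matrix_scores_zero(self):
        m = matrix_from_entries({}, 4)
        assert score_clone("ACDE", m) == 0.0

    def test_hand_summed_lookups(self):
        m = matrix_from_entries({("A", 0): 0.5, ("Y", 1): -0.25}, 2)
        assert score_clone("AY", m) == pytest.approx(0.25)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            score_clone("ACD", matrix_from_entries({}, 2))

    @given(st.integers(0, 2**31 - 1))
    def test_additivity_matches_loop_reference(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(1, 8))
        values = rng.normal(size=(20, length))
        m = LogScoreMatrix(values, "pserm", 0.05, round_pair=("R7", "R6"))
        ref_matrix = {a: values[AA_INDEX[a]].tolist() for a in AMINO_ACIDS}
        clones = list({"".join(rng.choice(list(AMINO_ACIDS), length))
                       for _ in range(10)})
        vec = score_clones(clones, m)
        for c in clones:
            expected = ref_score(c, ref_matrix)
            assert score_clone(c, m) == pytest.approx(expected, abs=1e-12)
            assert vec[c] == pytest.approx(expected, abs=1e-12)

    def test_column_shift_moves_all_scores_but_not_ranks(self, rng):
        values = rng.normal(size=(20, 3))
        m = LogScoreMatrix(values, "pserm", 0.05, round_pair=("R7", "R6"))
        shifted = LogScoreMatrix(values.copy(), "pserm", 0.05,
                                 round_pair=("R7", "R6"))
        shifted.values[:, 1] += 0.7
        clones = ["ACD", "WYV", "GGG", "KLM"]
        s0 = score_clones(clones, m)
        s1 = score_clones(clones, shifted)
        assert np.allclose(s1 - s0, 0.7)
        assert rank_top_k(s0, 4) == rank_top_k(s1, 4)


class TestRanking:
    def test_descending_top_k(self):
        s = pd.Series({"AA": 1.0, "AB": 3.0, "AC": 2.0})
        assert rank_top_k(s, 2) == ["AB", "AC"]

    def test_k_larger_than_candidates(self):
        s = pd.Series({"AA": 1.0, "AB": 3.0})
        assert rank_top_k(s, 40) == ["AB", "AA"]

    def test_lexicographic_tie_break(self):
        s = pd.Series({"AB": 1.0, "AA": 1.0, "AC": 2.0})
        assert rank_top_k(s, 3) == ["AC", "AA", "AB"]

    def test_nan_values_excluded(self):
        s = pd.Series({"AA": 1.0, "AB": np.nan})
        assert rank_top_k(s, 5) == ["AA"]

    def test_exclude_wt(self):
        s = pd.Series({"AA": 9.0, "AB": 1.0})
        assert rank_top_k(s, 5, exclude_wt=True, wt_string="AA") == ["AB"]

    def test_overlap_cases(self):
        assert overlap_selection({"a", "b"}, {"c"}) == set()
        assert overlap_selection({"a", "b"}, {"a", "b"}) == {"a", "b"}
        assert overlap_selection({"a", "b", "c"}, {"b", "c", "d"}) == {"b", "c"}


class TestCysteineFilter:
    def test_unpaired_cysteine_rule(self):
        kept, removed = cysteine_filter({"SASFYYATYI", "SACFYYATYI"})
        assert kept == {"SASFYYATYI"}
        assert removed == {"SACFYYATYI"}

    def test_empty(self):
        assert cysteine_filter(set()) == (set(), set())

    @given(st.sets(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=6),
                   max_size=30))
    def test_partition(self, clones):
        kept, removed = cysteine_filter(clones)
        assert kept | removed == clones
        assert kept & removed == set()


class TestEnrichmentMetrics:
    def make_table(self, f_by_round):
        """CloneTable with one clone 'AB' at given frequencies (plus filler)."""
        import pandas as pd

        from psermkit.reads import CloneTable

        rounds = list(f_by_round)
        counts = pd.DataFrame(
            {(r, k): [int(1000 * f_by_round[r]), 1000 - int(1000 * f_by_round[r])]
             for r in rounds for k in (1, 2)},
            index=pd.Index(["AB", "WW"], name="mutation_string"), dtype=np.int64,
        )
        counts.columns = pd.MultiIndex.from_tuples(counts.columns)
        freqs = pd.DataFrame(
            {r: [f_by_round[r], 1 - f_by_round[r]] for r in rounds},
            index=counts.index,
        )
        totals = {(r, k): 1000 for r in rounds for k in (1, 2)}
        return CloneTable(counts=counts, freqs=freqs, totals=totals,
                          rounds=rounds, replicates=[1, 2])

    def test_constant_frequency_gives_zero_ratios(self):
        table = self.make_table({"R2": 0.1, "R6": 0.1, "R7": 0.1})
        m = enrichment_metrics(table, "R7", "R2", "R6")
        assert m.loc["AB", "global_er"] == pytest.approx(0.0)
        assert m.loc["AB", "local_er"] == pytest.approx(0.0)

    def test_doubling_gives_one_bit(self):
        table = self.make_table({"R2": 0.1, "R6": 0.1, "R7": 0.2})
        m = enrichment_metrics(table, "R7", "R2", "R6")
        assert m.loc["AB", "local_er"] == pytest.approx(1.0)
        assert m.loc["AB", "global_er"] == pytest.approx(1.0)

    def test_zero_early_frequency_is_undefined_and_unranked(self):
        table = self.make_table({"R2": 0.0, "R6": 0.1, "R7": 0.2})
        m = enrichment_metrics(table, "R7", "R2", "R6")
        assert np.isnan(m.loc["AB", "global_er"])
        assert "AB" not in rank_top_k(m["global_er"], 10)

    def test_unknown_round_rejected(self):
        table = self.make_table({"R2": 0.1, "R6": 0.1, "R7": 0.1})
        with pytest.raises(ConfigError):
            enrichment_metrics(table, "R9", "R2", "R6")


class TestSelectClones:
    def test_equal_rounds_make_tiebreak_selection(self):
        """Identical compared rounds give all-zero PSERMs: pure tie-break."""
        from psermkit.matrices import pserms_for_rounds

        table = table_from_counts({"AW": 40, "DY": 40, "HV": 20})
        pserms = pserms_for_rounds(table, [("R5", "R5"), ("R5", "R5")])
        # dict collapses identical labels; build two distinct zero matrices
        z = list(pserms.values())[0]
        pair = {"pserm_A": z, "pserm_B": z}
        report = select_clones(table, pair, k=2, exclude_wt=False)
        assert report.top_k["pserm_A"] == ["AW", "DY"]  # lexicographic
        assert report.overlap == {"AW", "DY"}
        assert report.final == {"AW", "DY"}

    def test_cysteine_removed_from_final(self):
        m = matrix_from_entries({("C", 0): 5.0, ("W", 0): 4.0}, 2)
        table = table_from_counts({"CA": 10, "WA": 10, "GA": 10})
        report = select_clones(table, {"a": m, "b": m}, k=2, exclude_wt=False)
        assert report.overlap == {"CA", "WA"}
        assert report.removed_for_cysteine == {"CA"}
        assert report.final == {"WA"}

    def test_needs_exactly_two_pserms(self):
        m = matrix_from_entries({}, 2)
        table = table_from_counts({"AA": 5})
        with pytest.raises(ConfigError):
            select_clones(table, {"a": m}, k=2)


class TestNetCharge:
    def test_no_ionizable_side_chains(self):
        assert net_charge("GGGG") == pytest.approx(0.0)

    def test_single_arginine_nearly_plus_one(self):
        # 1 / (1 + 10^(7.4 - 12.48)) = 0.99999168...
        assert net_charge("R") == pytest.approx(0.9999917, abs=1e-6)

    def test_aspartate_arginine_nearly_cancel(self):
        assert net_charge("DR") == pytest.approx(0.0, abs=0.01)

    def test_termini_change_the_sum_when_enabled(self):
        free = net_charge("GG", ChargeModel(include_termini=True))
        internal = net_charge("GG")
        assert internal == pytest.approx(0.0)
        assert free != internal

    def test_monotone_decreasing_in_ph(self):
        seq = "DRHKYCE"
        charges = [net_charge(seq, ChargeModel(pH=ph))
                   for ph in np.linspace(1.0, 13.0, 25)]
        assert all(a > b for a, b in zip(charges, charges[1:]))

    def test_non_canonical_residue_rejected(self):
        with pytest.raises(DataError):
            net_charge("GXG")
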