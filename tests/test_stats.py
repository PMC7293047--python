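"""Standardized Pearson residuals, chi-square tests, count tables."""

import numpy as np
import pytest
from scipy import stats as sps

from ntcana import data as bundled
from ntcana.classify import AssignmentResult
from ntcana.stats import (
    ContingencyTable,
    TableError,
    build_ntc_sequence_table,
    expected_counts,
    row_chi_square,
    standardized_pearson_residuals,
)


def _result(ntc, seq):
    return AssignmentResult(
        step_id="x", ntc=ntc, cana="AAA", distance=0.0, nearest_class=ntc,
        votes=12, confal_components=(), confal=100.0, torsion_rmsd=0.0,
        sequence=seq,
    )


@pytest.fixture(scope="module")
def riboswitch():
    return bundled.riboswitch_counts()


@pytest.fixture(scope="module")
def ribosome():
    return bundled.ribosome_counts()


class TestExpectedCounts:
    def test_uniform_table(self):
        t = ContingencyTable(["a", "b"], ["x", "y"], [[10, 10], [10, 10]])
        assert np.allclose(expected_counts(t), 10.0)

    def test_riboswitch_aa00_inside_expectation(self, riboswitch):
        e = expected_counts(riboswitch)
        i = riboswitch.row_labels.index("AA00")
        j = riboswitch.col_labels.index("Inside")
        assert e[i, j] == pytest.approx(4675 * 1777 / 9045, abs=0.1)
        assert e[i, j] == pytest.approx(918.5, abs=0.1)

    def test_conservation(self, ribosome):
        e = expected_counts(ribosome)
        assert e.sum() == pytest.approx(ribosome.total, abs=1e-9)
        assert np.allclose(e.sum(axis=1), ribosome.counts.sum(axis=1))
        assert np.allclose(e.sum(axis=0), ribosome.counts.sum(axis=0))

    def test_zero_margin_rejected(self):
        with pytest.raises(TableError):
            ContingencyTable(["a", "b"], ["x", "y"], [[0, 0], [1, 2]])


class TestResiduals:
    def test_riboswitch_published_values(self, riboswitch):
        res = standardized_pearson_residuals(riboswitch)
        want = {
            "AA00": -8.1, "AA01": -4.8, "AA05": 3.7, "AA12": 4.4,
            "AB04": 5.5, "IC01": 4.6, "OP05": 8.1, "OP15": 9.4, "NANT": 6.6,
        }
        for ntc, value in want.items():
            assert round(res.residual(ntc, "Inside"), 1) == value

    def test_ribosome_published_values(self, ribosome):
        res = standardized_pearson_residuals(ribosome)
        want = {
            "AA00": 3.1, "AA04": 10.4, "AA08": -9.4, "AA06": -4.8,
            "AB05": 3.5, "OP03": -4.6, "OP04": 4.8, "NANT": -4.9,
        }
        for ntc, value in want.items():
            assert round(res.residual(ntc, "Xray"), 1) == value

    def test_uniform_table_residuals_vanish(self):
        t = ContingencyTable(["a", "b"], ["x", "y"], [[10, 10], [10, 10]])
        res = standardized_pearson_residuals(t)
        assert np.allclose(res.residuals, 0.0)
        assert np.all(res.flags == "ns")

    def test_two_column_residuals_antisymmetric(self, riboswitch):
        res = standardized_pearson_residuals(riboswitch)
        assert np.allclose(res.residuals[:, 0], -res.residuals[:, 1], atol=1e-9)

    def test_observed_minus_expected_sums_to_zero(self, ribosome):
        res = standardized_pearson_residuals(ribosome)
        assert abs((ribosome.counts - res.expected).sum()) < 1e-9

    def test_row_values_invariant_under_collapsing_other_rows(self, rng):
        counts = rng.integers(5, 200, size=(8, 4))
        t = ContingencyTable(
            [f"r{i}" for i in range(8)], list("wxyz"), counts
        )
        full = standardized_pearson_residuals(t)
        collapsed = t.collapse_rows(["r0", "r3"])
        part = standardized_pearson_residuals(collapsed)
        for row in ("r0", "r3"):
            for col in "wxyz":
                assert part.residual(row, col) == pytest.approx(
                    full.residual(row, col), abs=1e-9
                )

    def test_flags_thresholds(self, riboswitch):
        res = standardized_pearson_residuals(riboswitch)
        i = riboswitch.row_labels.index("OP15")
        j = riboswitch.col_labels.index("Inside")
        assert res.flags[i, j] == "over"
        i2 = riboswitch.row_labels.index("AA00")
        assert res.flags[i2, j] == "under"


class TestRowChiSquare:
    def test_null_row_not_significant(self):
        t = ContingencyTable(["a", "b"], ["x", "y"], [[10, 10], [30, 30]])
        chisq, df, sig = row_chi_square(t, "a")
        assert chisq == pytest.approx(0.0)
        assert df == 1
        assert not sig

    def test_fifteen_df_critical_value_exceeds_30(self):
        # 16 columns -> 15 degrees of freedom at alpha 0.01
        assert sps.chi2.ppf(0.99, 15) > 30.0
        assert sps.chi2.ppf(0.99, 15) == pytest.approx(30.58, abs=0.01)

    def test_matches_cell_sum_oracle(self, rng):
        for _ in range(1000):
            counts = rng.integers(1, 100, size=(3, 4))
            t = ContingencyTable(["a", "b", "c"], list("wxyz"), counts)
            e = (
                counts.sum(axis=1, keepdims=True)
                * counts.sum(axis=0, keepdims=True)
                / counts.sum()
            )
            chisq, df, _ = row_chi_square(t, "b")
            brute = sum((counts[1, j] - e[1, j]) ** 2 / e[1, j] for j in range(4))
            assert chisq == pytest.approx(brute, rel=1e-12)
            assert df == 3


class TestSequenceTable:
    def test_simple_counting(self):
        res = [_result("AA00", "GC"), _result("AA00", "GC"), _result("NANT", "AU")]
        t, discarded = build_ntc_sequence_table(res)
        assert discarded == 0
        assert t.to_frame().loc["AA00", "GC"] == 2
        assert t.to_frame().loc["NANT", "AU"] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(TableError):
            build_ntc_sequence_table([])

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(TableError):
            build_ntc_sequence_table([_result("AA00", "AU"), _result("AA00", "AT")])

    def test_undetermined_bases_discarded(self):
        res = [_result("AA00", "GC"), _result("AA00", "GN")]
        t, discarded = build_ntc_sequence_table(res)
        assert discarded == 1
        assert t.total == 1

    def test_column_margins_match_multinomial_draw(self, rng):
        seqs = ["AA", "AC", "GU", "GG"]
        draws = rng.multinomial(500, [0.4, 0.3, 0.2, 0.1])
        results = []
        for seq, n in zip(seqs, draws):
            results.extend(_result("AA00", seq) for _ in range(n))
        t, _ = build_ntc_sequence_table(results)
        frame = t.to_frame()
        for seq, n in zip(seqs, draws):
            if n:
                assert frame.loc["AA00", seq] == n
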