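"""Fold-change, Fisher and BH operations against published values,
hand computations and hypothesis-style properties."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from faecalomics import (
    CountTable,
    DeConfig,
    bh_adjust,
    cross_couple_common,
    fisher_count_test,
    load_published_sibling_counts,
    log2fc_pseudo,
    per_sample_de,
    round_half_up,
    sibling_compare,
)
from faecalomics.diffexpr import DiffRecord
from oracles import enumeration_fisher


class TestLog2fc:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (27.1, 79.7, -1.52),  # published couple #1 down-regulated miRNA
            (7.9, 0.0, 3.15),     # published couple #1 ASD-only miRNA
            (0.0, 429.1, -8.75),  # published couple #1 control-only piRNA
        ],
    )
    def test_published_pairs(self, a, b, expected):
        assert round_half_up(log2fc_pseudo(a, b), 2) == expected

    def test_identity(self):
        for x in (0.0, 1.0, 17.3):
            assert log2fc_pseudo(x, x) == 0.0

    @given(
        st.floats(0, 1e6, allow_nan=False),
        st.floats(0, 1e6, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, a, b):
        assert log2fc_pseudo(a, b) == pytest.approx(-log2fc_pseudo(b, a), abs=1e-12)

    @given(
        st.floats(0, 1e4), st.floats(0, 1e4), st.floats(0.01, 100)
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_case_count(self, a, b, delta):
        assert log2fc_pseudo(a + delta, b) > log2fc_pseudo(a, b)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log2fc_pseudo(-1.0, 2.0)


class TestFisher:
    def test_identical_margins_give_one(self):
        assert fisher_count_test(5, 100, 5, 100) == 1.0

    def test_disjoint_table(self):
        # [[0,10],[10,0]]: 2 of the C(20,10) equiprobable extreme tables
        p = fisher_count_test(0, 10, 10, 10)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_agrees_with_scipy_and_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            a, b, c, d = rng.integers(0, 20, size=4)
            if a + b == 0 or c + d == 0:
                continue
            p = fisher_count_test(a, a + b, c, c + d)
            assert p == pytest.approx(enumeration_fisher(a, b, c, d), abs=1e-10)
            assert p == pytest.approx(
                stats.fisher_exact([[a, b], [c, d]])[1], abs=1e-9
            )

    def test_half_up_rounding_of_fractional_counts(self):
        # 2.5 rounds half-up to 3, the 7.5 remainder to 8: cells round
        # independently before the table is built
        assert fisher_count_test(2.5, 10, 1, 10) == pytest.approx(
            enumeration_fisher(3, 8, 1, 9), abs=1e-12
        )

    def test_bad_libsize_rejected(self):
        with pytest.raises(ValueError):
            fisher_count_test(1, 0, 1, 10)


class TestBhAdjust:
    def test_all_equal_stay_equal(self):
        out = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_hand_computed_stepup(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_bounds(self, ps):
        out = bh_adjust(ps)
        assert ((out >= np.asarray(ps) - 1e-12) & (out <= 1.0 + 1e-12)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _norm_table(values: dict, libsize: float = 10_000.0) -> CountTable:
    df = pd.DataFrame(values)
    return CountTable(
        df, library_sizes=pd.Series(libsize, index=df.columns)
    )


class TestPerSampleDe:
    def test_absent_feature_is_null(self):
        t = _norm_table({"case": [0.0, 50.0], "c1": [0.0, 50.0], "c2": [0.0, 50.0]})
        records = per_sample_de(t, "case", ["c1", "c2"])
        absent = records[0]
        assert absent.log2fc == 0.0 and absent.p_value == 1.0
        assert not absent.significant and absent.presence == "absent"

    def test_identical_case_and_controls_nothing_significant(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(60, 50).astype(float)
        t = _norm_table({"case": col, "c1": col, "c2": col})
        records = per_sample_de(t, "case", ["c1", "c2"])
        assert not any(r.significant for r in records)

    def test_spiked_feature_flagged(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(100, 40).astype(float) + 1
        case = base.copy()
        case[0] *= 8  # true log2FC 3
        t = _norm_table(
            {"case": case, **{f"c{i}": base for i in range(1, 7)}}
        )
        records = per_sample_de(t, "case", [f"c{i}" for i in range(1, 7)])
        assert records[0].significant and records[0].log2fc > 1

    def test_case_in_controls_rejected(self):
        t = _norm_table({"case": [1.0], "c1": [1.0]})
        with pytest.raises(ValueError, match="also listed"):
            per_sample_de(t, "case", ["case", "c1"])

    def test_unknown_sample_rejected(self):
        t = _norm_table({"case": [1.0], "c1": [1.0]})
        with pytest.raises(ValueError, match="unknown sample"):
            per_sample_de(t, "case", ["nope"])


class TestSiblingCompare:
    def test_swap_negates_lfc_and_presence(self):
        rng = np.random.default_rng(3)
        vals = {
            "asd": rng.poisson(50, 30).astype(float),
            "ctrl": rng.poisson(50, 30).astype(float),
        }
        vals["asd"][0], vals["ctrl"][1] = 0.0, 0.0
        t = _norm_table(vals)
        fwd, _ = sibling_compare(t, "asd", "ctrl")
        rev, _ = sibling_compare(t, "ctrl", "asd")
        for f, r in zip(fwd, rev):
            assert f.log2fc == pytest.approx(-r.log2fc, abs=1e-12)
            assert {f.presence, r.presence} in (
                {"common"}, {"absent"}, {"only_a", "only_b"},
            ) or f.presence == r.presence

    def test_empty_table_empty_summary(self):
        t = _norm_table({"asd": [], "ctrl": []})
        records, summary = sibling_compare(t, "asd", "ctrl")
        assert records == []
        assert summary.to_numpy().sum() == 0 or summary.empty

    def test_same_sample_twice_rejected(self):
        t = _norm_table({"asd": [1.0]})
        with pytest.raises(ValueError, match="distinct"):
            sibling_compare(t, "asd", "asd")

    def test_summary_counts_partition_features(self):
        rng = np.random.default_rng(4)
        vals = {
            "asd": rng.poisson(40, 25).astype(float),
            "ctrl": rng.poisson(40, 25).astype(float),
        }
        vals["asd"][:3] = 0.0
        vals["ctrl"][3:5] = 0.0
        t = _norm_table(vals)
        _, summary = sibling_compare(t, "asd", "ctrl")
        row = summary.loc["all"]
        n_absent = sum(
            1 for a, b in zip(vals["asd"], vals["ctrl"]) if a == 0 and b == 0
        )
        assert (
            row["common_total"] + row["only_asd"] + row["only_ctrl"] + n_absent
            == 25
        )


class TestCrossCoupleCommon:
    @staticmethod
    def _rec(feature, lfc, sig=True):
        return DiffRecord(feature, 1.0, 1.0, lfc, 0.01, 0.02, sig, "common")

    def test_disjoint_significant_sets_empty(self):
        res = cross_couple_common(
            {
                "c1": [self._rec("f1", 2.0), self._rec("f2", 2.0, sig=False)],
                "c2": [self._rec("f2", 2.0), self._rec("f1", 2.0, sig=False)],
            }
        )
        assert res == {"up": [], "down": []}

    def test_sign_conflict_excluded(self):
        res = cross_couple_common(
            {
                "c1": [self._rec("f1", 2.0)],
                "c2": [self._rec("f1", -2.0)],
            }
        )
        assert res == {"up": [], "down": []}

    def test_consistent_features_partitioned_by_sign(self):
        res = cross_couple_common(
            {
                "c1": [self._rec("up1", 1.5), self._rec("dn1", -2.0)],
                "c2": [self._rec("up1", 3.0), self._rec("dn1", -1.2)],
            }
        )
        assert res == {"up": ["up1"], "down": ["dn1"]}

    def test_single_couple_rejected(self):
        with pytest.raises(ValueError, match="two sibling"):
            cross_couple_common({"c1": []})


class TestPublishedTable:
    """Consistency checks of the published sibling-couple reference values."""

    def test_every_row_significant_in_both_couples_with_consistent_sign(self):
        df = load_published_sibling_counts()
        results = {}
        for couple in ("1", "2"):
            recs = []
            for row in df.itertuples():
                a = getattr(row, f"asd_{couple}")
                b = getattr(row, f"ctrl_{couple}")
                p = getattr(row, f"fisher_p_{couple}")
                lfc = log2fc_pseudo(a, b)
                recs.append(
                    DiffRecord(row.feature, a, b, lfc, p, p, True, "common")
                )
            results[couple] = recs
        common = cross_couple_common(results)
        assert len(common["up"]) + len(common["down"]) == len(df)
        # the published sign pattern: 4 down + 4 up miRNAs, 13 down + 31 up piRNAs
        mirna = set(df[df.rna_class == "miRNA"].feature)
        assert sum(f in mirna for f in common["down"]) == 4
        assert sum(f in mirna for f in common["up"]) == 4
        assert len(common["down"]) == 4 + 13
        assert len(common["up"]) == 4 + 31

    def test_published_thresholds_hold(self):
        df = load_published_sibling_counts()
        for couple in ("1", "2"):
            lfc = [
                log2fc_pseudo(a, b)
                for a, b in zip(df[f"asd_{couple}"], df[f"ctrl_{couple}"])
            ]
            assert all(abs(x) >= 1.0 for x in lfc)
            assert (df[f"fisher_p_{couple}"] < 0.05).all()
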