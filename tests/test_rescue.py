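"""The rescue statistic and decision procedure: the combined p-value, basal
thresholds, the smaller-fold-change rule, category partitioning, and recovery
of ground-truth rescue labels from simulated counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trap_rescue as tr
from trap_rescue.errors import DataError
from trap_rescue.rescue import CATEGORIES


def de_frame(log2fc, wald_p, testable=None):
    n = len(log2fc)
    if testable is None:
        testable = [True] * n
    lfc = [np.nan if not t else v for v, t in zip(log2fc, testable)]
    p = [np.nan if not t else v for v, t in zip(wald_p, testable)]
    return pd.DataFrame(
        {
            "base_mean": 100.0,
            "log2fc": lfc,
            "se": 0.2,
            "wald_p": p,
            "bh_q": p,
            "testable": testable,
        },
        index=[f"g{i}" for i in range(n)],
    )


class TestCombinedP:
    def test_worked_examples(self):
        assert tr.combined_p([0.04, 0.01]) == pytest.approx(0.00125)
        assert tr.combined_p([0.0, 0.0]) == 0.0
        assert tr.combined_p([0.9, 0.9]) == 1.0  # formula gives 1.62, clamped

    def test_grid_matches_formula(self):
        grid = np.linspace(0.0, 1.0, 10)
        for pa in grid:
            for pb in grid:
                expected = min(1.0, (pa + pb) ** 2 / 2)
                assert tr.combined_p([pa, pb]) == pytest.approx(expected, abs=1e-15)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=5),
        st.integers(0, 4),
        st.floats(0, 1),
    )
    def test_monotone_in_each_argument(self, pvals, which, bump):
        which %= len(pvals)
        lower = tr.combined_p(pvals)
        raised = list(pvals)
        raised[which] = min(1.0, raised[which] + bump)
        assert tr.combined_p(raised) >= lower - 1e-15

    def test_clamp_engaged_iff_sum_exceeds_sqrt_n(self):
        for pvals in ([0.8, 0.7], [0.5, 0.95], [0.3, 0.3], [1.0, 0.42]):
            total, n = sum(pvals), len(pvals)
            if total > np.sqrt(n):
                assert tr.combined_p(pvals) == 1.0
            else:
                assert tr.combined_p(pvals) == pytest.approx(total**2 / n)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DataError):
            tr.combined_p([])
        with pytest.raises(DataError):
            tr.combined_p([0.5, 1.2])


class TestCallBasal:
    def test_threshold_examples(self):
        de = de_frame([0.60, 0.56, -1.0, -0.70], [0.01, 0.001, 0.2, 0.049])
        out = tr.call_basal(de)
        assert list(out) == ["up", "ns", "ns", "down"]

    def test_not_testable_is_ns(self):
        de = de_frame([2.0, 2.0], [0.001, 0.001], testable=[True, False])
        assert list(tr.call_basal(de)) == ["up", "ns"]

    def test_adjusted_flag_switches_p_column(self):
        de = de_frame([1.0], [0.01])
        de["bh_q"] = [0.2]
        assert tr.call_basal(de).iloc[0] == "up"
        assert tr.call_basal(de, use_adjusted=True).iloc[0] == "ns"


class TestCallRescue:
    def test_worked_example(self):
        a = de_frame([1.2], [0.001])
        c = de_frame([0.2], [0.5])
        b = de_frame([-1.0], [0.004])
        res = tr.call_rescue(a, c, b)
        assert res["rescue_status"].iloc[0] == "rescued"
        assert res["combined_p"].iloc[0] == pytest.approx(1.25e-5)

    def test_larger_fold_change_is_not_rescued(self):
        a = de_frame([1.2], [0.001])
        c = de_frame([1.3], [0.01])
        b = de_frame([-0.1], [1e-6])
        assert tr.call_rescue(a, c, b)["rescue_status"].iloc[0] == "not_rescued"

    def test_tie_is_not_rescued(self):
        a = de_frame([1.2], [0.001])
        c = de_frame([-1.2], [0.01])
        b = de_frame([0.0], [0.001])
        assert tr.call_rescue(a, c, b)["rescue_status"].iloc[0] == "not_rescued"

    def test_basal_ns_is_not_applicable(self):
        a = de_frame([0.1], [0.9])
        c = de_frame([0.0], [0.9])
        b = de_frame([0.0], [0.9])
        assert tr.call_rescue(a, c, b)["rescue_status"].iloc[0] == "not_applicable"

    def test_missing_icd_data_flagged(self):
        a = de_frame([1.2], [0.001])
        c = de_frame([0.0], [0.5], testable=[False])
        b = de_frame([0.0], [0.004])
        res = tr.call_rescue(a, c, b)
        assert res["rescue_status"].iloc[0] == "not_rescued"
        assert bool(res["missing_data"].iloc[0])

    def test_strict_mode_demands_wildtype_like_icd_contrast(self):
        a = de_frame([2.0], [0.001])
        c = de_frame([1.0], [0.001])  # smaller but still significantly altered
        b = de_frame([-1.0], [0.001])
        assert tr.call_rescue(a, c, b)["rescue_status"].iloc[0] == "rescued"
        assert tr.call_rescue(a, c, b, strict=True)["rescue_status"].iloc[0] == "not_rescued"


class TestCategorize:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            ("rescued", "rescued", "rescued_both"),
            ("rescued", "not_rescued", "rescued_plus19_only"),
            ("not_rescued", "rescued", "rescued_delta19_only"),
            ("not_rescued", "not_rescued", "not_rescued"),
            ("not_applicable", "not_applicable", "not_applicable"),
        ],
    )
    def test_category_table(self, s1, s2, expected):
        out = tr.categorize(pd.Series([s1], index=["g"]), pd.Series([s2], index=["g"]))
        assert out.iloc[0] == expected


class TestCallIcdEffect:
    def test_basal_ns_gene_with_icd_shift_called(self):
        within = de_frame([0.8], [0.01])
        basal = pd.Series(["ns"], index=within.index)
        assert tr.call_icd_effect(within, basal).iloc[0] == "up"

    def test_basal_significant_gene_excluded(self):
        within = de_frame([0.8], [0.01])
        basal = pd.Series(["up"], index=within.index)
        assert tr.call_icd_effect(within, basal).iloc[0] == "ns"

    def test_opposite_direction_flag(self):
        basal = de_frame([0.0, 0.0], [0.9, 0.9])
        plus = de_frame([0.8, 0.8], [0.01, 0.01])
        delta = de_frame([-0.8, 0.8], [0.01, 0.01])
        master = tr.classify_genotype(
            basal,
            {"plus19": {"vs_wt": plus, "within": plus},
             "delta19": {"vs_wt": delta, "within": delta}},
        )
        assert bool(master["icd_opposite"].iloc[0])
        assert not bool(master["icd_opposite"].iloc[1])


class TestExpandedCommon:
    def _tables(self, lfc_rows, p_rows):
        genos = ["cKO", "KI_plus19", "KI_delta19"]
        return {
            g: de_frame([r[i] for r in lfc_rows], [r[i] for r in p_rows])
            for i, g in enumerate(genos)
        }

    def test_relaxed_rule(self):
        # gene 0: significant in cKO, relaxed-passing elsewhere -> common up
        # gene 1: one genotype below the relaxed bar -> excluded
        # gene 2: strong FC everywhere but significant nowhere -> excluded
        tables = self._tables(
            [(0.60, 0.52, 0.55), (0.60, 0.52, 0.49), (0.9, 0.9, 0.9)],
            [(0.01, 0.8, 0.8), (0.01, 0.8, 0.8), (0.4, 0.4, 0.4)],
        )
        out = tr.expanded_common(tables)
        assert out["common_up"] == ["g0"]
        assert out["common_down"] == []

    def test_common_down(self):
        tables = self._tables(
            [(-0.8, -0.51, -0.7)], [(0.001, 0.9, 0.9)]
        )
        assert tr.expanded_common(tables)["common_down"] == ["g0"]


class TestClassificationRecovery:
    def test_partition_property(self, recovery_run):
        """Every basal-significant gene gets exactly one of the four categories."""
        _truth, masters, _manifest, _out = recovery_run
        for master in masters.values():
            basal = master[master["basal_direction"] != "ns"]
            assert basal["category"].isin(CATEGORIES[:4]).all()
            assert (master.loc[master["basal_direction"] == "ns", "category"]
                    == "not_applicable").all()

    def test_truth_recovery(self, recovery_run):
        """>=85% of truly fully-rescued genes recovered; <=10% of truly
        unrescued genes miscalled as rescued by both ICDs."""
        truth, masters, _manifest, _out = recovery_run
        rb = truth.index[truth["label"] == "rescued_both"]
        nr = truth.index[truth["label"] == "not_rescued"]
        for master in masters.values():
            assert (master.loc[rb, "category"] == "rescued_both").mean() >= 0.85
            assert (master.loc[nr, "category"] == "rescued_both").mean() <= 0.10

    def test_single_icd_rescue_labels_recovered(self, recovery_run):
        truth, masters, _manifest, _out = recovery_run
        for label, cat in (
            ("rescued_plus19_only", "rescued_plus19_only"),
            ("rescued_delta19_only", "rescued_delta19_only"),
        ):
            genes = truth.index[truth["label"] == label]
            for master in masters.values():
                assert (master.loc[genes, "category"] == cat).mean() >= 0.7

    def test_null_basal_rate_conservative(self, null_de):
        """Joint |log2FC| and p criterion calls <5% of null genes basal."""
        assert (tr.call_basal(null_de) != "ns").mean() < 0.05
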