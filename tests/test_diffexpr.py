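"""Normalization, dispersion and Wald-test behavior, including the hand
oracles, calibration under the null, and an independent cross-check of the
fold-change estimates against DESeq2's implementation."""

import numpy as np
import pandas as pd
import pytest

import trap_rescue as tr
from trap_rescue.design import Contrast
from trap_rescue.diffexpr import DISPERSION_FLOOR, bh_adjust
from trap_rescue.errors import ConfigError, DataError


def two_group_design(n_per=4):
    rows = []
    for geno, treat in (("WT", "Cre"), ("cKO", "Cre")):
        for i in range(n_per):
            rows.append((f"{geno}.r{i}", geno, treat, i + 1, 1.0))
    return pd.DataFrame(
        rows, columns=["sample_id", "genotype", "treatment", "replicate", "size_multiplier"]
    )


CONTRAST = Contrast(("cKO", "Cre"), ("WT", "Cre"))


class TestSizeFactors:
    def test_hand_oracle(self):
        counts = pd.DataFrame([[10, 20], [30, 60], [50, 100]], columns=["a", "b"])
        f = tr.size_factors(counts)
        assert f["a"] == pytest.approx(0.7071, abs=5e-5)
        assert f["b"] == pytest.approx(1.4142, abs=5e-5)

    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 9, 40], "b": [5, 9, 40], "c": [5, 9, 40]})
        assert np.allclose(tr.size_factors(counts), 1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(100, size=200) + 1
        scaled = pd.DataFrame({"a": col, "b": col * 3})
        f = tr.size_factors(scaled)
        assert f["b"] / f["a"] == pytest.approx(3.0, rel=1e-9)

    def test_gene_permutation_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(50, size=(100, 4)) + 1)
        perm = counts.sample(frac=1, random_state=2)
        pd.testing.assert_series_equal(tr.size_factors(counts), tr.size_factors(perm))

    def test_empty_reference_set_errors_with_advice(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ConfigError, match="pseudo"):
            tr.size_factors(counts)
        f = tr.size_factors(counts, pseudo_reference=True)
        assert (f > 0).all()


class TestEstimateDispersion:
    def test_poisson_counts_give_near_zero_alpha(self):
        rng = np.random.default_rng(3)
        design = tr.make_design(replicates=4, seed=4)
        design["size_multiplier"] = 1.0
        counts = pd.DataFrame(
            rng.poisson(100, size=(500, len(design))), columns=design["sample_id"]
        )
        alpha = tr.estimate_dispersion(counts, tr.size_factors(counts), design)
        assert alpha.median() <= 0.01

    def test_nb_alpha_recovered(self):
        truth = tr.make_truth(
            tr.SimulationConfig(n_genes=300, seed=5, proportions={}, dispersion=0.1,
                                base_mean_log_mean=np.log(200.0), base_mean_log_sd=0.0)
        )
        design = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(50)],
                "genotype": "WT",
                "treatment": "Cre",
                "replicate": np.arange(1, 51),
                "size_multiplier": 1.0,
            }
        )
        counts = tr.simulate_counts(truth, design, seed=6)
        alpha = tr.estimate_dispersion(counts, tr.size_factors(counts), design)
        assert ((alpha >= 0.05) & (alpha <= 0.2)).mean() >= 0.9

    def test_constant_counts_hit_floor(self):
        design = two_group_design()
        counts = pd.DataFrame(
            np.full((10, len(design)), 7), columns=design["sample_id"]
        )
        alpha = tr.estimate_dispersion(counts, tr.size_factors(counts), design)
        assert (alpha == DISPERSION_FLOOR).all()

    def test_all_singleton_conditions_error(self):
        design = two_group_design(n_per=1)
        counts = pd.DataFrame(
            np.full((5, len(design)), 9), columns=design["sample_id"]
        )
        with pytest.raises(DataError):
            tr.estimate_dispersion(counts, tr.size_factors(counts), design)


class TestWaldTest:
    def test_doubled_counts_give_log2fc_one(self):
        design = two_group_design()
        base = np.array([[40, 44, 36, 42]] * 6)
        counts = pd.DataFrame(
            np.hstack([base, base * 2]),
            columns=list(design.loc[design.genotype == "WT", "sample_id"])
            + list(design.loc[design.genotype == "cKO", "sample_id"]),
        )
        factors = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(0.0, index=counts.index)
        res = tr.wald_test(counts, factors, disp, design, CONTRAST)
        assert np.allclose(res["log2fc"], 1.0, atol=1e-6)

    def test_swapping_contrast_negates_log2fc(self, small_simulation):
        _truth, design, counts = small_simulation
        f = tr.size_factors(counts)
        d = tr.estimate_dispersion(counts, f, design)
        fwd = tr.wald_test(counts, f, d, design, CONTRAST)
        rev = tr.wald_test(
            counts, f, d, design, Contrast(("WT", "Cre"), ("cKO", "Cre"))
        )
        m = fwd["testable"]
        np.testing.assert_allclose(fwd.loc[m, "log2fc"], -rev.loc[m, "log2fc"], atol=1e-9)
        np.testing.assert_allclose(fwd.loc[m, "wald_p"], rev.loc[m, "wald_p"], atol=1e-12)

    def test_all_zero_gene_not_testable(self):
        design = two_group_design()
        counts = pd.DataFrame(
            np.vstack([np.zeros(8, dtype=int), np.full(8, 50)]),
            columns=design["sample_id"],
        )
        res = tr.wald_test(
            counts, pd.Series(1.0, index=counts.columns),
            pd.Series(0.01, index=counts.index), design, CONTRAST,
        )
        assert not res.loc[0, "testable"]
        assert np.isnan(res.loc[0, "wald_p"])
        assert res.loc[1, "testable"]

    def test_null_type_one_error_calibrated(self, null_de):
        frac = (null_de.loc[null_de["testable"], "wald_p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_parameter_recovery_bias_and_power(self, recovery_run):
        """|bias| of estimated log2FC < 0.1 and power >= 0.9 on basal genes."""
        truth, _masters, _manifest, out = recovery_run
        de = pd.read_csv(out / "de" / "cKO:Cre_vs_WT:Cre.tsv", sep="\t", index_col=0)
        basal = truth.index[truth["beta_cKO"] != 0]
        err = de.loc[basal, "log2fc"] - truth.loc[basal, "beta_cKO"]
        assert abs(err.mean()) < 0.1
        assert (de.loc[basal, "wald_p"] < 0.05).mean() >= 0.9

    def test_matches_deseq2_fold_changes(self):
        """Independent cross-check: unshrunk log2FCs track pydeseq2's MLE."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        truth = tr.make_truth(
            tr.SimulationConfig(n_genes=200, seed=8, proportions={"not_rescued": 0.3})
        )
        design = two_group_design(n_per=5)
        counts = tr.simulate_counts(truth, design, seed=9)
        f = tr.size_factors(counts)
        d = tr.estimate_dispersion(counts, f, design)
        ours = tr.wald_test(counts, f, d, design, CONTRAST)

        meta = design.set_index("sample_id")[["genotype"]]
        dds = DeseqDataSet(
            counts=counts.T, metadata=meta, design="~genotype", quiet=True
        )
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["genotype", "cKO", "WT"], quiet=True)
        stats.summary()
        theirs = stats.results_df["log2FoldChange"]
        mask = ours["testable"] & (ours["base_mean"] > 20)
        diff = (ours.loc[mask, "log2fc"] - theirs[mask]).abs()
        assert diff.median() < 0.1
        assert np.corrcoef(ours.loc[mask, "log2fc"], theirs[mask])[0, 1] > 0.98


class TestBHAdjust:
    def test_hand_oracle(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p(self):
        assert bh_adjust([0.3]).iloc[0] == pytest.approx(0.3)

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(size=200)
        q = bh_adjust(p).to_numpy()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_nan_excluded_from_m(self):
        q = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q.iloc[1])
        # m = 2, not 3
        assert q.iloc[0] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])
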