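"""Shotgun-side statistics: imputation, moderated t-test, filters, ORA."""

import subprocess
import textwrap
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from maldimatch.diffstats import (
    DownshiftImputer,
    ModeratedTTest,
    PeptideTable,
    enriched_proteins,
    fold_change_classify,
    impute_missing,
    moderated_ttest,
    ora_hypergeometric,
    read_peptides_table,
    validate_proteins,
)


def toy_table(intensities: np.ndarray, groups=("control", "case"), unique=None, proteins=None):
    n, m = intensities.shape
    n_rep = m // 2
    df = pd.DataFrame(
        {
            "Sequence": [f"PEP{i}K" for i in range(n)],
            "Mass": np.linspace(700, 2000, n),
            "Proteins": proteins if proteins is not None else [f"P{i}" for i in range(n)],
            "Leading razor protein": proteins if proteins is not None else [f"P{i}" for i in range(n)],
            "Unique": unique if unique is not None else ["yes"] * n,
        }
    )
    for r in range(n_rep):
        df[f"Intensity {groups[0]}_{r + 1}"] = intensities[:, r]
    for r in range(n_rep):
        df[f"Intensity {groups[1]}_{r + 1}"] = intensities[:, n_rep + r]
    return read_peptides_table(df, group_names=groups)


class TestImputation:
    def test_complete_table_returned_unchanged(self, rng):
        t = toy_table(np.exp2(rng.normal(25, 2, (20, 6))))
        out = impute_missing(t, seed=0)
        pd.testing.assert_frame_equal(out.log2, t.log2)

    def test_observed_cells_never_altered_flags_partition_missing(self, rng):
        x = np.exp2(rng.normal(25, 2, (200, 6)))
        x[rng.random((200, 6)) < 0.2] = 0.0
        t = toy_table(x)
        out = impute_missing(t, seed=1)
        assert not out.log2.isna().any().any()
        obs = t.observed.to_numpy()
        np.testing.assert_array_equal(
            out.log2.to_numpy()[obs], t.log2.to_numpy()[obs]
        )
        # imputed flags (still-False observed) are exactly the missing cells
        assert ((~out.observed).to_numpy() == np.isnan(t.log2.to_numpy())).all()

    def test_deterministic_given_seed(self, rng):
        x = np.exp2(rng.normal(25, 2, (50, 6)))
        x[rng.random((50, 6)) < 0.3] = 0.0
        a = impute_missing(toy_table(x), seed=42).log2
        b = impute_missing(toy_table(x), seed=42).log2
        pd.testing.assert_frame_equal(a, b)

    def test_downshifted_distribution_moments(self, rng):
        """Imputed cells follow Normal(mean - 1.8 sd, (0.3 sd)^2) per column."""
        n = 20000
        x = rng.normal(25.0, 2.0, (n, 2))
        x[: n // 2, 0] = np.nan
        imp = DownshiftImputer(downshift=1.8, width=0.3, random_state=5).fit(x)
        filled = imp.transform(x)
        drawn = filled[: n // 2, 0]
        mean_obs, sd_obs = imp.col_mean_[0], imp.col_sd_[0]
        se_mean = 0.3 * sd_obs / np.sqrt(n // 2)
        assert abs(drawn.mean() - (mean_obs - 1.8 * sd_obs)) < 3 * se_mean
        sd_target = 0.3 * sd_obs
        se_sd = sd_target / np.sqrt(2 * (n // 2))
        assert abs(drawn.std(ddof=1) - sd_target) < 3 * se_sd

    def test_column_with_too_few_observations_named(self):
        x = np.exp2(np.full((5, 6), 25.0))
        x[:4, 2] = 0.0
        t = toy_table(x)
        with pytest.raises(ValueError, match="control_3"):
            impute_missing(t, seed=0)


class TestModeratedTTest:
    def test_identical_group_means_give_t_zero_p_one(self):
        x = np.exp2(
            np.array(
                [[25.0, 26.0, 27.0, 25.0, 26.0, 27.0], [20.0, 21.0, 22.0, 20.0, 21.0, 22.0]]
            )
        )
        t, _ = moderated_ttest(toy_table(x))
        assert t.stats["t_mod"].iloc[0] == 0.0
        assert t.stats["p"].iloc[0] == 1.0

    def test_zero_prior_df_reproduces_ordinary_t_test(self, rng):
        x = rng.normal(25, 2, (300, 6))
        y = np.array(["a"] * 3 + ["b"] * 3)
        est = ModeratedTTest(prior_df=0).fit(x.T, y)
        ref_t, ref_p = sps.ttest_ind(x[:, 3:], x[:, :3], axis=1, equal_var=True)
        np.testing.assert_allclose(est.t_, ref_t, atol=1e-10)
        np.testing.assert_allclose(est.p_, ref_p, atol=1e-10)

    def test_infinite_prior_limit_uses_pooled_variance_z(self, rng):
        # identical within-group sample variance everywhere drives d0 to infinity
        base = rng.normal(0, 1, 6)
        x = np.tile(base, (50, 1))
        shifts = rng.normal(0, 1, 50)[:, None] * np.array([0, 0, 0, 1, 1, 1])
        x = x + shifts
        est = ModeratedTTest().fit(x.T, np.array(["a"] * 3 + ["b"] * 3))
        assert np.isinf(est.d0_)
        expected = (x[:, 3:].mean(axis=1) - x[:, :3].mean(axis=1)) / np.sqrt(
            est.s0_sq_ * (2.0 / 3.0)
        )
        np.testing.assert_allclose(est.t_, expected, rtol=1e-9)

    def test_null_p_values_are_calibrated(self, rng):
        x = rng.normal(25, 2, (10000, 6))
        est = ModeratedTTest().fit(x.T, np.array(["a"] * 3 + ["b"] * 3))
        frac = (est.p_ < 0.05).mean()
        assert 0.04 <= frac <= 0.06
        ks = sps.kstest(est.p_, "uniform").statistic
        assert ks < 0.02

    def test_agrees_with_limma_reference(self, rng, tmp_path):
        """Cross-check t, p and the prior against Bioconductor limma."""
        x = rng.normal(25, 1.5, (120, 6))
        x[:30, 3:] += 2.0
        x[40:60] = 25.0 + (x[40:60] - 25.0) * 3.0  # heteroscedastic block
        csv = tmp_path / "mat.csv"
        pd.DataFrame(x).to_csv(csv, index=False)
        out = tmp_path / "limma.csv"
        script = tmp_path / "run.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(limma))
                x <- as.matrix(read.csv("{csv}"))
                design <- cbind(1, c(0,0,0,1,1,1))
                fit <- eBayes(lmFit(x, design))
                write.csv(data.frame(t=fit$t[,2], p=fit$p.value[,2],
                                     d0=fit$df.prior, s02=fit$s2.prior),
                          "{out}", row.names=FALSE)
                """
            )
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True
        )
        if proc.returncode != 0:
            pytest.skip(f"Rscript/limma unavailable: {proc.stderr[:200]}")
        ref = pd.read_csv(out)
        est = ModeratedTTest().fit(x.T, np.array(["a"] * 3 + ["b"] * 3))
        assert est.d0_ == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert est.s0_sq_ == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(est.t_, ref["t"], rtol=1e-6)
        np.testing.assert_allclose(est.p_, ref["p"], rtol=1e-6)


class TestFoldChange:
    def test_fourfold_gives_log2fc_two_case_label(self):
        x = np.exp2(np.array([[20.0, 20.0, 20.0, 22.0, 22.0, 22.0]]))
        t = fold_change_classify(toy_table(x))
        assert t.stats["log2fc"].iloc[0] == pytest.approx(2.0)
        assert t.stats["group"].iloc[0] == "case"

    def test_equal_means_unclassified(self):
        x = np.exp2(np.full((1, 6), 24.0))
        t = fold_change_classify(toy_table(x))
        assert t.stats["log2fc"].iloc[0] == 0.0
        assert t.stats["group"].iloc[0] == "unclassified"

    def test_planted_negative_fold_changes_recovered(self, small_sim):
        _, table_df, truth, _ = small_sim
        t = read_peptides_table(table_df, group_names=("control", "case"))
        t = impute_missing(t, seed=0)
        t = fold_change_classify(t)
        neg = truth.peptides["log2fc"].to_numpy() < 0
        labels = t.stats["group"].to_numpy()[neg]
        assert (labels == "control").mean() >= 0.95

    def test_label_sign_invariant(self, small_sim):
        _, table_df, _, _ = small_sim
        t = fold_change_classify(
            impute_missing(read_peptides_table(table_df), seed=0)
        )
        fc = t.stats["log2fc"]
        assert (t.stats["group"][fc > 0] == "case").all()
        assert (t.stats["group"][fc < 0] == "control").all()


class TestProteinFilters:
    def test_presence_rule_two_of_three(self):
        x = np.exp2(np.full((2, 6), 25.0))
        x[0, 2] = 0.0  # control observed (T, T, F) -> present
        x[1, 1:3] = 0.0  # control observed (T, F, F) -> absent
        t = toy_table(x, proteins=["A", "B"])
        calls = validate_proteins(t, min_replicates=2)
        assert bool(calls.loc["A", "control"]) is True
        assert bool(calls.loc["B", "control"]) is False

    def test_non_unique_peptides_do_not_validate(self):
        x = np.exp2(np.full((1, 6), 25.0))
        t = toy_table(x, unique=["no"])
        calls = validate_proteins(t)
        assert not calls["control"].any() and not calls["case"].any()

    def test_exclusive_partition_matches_planted_truth(self):
        rng = np.random.default_rng(2)
        x = np.exp2(rng.normal(25, 0.2, (9, 6)))
        x[:3, 3:] = 0.0  # proteins 0-2 only in control
        x[3:6, :3] = 0.0  # proteins 3-5 only in case
        t = toy_table(x, proteins=[f"P{i}" for i in range(9)])
        calls = validate_proteins(t)
        assert set(calls.index[calls["status"] == "exclusive:control"]) == {"P0", "P1", "P2"}
        assert set(calls.index[calls["status"] == "exclusive:case"]) == {"P3", "P4", "P5"}
        assert set(calls.index[calls["status"] == "shared"]) == {"P6", "P7", "P8"}

    @pytest.mark.parametrize(
        "ratios,expect",
        [((5.0, 5.0, 1.0), True), ((4.0, 4.0, 4.0), False), ((5.0, 1.0, 5.0), True)],
    )
    def test_fourfold_enrichment_rule(self, ratios, expect):
        df = pd.DataFrame(
            [[10.0, 10.0, 10.0, 10.0 * ratios[0], 10.0 * ratios[1], 10.0 * ratios[2]]],
            columns=["c_1", "c_2", "c_3", "d_1", "d_2", "d_3"],
            index=["prot"],
        )
        groups = {"c": ["c_1", "c_2", "c_3"], "d": ["d_1", "d_2", "d_3"]}
        out = enriched_proteins(df, groups, fold=4.0, min_animals=2, paired=True)
        assert ("prot" in out["d"]) is expect
        out_unpaired = enriched_proteins(df, groups, fold=4.0, min_animals=2)
        assert ("prot" in out_unpaired["d"]) is expect

    def test_filters_are_row_order_invariant(self, rng):
        x = np.exp2(rng.normal(25, 2, (30, 6)))
        x[rng.random((30, 6)) < 0.3] = 0.0
        prot = [f"P{i % 10}" for i in range(30)]
        t = toy_table(x, proteins=prot)
        perm = rng.permutation(30)
        t_perm = toy_table(x[perm], proteins=[prot[i] for i in perm])
        a = validate_proteins(t).sort_index()
        b = validate_proteins(t_perm).sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestORA:
    def test_exact_value_n20(self):
        """k=4 of K=5 in n=6 from N=20: exact enumeration gives ~0.01393."""
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        selected = {f"g{i}" for i in range(4)} | {"g10", "g11"}
        res = ora_hypergeometric(selected, {"T": term}, universe)
        expected = (comb(5, 4) * comb(15, 2) + comb(5, 5) * comb(15, 1)) / comb(20, 6)
        assert res["p"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_small_term(self):
        universe = {f"g{i}" for i in range(10)}
        res = ora_hypergeometric({"g1"}, {"T": {"g2"}}, universe)
        # P(X >= 0) = 1; P(X >= 1) would be 0.1
        assert res["p"].iloc[0] == 1.0
        res2 = ora_hypergeometric({"g2"}, {"T": {"g2"}}, universe)
        assert res2["p"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_term_equal_universe_certain(self):
        universe = {f"g{i}" for i in range(8)}
        res = ora_hypergeometric({"g0", "g1"}, {"ALL": set(universe)}, universe)
        assert res["p"].iloc[0] == 1.0

    def test_bh_adjustment_monotone(self, rng):
        universe = {f"g{i}" for i in range(50)}
        terms = {
            f"T{j}": set(rng.choice(sorted(universe), size=rng.integers(3, 15), replace=False))
            for j in range(20)
        }
        selected = set(rng.choice(sorted(universe), size=10, replace=False))
        res = ora_hypergeometric(selected, terms, universe)
        assert (res["p_adj"] >= res["p"] - 1e-15).all()
        assert (res["p"].diff().fillna(0) >= -1e-15).all()
        assert (res["p_adj"].diff().fillna(0) >= -1e-15).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(set(), {"T": {"a"}}, {"a"})
        with pytest.raises(ValueError):
            ora_hypergeometric({"zz"}, {"T": {"a"}}, {"a"})
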