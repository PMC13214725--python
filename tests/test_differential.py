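import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from proteoheat import (DifferentialAbundanceModel, IntensityMatrix, SampleDesign,
                        SimConfig, ValidationError, bh_adjust, ebayes_moderate,
                        generate_dataset)

from conftest import design_24


def matrix_24(values_by_cell, design):
    """One-protein matrix laid out over the 24-sample design."""
    meta = design.table
    row = np.empty(len(meta))
    for i, (_, s) in enumerate(meta.iterrows()):
        row[i] = values_by_cell[(s.tolerance_class, s.day)][s.replicate - 1]
    df = pd.DataFrame([row] * 12, index=[f"P{i}" for i in range(12)],
                      columns=meta.index)
    return IntensityMatrix.from_values(df, "imputed")


# --------------------------------------------------------------------------
# OLS fitting
# --------------------------------------------------------------------------

class TestFit:
    def test_identical_groups_zero_coefficients(self):
        design = design_24()
        cells = {(c, d): [5.0, 5.0, 5.0] for c in ("tolerant", "sensitive")
                 for d in (0, 6)}
        res = DifferentialAbundanceModel(matrix_24(cells, design), design).fit(
            moderate=False)
        np.testing.assert_allclose(res.coefficients[:, 0], 5.0)
        np.testing.assert_allclose(res.coefficients[:, 1:], 0.0, atol=1e-12)
        assert res.var_floored.all()  # zero residual variance floored, flagged

    def test_hand_ols_day_shift(self):
        # both classes: day0 = [1,2,3] per genotype, day6 = [2,3,4]
        # -> day coefficient 1.0, interaction 0.  Each of the 4 class-day
        # cells holds [1,2,3,1,2,3] (+shift): SS = 4 per cell, RSS = 16,
        # df = 24 - 4 = 20, so pooled s^2 = 16/20 = 0.8.
        design = design_24()
        cells = {("tolerant", 0): [1, 2, 3], ("tolerant", 6): [2, 3, 4],
                 ("sensitive", 0): [1, 2, 3], ("sensitive", 6): [2, 3, 4]}
        res = DifferentialAbundanceModel(matrix_24(cells, design), design).fit(
            moderate=False)
        tab = res.contrast("sensitive_day")
        np.testing.assert_allclose(tab["log2fc"], 1.0)
        np.testing.assert_allclose(res.contrast("interaction")["log2fc"], 0.0,
                                   atol=1e-12)
        np.testing.assert_allclose(res.s2, 0.8)
        assert res.moderation.df_residual == 20

    def test_against_normal_equations_oracle(self, complete_dataset):
        matrix, design, _ = complete_dataset
        model = DifferentialAbundanceModel(matrix, design)
        res = model.fit(moderate=False)
        X = model.exog
        rng = np.random.default_rng(0)
        for i in rng.choice(matrix.n_proteins, size=50, replace=False):
            y = matrix.values.iloc[i].to_numpy()
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(res.coefficients[i], beta, atol=1e-10)
            rss = ((y - X @ beta) ** 2).sum()
            np.testing.assert_allclose(res.s2[i], rss / (len(y) - X.shape[1]),
                                       atol=1e-10)

    def test_equivariance_under_constant_shift(self, complete_dataset):
        matrix, design, _ = complete_dataset
        shifted = IntensityMatrix(matrix.values + 7.5, matrix.mask, "imputed")
        t1 = DifferentialAbundanceModel(matrix, design).fit().contrast("interaction")
        t2 = DifferentialAbundanceModel(shifted, design).fit().contrast("interaction")
        np.testing.assert_allclose(t1["t"], t2["t"], atol=1e-9)

    def test_rank_deficient_design_names_columns(self):
        # tolerant genotypes observed at day 0 only -> empty tolerant:day6 cell
        rows = []
        for geno, klass, days in (("T1", "tolerant", (0,)), ("S1", "sensitive", (0, 6))):
            for day in days:
                for rep in (1, 2, 3):
                    rows.append((f"{geno}_d{day}_r{rep}", geno, klass, day, rep))
        df = pd.DataFrame(rows, columns=["sample_id", "genotype", "tolerance_class",
                                         "day", "replicate"]).set_index("sample_id")
        design = SampleDesign(df)
        vals = pd.DataFrame(np.random.default_rng(0).normal(size=(5, len(df))),
                            index=[f"P{i}" for i in range(5)], columns=df.index)
        with pytest.raises(ValidationError, match="collinear"):
            DifferentialAbundanceModel(IntensityMatrix.from_values(vals, "imputed"),
                                       design)

    def test_genotype_level_model_matches_class_model_when_balanced(self,
                                                                    complete_dataset):
        matrix, design, _ = complete_dataset
        a = DifferentialAbundanceModel(matrix, design, model="class_day").fit(
            moderate=False).contrast("interaction")
        b = DifferentialAbundanceModel(matrix, design, model="genotype_day").fit(
            moderate=False).contrast("interaction")
        # class-level effect estimates agree; variances differ by model df
        np.testing.assert_allclose(a["log2fc"], b["log2fc"], atol=1e-10)


# --------------------------------------------------------------------------
# empirical Bayes moderation
# --------------------------------------------------------------------------

class TestModeration:
    def test_identical_variances_are_fixed_point(self):
        params = ebayes_moderate(np.full(100, 0.25), d=4)
        np.testing.assert_allclose(params.posterior_var(np.full(100, 0.25)), 0.25,
                                   rtol=1e-9)

    def test_d0_zero_reduces_to_classical_t(self, complete_dataset):
        matrix, design, _ = complete_dataset
        model = DifferentialAbundanceModel(matrix, design)
        classical = model.fit(moderate=False).contrast("sensitive_day")
        forced = model.fit(d0=0.0).contrast("sensitive_day")
        np.testing.assert_allclose(forced["t"], classical["t"], atol=1e-10)

    def test_d0_infinite_uses_prior_variance_everywhere(self, complete_dataset):
        matrix, design, _ = complete_dataset
        model = DifferentialAbundanceModel(matrix, design)
        res = model.fit(d0=np.inf, s0_sq=0.3)
        np.testing.assert_allclose(res.s2_post, 0.3)
        tab = res.contrast("sensitive_day")
        c = model.contrast_spec("sensitive_day").coefficients
        unit = c @ res.xtx_inv @ c
        expected_t = (res.coefficients @ c) / np.sqrt(0.3 * unit)
        np.testing.assert_allclose(tab["t"], expected_t, atol=1e-10)

    def test_posterior_var_between_prior_and_sample(self):
        s2 = np.array([0.01, 0.1, 1.0, 10.0])
        params = ebayes_moderate(np.r_[s2, np.full(20, 0.5)], d=4)
        post = params.posterior_var(s2)
        lo = np.minimum(s2, params.s0_sq)
        hi = np.maximum(s2, params.s0_sq)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_too_few_variances_disable_moderation(self):
        with pytest.warns(UserWarning, match="moderation disabled"):
            params = ebayes_moderate(np.array([0.5, 0.6, 0.7]), d=4)
        assert params.d0 == 0.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_parameter_recovery(self, seed):
        rng = np.random.default_rng(seed)
        d0, s0_sq, d, n = 4.0, 1.0, 4, 5000
        sigma2 = d0 * s0_sq / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        params = ebayes_moderate(s2, d)
        assert abs(params.d0 - d0) <= 1.0
        assert abs(params.s0_sq - s0_sq) <= 0.2


def test_limma_cross_check(tmp_path):
    """Independent oracle: R/limma lmFit + eBayes on the same fixture."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    cfg = SimConfig(seed=11, n_proteins=60, n_day_effect=5, n_class_effect=5,
                    n_interaction=3, n_on_off=0, n_switch_like=0, missing_target=0.0)
    matrix, design, _ = generate_dataset(cfg)
    res = DifferentialAbundanceModel(
        IntensityMatrix(matrix.values, matrix.mask, "imputed"), design).fit()
    tab = res.contrast("sensitive_day")
    matrix.values.to_csv(tmp_path / "mat.tsv", sep="\t")
    design.table.reset_index().to_csv(tmp_path / "design.csv", index=False)
    script = tmp_path / "check.R"
    script.write_text(
        'suppressMessages(library(limma))\n'
        'mat <- as.matrix(read.delim("mat.tsv", row.names=1, check.names=FALSE))\n'
        'des <- read.csv("design.csv")\n'
        'cls <- factor(des$tolerance_class, levels=c("sensitive","tolerant"))\n'
        'day <- factor(des$day)\n'
        'fit <- eBayes(lmFit(mat, model.matrix(~ cls * day)))\n'
        'out <- data.frame(t=fit$t[,"day6"], p=fit$p.value[,"day6"])\n'
        'write.table(out, "r.tsv", sep="\\t", quote=FALSE)\n'
        'cat(fit$df.prior, fit$s2.prior, "\\n")\n'
    )
    proc = subprocess.run(["Rscript", "check.R"], cwd=tmp_path,
                          capture_output=True, text=True, timeout=300)
    assert proc.returncode == 0, proc.stderr
    r_d0, r_s0 = map(float, proc.stdout.split()[:2])
    r_tab = pd.read_csv(tmp_path / "r.tsv", sep="\t", index_col=0)
    assert res.moderation.d0 == pytest.approx(r_d0, rel=1e-4)
    assert res.moderation.s0_sq == pytest.approx(r_s0, rel=1e-4)
    np.testing.assert_allclose(tab["t"].to_numpy(), r_tab["t"].to_numpy(), atol=1e-8)
    np.testing.assert_allclose(tab["p"].to_numpy(), r_tab["p"].to_numpy(), atol=1e-8)


# --------------------------------------------------------------------------
# BH adjustment and DAP calling
# --------------------------------------------------------------------------

class TestBH:
    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_printed_four_vector(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_nan_propagates_and_is_excluded(self):
        out = bh_adjust([0.02, np.nan, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.04, 0.04])  # m = 2

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_statsmodels(self, p):
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)


class TestDapCalling:
    @pytest.mark.parametrize("shift,expect", [
        (1.2, True),    # clears both thresholds
        (0.9, False),   # fold-change gate fails
        (1.0, True),    # boundary |log2FC| = 1 counts
    ])
    def test_threshold_rules_at_boundary(self, shift, expect):
        # balanced residuals make the estimated log2FC exactly the planted shift
        design = design_24()
        meta = design.table
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 0.05, size=(20, len(meta)))
        probe = np.zeros(len(meta))
        for cell in meta.groupby(["tolerance_class", "day"]).groups.values():
            idx = meta.index.get_indexer(cell)
            probe[idx] = 10.0 + np.array([-0.01, 0.0, 0.01] * (len(idx) // 3))
        probe[ (meta["day"] == 6).to_numpy()] += shift
        vals[0] = probe
        df = pd.DataFrame(vals, index=[f"P{i}" for i in range(20)],
                          columns=meta.index)
        res = DifferentialAbundanceModel(
            IntensityMatrix.from_values(df, "imputed"), design).fit()
        daps = res.call_daps("sensitive_day")
        assert daps.loc["P0", "log2fc"] == pytest.approx(shift, abs=1e-9)
        assert daps.loc["P0", "adj_p"] < 0.05
        assert bool(daps.loc["P0", "significant"]) is expect

    def test_call_daps_applies_both_gates(self, complete_dataset):
        matrix, design, registry = complete_dataset
        res = DifferentialAbundanceModel(matrix, design).fit()
        daps = res.call_daps("sensitive_day", alpha=0.05, lfc_min=1.0)
        manual = (daps["adj_p"] < 0.05) & (daps["log2fc"].abs() >= 1.0)
        assert (daps["significant"] == manual).all()
        assert (daps.loc[daps["log2fc"] >= 0, "direction"] == "up").all()

    def test_interaction_has_no_fold_change_gate(self, complete_dataset):
        matrix, design, _ = complete_dataset
        res = DifferentialAbundanceModel(matrix, design).fit()
        inter = res.interaction_daps(fdr=0.05)
        assert (inter["significant"] == (inter["adj_p"] < 0.05)).all()

    def test_symmetric_day_shift_has_zero_interaction(self):
        design = design_24()
        cells = {("tolerant", 0): [1, 2, 3], ("tolerant", 6): [3, 4, 5],
                 ("sensitive", 0): [5, 6, 7], ("sensitive", 6): [7, 8, 9]}
        res = DifferentialAbundanceModel(matrix_24(cells, design), design).fit(
            moderate=False)
        np.testing.assert_allclose(res.contrast("interaction")["log2fc"], 0.0,
                                   atol=1e-12)

    def test_summary_reports_counts(self, complete_dataset):
        matrix, design, _ = complete_dataset
        text = DifferentialAbundanceModel(matrix, design).fit().summary()
        assert "interaction" in text and "prior d0" in text
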