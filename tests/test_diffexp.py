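"""TMM normalization, the random-intercept mixed model, BH, Fisher and sex QC."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from norfscan.core import ExpressionMatrix
from norfscan.diffexp import (
    bh_adjust,
    de_norfs,
    fisher_enrichment,
    fit_mixed_model,
    log_cpm,
    run_diffexp,
    sex_qc,
    tmm_factors,
)
from norfscan.matching import NorfTranscriptMatch
from norfscan.simulate import generate_case_control_counts, generate_annotation

from conftest import bh_bruteforce, fisher_p_enumeration


def counts_matrix(arr, prefix="s"):
    arr = np.asarray(arr)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"g{i}" for i in range(arr.shape[0])],
            columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
        ),
        "count",
    )


class TestTmm:
    def test_identical_columns_unit_factors(self):
        m = counts_matrix(np.tile([[10], [200], [35]], (1, 4)))
        f = tmm_factors(m)
        np.testing.assert_allclose(f.factors, 1.0, atol=1e-12)

    def test_pure_depth_change_absorbed_by_library_size(self, rng):
        col = rng.integers(5, 400, 40)
        m = counts_matrix(np.column_stack([col, 2 * col, col]))
        f = tmm_factors(m)
        np.testing.assert_allclose(f.factors, 1.0, atol=1e-9)

    def test_scaling_one_sample_leaves_factors(self, rng):
        base = rng.integers(5, 300, size=(50, 5))
        f1 = tmm_factors(counts_matrix(base))
        scaled = base.astype(float).copy()
        scaled[:, 2] *= 3.0
        f2 = tmm_factors(counts_matrix(scaled))
        # library size absorbs the scale; only the finite-count precision
        # weights move, so invariance is approximate (edgeR behaves alike)
        np.testing.assert_allclose(f1.factors, f2.factors, rtol=1e-2)

    def test_geometric_mean_one(self, rng):
        m = counts_matrix(rng.negative_binomial(5, 0.3, size=(60, 8)) + 1)
        f = tmm_factors(m)
        assert abs(np.exp(np.mean(np.log(f.factors))) - 1.0) < 1e-9

    def test_all_zero_sample_rejected(self):
        m = counts_matrix([[0, 5], [0, 7]])
        with pytest.raises(ValueError):
            tmm_factors(m)

    def test_matches_edger_reference(self, rng, tmp_path):
        """Factors agree with edgeR's published TMM implementation to 1e-8."""
        counts = rng.negative_binomial(5, 0.3, size=(30, 6)) + 1
        f = tmm_factors(counts_matrix(counts))
        csv = tmp_path / "counts.csv"
        pd.DataFrame(counts).to_csv(csv, index=False)
        out = subprocess.run(
            [
                "Rscript", "-e",
                f'suppressMessages(library(edgeR));'
                f'x<-as.matrix(read.csv("{csv}"));'
                f'cat(sprintf("%.12f ", calcNormFactors(x)))',
            ],
            capture_output=True, text=True, check=True,
        )
        expected = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(f.factors, expected, atol=1e-8)


class TestLogCpm:
    def test_zero_count_is_minus_one(self):
        m = counts_matrix([[0, 10], [100, 90]])
        lc = log_cpm(m, tmm_factors(m))
        assert lc.values.iloc[0, 0] == pytest.approx(np.log2(0.5))

    def test_count_at_cpm_one(self):
        vals = np.array([[1, 1], [999_999, 999_999]])
        m = counts_matrix(vals)
        lc = log_cpm(m, tmm_factors(m))
        # library size 1e6, factor 1 -> count 1 is CPM 1 -> log2(1.5)
        assert lc.values.iloc[0, 0] == pytest.approx(np.log2(1.5), abs=1e-9)

    def test_monotone_in_count(self):
        m = counts_matrix([[0, 5], [10, 5], [100, 5]])
        lc = log_cpm(m, tmm_factors(m))
        assert lc.values["s0"].is_monotonic_increasing


class TestMixedModel:
    def test_singleton_groups_reduce_to_ols(self, rng):
        n = 40
        x = rng.binomial(1, 0.5, n).astype(float)
        y = 1.0 + 0.5 * x + rng.normal(0, 1, n)
        design = pd.DataFrame({"intercept": np.ones(n), "diagnosis": x})
        fit = fit_mixed_model(y, design, np.arange(n), "diagnosis")
        X = design.to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert fit.method == "ols"
        assert fit.effect == pytest.approx(beta[1], abs=1e-8)
        assert fit.se == pytest.approx(se, abs=1e-8)

    def test_matches_statsmodels_reml(self, rng):
        import statsmodels.formula.api as smf

        n_ind = 50
        groups = np.repeat(np.arange(n_ind), 2)
        x = rng.binomial(1, 0.5, n_ind)[groups].astype(float)
        y = 0.7 * x + rng.normal(0, 0.6, n_ind)[groups] + rng.normal(0, 1, 2 * n_ind)
        design = pd.DataFrame({"intercept": np.ones(2 * n_ind), "diagnosis": x})
        fit = fit_mixed_model(y, design, groups, "diagnosis")
        df = pd.DataFrame({"y": y, "x": x, "g": groups})
        sm_fit = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=True)
        assert fit.effect == pytest.approx(sm_fit.params["x"], abs=1e-6)
        assert fit.se == pytest.approx(sm_fit.bse["x"], rel=1e-4)
        assert fit.sigma2_e == pytest.approx(sm_fit.scale, rel=1e-4)

    def test_singular_design_names_aliased_column(self, rng):
        n = 20
        x = rng.binomial(1, 0.5, n).astype(float)
        design = pd.DataFrame(
            {"intercept": np.ones(n), "diagnosis": x, "copy": x}
        )
        with pytest.raises(ValueError, match="aliased"):
            fit_mixed_model(rng.normal(size=n), design, np.arange(n) // 2, "diagnosis")

    def test_effect_recovery_small_bias(self):
        """Planted effect 1.0 recovered with |bias| < 0.05 (replicated)."""
        rng = np.random.default_rng(5)
        n_ind, effect = 100, 1.0
        groups = np.repeat(np.arange(n_ind), 2)
        estimates = []
        for _ in range(60):
            x = rng.binomial(1, 0.5, n_ind)[groups].astype(float)
            y = (
                effect * x
                + rng.normal(0, 0.3, n_ind)[groups]
                + rng.normal(0, 0.5, 2 * n_ind)
            )
            design = pd.DataFrame({"intercept": np.ones(2 * n_ind), "diagnosis": x})
            estimates.append(fit_mixed_model(y, design, groups, "diagnosis").effect)
        assert abs(np.mean(estimates) - effect) < 0.05


class TestBh:
    def test_textbook_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_nan_propagates_and_excluded_from_m(self):
        q = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_bruteforce([0.01, 0.02]))

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_order_preserving(self, rng):
        p = np.sort(rng.uniform(0, 1, 50))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all()


class TestFisher:
    def test_balanced_table(self):
        oddsratio, p = fisher_enrichment(1, 1, 1, 1)
        assert oddsratio == 1.0
        assert p == 1.0

    def test_diagonal_table_enumeration(self):
        _, p = fisher_enrichment(2, 0, 0, 2)
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_zero_cell_odds_ratio_infinite(self):
        oddsratio, _ = fisher_enrichment(3, 0, 1, 2)
        assert np.isinf(oddsratio)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(0, 0, 3, 4)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(0, 8, 4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = fisher_enrichment(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(
                fisher_p_enumeration(int(a), int(b), int(c), int(d)), abs=1e-10
            )


class TestDeNorfs:
    MATCHES = [
        NorfTranscriptMatch("n1", "t1", "contained", "lincRNA"),
        NorfTranscriptMatch("n2", "t2", "contained", "lincRNA"),
        NorfTranscriptMatch("n2", "t3", "contained", "lincRNA"),
    ]

    def frame(self, rows):
        return pd.DataFrame(
            rows, columns=["transcript_id", "effect", "qvalue", "direction"]
        )

    def test_no_de_transcripts_empty(self):
        de = self.frame([("t1", 1.0, 0.5, "up")])
        assert de_norfs(de, self.MATCHES).empty

    def test_direction_inherited(self):
        de = self.frame([("t1", 1.0, 0.01, "up"), ("t2", -1.0, 0.5, "down")])
        out = de_norfs(de, self.MATCHES)
        assert out.to_dict("records")[0]["norf_id"] == "n1"
        assert out.to_dict("records")[0]["direction"] == "up"

    def test_conflicting_directions_reported_both(self):
        de = self.frame([("t2", 1.0, 0.01, "up"), ("t3", -1.0, 0.01, "down")])
        out = de_norfs(de, self.MATCHES)
        assert out["direction"].tolist() == ["both"]

    def test_monotone_in_threshold(self):
        de = self.frame([("t1", 1.0, 0.01, "up"), ("t2", -1.0, 0.04, "down")])
        strict = set(de_norfs(de, self.MATCHES, q_threshold=0.02)["norf_id"])
        loose = set(de_norfs(de, self.MATCHES, q_threshold=0.05)["norf_id"])
        assert strict <= loose


class TestEndToEndDe:
    def test_planted_fold_changes_recovered(self):
        transcripts = generate_annotation(21, n_genes=50)
        counts, meta, truth = generate_case_control_counts(
            22, transcripts, n_cnt=40, n_scz=30, n_bd=0,
            de_fraction=0.2, lfc_range=(1.5, 2.5),
        )
        m = ExpressionMatrix(counts.astype(float), "count")
        lc = log_cpm(m, tmm_factors(m))
        de = run_diffexp(lc, meta, case="SCZ", covariates=("age",))
        called = set(de.loc[de["qvalue"] < 0.05, "transcript_id"])
        planted = set(truth.de_transcripts["SCZ"])
        sensitivity = len(called & planted) / len(planted)
        fdr = (len(called - planted) / len(called)) if called else 0.0
        assert sensitivity >= 0.8
        assert fdr <= 0.1

    def test_estimated_lfc_signs_match_truth(self):
        transcripts = generate_annotation(31, n_genes=40)
        counts, meta, truth = generate_case_control_counts(
            32, transcripts, n_cnt=30, n_scz=30, n_bd=0,
            de_fraction=0.25, lfc_range=(1.5, 2.5),
        )
        m = ExpressionMatrix(counts.astype(float), "count")
        de = run_diffexp(log_cpm(m, tmm_factors(m)), meta, case="SCZ")
        est = dict(zip(de["transcript_id"], de["effect"]))
        for tid, lfc in truth.de_transcripts["SCZ"].items():
            assert np.sign(est[tid]) == np.sign(lfc)


class TestSexQc:
    def make_data(self, flip_one=False):
        rng = np.random.default_rng(0)
        sexes = ["M"] * 6 + ["F"] * 6
        samples = [f"s{i}" for i in range(12)]
        chry = np.where(np.array(sexes) == "M", 5.0, 0.0) + rng.normal(0, 0.1, 12)
        xist = np.where(np.array(sexes) == "F", 8.0, 0.5) + rng.normal(0, 0.1, 12)
        vals = pd.DataFrame([chry, xist], index=["yg1", "XIST"], columns=samples)
        meta_sex = list(sexes)
        if flip_one:
            meta_sex[0] = "F"
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "diagnosis": ["CNT"] * 12,
                "individual_id": samples,
                "sex": meta_sex,
            }
        )
        return ExpressionMatrix(vals, "logCPM"), meta

    def test_concordant_labels_unflagged(self):
        m, meta = self.make_data()
        report = sex_qc(m, meta, ["yg1"], "XIST")
        assert not report["flagged"].any()

    def test_planted_mislabel_flagged(self):
        m, meta = self.make_data(flip_one=True)
        report = sex_qc(m, meta, ["yg1"], "XIST")
        assert report.loc[report["sample_id"] == "s0", "flagged"].item()
        assert report["flagged"].sum() == 1

    def test_constant_xist_degenerate(self):
        m, meta = self.make_data()
        m.values.loc["XIST"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            report = sex_qc(m, meta, ["yg1"], "XIST")
        assert not report["flagged"].any()

    def test_missing_xist_warns(self):
        m, meta = self.make_data()
        with pytest.warns(UserWarning, match="absent"):
            report = sex_qc(m, meta, ["yg1"], "GENE_NOT_THERE")
        assert "mean_chry" in report
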