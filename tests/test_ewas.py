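"""Treatment EWAS: phi coefficients, adjustment sets, per-CpG regression
against a normal-equations oracle, genomic control, significance calling,
dose-response coding, paired contrasts and annotation enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ewasmed.ewas import (
    EWAS_ALPHA,
    PhiMatrix,
    annotation_enrichment,
    call_significant,
    dose_response_trend,
    genomic_control_adjust,
    ordinal_dose_code,
    paired_exposure_ewas,
    phi_matrix,
    run_ewas,
    select_adjustment_set,
)
from ewasmed.qc import MethylationMatrix


def _mm(vals):
    vals = np.asarray(vals, float)
    g, n = vals.shape
    return MethylationMatrix(
        vals, [f"cg{i}" for i in range(g)], [f"S{j}" for j in range(n)], scale="M"
    )


def _ols_oracle(X, y):
    """Brute-force normal equations: coefficient, SE, t, p for column 1."""
    XtXi = np.linalg.inv(X.T @ X)
    beta = XtXi @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = resid @ resid / dof
    se = np.sqrt(s2 * XtXi[1, 1])
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), dof)
    return beta[1], se, t, p


class TestPhi:
    def test_hand_table_closed_form(self):
        # 2x2 table a=30, b=10, c=10, d=50 -> phi = 1400/2400
        x = np.array([1] * 40 + [0] * 60)
        y = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 50)
        pm = phi_matrix(pd.DataFrame({"x": x, "y": y}))
        assert pm.phi.loc["x", "y"] == pytest.approx(1400 / 2400, abs=1e-12)
        chi2 = 100 * (1400 / 2400) ** 2
        assert pm.p.loc["x", "y"] == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-12)

    def test_identical_columns_give_phi_one(self):
        x = np.array([0, 1, 1, 0, 1])
        pm = phi_matrix(pd.DataFrame({"a": x, "b": x}))
        assert pm.phi.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, binary_treatments):
        pm = phi_matrix(binary_treatments)
        off = pm.phi.values[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_degenerate_margin_flagged_nan(self):
        df = pd.DataFrame({"a": [1, 1, 1], "b": [0, 1, 0]})
        with pytest.warns(UserWarning, match="degenerate"):
            pm = phi_matrix(df)
        assert np.isnan(pm.phi.loc["a", "b"])


class TestAdjustmentSet:
    def _pm(self, phi_ab, p_ab):
        names = ["a", "b"]
        phi = pd.DataFrame([[1.0, phi_ab], [phi_ab, 1.0]], index=names, columns=names)
        p = pd.DataFrame([[0.0, p_ab], [p_ab, 0.0]], index=names, columns=names)
        return PhiMatrix(phi, p)

    def test_strongly_correlated_cotreatment_excluded(self):
        assert select_adjustment_set(self._pm(0.5, 1e-40), "a") == []

    def test_weakly_correlated_cotreatment_included(self):
        assert select_adjustment_set(self._pm(0.2, 1e-10), "a") == ["b"]

    def test_high_phi_without_significance_included(self):
        assert select_adjustment_set(self._pm(0.5, 0.2), "a") == ["b"]

    def test_single_treatment_study_empty_set(self):
        pm = PhiMatrix(pd.DataFrame([[1.0]], index=["a"], columns=["a"]),
                       pd.DataFrame([[0.0]], index=["a"], columns=["a"]))
        assert select_adjustment_set(pm, "a") == []

    def test_unknown_treatment_rejected(self):
        with pytest.raises(KeyError):
            select_adjustment_set(self._pm(0.1, 0.5), "zzz")


class TestRunEwas:
    def test_noise_free_effect_recovered_exactly(self, rng):
        n = 100
        exposure = rng.integers(0, 2, n).astype(float)
        cov = pd.DataFrame({"c1": rng.normal(size=n)})
        M = (1.0 * exposure + 0.5 * cov["c1"].values)[None, :]
        rec = run_ewas(_mm(M), exposure, cov)
        assert rec["beta"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        n = 20
        exposure = rng.normal(size=n)
        cov = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        Y = rng.normal(size=(5, n))
        rec = run_ewas(_mm(Y), exposure, cov)
        X = np.column_stack([np.ones(n), exposure, cov.values])
        for g in range(5):
            b, se, t, p = _ols_oracle(X, Y[g])
            assert rec["beta"].iloc[g] == pytest.approx(b, abs=1e-8)
            assert rec["se"].iloc[g] == pytest.approx(se, abs=1e-8)
            assert rec["p_raw"].iloc[g] == pytest.approx(p, abs=1e-6)

    def test_null_calibration(self, rng):
        n, g = 100, 1000
        exposure = rng.integers(0, 2, n).astype(float)
        Y = rng.normal(size=(g, n))
        rec = run_ewas(_mm(Y), exposure)
        frac = (rec["p_raw"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / g))

    def test_masked_entries_use_complete_cases(self, rng):
        n = 60
        exposure = rng.integers(0, 2, n).astype(float)
        Y = rng.normal(size=(2, n))
        Y[0, :10] = np.nan
        rec = run_ewas(_mm(Y), exposure)
        assert rec["n_used"].iloc[0] == 50 and rec["n_used"].iloc[1] == 60
        keep = ~np.isnan(Y[0])
        X = np.column_stack([np.ones(keep.sum()), exposure[keep]])
        b, se, _, p = _ols_oracle(X, Y[0, keep])
        assert rec["beta"].iloc[0] == pytest.approx(b, abs=1e-10)

    def test_constant_exposure_in_complete_cases_flagged_na(self, rng):
        n = 30
        exposure = np.zeros(n)
        exposure[:5] = 1.0
        Y = rng.normal(size=(1, n))
        Y[0, :5] = np.nan  # exposure constant among complete cases
        rec = run_ewas(_mm(Y), exposure)
        assert np.isnan(rec["beta"].iloc[0])


class TestGenomicControl:
    def test_uniform_p_lambda_near_one(self, rng):
        p = rng.uniform(size=100000)
        rec, lam = genomic_control_adjust(pd.DataFrame({"p_raw": p}))
        assert lam == pytest.approx(1.0, abs=0.03)

    def test_null_median_chi2_gives_lambda_exactly_one(self):
        p0 = stats.chi2.sf(stats.chi2.ppf(0.5, 1), 1)
        rec, lam = genomic_control_adjust(pd.DataFrame({"p_raw": np.full(200, p0)}))
        assert lam == pytest.approx(1.0, rel=1e-12)
        np.testing.assert_allclose(rec["p_gc"], rec["p_raw"])

    def test_doubled_chi2_rescaled_back_to_null(self, rng):
        chi_null = stats.chi2.rvs(1, size=2000, random_state=123)
        p_inflated = stats.chi2.sf(2.0 * chi_null, 1)
        rec, lam = genomic_control_adjust(pd.DataFrame({"p_raw": p_inflated}))
        scale = np.median(2.0 * chi_null) / stats.chi2.ppf(0.5, 1)
        assert lam == pytest.approx(scale, rel=1e-10)
        # hand-scaled oracle: chi2/lambda then back to p
        oracle = stats.chi2.sf(2.0 * chi_null / lam, 1)
        np.testing.assert_allclose(np.sort(rec["p_gc"]), np.sort(oracle), rtol=1e-8)

    def test_deflation_never_applied(self, rng):
        p = np.clip(rng.uniform(size=500) ** 0.5, 1e-12, 1)  # deflated stats
        rec, lam = genomic_control_adjust(pd.DataFrame({"p_raw": p}))
        assert lam < 1
        np.testing.assert_array_equal(rec["p_gc"], rec["p_raw"])

    def test_all_na_rejected(self):
        with pytest.raises(ValueError, match="all p-values"):
            genomic_control_adjust(pd.DataFrame({"p_raw": [np.nan, np.nan]}))


class TestSignificance:
    def test_threshold_is_strict(self):
        rec = pd.DataFrame(
            {"cpg_id": ["a", "b", "c"], "p_gc": [8.9e-8, 9e-8, np.nan]}
        )
        hits = call_significant(rec)
        assert list(hits["cpg_id"]) == ["a"]

    def test_empty_input_empty_output(self):
        assert len(call_significant(pd.DataFrame({"p_gc": []}))) == 0


class TestDoseResponse:
    def test_hand_binned_tertiles(self):
        dose = np.array([0.0, 0.0, 1, 2, 3, 4, 5, 6, 7, 8, 9])
        code = ordinal_dose_code(dose)
        np.testing.assert_array_equal(code, [0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3])

    def test_boundary_ties_go_to_lower_bin(self):
        dose = np.array([0.0, 1, 1, 1, 2, 2, 2, 3, 3, 3])
        code = ordinal_dose_code(dose)
        # q1 = 1, q2 = 2 with <=-inclusive upper boundaries
        np.testing.assert_array_equal(code, [0, 1, 1, 1, 2, 2, 2, 3, 3, 3])

    def test_too_few_distinct_doses_rejected(self):
        with pytest.raises(ValueError, match="tertiles"):
            ordinal_dose_code(np.array([0, 1, 1, 2, 2]))

    def test_monotone_signal_detected(self, rng):
        n = 60
        dose = np.concatenate([np.zeros(15), rng.uniform(1, 10, 45)])
        code = ordinal_dose_code(dose)
        M = (0.5 * code + rng.normal(0, 0.01, n))[None, :]
        rec = dose_response_trend(_mm(M), dose)
        assert rec["trend_p"].iloc[0] < 1e-10 and rec["beta"].iloc[0] > 0

    def test_null_calibration(self, rng):
        n, g = 120, 1000
        dose = np.concatenate([np.zeros(30), rng.uniform(1, 10, 90)])
        Y = rng.normal(size=(g, n))
        rec = dose_response_trend(_mm(Y), dose)
        assert rec["dose_responsive"].mean() == pytest.approx(
            0.05, abs=3 * np.sqrt(0.05 * 0.95 / g)
        )


class TestPairedEwas:
    def test_identical_treatments_reduce_to_single_ewas(self, rng):
        n = 80
        t = rng.integers(0, 2, n)
        T = pd.DataFrame({"a": t, "b": t})
        Y = rng.normal(size=(4, n)) + 0.8 * t
        single = run_ewas(_mm(Y), t.astype(float))
        paired = paired_exposure_ewas(_mm(Y), T, "a", "b")
        np.testing.assert_allclose(paired["beta"], single["beta"], atol=1e-10)
        assert paired["n_used"].iloc[0] == n

    def test_discordant_samples_dropped(self, rng):
        a = np.array([1] * 100 + [0] * 100 + [1] * 50)
        b = np.array([1] * 100 + [0] * 100 + [0] * 50)
        T = pd.DataFrame({"a": a, "b": b})
        Y = rng.normal(size=(2, 250))
        rec = paired_exposure_ewas(_mm(Y), T, "a", "b")
        assert (rec["n_used"] == 200).all()

    def test_small_group_errors_with_counts(self, rng):
        a = np.array([1] * 5 + [0] * 50)
        b = np.array([1] * 5 + [0] * 50)
        Y = rng.normal(size=(1, 55))
        with pytest.raises(ValueError, match="both=5"):
            paired_exposure_ewas(_mm(Y), pd.DataFrame({"a": a, "b": b}), "a", "b")

    def test_joint_only_effect_found_by_paired_contrast(self):
        # effect present only under joint exposure: the both-vs-neither
        # contrast sees the full shift while each single EWAS is diluted
        rng = np.random.default_rng(42)
        n = 400
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        joint = (a == 1) & (b == 1)
        Y = rng.normal(0, 1, size=(1, n))
        Y[0, joint] += 2.0
        T = pd.DataFrame({"a": a, "b": b})
        paired = paired_exposure_ewas(_mm(Y), T, "a", "b")
        single = run_ewas(_mm(Y), a.astype(float), pd.DataFrame({"b": b.astype(float)}))
        assert paired["p_raw"].iloc[0] < single["p_raw"].iloc[0] * 1e-3


class TestEnrichment:
    def _annotation(self, n, cats, rng):
        return pd.DataFrame(
            {
                "cpg_id": [f"cg{i}" for i in range(n)],
                "island_category": rng.choice(cats, n),
                "region": rng.choice(["body", "intergenic"], n),
            }
        )

    def test_hand_arithmetic_odds_ratio(self):
        # hit-in=10, hit-out=90, bg-in=100, bg-out=9900 -> sample OR 11.0
        n = 10000
        ann = pd.DataFrame(
            {
                "cpg_id": [f"cg{i}" for i in range(n)],
                "island_category": ["open_sea"] * 100 + ["island"] * 9900,
                "region": ["body"] * n,
            }
        )
        hits = [f"cg{i}" for i in range(10)] + [f"cg{i}" for i in range(100, 190)]
        out = annotation_enrichment(hits, ann, list(ann["cpg_id"]))
        row = out.loc[out["category"] == "open_sea"].iloc[0]
        assert row["odds_ratio"] == pytest.approx(11.0, abs=1e-12)
        # exact-test oracle: scipy's conditional MLE and Fisher p on same table
        oref = stats.contingency.odds_ratio([[10, 90], [100, 9900]])
        assert row["odds_ratio_cmle"] == pytest.approx(oref.statistic, rel=1e-9)
        _, pref = stats.fisher_exact([[10, 90], [100, 9900]])
        assert row["p"] == pytest.approx(pref, rel=1e-9)

    def test_uniform_hits_not_enriched(self, rng):
        ann = self._annotation(2000, ["island", "shore", "open_sea"], rng)
        hits = list(rng.choice(ann["cpg_id"], 100, replace=False))
        out = annotation_enrichment(hits, ann, list(ann["cpg_id"]))
        assert (out["p_fdr"] > 0.05).all()

    def test_complement_categories_reciprocal(self, rng):
        ann = self._annotation(500, ["in", "out"], rng)
        hits = list(rng.choice(ann["cpg_id"], 50, replace=False))
        out = annotation_enrichment(hits, ann, list(ann["cpg_id"]))
        sub = out.loc[out["annotation"] == "island_category"]
        ors = sub.set_index("category")["odds_ratio"]
        assert ors["in"] == pytest.approx(1.0 / ors["out"], rel=1e-9)

    def test_unannotated_background_rejected(self, rng):
        ann = self._annotation(10, ["island"], rng)
        with pytest.raises(KeyError, match="missing annotation"):
            annotation_enrichment(["cg0"], ann, ["cg0", "cg999"])
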