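"""Benchmark experiments exercising the whole analysis chain on synthetic
cohorts with known ground truth: null calibration of the EWAS, power to
recover injected effects, closed-form validation of the mediation engine,
and recovery of designed mediation proportions.

These are the package's standing validation experiments; the test suite
asserts on their outputs and ``scripts/acceptance.py`` reports them.
Problem sizes are chosen to finish in minutes on one core while keeping
Monte-Carlo error well inside the tolerances being checked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import chc as chc_mod
from . import ewas as ewas_mod
from . import mediate as med_mod
from . import qc as qc_mod
from .simulate import OutcomeModel, SimulationConfig, simulate_cohort

__all__ = [
    "ewas_covariates",
    "null_calibration",
    "power_recovery",
    "mediation_identity_check",
    "mediation_recovery",
    "designed_combined_mediation",
    "deconvolution_error",
]

# study conditions for the mediation-recovery experiments: treatment shifts
# the mediator CpG by DELTA on the M scale; the outcome's total logit-scale
# path is TOTAL_PATH, split between the mediated and direct routes so the
# linear-probability proportion mediated equals the designed value
DELTA = 0.8
NOISE_SD = 0.5
TOTAL_PATH = 1.0


def ewas_covariates(cohort, m_matrix, k_max: int = 10) -> pd.DataFrame:
    """Standard adjustment covariates: sex, age, estimated leukocyte
    proportions (dropping the largest subtype) and the leading methylation
    principal components."""
    cell = qc_mod.estimate_cell_proportions(m_matrix.to_beta(), cohort.reference_profiles)
    pca = qc_mod.methylation_pca(m_matrix, k_max=k_max)
    sheet = cohort.sample_sheet
    return pd.concat(
        [
            sheet[["sex", "age"]].reset_index(drop=True),
            cell.proportions.drop(columns=cell.proportions.columns[0]).reset_index(drop=True),
            pca.scores.iloc[:, : pca.k].reset_index(drop=True),
        ],
        axis=1,
    )


def _ewas_chain(seed, n_samples, n_cpgs, causal, treatment="chemo"):
    cfg = SimulationConfig(
        n_samples=n_samples,
        n_cpgs=n_cpgs,
        treatments=[("chemo", 0.5), ("radio", 0.3)],
        phi_targets=np.array([[1.0, 0.2], [0.2, 1.0]]),
        causal_cpgs=causal,
        noise_sd=NOISE_SD,
        seed=seed,
    )
    cohort = simulate_cohort(cfg)
    beta_qc, _ = qc_mod.apply_qc_filters(cohort.beta, cohort.detection_p)
    M = beta_qc.to_m()
    cov = ewas_covariates(cohort, M)
    phi = ewas_mod.phi_matrix(cohort.sample_sheet[["chemo", "radio"]])
    adj = ewas_mod.select_adjustment_set(phi, treatment)
    cov = pd.concat(
        [cov, cohort.sample_sheet[adj].astype(float).reset_index(drop=True)], axis=1
    )
    rec = ewas_mod.run_ewas(M, cohort.sample_sheet[treatment].values, cov,
                            treatment=treatment)
    rec, lam = ewas_mod.genomic_control_adjust(rec)
    return rec, lam


def null_calibration(seed: int, n_samples: int = 500, n_cpgs: int = 5000) -> dict:
    """EWAS chain with zero injected effects: lambda and the p<0.05 rate."""
    rec, lam = _ewas_chain(seed, n_samples, n_cpgs, causal={})
    p = rec["p_raw"].dropna().values
    return {
        "lambda": lam,
        "frac_p_lt_05": float((p < 0.05).mean()),
        "n_tests": int(p.size),
    }


def power_recovery(
    seed: int,
    n_causal: int = 20,
    delta: float = 0.8,
    n_samples: int = 500,
    n_cpgs: int = 2000,
) -> dict:
    """Injected-effect recovery at epigenome-wide significance.

    ``n_causal`` CpGs get a shift of ``delta`` M-units in the exposed;
    recovery = count called at p_gc < 9e-8.
    """
    causal = {"chemo": [(i, delta) for i in range(n_causal)]}
    rec, lam = _ewas_chain(seed, n_samples, n_cpgs, causal)
    hits = set(ewas_mod.call_significant(rec)["cpg_id"])
    truth = {f"cg{i:08d}" for i in range(n_causal)}
    return {
        "n_causal": n_causal,
        "n_recovered": len(hits & truth),
        "n_false": len(hits - truth),
        "lambda": lam,
    }


def mediation_identity_check(seed: int, n_params: int = 20, n: int = 300,
                             n_draws: int = 1000) -> dict:
    """Identity-link mediation vs the product-of-coefficients closed form.

    For random parameterizations, the quasi-Bayesian ACME with a linear
    outcome model must match a_hat * b_hat (fitted on the same data)
    within Monte-Carlo error; returns the worst deviation in units of the
    Monte-Carlo standard error.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_params):
        a = rng.uniform(0.2, 1.2)
        b = rng.uniform(-0.8, 0.8)
        c = rng.uniform(-0.5, 0.5)
        t = rng.integers(0, 2, n).astype(float)
        m = a * t + rng.normal(0, 1, n)
        y = b * m + c * t + rng.normal(0, 1, n)
        r = med_mod.mediate_single(
            t, m, y, n_draws=n_draws, seed=int(rng.integers(2**31)),
            outcome_family="linear",
        )
        ahat = sm.OLS(m, np.column_stack([np.ones(n), t])).fit().params[1]
        bhat = sm.OLS(y, np.column_stack([np.ones(n), t, m])).fit().params[2]
        worst = max(worst, abs(r.acme - ahat * bhat) / r.acme_mc_se)
    return {"max_abs_deviation_mc_se": worst, "n_params": n_params}


def _recovery_cohort(prop: float, seed: int, n: int = 2000, n_cpgs: int = 100):
    b = prop * TOTAL_PATH / DELTA
    c = (1.0 - prop) * TOTAL_PATH
    cfg = SimulationConfig(
        n_samples=n,
        n_cpgs=n_cpgs,
        treatments=[("chemo", 0.5)],
        causal_cpgs={"chemo": [(0, DELTA)]},
        noise_sd=NOISE_SD,
        outcome_models={
            "chc": OutcomeModel(treatment_coefs={"chemo": c}, mediator_coefs={0: b})
        },
        seed=seed,
    )
    return simulate_cohort(cfg)


def _estimate_prop(cohort, n_draws: int, seed: int) -> float:
    M = cohort.beta.to_m()
    cov = ewas_covariates(cohort, M)
    resid = chc_mod.compute_residuals(M, cov)
    sheet = cohort.sample_sheet
    out_cov = sheet[["age", "sex"]].astype(float)
    r = med_mod.mediate_single(
        sheet["chemo"].values.astype(float),
        resid.values[0],
        sheet["chc_chc"].values.astype(float),
        None,
        out_cov,
        n_draws=n_draws,
        seed=seed,
    )
    return r.prop_mediated


def mediation_recovery(
    seed: int,
    designs: tuple = (0.10, 0.35, 0.55, 0.70),
    n_reps: int = 50,
    n: int = 2000,
    n_draws: int = 1000,
) -> dict:
    """Recovery of designed mediation proportions over replicate cohorts.

    ``n_reps`` cohorts cycle through the designed proportions; each is
    simulated, residualized and pushed through the mediation engine, and
    the absolute error against the design is recorded.
    """
    rng = np.random.default_rng(seed)
    errs: dict[float, list] = {d: [] for d in designs}
    for i in range(n_reps):
        d = designs[i % len(designs)]
        co = _recovery_cohort(d, seed=int(rng.integers(2**31)), n=n)
        est = _estimate_prop(co, n_draws, seed=int(rng.integers(2**31)))
        errs[d].append(abs(est - d))
    all_errs = [e for v in errs.values() for e in v]
    return {
        "mae": float(np.mean(all_errs)),
        "per_design_mae": {d: float(np.mean(v)) for d, v in errs.items()},
        "n_reps": n_reps,
    }


def designed_combined_mediation(seed: int, prop: float = 0.70, n: int = 2000,
                                n_draws: int = 1000, n_reps: int = 8) -> dict:
    """Combined-score mediation on cohorts designed for a target proportion.

    Mirrors the headline analysis: build the combined residual-M score and
    run the mediation engine with it as the mediator.  The percent
    mediation and total-effect odds ratio are averaged over ``n_reps``
    replicate cohorts (a single cohort at this sample size carries a
    sampling standard deviation of roughly 8-9 percentage points).
    """
    rng = np.random.default_rng(seed)
    pcts, ors = [], []
    for _ in range(n_reps):
        co = _recovery_cohort(prop, seed=int(rng.integers(2**31)), n=n)
        M = co.beta.to_m()
        cov = ewas_covariates(co, M)
        resid = chc_mod.compute_residuals(M, cov)
        sheet = co.sample_sheet
        out_cov = sheet[["age", "sex"]].astype(float)
        score = med_mod.combined_score([resid.cpg_ids[0]], resid)
        r = med_mod.mediate_combined(
            sheet["chemo"].values.astype(float),
            score,
            sheet["chc_chc"].values.astype(float),
            None,
            out_cov,
            n_draws=n_draws,
            seed=int(rng.integers(2**31)),
        )
        pcts.append(r.pct_mediation)
        ors.append(r.total_or)
    return {
        "pct_mediation": float(np.mean(pcts)),
        "designed_pct": 100.0 * prop,
        "total_or": float(np.mean(ors)),
        "n_reps": n_reps,
    }


def deconvolution_error(seed: int, noise_sd: float, n_samples: int = 50,
                        n_cpgs: int = 600) -> float:
    """Max absolute error of recovered Dirichlet mixing weights."""
    cfg = SimulationConfig(
        n_samples=n_samples, n_cpgs=n_cpgs, noise_sd=noise_sd, seed=seed,
        treatments=[("t", 0.5)],
    )
    co = simulate_cohort(cfg)
    cell = qc_mod.estimate_cell_proportions(co.beta, co.reference_profiles)
    return float(
        np.abs(cell.proportions.values - co.ground_truth.cell_proportions).max()
    )
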