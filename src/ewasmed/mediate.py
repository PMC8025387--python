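"""Quasi-Bayesian causal mediation analysis for a continuous mediator
(residual M value or a combined methylation score) and a binary outcome.

Two parametric models are fitted on the incident risk set:

* mediator model — OLS:      M_resid ~ treatment + co-treatment covariates
* outcome model  — logistic: CHC ~ treatment + M_resid + age + sex + PRS
  + co-treatment covariates

``n_draws`` parameter vectors are then drawn from the multivariate normal
centred at each model's MLE with its estimated covariance.  For every
draw, counterfactual mediator values M(0), M(1) are simulated from the
mediator model (sharing one residual-error draw per sample between the
two treatment arms, which cancels in the mediated contrast and keeps the
Monte-Carlo error small) and plugged into the outcome model to obtain
potential outcome probabilities.  Averaging over samples and both
reference arms gives, per draw, the average causal mediation effect
(ACME), the average direct effect (ADE) and their sum, the total effect,
all on the risk-difference scale.  Point estimates are draw means,
intervals are two-sided percentiles, and the ACME p-value is the
two-sided tail fraction of the draw distribution.

The proportion mediated is ACME / total effect; with an identity-link
outcome this reduces to the classical product-of-coefficients ratio
a*b / (a*b + c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .chc import ResidualMethylation, bh_fdr

__all__ = [
    "MediationResult",
    "CombinedScore",
    "mediate_single",
    "select_mediators",
    "prune_mediators",
    "combined_score",
    "mediate_combined",
]


@dataclass
class MediationResult:
    treatment: str
    chc: str
    mediator_id: str
    acme: float
    ade: float
    total_effect: float
    prop_mediated: float
    acme_ci: tuple[float, float]
    ade_ci: tuple[float, float]
    total_ci: tuple[float, float]
    acme_p: float
    acme_mc_se: float
    total_or: float
    n_draws: int
    seed: int
    n_used: int
    opposite_sign_warning: bool = False

    @property
    def pct_mediation(self) -> float:
        return 100.0 * self.prop_mediated

    def __post_init__(self) -> None:
        tol = max(3.0 * self.acme_mc_se, 1e-12)
        if abs(self.acme + self.ade - self.total_effect) > tol:
            raise AssertionError("ACME + ADE != total effect beyond MC tolerance")

    def to_dict(self) -> dict:
        return {
            "treatment": self.treatment,
            "chc": self.chc,
            "mediator": self.mediator_id,
            "acme": self.acme,
            "acme_lo": self.acme_ci[0],
            "acme_hi": self.acme_ci[1],
            "ade": self.ade,
            "total": self.total_effect,
            "total_or": self.total_or,
            "prop_mediated": self.prop_mediated,
            "pct_mediation": self.pct_mediation,
            "acme_p": self.acme_p,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "n_used": self.n_used,
        }


@dataclass
class CombinedScore:
    score: pd.Series  # per-sample sum of residual M values
    cpg_ids: list[str]
    n_excluded: int = 0


def _mvn_draws(rng, mean: np.ndarray, cov: np.ndarray, n: int) -> np.ndarray:
    cov = (cov + cov.T) / 2.0
    jitter = 1e-12 * np.eye(len(mean))
    L = np.linalg.cholesky(cov + jitter)
    return mean + rng.standard_normal((n, len(mean))) @ L.T


def mediate_single(
    treatment: np.ndarray | pd.Series,
    mediator: np.ndarray | pd.Series,
    outcome: np.ndarray | pd.Series,
    mediator_covariates: pd.DataFrame | None = None,
    outcome_covariates: pd.DataFrame | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    outcome_family: str = "logistic",
    treatment_name: str = "treatment",
    chc: str = "chc",
    mediator_id: str = "mediator",
) -> MediationResult:
    """ACME / ADE / total-effect estimation for one (treatment, mediator,
    CHC) triple.  See the module docstring for the algorithm.

    ``outcome_family`` is ``"logistic"`` (binary CHC; effects on the
    risk-difference scale) or ``"linear"`` (identity link, used for
    closed-form validation).
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    t = np.asarray(treatment, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    mc = (
        np.asarray(mediator_covariates, dtype=float)
        if mediator_covariates is not None and mediator_covariates.shape[1] > 0
        else np.empty((t.size, 0))
    )
    oc = (
        np.asarray(outcome_covariates, dtype=float)
        if outcome_covariates is not None and outcome_covariates.shape[1] > 0
        else np.empty((t.size, 0))
    )
    ok = (
        np.isfinite(t)
        & np.isfinite(m)
        & np.isfinite(y)
        & np.all(np.isfinite(mc), axis=1)
        & np.all(np.isfinite(oc), axis=1)
    )
    t, m, y, mc, oc = t[ok], m[ok], y[ok], mc[ok], oc[ok]
    n = t.size
    if n < 20:
        raise ValueError(f"only {n} complete cases; too few for mediation")

    # mediator model: M ~ 1 + T + mc
    Xm = np.column_stack([np.ones(n), t, mc])
    med_fit = sm.OLS(m, Xm).fit()
    sigma = float(np.sqrt(med_fit.scale))

    # outcome model: Y ~ 1 + T + M + oc
    Xy = np.column_stack([np.ones(n), t, m, oc])
    if outcome_family == "logistic":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out_fit = sm.Logit(y, Xy).fit(disp=0, maxiter=200)
        if not out_fit.mle_retvals.get("converged", False):
            raise RuntimeError("outcome model did not converge")
        # total-effect OR from the outcome model without the mediator
        Xt = np.column_stack([np.ones(n), t, oc])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tot_fit = sm.Logit(y, Xt).fit(disp=0, maxiter=200)
        total_or = float(np.exp(tot_fit.params[1]))
    elif outcome_family == "linear":
        out_fit = sm.OLS(y, Xy).fit()
        total_or = float("nan")
    else:
        raise ValueError(f"unknown outcome_family {outcome_family!r}")

    rng = np.random.default_rng(seed)
    Bm = _mvn_draws(rng, med_fit.params, np.asarray(med_fit.cov_params()), n_draws)
    By = _mvn_draws(rng, out_fit.params, np.asarray(out_fit.cov_params()), n_draws)
    eps = rng.standard_normal((n_draws, n)) * sigma

    # counterfactual mediators per draw x sample
    Xm0 = Xm.copy(); Xm0[:, 1] = 0.0
    Xm1 = Xm.copy(); Xm1[:, 1] = 1.0
    M0 = Bm @ Xm0.T + eps
    M1 = Bm @ Xm1.T + eps

    # outcome linear predictor pieces: eta = base(t_out) + b_M * M
    oc_part = By[:, 3:] @ oc.T if oc.shape[1] else 0.0
    base0 = By[:, [0]] + oc_part          # T = 0
    base1 = base0 + By[:, [1]]            # T = 1
    bM = By[:, [2]]
    link = expit if outcome_family == "logistic" else (lambda x: x)

    def ymean(base, M):
        return link(base + bM * M).mean(axis=1)

    acme0 = ymean(base0, M1) - ymean(base0, M0)
    acme1 = ymean(base1, M1) - ymean(base1, M0)
    ade0 = ymean(base1, M0) - ymean(base0, M0)
    ade1 = ymean(base1, M1) - ymean(base0, M1)
    acme_d = 0.5 * (acme0 + acme1)
    ade_d = 0.5 * (ade0 + ade1)
    total_d = acme_d + ade_d

    def ci(d):
        lo, hi = np.percentile(d, [2.5, 97.5])
        return float(lo), float(hi)

    acme = float(acme_d.mean())
    ade = float(ade_d.mean())
    total = float(total_d.mean())
    prop = acme / total if total != 0 else float("nan")
    opposite = bool(np.isfinite(prop) and (prop < 0 or prop > 1))
    if opposite:
        warnings.warn(
            f"proportion mediated {prop:.3f} outside [0, 1] for "
            f"({treatment_name}, {mediator_id}, {chc}) — ACME and direct "
            "effect disagree in sign; reported unclamped"
        )
    n_neg = int((acme_d < 0).sum())
    n_pos = int((acme_d > 0).sum())
    p = 2.0 * min(n_neg, n_pos) / n_draws
    p = float(min(max(p, 1.0 / n_draws), 1.0))
    return MediationResult(
        treatment=treatment_name,
        chc=chc,
        mediator_id=mediator_id,
        acme=acme,
        ade=ade,
        total_effect=total,
        prop_mediated=float(prop),
        acme_ci=ci(acme_d),
        ade_ci=ci(ade_d),
        total_ci=ci(total_d),
        acme_p=p,
        acme_mc_se=float(acme_d.std(ddof=1) / np.sqrt(n_draws)),
        total_or=total_or,
        n_draws=n_draws,
        seed=seed,
        n_used=n,
        opposite_sign_warning=opposite,
    )


def select_mediators(
    results: list[MediationResult], fdr_q: float = 0.05
) -> pd.DataFrame:
    """BH-FDR over candidate CpGs within each (treatment, CHC) pair.

    Returns the FDR-significant records with an ``acme_p_fdr`` column.
    """
    if not results:
        raise ValueError("empty candidate list")
    df = pd.DataFrame([r.to_dict() for r in results])
    df["acme_p_fdr"] = np.nan
    for (_, _), idx in df.groupby(["treatment", "chc"]).groups.items():
        df.loc[idx, "acme_p_fdr"] = bh_fdr(df.loc[idx, "acme_p"].values)
    return df.loc[df["acme_p_fdr"] < fdr_q].copy()


def prune_mediators(
    candidates: pd.DataFrame,
    resid: ResidualMethylation,
    r2_threshold: float = 0.05,
) -> list[str]:
    """Top-down correlation pruning of significant mediator CpGs.

    Candidates are sorted by estimated ACME in decreasing order (ties
    broken lexicographically by CpG id); a CpG is kept iff the squared
    Pearson correlation of its residual M with every already-kept CpG is
    below the threshold.
    """
    if candidates.empty:
        raise ValueError("no candidate mediators to prune")
    order = candidates.sort_values(
        ["acme", "mediator"], ascending=[False, True], kind="mergesort"
    )["mediator"].tolist()
    idx = {c: i for i, c in enumerate(resid.cpg_ids)}
    kept: list[str] = []
    for cpg in order:
        x = resid.values[idx[cpg]]
        ok_all = True
        for k in kept:
            yv = resid.values[idx[k]]
            both = np.isfinite(x) & np.isfinite(yv)
            r = np.corrcoef(x[both], yv[both])[0, 1]
            if r * r >= r2_threshold:
                ok_all = False
                break
        if ok_all:
            kept.append(cpg)
    return kept


def combined_score(cpg_ids: list[str], resid: ResidualMethylation) -> CombinedScore:
    """Per-sample sum of residual M values over the pruned mediator CpGs.

    Samples missing a residual at any constituent CpG get a NaN score and
    drop out of combined analyses (logged via the ``n_excluded`` count).
    """
    if not cpg_ids:
        raise ValueError("combined score needs at least one CpG")
    idx = {c: i for i, c in enumerate(resid.cpg_ids)}
    rows = [idx[c] for c in cpg_ids]
    vals = resid.values[rows, :]
    score = vals.sum(axis=0)
    incomplete = ~np.all(np.isfinite(vals), axis=0)
    score = np.where(incomplete, np.nan, score)
    n_excl = int(incomplete.sum())
    if n_excl:
        warnings.warn(f"{n_excl} samples lack a residual at a score CpG; excluded")
    return CombinedScore(
        pd.Series(score, index=resid.sample_ids, name="combined_score"),
        list(cpg_ids),
        n_excl,
    )


def mediate_combined(
    treatment,
    score: CombinedScore,
    outcome,
    mediator_covariates: pd.DataFrame | None = None,
    outcome_covariates: pd.DataFrame | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    treatment_name: str = "treatment",
    chc: str = "chc",
) -> MediationResult:
    """Mediation with the combined methylation score as the mediator."""
    return mediate_single(
        treatment,
        score.score.values,
        outcome,
        mediator_covariates,
        outcome_covariates,
        n_draws=n_draws,
        seed=seed,
        treatment_name=treatment_name,
        chc=chc,
        mediator_id="combined",
    )
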