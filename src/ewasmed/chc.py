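"""Association of treatment-associated CpGs with incident chronic health
conditions (CHCs).

Methylation enters as residual M values — the part of each CpG's M value
not explained by sex, age, leukocyte proportions and the genetic and
methylation principal components (treatments deliberately left out, so
the treatment-driven signal survives in the residual).  Each residual is
tested against incident CHC status in a logistic model adjusted for age,
sex and the CHC-specific polygenic risk score, with Benjamini-Hochberg
FDR across CpGs.  Survivors whose condition predates the blood draw are
excluded from that condition's risk set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .qc import MethylationMatrix

__all__ = [
    "ResidualMethylation",
    "compute_residuals",
    "filter_incident",
    "associate_chc",
    "bh_fdr",
    "incidence_summary",
    "proportion_ci",
]


@dataclass
class ResidualMethylation:
    """CpG x sample residual M values plus the covariates regressed out."""

    values: np.ndarray
    cpg_ids: list[str]
    sample_ids: list[str]
    covariate_names: list[str]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[0]

    def as_matrix(self) -> MethylationMatrix:
        return MethylationMatrix(
            self.values, self.cpg_ids, self.sample_ids, scale="M"
        )


def compute_residuals(
    mm: MethylationMatrix, covariates: pd.DataFrame | None = None
) -> ResidualMethylation:
    """Per-CpG OLS residual of M on the covariates (intercept always included).

    Complete-case on the mask per CpG; masked entries stay NaN.  A
    rank-deficient design leaves the CpG all-NaN.
    """
    if mm.scale != "M":
        raise ValueError("residuals are computed on the M scale")
    n = mm.n_samples
    if covariates is None or covariates.shape[1] == 0:
        C = np.ones((n, 1))
        names = ["intercept"]
    else:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        names = ["intercept"] + list(covariates.columns)
    base_ok = np.all(np.isfinite(C), axis=1)
    out = np.full_like(mm.values, np.nan)
    Y = mm.values  # CpG x sample
    complete = ~mm.mask[:, base_ok].any(axis=1) if base_ok.any() else np.zeros(mm.n_cpgs, bool)

    def resid_block(rows_ok: np.ndarray, cpgs: np.ndarray) -> None:
        X = C[rows_ok]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            return
        Yb = Y[np.ix_(cpgs, np.flatnonzero(rows_ok))].T  # n_ok x n_cpg
        coef, *_ = np.linalg.lstsq(X, Yb, rcond=None)
        R = Yb - X @ coef
        out[np.ix_(cpgs, np.flatnonzero(rows_ok))] = R.T

    cc = np.flatnonzero(complete)
    if cc.size:
        resid_block(base_ok, cc)
    rest = np.setdiff1d(np.arange(mm.n_cpgs), cc)
    for g in rest:
        ok = base_ok & ~mm.mask[g]
        if ok.sum() > C.shape[1]:
            resid_block(ok, np.array([g]))
    return ResidualMethylation(out, list(mm.cpg_ids), list(mm.sample_ids), names)


def filter_incident(sample_sheet: pd.DataFrame, chc: str) -> pd.Series:
    """Boolean risk-set indicator for one CHC.

    Excludes survivors whose condition began before the blood draw
    (prevalent flag 1) and, with a warning, anyone with a missing flag.
    """
    status_col, prev_col = f"chc_{chc}", f"prevalent_{chc}"
    for col in (status_col, prev_col):
        if col not in sample_sheet.columns:
            raise KeyError(f"sample sheet lacks column {col!r}")
    prev = sample_sheet[prev_col]
    n_na = int(prev.isna().sum())
    if n_na:
        warnings.warn(f"{n_na} samples missing onset-timing flag for {chc!r}; excluded")
    in_risk = prev.notna() & (pd.to_numeric(prev, errors="coerce") == 0)
    return in_risk.rename(f"risk_set_{chc}")


def _logit_fit(X: np.ndarray, y: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        res = model.fit(disp=0, maxiter=100)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("logistic fit did not converge")
    if np.abs(res.params).max() > 50:
        raise RuntimeError("complete or quasi-complete separation suspected")
    return res


def associate_chc(
    resid: ResidualMethylation,
    status: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    chc: str = "chc",
    min_group: int = 10,
) -> pd.DataFrame:
    """Per-CpG logistic regression of incident CHC status on residual M.

    ``covariates`` holds age, sex and the CHC-specific PRS (already
    restricted to the risk set, like ``status`` and the residual columns).
    Returns one record per CpG with the Wald test on the residual-M
    coefficient; non-convergent or separated fits come back NaN-flagged.
    """
    y = np.asarray(status, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if y.size != len(resid.sample_ids):
        raise ValueError("status length does not match residual samples")
    rows = []
    for g in range(resid.n_cpgs):
        m = resid.values[g]
        ok = np.isfinite(m) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
        n_cases = int((y[ok] == 1).sum())
        n_controls = int((y[ok] == 0).sum())
        rec = {
            "cpg_id": resid.cpg_ids[g],
            "chc": chc,
            "or": np.nan,
            "log_or": np.nan,
            "se": np.nan,
            "p": np.nan,
            "n_cases": n_cases,
            "n_controls": n_controls,
            "note": "",
        }
        if n_cases < min_group or n_controls < min_group:
            rec["note"] = "too few cases or controls"
            rows.append(rec)
            continue
        X = np.column_stack([np.ones(ok.sum()), m[ok], C[ok]])
        try:
            res = _logit_fit(X, y[ok])
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            rec["note"] = str(exc)
            rows.append(rec)
            continue
        b, s = res.params[1], res.bse[1]
        rec.update(
            {
                "or": float(np.exp(b)),
                "log_or": float(b),
                "se": float(s),
                "p": float(2 * stats.norm.sf(abs(b / s))),
            }
        )
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p"].values)
    return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    NaN entries pass through as NaN and do not occupy ranks.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def proportion_ci(
    count: int, nobs: int, alpha: float = 0.05, method: str = "wald"
) -> tuple[float, float]:
    """Binomial CI for an incidence proportion (Wald default, configurable)."""
    from statsmodels.stats.proportion import proportion_confint

    method = {"wald": "normal"}.get(method, method)
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method=method)
    return float(lo), float(hi)


def incidence_summary(
    sample_sheet: pd.DataFrame,
    chcs: list[str] | None = None,
    ci_method: str = "wald",
) -> pd.DataFrame:
    """Per-CHC incident N, N at risk, percent (1 decimal) and 95% CI.

    N at risk excludes prevalent cases; percent = 100 * incident / at-risk.
    """
    if chcs is None:
        chcs = [c[len("chc_"):] for c in sample_sheet.columns if c.startswith("chc_")]
    rows = []
    for chc in chcs:
        risk = filter_incident(sample_sheet, chc)
        at_risk = int(risk.sum())
        if at_risk == 0:
            raise ValueError(f"zero at-risk samples for {chc!r}")
        incident = int(
            (sample_sheet.loc[risk, f"chc_{chc}"].astype(int) == 1).sum()
        )
        pct = round(100.0 * incident / at_risk, 1)
        lo, hi = proportion_ci(incident, at_risk, method=ci_method)
        rows.append(
            {
                "chc": chc,
                "incident_n": incident,
                "n_at_risk": at_risk,
                "percent": pct,
                "ci_lo": round(100 * lo, 1),
                "ci_hi": round(100 * hi, 1),
            }
        )
    return pd.DataFrame(rows)
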