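"""Treatment-specific epigenome-wide association testing.

Per-CpG multiple linear regression of M values on a binary exposure (or an
ordinal dose code) plus covariates, with genomic-control inflation
correction, strict epigenome-wide significance calling, paired-exposure
contrasts and annotation enrichment.

The phi coefficient between binary treatments drives covariate selection:
a co-treatment is left out of the adjustment set when it is strongly
entangled with the exposure of interest (phi > 0.4 and p < 0.05), since
adjusting for a near-collinear exposure would absorb the signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc import MethylationMatrix

__all__ = [
    "PhiMatrix",
    "phi_matrix",
    "select_adjustment_set",
    "run_ewas",
    "genomic_control_adjust",
    "call_significant",
    "dose_response_trend",
    "paired_exposure_ewas",
    "annotation_enrichment",
    "EWAS_ALPHA",
]

EWAS_ALPHA = 9e-8  # epigenome-wide significance (5% family-wise error)
_NULL_MEDIAN_CHI2 = stats.chi2.ppf(0.5, 1)  # 0.45493...


@dataclass
class PhiMatrix:
    phi: pd.DataFrame
    p: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.phi.values
        ok = ~np.isnan(vals)
        if (np.abs(vals[ok]) > 1 + 1e-12).any():
            raise ValueError("|phi| must be <= 1")


def phi_matrix(treatments: pd.DataFrame) -> PhiMatrix:
    """Pairwise phi coefficients between binary exposures, with chi-square p.

    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) from the 2x2 table; the
    p-value comes from chi2 = n * phi^2 with 1 df.  Degenerate margins
    (an all-0 or all-1 column) yield NaN with a warning.
    """
    names = list(treatments.columns)
    k = len(names)
    phi = np.eye(k)
    pvals = np.zeros((k, k))
    X = treatments.values.astype(int)
    n = X.shape[0]
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = X[:, i], X[:, j]
            a = int(((xi == 1) & (xj == 1)).sum())
            b = int(((xi == 1) & (xj == 0)).sum())
            c = int(((xi == 0) & (xj == 1)).sum())
            d = int(((xi == 0) & (xj == 0)).sum())
            denom = (a + b) * (c + d) * (a + c) * (b + d)
            if denom == 0:
                warnings.warn(
                    f"phi undefined for pair ({names[i]!r}, {names[j]!r}): "
                    "degenerate margin"
                )
                phi[i, j] = phi[j, i] = np.nan
                pvals[i, j] = pvals[j, i] = np.nan
                continue
            ph = (a * d - b * c) / np.sqrt(denom)
            phi[i, j] = phi[j, i] = ph
            pvals[i, j] = pvals[j, i] = stats.chi2.sf(n * ph**2, 1)
    return PhiMatrix(
        pd.DataFrame(phi, index=names, columns=names),
        pd.DataFrame(pvals, index=names, columns=names),
    )


def select_adjustment_set(
    phi: PhiMatrix,
    treatment: str,
    phi_cut: float = 0.4,
    phi_p: float = 0.05,
) -> list[str]:
    """Co-treatments to adjust for: all others EXCEPT phi > 0.4 & p < 0.05."""
    if treatment not in phi.phi.index:
        raise KeyError(f"unknown treatment {treatment!r}")
    keep = []
    for other in phi.phi.index:
        if other == treatment:
            continue
        ph, p = phi.phi.loc[treatment, other], phi.p.loc[treatment, other]
        if np.isnan(ph) or not (ph > phi_cut and p < phi_p):
            keep.append(other)
    return keep


def _design(exposure: np.ndarray, covariates: pd.DataFrame | None) -> np.ndarray:
    cols = [np.ones_like(exposure, dtype=float), exposure.astype(float)]
    if covariates is not None and covariates.shape[1] > 0:
        cols.extend(np.asarray(covariates, dtype=float).T)
    return np.column_stack(cols)


def _ols_exposure_stats(X: np.ndarray, Y: np.ndarray):
    """OLS of each column of Y on X; returns stats for coefficient 1.

    Y is n x G.  Returns (beta, se, t, p, dof) arrays over G.
    """
    n, p = X.shape
    dof = n - p
    XtX = X.T @ X
    XtXi = np.linalg.inv(XtX)
    coef = XtXi @ (X.T @ Y)  # p x G
    resid = Y - X @ coef
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtXi[1, 1])
    beta = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, pvals, dof


def run_ewas(
    mm: MethylationMatrix,
    exposure: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    treatment: str = "exposure",
) -> pd.DataFrame:
    """Per-CpG OLS of M on exposure + covariates with a two-sided t-test.

    Complete-case per CpG on the missingness mask.  CpGs with a
    rank-deficient design or a constant exposure among complete cases are
    returned with NaN statistics and the pipeline continues.
    """
    if mm.scale != "M":
        raise ValueError("EWAS runs on the M scale; call .to_m() first")
    exposure = np.asarray(exposure, dtype=float)
    if exposure.size != mm.n_samples:
        raise ValueError("exposure length does not match the matrix")
    cov_arr = (
        np.asarray(covariates, dtype=float)
        if covariates is not None and covariates.shape[1] > 0
        else np.empty((mm.n_samples, 0))
    )
    base_ok = np.isfinite(exposure) & np.all(np.isfinite(cov_arr), axis=1)
    Y = mm.values.T  # n x G
    G = mm.n_cpgs
    beta = np.full(G, np.nan)
    se = np.full(G, np.nan)
    tstat = np.full(G, np.nan)
    pval = np.full(G, np.nan)
    n_used = np.zeros(G, dtype=int)

    def fit_block(rows: np.ndarray, cols: np.ndarray) -> None:
        Xb = _design(exposure[rows], pd.DataFrame(cov_arr[rows]))
        nb, pb = Xb.shape
        if nb <= pb or np.ptp(exposure[rows]) == 0:
            return
        if np.linalg.matrix_rank(Xb) < pb:
            return
        b, s, t, p, _ = _ols_exposure_stats(Xb, Y[np.ix_(rows, cols)])
        beta[cols], se[cols], tstat[cols], pval[cols] = b, s, t, p
        n_used[cols] = nb

    # fast path: CpGs complete in every base-ok sample
    rows_all = np.flatnonzero(base_ok)
    complete_cpgs = np.flatnonzero(~mm.mask[:, base_ok].any(axis=1))
    if complete_cpgs.size:
        fit_block(rows_all, complete_cpgs)
    # per-pattern path for CpGs with missingness
    rest = np.setdiff1d(np.arange(G), complete_cpgs)
    if rest.size:
        patterns: dict[bytes, list[int]] = {}
        for gidx in rest:
            key = (mm.mask[gidx] | ~base_ok).tobytes()
            patterns.setdefault(key, []).append(gidx)
        for key, cols in patterns.items():
            miss = np.frombuffer(key, dtype=bool)
            rows = np.flatnonzero(~miss)
            if rows.size:
                fit_block(rows, np.asarray(cols))

    return pd.DataFrame(
        {
            "cpg_id": mm.cpg_ids,
            "treatment": treatment,
            "beta": beta,
            "se": se,
            "t": tstat,
            "p_raw": pval,
            "n_used": n_used,
        }
    )


def genomic_control_adjust(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Median-chi-square genomic control.

    lambda = median(chi2_1(p_raw)) / chi2_1 null median; when lambda > 1
    every chi-square statistic is deflated by lambda and p recomputed,
    otherwise p_gc = p_raw (never inflate significance).  Returns the
    annotated records and lambda.
    """
    p = records["p_raw"].values.astype(float)
    finite = np.isfinite(p)
    if not finite.any():
        raise ValueError("all p-values are NA; cannot compute genomic control")
    if finite.sum() < 100:
        warnings.warn(
            f"genomic control on only {int(finite.sum())} finite p-values; "
            "lambda is unstable"
        )
    chi2 = stats.chi2.isf(p[finite], 1)
    lam = float(np.median(chi2) / _NULL_MEDIAN_CHI2)
    out = records.copy()
    p_gc = p.copy()
    if lam > 1:
        p_gc[finite] = stats.chi2.sf(chi2 / lam, 1)
    out["p_gc"] = p_gc
    out["lambda_gc"] = lam
    return out, lam


def call_significant(records: pd.DataFrame, threshold: float = EWAS_ALPHA) -> pd.DataFrame:
    """Epigenome-wide hits: p_gc strictly below the threshold."""
    if "p_gc" not in records.columns:
        raise ValueError("run genomic_control_adjust first (p_gc missing)")
    mask = records["p_gc"].values < threshold
    return records.loc[np.nan_to_num(mask, nan=False)].copy()


def ordinal_dose_code(dose: np.ndarray) -> np.ndarray:
    """0 for unexposed; exposed doses cut at tertiles into codes 1/2/3.

    Tertile boundaries are <=-inclusive on the upper side, so a dose tied
    with a boundary falls in the lower bin.
    """
    dose = np.asarray(dose, dtype=float)
    if (dose < 0).any():
        raise ValueError("doses must be nonnegative")
    exposed = dose > 0
    pos = dose[exposed]
    if np.unique(pos).size < 3:
        raise ValueError("fewer than 3 distinct positive doses; tertiles impossible")
    q1, q2 = np.quantile(pos, [1.0 / 3.0, 2.0 / 3.0])
    code = np.zeros_like(dose)
    code[exposed & (dose <= q1)] = 1
    code[exposed & (dose > q1) & (dose <= q2)] = 2
    code[exposed & (dose > q2)] = 3
    return code


def dose_response_trend(
    mm: MethylationMatrix,
    dose: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    treatment: str = "dose",
) -> pd.DataFrame:
    """Linear trend test of M on the ordinal dose code (0/1/2/3)."""
    code = ordinal_dose_code(np.asarray(dose, dtype=float))
    rec = run_ewas(mm, code, covariates, treatment=treatment)
    rec = rec.rename(columns={"p_raw": "trend_p"})
    rec["dose_responsive"] = rec["trend_p"] < 0.05
    return rec


def paired_exposure_ewas(
    mm: MethylationMatrix,
    treatments: pd.DataFrame,
    treat_a: str,
    treat_b: str,
    covariates: pd.DataFrame | None = None,
    min_group: int = 10,
) -> pd.DataFrame:
    """Both-vs-neither contrast for a treatment pair.

    Restricts to samples exposed to both or to neither treatment and runs
    the usual per-CpG regression on that binary indicator, with the two
    paired treatments removed from the covariates.
    """
    a = treatments[treat_a].values.astype(int)
    b = treatments[treat_b].values.astype(int)
    both = (a == 1) & (b == 1)
    neither = (a == 0) & (b == 0)
    if both.sum() < min_group or neither.sum() < min_group:
        raise ValueError(
            f"paired EWAS needs >= {min_group} per group; got "
            f"both={int(both.sum())}, neither={int(neither.sum())}"
        )
    keep = np.flatnonzero(both | neither)
    indicator = both[keep].astype(float)
    cov = None
    if covariates is not None:
        cov = covariates.drop(columns=[c for c in (treat_a, treat_b) if c in covariates], errors="ignore")
        cov = cov.iloc[keep].reset_index(drop=True)
    sub = mm.subset(sample_idx=keep)
    return run_ewas(sub, indicator, cov, treatment=f"{treat_a}+{treat_b}")


def annotation_enrichment(
    hits: set[str] | list[str],
    annotation: pd.DataFrame,
    background: list[str],
    columns: tuple[str, ...] = ("island_category", "region"),
) -> pd.DataFrame:
    """Per-category Fisher-exact enrichment of hits against the background.

    The comparison mirrors "hits vs overall array content": for each
    category the 2x2 table is [[hits in category, hits outside],
    [background in category, background outside]], the background row
    counting every tested CpG.  Reports the sample odds ratio ad/bc, the
    conditional-MLE odds ratio from the exact test, Fisher's two-sided p,
    and BH-FDR across all categories tested.
    """
    from .chc import bh_fdr

    hits = set(hits)
    ann = annotation.set_index("cpg_id") if "cpg_id" in annotation.columns else annotation
    missing = [c for c in background if c not in ann.index]
    if missing:
        raise KeyError(f"{len(missing)} background CpGs missing annotation, e.g. {missing[0]!r}")
    bg = ann.loc[list(background)]
    is_hit = np.array([c in hits for c in background])
    rows = []
    for col in columns:
        for cat in pd.unique(bg[col].dropna()):
            in_cat = (bg[col] == cat).values
            a = int((is_hit & in_cat).sum())
            b = int((is_hit & ~in_cat).sum())
            c = int(in_cat.sum())
            d = int((~in_cat).sum())
            table = np.array([[a, b], [c, d]])
            _, p = stats.fisher_exact(table)
            with np.errstate(divide="ignore", invalid="ignore"):
                sample_or = (a * d) / (b * c) if b * c > 0 else np.inf
            cmle_or = stats.contingency.odds_ratio(table).statistic
            rows.append(
                {
                    "annotation": col,
                    "category": cat,
                    "n_hit_in": a,
                    "n_hit_out": b,
                    "n_bg_in": a + c,
                    "odds_ratio": sample_or,
                    "odds_ratio_cmle": cmle_or,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = bh_fdr(out["p"].values)
    return out
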