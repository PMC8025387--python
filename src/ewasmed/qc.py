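"""Methylation preprocessing: QC filters, normalization, scale transforms,
leukocyte deconvolution and methylation PCA.

The analysis scale throughout the package is the M-value,
``M = log2(beta / (1 - beta))``; beta values live in [0, 1] and are what
arrays report.  Missing entries (failed detection) are carried as a boolean
mask and as NaN in the value matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "MethylationMatrix",
    "CellProportions",
    "QcReport",
    "apply_qc_filters",
    "quantile_normalize",
    "beta_to_m",
    "m_to_beta",
    "estimate_cell_proportions",
    "methylation_pca",
    "PcaResult",
]

LEUKOCYTE_TYPES = ("neutrophils", "monocytes", "CD8T", "CD4T", "NK", "B")


@dataclass
class MethylationMatrix:
    """CpG x sample methylation matrix with a missingness mask.

    Parameters
    ----------
    values
        float array, shape (n_cpgs, n_samples).  NaN where masked.
    cpg_ids, sample_ids
        Unique ordered identifiers for rows / columns.
    scale
        ``"beta"`` (values in [0, 1]) or ``"M"`` (real line).
    """

    values: np.ndarray
    cpg_ids: list[str]
    sample_ids: list[str]
    scale: str = "beta"
    mask: np.ndarray = field(default=None)  # True = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (CpG x sample)")
        n_cpg, n_samp = self.values.shape
        self.cpg_ids = list(self.cpg_ids)
        self.sample_ids = list(self.sample_ids)
        if len(self.cpg_ids) != n_cpg or len(self.sample_ids) != n_samp:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.cpg_ids)) != n_cpg:
            raise ValueError("duplicate cpg_ids")
        if len(set(self.sample_ids)) != n_samp:
            raise ValueError("duplicate sample_ids")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")
            self.values = self.values.copy()
            self.values[self.mask] = np.nan
            self.mask = self.mask | np.isnan(self.values)
        if self.scale not in ("beta", "M"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "beta":
            ok = self.values[~self.mask]
            if ok.size and ((ok < 0).any() or (ok > 1).any()):
                raise ValueError("beta-scale values outside [0, 1]")

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_m(self) -> "MethylationMatrix":
        if self.scale == "M":
            return self
        vals = np.full_like(self.values, np.nan)
        ok = ~self.mask
        vals[ok] = beta_to_m(self.values[ok])
        return MethylationMatrix(vals, self.cpg_ids, self.sample_ids, scale="M")

    def to_beta(self) -> "MethylationMatrix":
        if self.scale == "beta":
            return self
        vals = np.full_like(self.values, np.nan)
        ok = ~self.mask
        vals[ok] = m_to_beta(self.values[ok])
        return MethylationMatrix(vals, self.cpg_ids, self.sample_ids, scale="beta")

    def subset(self, cpg_idx=None, sample_idx=None) -> "MethylationMatrix":
        cpg_idx = np.arange(self.n_cpgs) if cpg_idx is None else np.asarray(cpg_idx)
        sample_idx = (
            np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        )
        return MethylationMatrix(
            self.values[np.ix_(cpg_idx, sample_idx)],
            [self.cpg_ids[i] for i in cpg_idx],
            [self.sample_ids[j] for j in sample_idx],
            scale=self.scale,
        )


@dataclass
class QcReport:
    n_masked: int
    removed_samples: list[str]
    removed_probes: list[str]

    @property
    def n_removed_samples(self) -> int:
        return len(self.removed_samples)

    @property
    def n_removed_probes(self) -> int:
        return len(self.removed_probes)

    def to_dict(self) -> dict:
        return {
            "n_masked": self.n_masked,
            "removed_samples": self.removed_samples,
            "removed_probes": self.removed_probes,
            "n_removed_samples": self.n_removed_samples,
            "n_removed_probes": self.n_removed_probes,
        }


def apply_qc_filters(
    beta: MethylationMatrix,
    detection_p: np.ndarray,
    detection_p_threshold: float = 0.01,
    missing_frac: float = 0.05,
) -> tuple[MethylationMatrix, QcReport]:
    """Mask failed detections, then drop bad samples, then bad probes.

    An entry with detection p > ``detection_p_threshold`` is set missing.
    Samples with more than ``missing_frac`` missing entries are removed
    first (so one bad sample cannot take good probes down with it), then
    probes with more than ``missing_frac`` missing entries among the
    retained samples are removed.
    """
    detection_p = np.asarray(detection_p, dtype=float)
    if detection_p.shape != beta.values.shape:
        raise ValueError("detection_p shape does not match the beta matrix")
    mask = beta.mask | (detection_p > detection_p_threshold)
    n_masked = int(mask.sum() - beta.mask.sum())

    sample_missing = mask.mean(axis=0)
    keep_samples = sample_missing <= missing_frac
    if not keep_samples.any():
        raise ValueError("QC removed every sample (all exceed the missing fraction)")
    removed_samples = [s for s, k in zip(beta.sample_ids, keep_samples) if not k]

    probe_missing = mask[:, keep_samples].mean(axis=1)
    keep_probes = probe_missing <= missing_frac
    removed_probes = [c for c, k in zip(beta.cpg_ids, keep_probes) if not k]

    vals = beta.values.copy()
    vals[mask] = np.nan
    out = MethylationMatrix(
        vals[np.ix_(keep_probes, keep_samples)],
        [c for c, k in zip(beta.cpg_ids, keep_probes) if k],
        [s for s, k in zip(beta.sample_ids, keep_samples) if k],
        scale=beta.scale,
    )
    return out, QcReport(n_masked, removed_samples, removed_probes)


def apply_exclusion_list(
    mm: MethylationMatrix, excluded: "list[str] | str"
) -> tuple[MethylationMatrix, int]:
    """Drop probes named in an exclusion list (cross-reactive probes,
    SNP-proximal probes, sex-chromosome probes, ...).

    ``excluded`` is a list of CpG ids or a path to a file with one id per
    line.  Returns the filtered matrix and the number of probes removed;
    listed ids absent from the matrix are ignored.
    """
    if isinstance(excluded, (str, bytes)) or hasattr(excluded, "read_text"):
        from pathlib import Path

        lines = Path(excluded).read_text().split()
        excluded = [x for x in lines if x]
    drop = set(excluded)
    keep = [i for i, c in enumerate(mm.cpg_ids) if c not in drop]
    n_removed = mm.n_cpgs - len(keep)
    if n_removed == 0:
        return mm, 0
    return mm.subset(cpg_idx=np.asarray(keep)), n_removed


def _reference_quantiles(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pooled mean quantile function across samples.

    Each sample's sorted unmasked values are interpolated onto a common
    probability grid (one point per CpG) and averaged; for complete data
    this is exactly the mean of the per-sample order statistics.
    """
    n_cpg, n_samp = values.shape
    grid = np.linspace(0.0, 1.0, n_cpg)
    ref = np.zeros(n_cpg)
    for j in range(n_samp):
        x = np.sort(values[~mask[:, j], j])
        if x.size < 2:
            raise ValueError(f"sample column {j} has fewer than 2 unmasked values")
        ref += np.interp(grid, np.linspace(0.0, 1.0, x.size), x)
    return ref / n_samp


def quantile_normalize(mm: MethylationMatrix) -> MethylationMatrix:
    """Force every sample onto the pooled mean quantile distribution.

    The reference distribution is the across-sample mean of the per-sample
    order statistics, computed on CpGs observed in every sample.  Each
    sample's unmasked values are replaced by the reference quantile at
    their within-sample rank (linear interpolation when the sample has
    missing entries); ties receive the mean of their tied quantiles, so
    normalization is deterministic and rank-preserving.
    """
    if mm.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    ref = _reference_quantiles(mm.values, mm.mask)
    out = np.full_like(mm.values, np.nan)
    for j in range(mm.n_samples):
        ok = ~mm.mask[:, j]
        x = mm.values[ok, j]
        m = x.size
        if m < 2:
            raise ValueError(
                f"sample {mm.sample_ids[j]!r} has fewer than 2 unmasked values"
            )
        order = np.argsort(x, kind="mergesort")
        pos = np.linspace(0.0, 1.0, m)
        targets = np.interp(pos, np.linspace(0.0, 1.0, ref.size), ref)
        new = np.empty(m)
        new[order] = targets
        # ties -> mean of tied quantiles
        xs = x[order]
        start = 0
        for k in range(1, m + 1):
            if k == m or xs[k] != xs[start]:
                if k - start > 1:
                    new[order[start:k]] = targets[start:k].mean()
                start = k
        out[ok, j] = new
    return MethylationMatrix(out, mm.cpg_ids, mm.sample_ids, scale=mm.scale)


def beta_to_m(beta):
    """M = log2(beta / (1 - beta)); beta must lie strictly inside (0, 1)."""
    beta = np.asarray(beta, dtype=float)
    if ((beta <= 0) | (beta >= 1)).any():
        raise ValueError(
            "beta values must be strictly inside (0, 1); "
            "clip upstream (e.g. to [0.001, 0.999]) before transforming"
        )
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


@dataclass
class CellProportions:
    """Sample x cell-type proportion matrix from reference-based deconvolution."""

    proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    residual_norm: pd.Series

    def __post_init__(self) -> None:
        sums = self.proportions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("cell proportion rows must sum to 1")
        if (self.proportions.values < -1e-12).any():
            raise ValueError("cell proportions must be nonnegative")


def estimate_cell_proportions(
    mm: MethylationMatrix, reference: pd.DataFrame
) -> CellProportions:
    """Reference-based leukocyte deconvolution (Houseman-style).

    Solves, per sample, a nonnegative least-squares fit of the observed
    beta values at the reference's discriminating CpGs on the cell-type
    reference profiles, then renormalizes to proportions summing to one.

    Parameters
    ----------
    mm
        beta-scale matrix containing the reference CpGs.
    reference
        cell-type x CpG DataFrame of reference beta profiles.
    """
    if mm.scale != "beta":
        raise ValueError("deconvolution expects a beta-scale matrix")
    if reference.shape[0] < 2:
        raise ValueError("need at least 2 reference cell types")
    common = [c for c in reference.columns if c in set(mm.cpg_ids)]
    if not common:
        raise ValueError("no overlap between reference CpGs and the matrix")
    idx = {c: i for i, c in enumerate(mm.cpg_ids)}
    rows = [idx[c] for c in common]
    A = reference[common].values.T  # CpG x cell type
    props = np.zeros((mm.n_samples, reference.shape[0]))
    resid = np.zeros(mm.n_samples)
    for j in range(mm.n_samples):
        y = mm.values[rows, j]
        ok = ~np.isnan(y)
        w, rnorm = nnls(A[ok, :], y[ok])
        total = w.sum()
        if total <= 0:
            raise ValueError(f"deconvolution failed for sample {mm.sample_ids[j]!r}")
        props[j] = w / total
        resid[j] = rnorm
    df = pd.DataFrame(props, index=mm.sample_ids, columns=list(reference.index))
    return CellProportions(df, pd.Series(resid, index=mm.sample_ids))


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    eigenvalues: np.ndarray
    k: int
    n_imputed: int


def methylation_pca(mm: MethylationMatrix, k_max: int = 10) -> PcaResult:
    """Centered PCA of samples over CpG features (on the M scale).

    Masked entries are mean-imputed per CpG first.  The number of leading
    components ``k`` is chosen as the position of the largest relative
    eigenvalue drop (lambda_i - lambda_{i+1}) / lambda_i within the first
    ``k_max`` components, falling back to min(4, available) when the rule
    is degenerate.
    """
    if mm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = mm.values.T.copy()  # samples x CpGs
    n_imputed = int(np.isnan(X).sum())
    if n_imputed:
        col_means = np.nanmean(X, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        ii, jj = np.where(np.isnan(X))
        X[ii, jj] = col_means[jj]
    X = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (mm.n_samples - 1)
    scores = u * s
    ncomp = min(len(eig), mm.n_samples - 1)
    eig = eig[:ncomp]
    scores = scores[:, :ncomp]
    k = _choose_k(eig, k_max)
    df = pd.DataFrame(
        scores, index=mm.sample_ids, columns=[f"PC{i + 1}" for i in range(ncomp)]
    )
    return PcaResult(df, eig, k, n_imputed)


def _choose_k(eig: np.ndarray, k_max: int) -> int:
    upper = min(k_max, len(eig) - 1)
    if upper < 1 or eig[0] <= 0:
        return min(4, len(eig))
    drops = np.zeros(upper)
    for i in range(upper):
        if eig[i] > 0:
            drops[i] = (eig[i] - eig[i + 1]) / eig[i]
    if np.allclose(drops, drops[0]):
        return min(4, len(eig))
    return int(np.argmax(drops)) + 1
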