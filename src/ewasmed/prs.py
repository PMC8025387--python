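"""Polygenic risk scores: greedy LD pruning and risk-allele counting.

The panel is an ordered list of trait-associated SNPs; pruning scans it in
input order and keeps a SNP only if its squared Pearson correlation (r^2,
computed from the supplied genotype dosages) with every already-kept SNP
stays below the threshold.  The retained order therefore depends on the
input order — that ordering is part of the contract.  The score is the
unweighted sum of risk-allele dosages over the retained SNPs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["prune_snps", "compute_prs", "orient_dosages"]


def prune_snps(
    snp_ids: list[str],
    genotypes: pd.DataFrame,
    r2_threshold: float = 0.3,
) -> list[str]:
    """Greedy scan in input order; keep iff r^2 < threshold with all kept.

    Monomorphic SNPs have undefined r^2 and are dropped with a warning.
    """
    missing = [s for s in snp_ids if s not in genotypes.columns]
    if missing:
        raise KeyError(f"genotypes missing for SNPs {missing[:3]}...")
    kept: list[str] = []
    kept_vals: list[np.ndarray] = []
    for snp in snp_ids:
        x = genotypes[snp].values.astype(float)
        if np.nanstd(x) == 0:
            warnings.warn(f"SNP {snp!r} is monomorphic; r^2 undefined, dropped")
            continue
        ok = True
        for y in kept_vals:
            r = np.corrcoef(x, y)[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(snp)
            kept_vals.append(x)
    return kept


def orient_dosages(
    genotypes: pd.DataFrame,
    risk_allele: dict[str, str],
    counted_allele: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Flip dosages (2 - d) where the counted allele is not the risk allele."""
    if counted_allele is None:
        return genotypes
    out = genotypes.copy()
    for snp, risk in risk_allele.items():
        if snp in counted_allele and counted_allele[snp] != risk:
            out[snp] = 2.0 - out[snp]
    return out


def compute_prs(retained: list[str], genotypes: pd.DataFrame) -> pd.Series:
    """PRS = sum of risk-allele dosages; missing dosages mean-imputed per SNP."""
    if not retained:
        raise ValueError("no retained SNPs; cannot compute a polygenic risk score")
    G = genotypes[retained].astype(float).copy()
    n_missing = int(G.isna().sum().sum())
    if n_missing:
        warnings.warn(f"mean-imputing {n_missing} missing dosages")
        G = G.fillna(G.mean())
    return G.sum(axis=1).rename("prs")
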