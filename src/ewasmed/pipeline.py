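"""End-to-end orchestration of the analysis workflow:

simulate (or load) -> methylation QC -> deconvolution & PCs -> phi-guided
treatment EWAS with genomic control -> residual-M association with
incident CHCs (FDR) -> per-CpG mediation, mediator selection & pruning ->
combined-score mediation.

Every stage failure is re-raised tagged with the stage name, and the
manifest records the config hash, per-stage derived seeds, per-treatment
genomic-inflation lambdas and the counts entering and leaving each stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import chc as chc_mod
from . import ewas as ewas_mod
from . import mediate as med_mod
from . import prs as prs_mod
from . import qc as qc_mod
from .config import PipelineConfig, stage_seed
from .simulate import Cohort, OutcomeModel, SimulationConfig, simulate_cohort

__all__ = ["run_pipeline", "PipelineResult", "StageError", "significant_treatments"]


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


@dataclass
class PipelineResult:
    manifest: dict
    ewas: pd.DataFrame
    hits: pd.DataFrame
    chc_assoc: pd.DataFrame
    mediation: pd.DataFrame
    combined: pd.DataFrame
    cohort: Cohort
    residuals: object = None
    cell_props: object = None


def _simulation_config(cfg: PipelineConfig) -> SimulationConfig:
    sim = dict(cfg.simulation)
    if "outcome_models" in sim:
        sim["outcome_models"] = {
            k: (v if isinstance(v, OutcomeModel) else OutcomeModel(**v))
            for k, v in sim["outcome_models"].items()
        }
    for key in ("phi_targets", "maf", "dirichlet_alpha", "reference_profiles"):
        if key in sim and sim[key] is not None:
            sim[key] = np.asarray(sim[key], dtype=float)
    if "causal_cpgs" in sim:
        sim["causal_cpgs"] = {
            t: [(int(i), float(d)) for i, d in lst]
            for t, lst in sim["causal_cpgs"].items()
        }
    sim.setdefault("seed", stage_seed(cfg.seed, "simulate"))
    return SimulationConfig(**sim)


def significant_treatments(
    sheet: pd.DataFrame,
    chc: str,
    treatment_names: list[str],
    risk_mask: pd.Series,
    alpha: float = 0.05,
) -> list[str]:
    """Treatments with multivariable association p < alpha for this CHC.

    One-shot multivariable logistic of incident CHC status on all
    treatments plus age and sex, on the risk set.
    """
    sub = sheet.loc[risk_mask.values]
    y = sub[f"chc_{chc}"].astype(float).values
    X = np.column_stack(
        [np.ones(len(sub))]
        + [sub[t].astype(float).values for t in treatment_names]
        + [sub["age"].values, sub["sex"].astype(float).values]
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        pvals = fit.pvalues[1 : 1 + len(treatment_names)]
    except Exception:
        return []
    return [t for t, p in zip(treatment_names, pvals) if np.isfinite(p) and p < alpha]


def _genetic_pcs(genotypes: pd.DataFrame, n_pcs: int) -> pd.DataFrame:
    G = genotypes.values.astype(float)
    G = G - G.mean(axis=0)
    sd = G.std(axis=0)
    sd[sd == 0] = 1.0
    G = G / sd
    u, s, _ = np.linalg.svd(G, full_matrices=False)
    k = min(n_pcs, s.size)
    return pd.DataFrame(
        u[:, :k] * s[:k],
        index=genotypes.index,
        columns=[f"gPC{i + 1}" for i in range(k)],
    )


def run_pipeline(cfg: PipelineConfig, cohort: Cohort | None = None) -> PipelineResult:
    manifest: dict = {"config_hash": cfg.config_hash, "seed": cfg.seed, "stages": {}}

    # -- simulate ---------------------------------------------------------
    try:
        if cohort is None:
            sim_cfg = _simulation_config(cfg)
            cohort = simulate_cohort(sim_cfg)
            manifest["stages"]["simulate"] = {
                "seed": sim_cfg.seed,
                "n_samples": sim_cfg.n_samples,
                "n_cpgs": sim_cfg.n_cpgs,
            }
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    sheet = cohort.sample_sheet
    treatment_names = [
        c for c in sheet.columns
        if c not in ("sample_id", "age", "sex")
        and not c.startswith(("dose_", "chc_", "prevalent_"))
    ]

    # -- QC ---------------------------------------------------------------
    try:
        beta_qc, report = qc_mod.apply_qc_filters(
            cohort.beta, cohort.detection_p, cfg.detection_p, cfg.missing_frac
        )
        beta_qc = qc_mod.quantile_normalize(beta_qc)
        # clip normalized values back into the open unit interval
        vals = np.clip(beta_qc.values, 0.001, 0.999)
        vals[beta_qc.mask] = np.nan
        beta_qc = qc_mod.MethylationMatrix(
            vals, beta_qc.cpg_ids, beta_qc.sample_ids, scale="beta"
        )
        M = beta_qc.to_m()
        manifest["stages"]["qc"] = report.to_dict() | {
            "n_cpgs_kept": beta_qc.n_cpgs,
            "n_samples_kept": beta_qc.n_samples,
        }
    except Exception as exc:
        raise StageError("qc", exc) from exc
    kept_samples = set(beta_qc.sample_ids)
    sheet = sheet.loc[sheet["sample_id"].isin(kept_samples)].reset_index(drop=True)
    genotypes = cohort.genotypes.loc[beta_qc.sample_ids]

    # -- deconvolution & principal components -----------------------------
    try:
        ref = cohort.reference_profiles[
            [c for c in cohort.reference_profiles.columns if c in set(beta_qc.cpg_ids)]
        ]
        cell = qc_mod.estimate_cell_proportions(beta_qc, ref)
        pca = qc_mod.methylation_pca(M, k_max=cfg.k_max_meth_pcs)
        gpcs = _genetic_pcs(genotypes, cfg.n_genetic_pcs)
        manifest["stages"]["deconvolution"] = {
            "cell_types": list(cell.proportions.columns),
            "meth_pcs_used": pca.k,
        }
    except Exception as exc:
        raise StageError("deconvolution", exc) from exc
    # drop neutrophils (largest subtype) to break the sum-to-one collinearity
    cell_cov = cell.proportions.drop(columns=cell.proportions.columns[0])
    meth_pcs = pca.scores.iloc[:, : pca.k]
    base_cov = pd.concat(
        [
            sheet[["sex", "age"]].reset_index(drop=True),
            cell_cov.reset_index(drop=True),
            gpcs.reset_index(drop=True),
            meth_pcs.reset_index(drop=True),
        ],
        axis=1,
    )

    # -- treatment EWAS ----------------------------------------------------
    try:
        phi = ewas_mod.phi_matrix(sheet[treatment_names])
        all_recs, lambdas = [], {}
        for t in treatment_names:
            adj = ewas_mod.select_adjustment_set(phi, t, cfg.phi_cut, cfg.phi_p)
            cov = pd.concat(
                [base_cov, sheet[adj].reset_index(drop=True)], axis=1
            )
            rec = ewas_mod.run_ewas(M, sheet[t].values, cov, treatment=t)
            rec, lam = ewas_mod.genomic_control_adjust(rec)
            lambdas[t] = lam
            all_recs.append(rec)
        ewas_df = pd.concat(all_recs, ignore_index=True)
        hits = ewas_mod.call_significant(ewas_df, cfg.ewas_alpha)
        manifest["stages"]["ewas"] = {
            "lambda_gc": lambdas,
            "n_tests": len(ewas_df),
            "n_hits": len(hits),
            "hits_per_treatment": hits.groupby("treatment").size().to_dict(),
        }
    except Exception as exc:
        raise StageError("ewas", exc) from exc

    # -- residuals, PRS & CHC association ----------------------------------
    try:
        resid = chc_mod.compute_residuals(M, base_cov)
        chc_names = [c[len("chc_"):] for c in sheet.columns if c.startswith("chc_")]
        prs_by_chc = {}
        panels = getattr(cohort.ground_truth, "prs", {})
        for name in chc_names:
            panel_idx = cfg.simulation.get("prs_panels", {}).get(name)
            if panel_idx is not None:
                snp_ids = [genotypes.columns[i] for i in panel_idx]
                kept = prs_mod.prune_snps(snp_ids, genotypes, cfg.snp_r2)
                prs_by_chc[name] = prs_mod.compute_prs(kept, genotypes)
            else:
                prs_by_chc[name] = pd.Series(
                    np.zeros(len(sheet)), index=genotypes.index, name="prs"
                )
        assoc_frames = []
        hit_cpgs = {
            t: set(g["cpg_id"]) for t, g in hits.groupby("treatment")
        }
        for name in chc_names:
            risk = chc_mod.filter_incident(sheet, name)
            all_hit_ids = sorted(set().union(*hit_cpgs.values())) if hit_cpgs else []
            if not all_hit_ids:
                continue
            ridx = [resid.cpg_ids.index(c) for c in all_hit_ids]
            rsub = chc_mod.ResidualMethylation(
                resid.values[np.ix_(ridx, np.flatnonzero(risk.values))],
                all_hit_ids,
                [s for s, k in zip(resid.sample_ids, risk.values) if k],
                resid.covariate_names,
            )
            cov = pd.DataFrame(
                {
                    "age": sheet.loc[risk.values, "age"].values,
                    "sex": sheet.loc[risk.values, "sex"].astype(float).values,
                    "prs": prs_by_chc[name].values[risk.values],
                }
            )
            a = chc_mod.associate_chc(
                rsub,
                sheet.loc[risk.values, f"chc_{name}"].astype(float).values,
                cov,
                chc=name,
                min_group=cfg.min_group,
            )
            assoc_frames.append(a)
        chc_assoc = (
            pd.concat(assoc_frames, ignore_index=True)
            if assoc_frames
            else pd.DataFrame()
        )
        manifest["stages"]["chc_association"] = {
            "n_records": len(chc_assoc),
            "n_fdr_significant": int(
                (chc_assoc["p_fdr"] < cfg.fdr_q).sum()
            ) if len(chc_assoc) else 0,
        }
    except Exception as exc:
        raise StageError("chc_association", exc) from exc

    # -- mediation ---------------------------------------------------------
    try:
        med_results, combined_rows = [], []
        med_seed = stage_seed(cfg.seed, "mediation")
        if len(chc_assoc):
            sig = chc_assoc.loc[chc_assoc["p_fdr"] < cfg.fdr_q]
        else:
            sig = pd.DataFrame()
        pairs = sorted(
            {
                (t, row.chc)
                for t in hit_cpgs
                for _, row in sig.iterrows()
                if row.cpg_id in hit_cpgs[t]
            }
        )
        for (t, name) in pairs:
            cands = sorted(
                set(sig.loc[sig["chc"] == name, "cpg_id"]) & hit_cpgs[t]
            )
            if not cands:
                continue
            risk = chc_mod.filter_incident(sheet, name)
            rr = risk.values
            other_sig = [
                x
                for x in significant_treatments(sheet, name, treatment_names, risk)
                if x != t
                and x in ewas_mod.select_adjustment_set(phi, t, cfg.phi_cut, cfg.phi_p)
            ]
            med_cov = sheet.loc[rr, other_sig].astype(float).reset_index(drop=True) if other_sig else None
            out_cov = pd.concat(
                [
                    sheet.loc[rr, ["age"]].reset_index(drop=True),
                    sheet.loc[rr, ["sex"]].astype(float).reset_index(drop=True),
                    pd.DataFrame({"prs": prs_by_chc[name].values[rr]}),
                ]
                + ([sheet.loc[rr, other_sig].astype(float).reset_index(drop=True)] if other_sig else []),
                axis=1,
            )
            tvec = sheet.loc[rr, t].astype(float).values
            yvec = sheet.loc[rr, f"chc_{name}"].astype(float).values
            triple_results = []
            for cpg in cands:
                gi = resid.cpg_ids.index(cpg)
                try:
                    r = med_mod.mediate_single(
                        tvec,
                        resid.values[gi, rr],
                        yvec,
                        med_cov,
                        out_cov,
                        n_draws=cfg.n_draws,
                        seed=stage_seed(med_seed, f"{t}:{name}:{cpg}"),
                        treatment_name=t,
                        chc=name,
                        mediator_id=cpg,
                    )
                except (RuntimeError, ValueError) as exc:
                    warnings.warn(f"mediation failed for ({t}, {cpg}, {name}): {exc}")
                    continue
                triple_results.append(r)
            med_results.extend(triple_results)
            if not triple_results:
                continue
            selected = med_mod.select_mediators(triple_results, cfg.fdr_q)
            if selected.empty:
                continue
            rsub = chc_mod.ResidualMethylation(
                resid.values[:, rr],
                resid.cpg_ids,
                [s for s, k in zip(resid.sample_ids, rr) if k],
                resid.covariate_names,
            )
            pruned = med_mod.prune_mediators(selected, rsub, cfg.mediator_r2)
            score = med_mod.combined_score(pruned, rsub)
            comb = med_mod.mediate_combined(
                tvec,
                score,
                yvec,
                med_cov,
                out_cov,
                n_draws=cfg.n_draws,
                seed=stage_seed(med_seed, f"{t}:{name}:combined"),
                treatment_name=t,
                chc=name,
            )
            combined_rows.append(comb.to_dict() | {"constituents": ",".join(pruned)})
        mediation_df = pd.DataFrame([r.to_dict() for r in med_results])
        combined_df = pd.DataFrame(combined_rows)
        manifest["stages"]["mediation"] = {
            "seed": med_seed,
            "n_candidates": len(mediation_df),
            "n_combined_models": len(combined_df),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("mediation", exc) from exc

    return PipelineResult(
        manifest=manifest,
        ewas=ewas_df,
        hits=hits,
        chc_assoc=chc_assoc,
        mediation=mediation_df,
        combined=combined_df,
        cohort=cohort,
        residuals=resid,
        cell_props=cell,
    )
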