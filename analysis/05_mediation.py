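"""Causal mediation: from candidate CpGs to the combined methylation score.

For each (treatment, CHC) pair with FDR-significant CpG associations,
runs the quasi-Bayesian mediation engine per CpG, selects significant
mediators (BH-FDR on the ACME p), prunes them to an independent set
(r^2 < 0.05 on residual M, top-down by ACME), sums the survivors into a
combined score, and reports its percent mediation and the total-effect
odds ratio.  Writes mediation.tsv and mediation_combined.tsv.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from ewasmed import chc as chc_mod
from ewasmed import mediate as med_mod
from ewasmed import io as io_mod
from ewasmed.config import stage_seed
from ewasmed.experiments import ewas_covariates


def main():
    warnings.filterwarnings("ignore", category=UserWarning)
    cohort = io_mod.load_cohort(common.COHORT_DIR)
    beta_qc = io_mod.read_matrix(common.BETA_QC)
    M = beta_qc.to_m()
    sheet = cohort.sample_sheet
    hits = pd.read_csv(common.RESULTS / "hits.tsv", sep="\t")
    assoc = pd.read_csv(common.RESULTS / "chc_association.tsv", sep="\t")
    prs = pd.read_csv(common.RESULTS / "prs.csv")

    base_cov = ewas_covariates(cohort, M)
    resid = chc_mod.compute_residuals(M, base_cov)
    sig = assoc.loc[assoc["p_fdr"] < 0.05]
    hit_sets = {t: set(g["cpg_id"]) for t, g in hits.groupby("treatment")}

    all_results, combined_rows = [], []
    pairs = sorted(
        {
            (t, row.chc)
            for t in hit_sets
            for row in sig.itertuples()
            if row.cpg_id in hit_sets[t]
        }
    )
    for t, chc_name in pairs:
        cands = sorted(set(sig.loc[sig["chc"] == chc_name, "cpg_id"]) & hit_sets[t])
        risk = chc_mod.filter_incident(sheet, chc_name)
        rr = risk.values
        tvec = sheet.loc[rr, t].astype(float).values
        yvec = sheet.loc[rr, f"chc_{chc_name}"].astype(float).values
        prs_vec = prs.loc[prs["chc"] == chc_name, "prs"].values[rr]
        out_cov = pd.DataFrame(
            {
                "age": sheet.loc[rr, "age"].values,
                "sex": sheet.loc[rr, "sex"].astype(float).values,
                "prs": prs_vec,
            }
        )
        triple_results = []
        for cpg in cands:
            gi = resid.cpg_ids.index(cpg)
            r = med_mod.mediate_single(
                tvec, resid.values[gi, rr], yvec, None, out_cov,
                n_draws=1000, seed=stage_seed(common.SEED, f"{t}:{chc_name}:{cpg}"),
                treatment_name=t, chc=chc_name, mediator_id=cpg,
            )
            triple_results.append(r)
        all_results.extend(triple_results)
        selected = med_mod.select_mediators(triple_results)
        print(
            f"{t} -> {chc_name}: {len(cands)} candidate CpGs, "
            f"{len(selected)} significant mediators (ACME FDR < 0.05)"
        )
        if selected.empty:
            continue
        rsub = chc_mod.ResidualMethylation(
            resid.values[:, rr], resid.cpg_ids,
            [s for s, k in zip(resid.sample_ids, rr) if k],
            resid.covariate_names,
        )
        pruned = med_mod.prune_mediators(selected, rsub)
        score = med_mod.combined_score(pruned, rsub)
        comb = med_mod.mediate_combined(
            tvec, score, yvec, None, out_cov, n_draws=1000,
            seed=stage_seed(common.SEED, f"{t}:{chc_name}:combined"),
            treatment_name=t, chc=chc_name,
        )
        combined_rows.append(comb.to_dict() | {"constituents": ",".join(pruned)})
        print(
            f"  combined score over {len(pruned)} pruned CpGs: "
            f"{comb.pct_mediation:.1f}% mediation, total-effect OR "
            f"{comb.total_or:.2f}"
        )

    pd.DataFrame([r.to_dict() for r in all_results]).to_csv(
        common.RESULTS / "mediation.tsv", sep="\t", index=False
    )
    pd.DataFrame(combined_rows).to_csv(
        common.RESULTS / "mediation_combined.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
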