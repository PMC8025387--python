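"""Associate treatment-associated CpGs with incident CHCs.

Residualizes M values on the non-treatment covariates, builds the
CHC-specific polygenic risk scores (greedy r^2 < 0.3 pruning, risk-allele
sum), restricts each condition to its incident risk set, and fits the
per-CpG logistic models with BH-FDR.  Writes prs.csv and
chc_association.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from ewasmed import chc as chc_mod
from ewasmed import io as io_mod
from ewasmed import prs as prs_mod
from ewasmed.experiments import ewas_covariates


def main():
    cohort = io_mod.load_cohort(common.COHORT_DIR)
    beta_qc = io_mod.read_matrix(common.BETA_QC)
    M = beta_qc.to_m()
    sheet = cohort.sample_sheet
    hits = pd.read_csv(common.RESULTS / "hits.tsv", sep="\t")

    base_cov = ewas_covariates(cohort, M)
    resid = chc_mod.compute_residuals(M, base_cov)

    prs_rows = []
    prs_by_chc = {}
    for chc_name, panel_idx in common.STUDY["prs_panels"].items():
        snps = [cohort.genotypes.columns[i] for i in panel_idx]
        kept = prs_mod.prune_snps(snps, cohort.genotypes)
        score = prs_mod.compute_prs(kept, cohort.genotypes)
        prs_by_chc[chc_name] = score
        print(f"{chc_name}: PRS over {len(kept)}/{len(snps)} SNPs after pruning")
        prs_rows.append(
            pd.DataFrame({"sample_id": score.index, "chc": chc_name, "prs": score.values})
        )
    pd.concat(prs_rows).to_csv(common.RESULTS / "prs.csv", index=False)

    hit_ids = sorted(set(hits["cpg_id"]))
    ridx = [resid.cpg_ids.index(c) for c in hit_ids]
    frames = []
    for chc_name in common.STUDY["outcome_models"]:
        risk = chc_mod.filter_incident(sheet, chc_name)
        rr = risk.values
        rsub = chc_mod.ResidualMethylation(
            resid.values[np.ix_(ridx, np.flatnonzero(rr))],
            hit_ids,
            [s for s, k in zip(resid.sample_ids, rr) if k],
            resid.covariate_names,
        )
        cov = pd.DataFrame(
            {
                "age": sheet.loc[rr, "age"].values,
                "sex": sheet.loc[rr, "sex"].astype(float).values,
                "prs": prs_by_chc[chc_name].values[rr],
            }
        )
        assoc = chc_mod.associate_chc(
            rsub, sheet.loc[rr, f"chc_{chc_name}"].values, cov, chc=chc_name
        )
        n_sig = int((assoc["p_fdr"] < 0.05).sum())
        print(
            f"{chc_name}: risk set {int(rr.sum())} "
            f"({len(sheet) - int(rr.sum())} prevalent excluded); "
            f"{n_sig}/{len(assoc)} hit CpGs FDR-significant"
        )
        frames.append(assoc)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(common.RESULTS / "chc_association.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
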