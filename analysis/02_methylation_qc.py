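"""Methylation QC and preprocessing for the simulated cohort.

Masks failed detections, applies the 5% missingness filters, quantile
normalizes, estimates leukocyte proportions against the reference
profiles, and runs methylation PCA.  Writes the QC'd beta matrix,
cell-proportion estimates and PC scores under results/.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from ewasmed import io as io_mod
from ewasmed import qc as qc_mod


def main():
    cohort = io_mod.load_cohort(common.COHORT_DIR)
    beta_qc, report = qc_mod.apply_qc_filters(cohort.beta, cohort.detection_p)
    print(
        f"QC: masked {report.n_masked} entries, removed "
        f"{report.n_removed_samples} samples and {report.n_removed_probes} probes"
    )
    beta_qc = qc_mod.quantile_normalize(beta_qc)
    vals = np.clip(beta_qc.values, 0.001, 0.999)
    vals[beta_qc.mask] = np.nan
    beta_qc = qc_mod.MethylationMatrix(
        vals, beta_qc.cpg_ids, beta_qc.sample_ids, scale="beta"
    )
    io_mod.write_matrix(beta_qc, common.BETA_QC)
    with open(common.RESULTS / "qc_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    cell = qc_mod.estimate_cell_proportions(beta_qc, cohort.reference_profiles)
    cell.proportions.to_csv(common.SCRATCH / "cell_proportions.csv")
    err = np.abs(
        cell.proportions.values - cohort.ground_truth.cell_proportions
    ).max()
    print(f"deconvolution vs ground-truth proportions: max abs error {err:.3f}")

    pca = qc_mod.methylation_pca(beta_qc.to_m())
    pca.scores.iloc[:, : max(pca.k, 4)].to_csv(common.SCRATCH / "meth_pcs.csv")
    top = pca.eigenvalues[:5] / pca.eigenvalues.sum()
    print(
        f"methylation PCA kept k={pca.k} components; top-5 variance shares "
        + ", ".join(f"{v:.1%}" for v in top)
    )


if __name__ == "__main__":
    main()
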