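"""Validation experiments on cohorts with known ground truth.

Runs the standing benchmark suite — null calibration of the EWAS chain,
power for injected effects, the identity-link closed-form check of the
mediation engine, recovery of designed mediation proportions, and
deconvolution accuracy — and writes the numbers to
results/validation.json.  The same experiments back the acceptance
script; here they run at reduced replicate counts for a quick look.
"""

import json
import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from ewasmed import experiments as ex
from ewasmed.config import stage_seed


def main():
    warnings.filterwarnings("ignore", category=UserWarning)
    out = {}
    out["null"] = ex.null_calibration(stage_seed(common.SEED, "null"))
    print(
        f"null chain: lambda_gc = {out['null']['lambda']:.3f}, "
        f"p<0.05 rate = {out['null']['frac_p_lt_05']:.4f}"
    )
    out["power"] = ex.power_recovery(stage_seed(common.SEED, "power"))
    print(
        f"power: {out['power']['n_recovered']}/{out['power']['n_causal']} "
        f"injected CpGs recovered at 9e-8, {out['power']['n_false']} false"
    )
    out["identity"] = ex.mediation_identity_check(stage_seed(common.SEED, "id"))
    print(
        "identity-link mediation vs product of coefficients: worst deviation "
        f"{out['identity']['max_abs_deviation_mc_se']:.2f} MC standard errors"
    )
    out["recovery"] = ex.mediation_recovery(
        stage_seed(common.SEED, "recovery"), n_reps=16, n_draws=500
    )
    print(
        f"designed-proportion recovery (16 cohorts): MAE = "
        f"{out['recovery']['mae']:.3f}"
    )
    out["deconvolution"] = {
        "noise_free": ex.deconvolution_error(stage_seed(common.SEED, "d0"), 0.0),
        "noise_03": ex.deconvolution_error(stage_seed(common.SEED, "d3"), 0.3),
    }
    print(
        "deconvolution max error: "
        f"{out['deconvolution']['noise_free']:.2e} noise-free, "
        f"{out['deconvolution']['noise_03']:.3f} at M-noise 0.3"
    )
    common.RESULTS.mkdir(exist_ok=True)
    with open(common.RESULTS / "validation.json", "w") as fh:
        json.dump(out, fh, indent=2, default=float)


if __name__ == "__main__":
    main()
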