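"""Shared study configuration for the numbered analysis scripts.

Defines one synthetic survivor cohort emulating the structure of the real
study: four correlated treatment exposures (two chemotherapy classes, two
radiotherapy fields, with the chemotherapy pair strongly phi-correlated),
treatment-shifted CpGs, two cardiometabolic outcomes partially mediated
by methylation, and PRS SNP panels.  Every script reads this config, so
the whole analysis is reproducible from the one seed below.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"          # small summary tables
SCRATCH = ROOT / "scratch"          # large regenerable intermediates
COHORT_DIR = SCRATCH / "cohort"
BETA_QC = SCRATCH / "beta_qc.tsv"
RESULTS.mkdir(exist_ok=True)
SCRATCH.mkdir(exist_ok=True)

SEED = 20260929

STUDY = dict(
    n_samples=800,
    n_cpgs=1200,
    treatments=[
        ("alkylating", 0.58),
        ("antimetabolites", 0.50),
        ("chest_rt", 0.28),
        ("abdominal_rt", 0.20),
    ],
    # antimetabolites strongly co-occur with alkylating agents; the two
    # radiotherapy fields co-occur with each other
    phi_targets=[
        [1.0, 0.45, 0.10, 0.05],
        [0.45, 1.0, 0.05, 0.05],
        [0.10, 0.05, 1.0, 0.50],
        [0.05, 0.05, 0.50, 1.0],
    ],
    causal_cpgs={
        "alkylating": [(0, -0.9), (1, -0.8), (2, 0.8)],
        "abdominal_rt": [(10, 0.9), (11, 0.8), (12, 0.8), (13, -0.9)],
    },
    noise_sd=0.5,
    outcome_models={
        "hypercholesterolemia": dict(
            intercept=-0.8,
            treatment_coefs={"abdominal_rt": 0.3},
            mediator_coefs={10: 0.7, 11: 0.5},
            age_coef=0.2,
            prs_coef=0.2,
            prevalent_frac=0.15,
        ),
        "obesity": dict(
            intercept=0.3,
            treatment_coefs={"alkylating": 0.4},
            mediator_coefs={0: -0.5},
            sex_coef=0.2,
            prs_coef=0.2,
            prevalent_frac=0.20,
        ),
    },
    detection_fail_rate=0.005,
    n_snps=40,
    prs_panels={
        "hypercholesterolemia": list(range(0, 10)),
        "obesity": list(range(10, 20)),
    },
)


def pipeline_config(n_draws: int = 1000):
    from ewasmed.config import PipelineConfig

    return PipelineConfig(seed=SEED, n_draws=n_draws, simulation=dict(STUDY))
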