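"""Synthetic survivor-cohort generator with full ground truth.

Emulates the statistical structure the downstream analyses assume:

* correlated binary treatment exposures (Gaussian copula; target pairwise
  phi coefficients are converted to latent normal correlations by
  numerically inverting the bivariate-normal orthant probability),
* blood methylation as a Dirichlet cell-type mixture of reference beta
  profiles, with treatment effects injected as shifts (delta) on the
  M scale at designated causal CpGs plus Gaussian M-scale noise,
* detection-p matrices with an injected failure rate,
* genotype dosages in {0, 1, 2} under Hardy-Weinberg sampling,
* binary chronic-health-condition (CHC) outcomes from a logistic model on
  treatments, mediator-CpG residual M values, age, sex and a polygenic
  risk score, with a configurable fraction of cases flagged prevalent
  (onset before the blood draw).

Everything is driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .qc import MethylationMatrix, beta_to_m, m_to_beta

__all__ = [
    "OutcomeModel",
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "phi_to_latent_rho",
    "generate_treatments",
    "generate_cell_proportions",
    "default_reference_profiles",
    "generate_methylation",
    "generate_outcomes",
    "generate_genotypes",
    "simulate_cohort",
]

BETA_CLIP = (0.001, 0.999)  # keeps M values finite


@dataclass
class OutcomeModel:
    """Logistic generating model for one CHC.

    ``mediator_coefs`` act on per-CpG mean-centered M values (the
    generator's stand-in for covariate-residualized M).
    """

    intercept: float = 0.0
    treatment_coefs: dict[str, float] = field(default_factory=dict)
    mediator_coefs: dict[int, float] = field(default_factory=dict)
    age_coef: float = 0.0
    sex_coef: float = 0.0
    prs_coef: float = 0.0
    prevalent_frac: float = 0.0


@dataclass
class SimulationConfig:
    n_samples: int = 500
    n_cpgs: int = 1000
    treatments: list[tuple[str, float]] = field(
        default_factory=lambda: [("chemo", 0.5), ("radio", 0.3)]
    )
    phi_targets: np.ndarray | None = None  # treatment x treatment
    causal_cpgs: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    n_cell_types: int = 6
    reference_profiles: np.ndarray | None = None  # cell type x CpG, beta
    dirichlet_alpha: np.ndarray | None = None
    noise_sd: float = 0.5
    outcome_models: dict[str, OutcomeModel] = field(default_factory=dict)
    detection_fail_rate: float = 0.0
    n_snps: int = 20
    maf: np.ndarray | None = None
    # (source_snp, target_snp, resample_prob): target copies source, each
    # sample's dosage independently resampled with this probability -> LD block
    correlated_snp_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    prs_panels: dict[str, list[int]] = field(default_factory=dict)
    dose_scaled_effects: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, prev in self.treatments:
            if not 0 < prev < 1:
                raise ValueError(f"prevalence of {name!r} must be in (0,1)")
        for t, lst in self.causal_cpgs.items():
            for idx, delta in lst:
                if not 0 <= idx < self.n_cpgs:
                    raise ValueError(f"causal CpG index {idx} out of range for {t!r}")
                if not np.isfinite(delta):
                    raise ValueError("effect sizes must be finite")
        if self.maf is not None:
            maf = np.asarray(self.maf, float)
            if ((maf <= 0) | (maf > 0.5)).any():
                raise ValueError("minor allele frequencies must be in (0, 0.5]")

    @property
    def treatment_names(self) -> list[str]:
        return [name for name, _ in self.treatments]


@dataclass
class GroundTruth:
    causal_cpg_sets: dict[str, list[tuple[int, float]]]
    mediator_triples: list[tuple[str, int, str, float]]  # designed prop mediated
    cell_proportions: np.ndarray  # sample x cell type
    prs: dict[str, np.ndarray]
    latent_correlation: np.ndarray | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            causal_cpg_sets={
                t: [(int(i), float(x)) for i, x in lst]
                for t, lst in d["causal_cpg_sets"].items()
            },
            mediator_triples=[
                (t, int(i), chc, float(p)) for t, i, chc, p in d["mediator_triples"]
            ],
            cell_proportions=np.asarray(d["cell_proportions"], float),
            prs={k: np.asarray(v, float) for k, v in d["prs"].items()},
            latent_correlation=(
                None
                if d.get("latent_correlation") is None
                else np.asarray(d["latent_correlation"], float)
            ),
        )

    def to_dict(self) -> dict:
        return {
            "causal_cpg_sets": {
                t: [[int(i), float(d)] for i, d in lst]
                for t, lst in self.causal_cpg_sets.items()
            },
            "mediator_triples": [
                [t, int(i), chc, float(p)] for t, i, chc, p in self.mediator_triples
            ],
            "cell_proportions": self.cell_proportions.tolist(),
            "prs": {k: v.tolist() for k, v in self.prs.items()},
            "latent_correlation": (
                None
                if self.latent_correlation is None
                else self.latent_correlation.tolist()
            ),
        }


@dataclass
class Cohort:
    sample_sheet: pd.DataFrame
    beta: MethylationMatrix
    detection_p: np.ndarray
    genotypes: pd.DataFrame  # samples x SNPs, dosages
    ground_truth: GroundTruth
    reference_profiles: pd.DataFrame  # cell type x CpG


def _phi_from_rho(rho: float, t1: float, t2: float, p1: float, p2: float) -> float:
    """Phi coefficient implied by latent correlation rho at thresholds t1, t2."""
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    p11 = 1.0 - stats.norm.cdf(t1) - stats.norm.cdf(t2) + mvn.cdf([t1, t2])
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def phi_to_latent_rho(phi: float, p1: float, p2: float) -> float:
    """Invert the Gaussian-copula orthant probability for a target phi."""
    if phi == 0.0:
        return 0.0
    t1 = stats.norm.ppf(1.0 - p1)
    t2 = stats.norm.ppf(1.0 - p2)
    lo, hi = -0.999, 0.999
    f = lambda r: _phi_from_rho(r, t1, t2, p1, p2) - phi
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"target phi {phi} unattainable for prevalences {p1}, {p2}"
        )
    return brentq(f, lo, hi, xtol=1e-10)


def latent_correlation(config: SimulationConfig) -> np.ndarray:
    names = config.treatment_names
    k = len(names)
    if config.phi_targets is None:
        return np.eye(k)
    phi = np.asarray(config.phi_targets, float)
    if phi.shape != (k, k):
        raise ValueError("phi_targets shape must match number of treatments")
    if not np.allclose(phi, phi.T):
        raise ValueError("phi_targets must be symmetric")
    R = np.eye(k)
    prevs = [p for _, p in config.treatments]
    for i in range(k):
        for j in range(i + 1, k):
            R[i, j] = R[j, i] = phi_to_latent_rho(phi[i, j], prevs[i], prevs[j])
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-10:
        off = np.abs(R - np.eye(k))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            "latent correlation matrix is not positive semidefinite; "
            f"largest off-diagonal involves pair ({names[i]!r}, {names[j]!r})"
        )
    return R


def generate_treatments(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Binary treatment matrix with target prevalences and pairwise phi."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    R = latent_correlation(config)
    k = len(config.treatments)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
    Z = rng.standard_normal((config.n_samples, k)) @ L.T
    thresholds = stats.norm.ppf([1.0 - p for _, p in config.treatments])
    X = (Z > thresholds).astype(int)
    return pd.DataFrame(X, columns=config.treatment_names)


def generate_cell_proportions(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    alpha = (
        np.asarray(config.dirichlet_alpha, float)
        if config.dirichlet_alpha is not None
        # neutrophil-dominated blood-like mixture
        else np.array([20.0, 3.0, 3.0, 5.0, 2.0, 2.0])[: config.n_cell_types]
    )
    if alpha.size != config.n_cell_types:
        raise ValueError("dirichlet_alpha length must equal n_cell_types")
    return rng.dirichlet(alpha, size=config.n_samples)


def default_reference_profiles(
    n_cell_types: int, n_cpgs: int, rng: np.random.Generator
) -> np.ndarray:
    """Cell-type x CpG beta profiles with cell-type-discriminating CpGs."""
    base_m = rng.uniform(-3.0, 3.0, size=n_cpgs)
    offsets = rng.normal(0.0, 1.5, size=(n_cell_types, n_cpgs))
    return m_to_beta(np.clip(base_m + offsets, -6, 6))


def generate_methylation(
    config: SimulationConfig,
    treatments: pd.DataFrame,
    cell_props: np.ndarray,
    rng: np.random.Generator,
    reference: np.ndarray | None = None,
    doses: pd.DataFrame | None = None,
) -> tuple[MethylationMatrix, np.ndarray, np.ndarray]:
    """Mixture methylation with injected treatment effects.

    Returns (beta matrix, detection-p matrix, reference profiles).
    """
    n, g = config.n_samples, config.n_cpgs
    if reference is None:
        reference = (
            np.asarray(config.reference_profiles, float)
            if config.reference_profiles is not None
            else default_reference_profiles(config.n_cell_types, g, rng)
        )
    if reference.shape != (config.n_cell_types, g):
        raise ValueError(
            f"reference profile shape {reference.shape} does not match "
            f"(n_cell_types={config.n_cell_types}, n_cpgs={g})"
        )
    if ((reference <= 0) | (reference >= 1)).any():
        raise ValueError("reference beta profiles must be in (0, 1)")
    base_beta = cell_props @ reference  # sample x CpG
    M = beta_to_m(np.clip(base_beta, *BETA_CLIP))
    for tname, lst in config.causal_cpgs.items():
        exposed = treatments[tname].values.astype(float)
        if config.dose_scaled_effects and doses is not None:
            d = doses[tname].values
            pos = d[d > 0]
            scale = np.where(d > 0, d / np.median(pos), 0.0) if pos.size else exposed
        else:
            scale = exposed
        for idx, delta in lst:
            M[:, idx] += delta * scale
    if config.noise_sd > 0:
        M += rng.normal(0.0, config.noise_sd, size=(n, g))
    beta = np.clip(m_to_beta(M), *BETA_CLIP)
    det = rng.uniform(0.0, 0.01, size=(g, n))
    if config.detection_fail_rate > 0:
        fail = rng.random((g, n)) < config.detection_fail_rate
        det[fail] = rng.uniform(0.01, 1.0, size=int(fail.sum()))
    cpg_ids = [f"cg{i:08d}" for i in range(g)]
    sample_ids = [f"S{i:05d}" for i in range(n)]
    mm = MethylationMatrix(beta.T, cpg_ids, sample_ids, scale="beta")
    return mm, det, reference


def generate_outcomes(
    config: SimulationConfig,
    treatments: pd.DataFrame,
    methylation: MethylationMatrix,
    covariates: pd.DataFrame,
    rng: np.random.Generator,
    prs: dict[str, np.ndarray] | None = None,
    baseline_m: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binary CHC status + prevalent flags from the logistic generating model.

    The mediator term uses residual M values: M minus the cell-mixture
    baseline when ``baseline_m`` (CpG x sample) is given — i.e. exactly the
    injected treatment shift plus noise — otherwise per-CpG mean-centered
    M.  Age and sex are standardized internally so coefficient scales are
    comparable.
    """
    n = config.n_samples
    M = methylation.to_m().values  # CpG x sample
    if baseline_m is not None:
        M = M - np.asarray(baseline_m, dtype=float)
    out = {}
    for chc, model in config.outcome_models.items():
        eta = np.full(n, model.intercept, dtype=float)
        for tname, coef in model.treatment_coefs.items():
            if tname not in treatments.columns:
                raise ValueError(f"outcome model for {chc!r}: unknown treatment {tname!r}")
            eta += coef * treatments[tname].values
        for idx, coef in model.mediator_coefs.items():
            if not 0 <= idx < methylation.n_cpgs:
                raise ValueError(f"outcome model for {chc!r}: unknown CpG index {idx}")
            m = M[idx]
            eta += coef * (m - np.nanmean(m))
        if model.age_coef:
            age = covariates["age"].values
            eta += model.age_coef * (age - age.mean()) / max(age.std(), 1e-12)
        if model.sex_coef:
            eta += model.sex_coef * covariates["sex"].values
        if model.prs_coef and prs and chc in prs:
            p = prs[chc]
            eta += model.prs_coef * (p - p.mean()) / max(p.std(), 1e-12)
        prob = 1.0 / (1.0 + np.exp(-eta))
        status = (rng.random(n) < prob).astype(int)
        prevalent = np.zeros(n, dtype=int)
        if model.prevalent_frac > 0:
            cases = np.flatnonzero(status == 1)
            prevalent[cases] = (rng.random(cases.size) < model.prevalent_frac).astype(int)
        out[f"chc_{chc}"] = status
        out[f"prevalent_{chc}"] = prevalent
    return pd.DataFrame(out)


def generate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Dosage matrix (samples x SNPs), Binomial(2, maf) per SNP."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    maf = (
        np.asarray(config.maf, float)
        if config.maf is not None
        else np.full(config.n_snps, 0.3)
    )
    if ((maf <= 0) | (maf > 0.5)).any():
        raise ValueError("minor allele frequencies must be in (0, 0.5]")
    n_snps = maf.size
    G = rng.binomial(2, maf, size=(config.n_samples, n_snps)).astype(float)
    for src, tgt, resample in config.correlated_snp_pairs:
        G[:, tgt] = G[:, src]
        flip = rng.random(config.n_samples) < resample
        G[flip, tgt] = rng.binomial(2, maf[tgt], size=int(flip.sum()))
    cols = [f"rs{i + 1:06d}" for i in range(n_snps)]
    return pd.DataFrame(G, columns=cols)


def _designed_mediation_triples(config: SimulationConfig) -> list:
    """Closed-form designed proportion mediated for each (T, CpG, CHC).

    On the linear-probability scale the indirect path through CpG j is
    delta_j * b_j and the total path is sum_j delta_j b_j + c_T, so the
    designed proportion is the product-of-coefficients ratio.
    """
    triples = []
    for chc, model in config.outcome_models.items():
        for tname in model.treatment_coefs:
            deltas = dict(config.causal_cpgs.get(tname, []))
            indirect = {
                idx: deltas[idx] * b
                for idx, b in model.mediator_coefs.items()
                if idx in deltas
            }
            total = sum(indirect.values()) + model.treatment_coefs[tname]
            if not indirect:
                continue
            for idx, ab in indirect.items():
                prop = ab / total if total != 0 else np.nan
                if prop is not np.nan and abs(prop) > 2:
                    warnings.warn(
                        f"designed proportion mediated {prop:.2f} outside [-2, 2] "
                        f"for ({tname}, cg index {idx}, {chc})"
                    )
                triples.append((tname, idx, chc, float(prop)))
    return triples


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """End-to-end cohort draw: treatments, methylation, genotypes, outcomes."""
    rng = np.random.default_rng(config.seed)
    treatments = generate_treatments(config, rng)
    # cumulative doses: lognormal among the exposed, 0 otherwise
    doses = pd.DataFrame(
        {
            t: treatments[t].values
            * rng.lognormal(mean=3.0, sigma=0.5, size=config.n_samples)
            for t in config.treatment_names
        }
    )
    cell_props = generate_cell_proportions(config, rng)
    beta, det, reference = generate_methylation(
        config, treatments, cell_props, rng, doses=doses
    )
    genotypes = generate_genotypes(config, rng)
    prs = {
        chc: genotypes.values[:, panel].sum(axis=1)
        for chc, panel in config.prs_panels.items()
    }
    age = np.clip(rng.normal(34.0, 8.0, size=config.n_samples), 18.0, 66.0)
    sex = rng.integers(0, 2, size=config.n_samples)
    covs = pd.DataFrame({"age": age, "sex": sex})
    baseline_m = beta_to_m(np.clip(cell_props @ reference, *BETA_CLIP)).T  # CpG x sample
    chc = generate_outcomes(
        config, treatments, beta, covs, rng, prs=prs, baseline_m=baseline_m
    )
    sheet = pd.concat(
        [
            pd.DataFrame({"sample_id": beta.sample_ids}),
            covs,
            treatments,
            doses.add_prefix("dose_"),
            chc,
        ],
        axis=1,
    )
    gt = GroundTruth(
        causal_cpg_sets={t: list(lst) for t, lst in config.causal_cpgs.items()},
        mediator_triples=_designed_mediation_triples(config),
        cell_proportions=cell_props,
        prs={k: v.astype(float) for k, v in prs.items()},
        latent_correlation=latent_correlation(config),
    )
    genotypes.index = beta.sample_ids
    ref_df = pd.DataFrame(
        reference,
        index=[f"cell{i}" for i in range(config.n_cell_types)]
        if config.n_cell_types != 6
        else list(("neutrophils", "monocytes", "CD8T", "CD4T", "NK", "B")),
        columns=beta.cpg_ids,
    )
    return Cohort(sheet, beta, det, genotypes, gt, ref_df)
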