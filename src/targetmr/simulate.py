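"""Multi-study synthetic data with the structure a drug-target MR analysis assumes.

The generator produces individual-level cohorts (genotype dosages for four
PCSK9-locus-style SNPs, LDL cholesterol, downstream glycaemic and
anthropometric traits, binary diabetes status with an incident/prevalent
flag) and consortium-style summary-statistic records, from a single
:class:`SimulationConfig`.

Genotypes come from a Gaussian copula: each SNP's dosage is a double
thresholding of one coordinate of a latent multivariate normal, with
thresholds chosen so the marginal genotype frequencies are the (optionally
inbred) Hardy-Weinberg proportions, and the latent correlation solved
numerically so the realised genotypic r-squared hits its target.  Outcome
effects are fully mediated through LDL — the identifying assumption of the
MR design — so the per-1-mmol/L causal effect theta is the recoverable
estimand at every downstream stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .types import ConfigError, TargetMRError, TraitModel, VariantSpec

__all__ = [
    "SimulationConfig",
    "default_variants",
    "default_traits",
    "default_config",
    "coverage_config",
    "ld_sensitivity_config",
    "genotype_probs",
    "attainable_r",
    "latent_correlation",
    "sample_genotypes",
    "simulate_cohort",
    "simulate_all_cohorts",
    "emit_consortium_summary",
    "write_cohort",
    "read_cohort",
    "write_summary_records",
    "read_summary_records",
]

#: cohort TSV column order (after the per-SNP dosage columns)
COHORT_TRAIT_COLUMNS = [
    "ldl", "glucose", "hba1c", "log_insulin", "weight", "height",
    "bmi", "whr", "t2d", "case_type", "fasting",
]


def default_variants() -> List[VariantSpec]:
    """Four PCSK9-locus instruments with the published minor allele
    frequencies.  LDL effects for the first two are the printed per-allele
    estimates (-0.02, -0.34 mmol/L); the last two are plausible placeholders
    on the same scale.
    """
    return [
        VariantSpec("rs11583680", 0.14, -0.02),
        VariantSpec("rs11591147", 0.01, -0.34),
        VariantSpec("rs2479409", 0.36, -0.06),
        VariantSpec("rs11206510", 0.17, -0.10),
    ]


def default_traits() -> List[TraitModel]:
    """Calibrated outcome models: theta values are the headline per-1-mmol/L
    estimates (glucose 0.09 mmol/L, HbA1c 0.03%, weight 1.03 kg, height
    0.008 m, WHR 0.006, diabetes log-odds ln(1.29)); fasting insulin is null
    by construction.  Baselines and noise SDs are realistic adult-population
    values; diabetes baseline log-odds -2.30 gives ~9.1% prevalence.
    """
    return [
        TraitModel("glucose", "continuous", 0.09, 5.38, noise_sd=0.8, fasting_only=True),
        TraitModel("hba1c", "continuous", 0.03, 5.50, noise_sd=0.5),
        TraitModel("log_insulin", "continuous", 0.0, 4.10, noise_sd=0.6, fasting_only=True),
        TraitModel("weight", "continuous", 1.03, 78.0, noise_sd=15.0),
        TraitModel("height", "continuous", 0.008, 1.69, noise_sd=0.09),
        TraitModel("whr", "continuous", 0.006, 0.87, noise_sd=0.08),
        TraitModel("t2d", "binary", math.log(1.29), -2.30),
    ]


@dataclass
class SimulationConfig:
    """Full specification of the synthetic data-generating process."""

    n_studies: int
    n_per_study: List[int]
    variants: List[VariantSpec]
    ld_r2: np.ndarray  # target pairwise genotypic r^2, diagonal 1
    traits: List[TraitModel]
    baseline_ldl_mean: float = 3.50  # mmol/L; gives mean LDL ~3.41 after allele effects
    ldl_noise_sd: float = 0.85  # mmol/L
    hwe_inbreeding: Dict[int, float] = field(default_factory=dict)  # study index -> F
    prevalent_fraction: float = 0.5
    fasting_fraction: float = 0.7
    missing_rate: Dict[str, float] = field(default_factory=dict)  # column -> MCAR rate
    seed: int = 0

    def __post_init__(self) -> None:
        self.ld_r2 = np.asarray(self.ld_r2, dtype=float)
        self.validate()

    def validate(self) -> None:
        errors = []
        if len(self.n_per_study) != self.n_studies:
            errors.append("n_per_study length must equal n_studies")
        m = len(self.variants)
        if self.ld_r2.shape != (m, m):
            errors.append(f"ld_r2 must be {m}x{m}")
        else:
            if not np.allclose(np.diag(self.ld_r2), 1.0):
                errors.append("ld_r2 diagonal must be all 1")
            off = self.ld_r2[~np.eye(m, dtype=bool)]
            if np.any(off < 0) or np.any(off >= 1):
                errors.append("off-diagonal ld_r2 must lie in [0, 1)")
            if not np.allclose(self.ld_r2, self.ld_r2.T):
                errors.append("ld_r2 must be symmetric")
        for i, F in self.hwe_inbreeding.items():
            if not (0 <= F < 1):
                errors.append(f"inbreeding F for study {i} must be in [0,1)")
        if not (0 <= self.prevalent_fraction <= 1):
            errors.append("prevalent_fraction must be in [0,1]")
        if not (0 < self.fasting_fraction <= 1):
            errors.append("fasting_fraction must be in (0,1]")
        for col, r in self.missing_rate.items():
            if not (0 <= r < 1):
                errors.append(f"missing_rate[{col}] must be in [0,1)")
        if not (self.ldl_noise_sd > 0):
            errors.append("ldl_noise_sd must be > 0")
        if not math.isfinite(self.baseline_ldl_mean):
            errors.append("baseline_ldl_mean must be finite")
        if errors:
            raise ConfigError("; ".join(errors))

    # --- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_studies": self.n_studies,
            "n_per_study": list(map(int, self.n_per_study)),
            "variants": [asdict(v) for v in self.variants],
            "ld_r2": self.ld_r2.tolist(),
            "traits": [asdict(t) for t in self.traits],
            "baseline_ldl_mean": self.baseline_ldl_mean,
            "ldl_noise_sd": self.ldl_noise_sd,
            "hwe_inbreeding": {int(k): float(v) for k, v in self.hwe_inbreeding.items()},
            "prevalent_fraction": self.prevalent_fraction,
            "fasting_fraction": self.fasting_fraction,
            "missing_rate": dict(self.missing_rate),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["variants"] = [VariantSpec(**v) for v in d["variants"]]
        d["traits"] = [TraitModel(**t) for t in d["traits"]]
        d["ld_r2"] = np.asarray(d["ld_r2"], dtype=float)
        d["hwe_inbreeding"] = {int(k): float(v) for k, v in d.get("hwe_inbreeding", {}).items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def study_rng(self, study_index: int, stream: int = 0) -> np.random.Generator:
        """Deterministic per-study, per-stage substream.

        Seeding with the tuple (seed, stream, study_index) means adding a
        study or a stage never perturbs the draws of the others.
        """
        return np.random.default_rng([int(self.seed), int(stream), int(study_index)])


def default_config(seed: int = 0, n_studies: int = 20, n_per_study: int = 10_000) -> SimulationConfig:
    """The calibrated default world: 20 studies of 10 000, independent SNPs
    (the instruments were selected to be approximately independent), no HWE
    violations, no missingness.
    """
    variants = default_variants()
    return SimulationConfig(
        n_studies=n_studies,
        n_per_study=[n_per_study] * n_studies,
        variants=variants,
        ld_r2=np.eye(len(variants)),
        traits=default_traits(),
        seed=seed,
    )


def coverage_config(seed: int = 0) -> SimulationConfig:
    """Small configuration for repeated-replicate CI-coverage experiments.

    Drops the weakest instrument (per-allele LDL effect -0.02 mmol/L): at
    this sample size its first-stage t-statistic is ~2 and delta-method
    Wald-ratio intervals are not expected to be calibrated for weak
    instruments.  Glucose is the single outcome analysed.
    """
    variants = [
        VariantSpec("rs11591147", 0.01, -0.34),
        VariantSpec("rs2479409", 0.36, -0.06),
        VariantSpec("rs11206510", 0.17, -0.10),
    ]
    traits = [TraitModel("glucose", "continuous", 0.09, 5.38, noise_sd=0.8, fasting_only=True)]
    return SimulationConfig(
        n_studies=10,
        n_per_study=[3000] * 10,
        variants=variants,
        ld_r2=np.eye(3),
        traits=traits,
        seed=seed,
    )


def ld_sensitivity_config(seed: int = 0, n_studies: int = 10, n_per_study: int = 10_000) -> SimulationConfig:
    """Residual-LD regime: r^2 = 0.26 between the two common SNPs (the
    maximum residual correlation reported for the selected instruments),
    small LD elsewhere, for the univariable-vs-multivariable comparison.
    """
    variants = default_variants()
    r2 = np.eye(4)
    r2[0, 2] = r2[2, 0] = 0.05
    r2[2, 3] = r2[3, 2] = 0.26
    return SimulationConfig(
        n_studies=n_studies,
        n_per_study=[n_per_study] * n_studies,
        variants=variants,
        ld_r2=r2,
        traits=default_traits(),
        seed=seed,
    )


# --- genotype copula -------------------------------------------------------


def genotype_probs(maf: float, F: float = 0.0) -> np.ndarray:
    """Genotype probabilities (dosage 0, 1, 2 minor alleles) under
    Hardy-Weinberg with inbreeding coefficient F: heterozygote frequency
    2pq(1-F), homozygotes gain pqF each.
    """
    p, q = maf, 1.0 - maf
    return np.array([q * q + p * q * F, 2 * p * q * (1 - F), p * p + p * q * F])


def _thresholds(maf: float, F: float) -> np.ndarray:
    probs = genotype_probs(maf, F)
    c = np.cumsum(probs)[:2]
    return stats.norm.ppf(np.clip(c, 0.0, 1.0))


def _bvn_rect_probs(t1: np.ndarray, t2: np.ndarray, rho: float) -> np.ndarray:
    """3x3 genotype cell probabilities from a bivariate normal with
    correlation rho and double thresholds t1 (SNP A) and t2 (SNP B)."""
    hi = 1e10  # effectively +inf for the CDF
    a = np.concatenate([t1, [hi]])
    b = np.concatenate([t2, [hi]])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
                                    allow_singular=True)
    pts = np.array([[a[i], b[j]] for i in range(3) for j in range(3)])
    cdf = mvn.cdf(pts).reshape(3, 3)
    cells = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            cells[i, j] = (
                cdf[i, j]
                - (cdf[i - 1, j] if i > 0 else 0.0)
                - (cdf[i, j - 1] if j > 0 else 0.0)
                + (cdf[i - 1, j - 1] if i > 0 and j > 0 else 0.0)
            )
    return np.clip(cells, 0.0, 1.0)


def _genotypic_corr(maf_a: float, maf_b: float, rho: float, Fa: float, Fb: float) -> float:
    """Pearson correlation of the two dosage variables implied by latent rho."""
    ta, tb = _thresholds(maf_a, Fa), _thresholds(maf_b, Fb)
    cells = _bvn_rect_probs(ta, tb, rho)
    g = np.array([0.0, 1.0, 2.0])
    pa = cells.sum(axis=1)
    pb = cells.sum(axis=0)
    mu_a, mu_b = pa @ g, pb @ g
    var_a = pa @ g**2 - mu_a**2
    var_b = pb @ g**2 - mu_b**2
    e_ab = g @ cells @ g
    return float((e_ab - mu_a * mu_b) / math.sqrt(var_a * var_b))


_RHO_MAX = 0.9995


@lru_cache(maxsize=512)
def attainable_r(maf_a: float, maf_b: float, Fa: float = 0.0, Fb: float = 0.0) -> float:
    """Maximum genotypic correlation attainable by the copula (rho -> 1)."""
    return _genotypic_corr(maf_a, maf_b, _RHO_MAX, Fa, Fb)


@lru_cache(maxsize=512)
def latent_correlation(maf_a: float, maf_b: float, target_r2: float,
                       Fa: float = 0.0, Fb: float = 0.0) -> float:
    """Solve the latent normal correlation that yields the target genotypic
    r-squared (positive-correlation orientation).

    Raises :class:`ConfigError` if the target exceeds the copula-attainable
    bound for the two allele frequencies, reporting that bound.
    """
    if target_r2 == 0.0:
        return 0.0
    r_target = math.sqrt(target_r2)
    r_max = attainable_r(maf_a, maf_b, Fa, Fb)
    if r_target > r_max:
        raise ConfigError(
            f"target r^2 {target_r2:.3f} (r {r_target:.3f}) exceeds the "
            f"copula-attainable bound r {r_max:.3f} (r^2 {r_max**2:.3f}) "
            f"for mafs ({maf_a}, {maf_b})"
        )
    f = lambda rho: _genotypic_corr(maf_a, maf_b, rho, Fa, Fb) - r_target
    return float(optimize.brentq(f, 0.0, _RHO_MAX, xtol=1e-6))


def sample_genotypes(
    variants: Sequence[VariantSpec],
    ld_r2: np.ndarray,
    n: int,
    inbreeding_F: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Sample an (n x m) integer dosage matrix via the Gaussian copula.

    Marginals follow (inbred) HWE genotype frequencies; pairwise genotypic
    r-squared targets the ``ld_r2`` entries.  An explicit generation-time
    check verifies the realised correlations never exceed the attainable
    copula bound.
    """
    if not (0 <= inbreeding_F < 1):
        raise ConfigError(f"inbreeding F must be in [0,1), got {inbreeding_F}")
    rng = np.random.default_rng() if rng is None else rng
    m = len(variants)
    ld_r2 = np.asarray(ld_r2, dtype=float)
    latent = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            latent[i, j] = latent[j, i] = latent_correlation(
                variants[i].maf, variants[j].maf, float(ld_r2[i, j]),
                inbreeding_F, inbreeding_F,
            )
    eigvals = np.linalg.eigvalsh(latent)
    if eigvals[0] < -1e-8:
        raise ConfigError(
            f"latent correlation matrix is not positive semi-definite after "
            f"adjustment (smallest eigenvalue {eigvals[0]:.3e})"
        )
    chol = np.linalg.cholesky(latent + 1e-10 * np.eye(m))
    z = rng.standard_normal((n, m)) @ chol.T
    dosages = np.empty((n, m), dtype=np.int64)
    for j, v in enumerate(variants):
        t = _thresholds(v.maf, inbreeding_F)
        dosages[:, j] = np.searchsorted(t, z[:, j])
    # generation-time LD-bound check: realised |r| must respect the copula
    # maximum for each maf pair (up to Monte-Carlo noise)
    if n >= 100 and m > 1:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(dosages, rowvar=False)
        for i in range(m):
            for j in range(i + 1, m):
                bound = attainable_r(variants[i].maf, variants[j].maf,
                                     inbreeding_F, inbreeding_F)
                r_ij = corr[i, j]
                if np.isfinite(r_ij) and abs(r_ij) > bound + 6.0 / math.sqrt(n):
                    raise TargetMRError(
                        f"realised |r|={abs(r_ij):.3f} between "
                        f"{variants[i].snp_id} and {variants[j].snp_id} exceeds "
                        f"the attainable bound {bound:.3f}"
                    )
    return dosages


# --- cohorts ---------------------------------------------------------------


def simulate_cohort(
    config: SimulationConfig,
    study_index: int,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate one study's individual-level dataset.

    LDL is additive in the per-allele effects plus Gaussian noise; every
    other trait responds only to LDL (full mediation):

    * continuous: Y = baseline + theta * (baseline_ldl - LDL) + noise
    * binary:     P(case) = logistic(baseline_logodds + theta_D * (baseline_ldl - LDL))

    Diabetes cases are flagged prevalent with probability
    ``prevalent_fraction``; a ``fasting`` indicator marks individuals usable
    for fasting-only analytes.  BMI is derived as weight / height^2, never
    simulated directly.
    """
    if study_index >= config.n_studies:
        raise ConfigError(f"study_index {study_index} out of range (n_studies={config.n_studies})")
    rng = config.study_rng(study_index, stream=0) if rng is None else rng
    n = int(config.n_per_study[study_index])
    F = float(config.hwe_inbreeding.get(study_index, 0.0))
    G = sample_genotypes(config.variants, config.ld_r2, n, F, rng)

    betas = np.array([v.beta_ldl for v in config.variants])
    ldl = config.baseline_ldl_mean + G @ betas + rng.normal(0.0, config.ldl_noise_sd, n)
    ldl_lowering = config.baseline_ldl_mean - ldl  # per 1 mmol/L LOWER LDL exposure

    df = pd.DataFrame({"iid": [f"S{study_index}_{i}" for i in range(n)]})
    for j, v in enumerate(config.variants):
        df[v.snp_id] = G[:, j]
    df["ldl"] = ldl

    traits = {t.trait_name: t for t in config.traits}
    for t in config.traits:
        if t.kind == "continuous":
            df[t.trait_name] = t.baseline_mean + t.theta * ldl_lowering + rng.normal(0.0, t.noise_sd, n)
    for name in COHORT_TRAIT_COLUMNS:
        if name in ("ldl", "bmi", "t2d", "case_type", "fasting"):
            continue
        if name not in df.columns:
            df[name] = np.nan  # trait not configured in this world
    if "weight" in traits and "height" in traits:
        df["bmi"] = df["weight"] / df["height"] ** 2
    elif "bmi" not in df.columns:
        df["bmi"] = np.nan

    if "t2d" in traits:
        t = traits["t2d"]
        eta = t.baseline_mean + t.theta * ldl_lowering
        p_case = 1.0 / (1.0 + np.exp(-eta))
        case = (rng.random(n) < p_case).astype(np.int64)
        prevalent = rng.random(n) < config.prevalent_fraction
        case_type = np.where(case == 1, np.where(prevalent, "prevalent", "incident"), "none")
    else:
        case = np.zeros(n, dtype=np.int64)
        case_type = np.full(n, "none")
    df["t2d"] = case
    df["case_type"] = case_type
    df["fasting"] = (rng.random(n) < config.fasting_fraction).astype(np.int64)

    for col, rate in config.missing_rate.items():
        if rate > 0 and col in df.columns:
            mask = rng.random(n) < rate
            df.loc[mask, col] = np.nan

    df.attrs["study_id"] = f"study_{study_index:02d}"
    cols = ["iid"] + [v.snp_id for v in config.variants] + COHORT_TRAIT_COLUMNS
    return df[cols]


def simulate_all_cohorts(config: SimulationConfig) -> Dict[str, pd.DataFrame]:
    """All studies as {study_id: frame}, each from its own seed substream."""
    out = {}
    for i in range(config.n_studies):
        df = simulate_cohort(config, i)
        out[df.attrs["study_id"]] = df
    return out


# --- consortium summary records --------------------------------------------


def true_per_allele_effect(variant: VariantSpec, trait: TraitModel) -> float:
    """True per-minor-allele effect implied by full mediation:
    -theta * beta_ldl (positive when the LDL-lowering allele raises the
    trait).  For the LDL 'trait' itself this is beta_ldl."""
    return -trait.theta * variant.beta_ldl


def _per_allele_se(variant: VariantSpec, trait: Optional[TraitModel],
                   config: SimulationConfig, n_effective: int) -> float:
    """Large-sample SE of a per-allele regression coefficient:
    se^2 = sigma_resid^2 / (2 maf (1-maf) n); logistic analogue replaces
    sigma^2 with 1 / (pi (1-pi))."""
    pq2 = 2.0 * variant.maf * (1.0 - variant.maf)
    if trait is None:  # LDL itself
        sigma2 = config.ldl_noise_sd**2
    elif trait.kind == "continuous":
        sigma2 = trait.noise_sd**2 + (trait.theta * config.ldl_noise_sd) ** 2
    else:
        prev = 1.0 / (1.0 + math.exp(-trait.baseline_mean))
        sigma2 = 1.0 / (prev * (1.0 - prev))
    return math.sqrt(sigma2 / (pq2 * n_effective))


def emit_consortium_summary(
    config: SimulationConfig,
    source_id: str,
    n_effective: int,
    rng: Optional[np.random.Generator] = None,
    traits: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Consortium-style summary records drawn from the estimator's sampling
    distribution, without simulating the underlying individuals: for each
    (SNP, trait), beta ~ Normal(true per-allele effect, se^2) with the
    large-sample per-allele SE.  The LDL trait is always included.
    """
    if n_effective <= 0:
        raise ConfigError("n_effective must be > 0")
    rng = np.random.default_rng([int(config.seed), 90, abs(hash(source_id)) % (2**31)]) if rng is None else rng
    wanted = set(traits) if traits is not None else None
    rows = []
    for v in config.variants:
        targets = [("ldl", None)] + [(t.trait_name, t) for t in config.traits]
        for name, t in targets:
            if wanted is not None and name not in wanted:
                continue
            true_beta = v.beta_ldl if t is None else true_per_allele_effect(v, t)
            se = _per_allele_se(v, t, config, n_effective)
            rows.append({
                "source_id": source_id,
                "snp_id": v.snp_id,
                "trait": name,
                "effect_allele": "minor",
                "beta": rng.normal(true_beta, se),
                "se": se,
                "n": int(n_effective),
            })
    return pd.DataFrame(rows)


# --- TSV IO ----------------------------------------------------------------


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.attrs["study_id"] = Path(path).stem
    return df


def write_summary_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_summary_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
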