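"""Domain types shared across the pipeline.

The analysis is organised around a small number of record types that travel
between stages: variant and trait specifications feeding the simulator,
per-(study, SNP, trait) association estimates, inverse-variance pooled
estimates with heterogeneity statistics, and the per-1-mmol/L gene-centric
score.  All records serialise naturally to flat TSV rows via ``as_dict``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence


class TargetMRError(Exception):
    """Base class for pipeline errors."""


class ConfigError(TargetMRError):
    """Invalid configuration (aggregate messages where possible)."""


class DegenerateDataError(TargetMRError):
    """Data cannot support the requested fit (constant dosage, empty class...)."""


class SeparationError(TargetMRError):
    """Logistic fit diverged: complete or quasi-complete separation."""


class WeakInstrumentError(TargetMRError):
    """SNP-LDL effect too small to support Wald-ratio scaling."""


@dataclass(frozen=True)
class VariantSpec:
    """A genetic instrument: identity, minor allele frequency and its
    per-allele effect on LDL cholesterol.

    ``beta_ldl`` is expressed per copy of the *minor* allele and is <= 0 by
    convention: the counted allele is the LDL-lowering one.
    """

    snp_id: str
    maf: float
    beta_ldl: float

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ConfigError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")
        if self.beta_ldl > 0:
            raise ConfigError(
                f"{self.snp_id}: beta_ldl must be <= 0 (minor allele is the "
                f"LDL-lowering allele), got {self.beta_ldl}"
            )


@dataclass(frozen=True)
class TraitModel:
    """Generative model for one outcome trait.

    theta is the causal effect per 1 mmol/L *lower* LDL: trait units for
    continuous traits, log-odds for binary ones.  ``fasting_only`` marks
    analytes analysed only in fasting-flagged individuals (glucose, insulin).
    """

    trait_name: str
    kind: str  # "continuous" | "binary"
    theta: float
    baseline_mean: float  # trait units, or baseline log-odds for binary
    noise_sd: Optional[float] = None
    fasting_only: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ConfigError(f"{self.trait_name}: kind must be continuous|binary")
        if self.kind == "continuous":
            if self.noise_sd is None or not (self.noise_sd > 0):
                raise ConfigError(f"{self.trait_name}: continuous trait needs noise_sd > 0")
        elif self.noise_sd is not None:
            raise ConfigError(f"{self.trait_name}: binary trait must not set noise_sd")
        for v in (self.theta, self.baseline_mean):
            if not math.isfinite(v):
                raise ConfigError(f"{self.trait_name}: non-finite parameter {v}")


@dataclass(frozen=True)
class AssociationEstimate:
    """One (study, SNP, trait) regression result."""

    study_id: str
    snp_id: str
    trait_name: str
    beta: float
    se: float
    n: int
    model: str = "additive"  # additive | genotypic | multivariable
    scale: str = "per-allele"  # per-allele | per-mmol-lower-ldl
    flags: tuple = ()

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flags"] = ";".join(self.flags)
        return d


@dataclass(frozen=True)
class HWEResult:
    """Hardy-Weinberg goodness-of-fit for one (study, SNP)."""

    study_id: str
    snp_id: str
    counts: tuple  # (n_AA, n_Aa, n_aa) ordered by minor-allele dosage 0,1,2
    chi2: float
    p: float

    def as_dict(self) -> dict:
        n0, n1, n2 = self.counts
        return {
            "study_id": self.study_id,
            "snp_id": self.snp_id,
            "n_AA": n0,
            "n_Aa": n1,
            "n_aa": n2,
            "chi2": self.chi2,
            "p": self.p,
        }


@dataclass(frozen=True)
class LRTResult:
    """Additive vs genotypic likelihood-ratio test for one (study, SNP, trait)."""

    study_id: str
    snp_id: str
    trait_name: str
    stat: float
    df: int
    p: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class PooledEstimate:
    """An inverse-variance weighted combination with heterogeneity statistics.

    ``Q``, ``p_Q``, ``I2`` and ``I2_upper`` are only defined for k >= 2 and
    are ``None`` otherwise; ``tau2`` is populated for the random-effects
    method only.
    """

    snp_id: str
    trait_name: str
    method: str  # fixed | random
    beta: float
    se: float
    ci_low: float
    ci_high: float
    k: int
    Q: Optional[float] = None
    p_Q: Optional[float] = None
    I2: Optional[float] = None
    I2_upper: Optional[float] = None
    tau2: Optional[float] = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ScoreEstimate:
    """Gene-centric score on the per-1-mmol/L-lower-LDL scale.

    For binary traits the triple (or_, or_low, or_high) is the exponentiated
    (beta, ci_low, ci_high).
    """

    trait_name: str
    method: str
    beta_per_mmol: float
    se: float
    ci_low: float
    ci_high: float
    k_snps: int
    Q_snp: Optional[float] = None
    p_Q: Optional[float] = None
    I2_snp: Optional[float] = None
    I2_snp_upper: Optional[float] = None
    tau2: Optional[float] = None
    or_scale: Optional[tuple] = None  # (OR, low, high) for binary traits

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        or_scale = d.pop("or_scale")
        d["or"], d["or_low"], d["or_high"] = or_scale if or_scale else (None, None, None)
        return d


@dataclass(frozen=True)
class SummaryStatRecord:
    """One consortium-style summary-statistic row."""

    source_id: str
    snp_id: str
    trait_name: str
    effect_allele: str
    beta: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ConfigError(f"{self.source_id}/{self.snp_id}: se must be > 0")

    def as_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "snp_id": self.snp_id,
            "trait": self.trait_name,
            "effect_allele": self.effect_allele,
            "beta": self.beta,
            "se": self.se,
            "n": self.n,
        }


# normal 97.5% quantile used for every confidence interval (large-sample
# convention; no small-sample t adjustment)
Z975 = 1.959964
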