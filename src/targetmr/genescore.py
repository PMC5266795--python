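"""Wald-ratio scaling and the weighted gene-centric score.

Level 2 of the inference: each SNP's pooled per-allele outcome association
is rescaled by that SNP's own pooled per-allele LDL effect to a
per-1-mmol/L-*lower*-LDL basis (the Wald ratio, with the LDL denominator
treated as fixed), and the scaled estimates are combined across SNPs by
inverse-variance weighting into the gene-centric score (GS), with
between-SNP heterogeneity reported.

Orientation: the counted allele is LDL-lowering, so an outcome-raising
association of that allele yields a *positive* scaled effect — harmful
metabolic consequences of lower LDL appear as positive numbers (odds
ratios above 1).
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence

from . import meta
from .types import (
    ConfigError,
    PooledEstimate,
    ScoreEstimate,
    WeakInstrumentError,
    Z975,
)

__all__ = ["wald_scale", "gene_score", "run_trait_analysis"]

#: minimum |per-allele LDL effect| (mmol/L) accepted as a usable instrument
WEAK_INSTRUMENT_FLOOR = 0.005


def wald_scale(
    outcome_estimate: PooledEstimate,
    ldl_estimate: PooledEstimate,
    weak_instrument_floor: float = WEAK_INSTRUMENT_FLOOR,
    ratio_variance: bool = False,
) -> PooledEstimate:
    """Rescale a per-allele outcome estimate to per 1 mmol/L lower LDL.

    beta_per_mmol = outcome_beta / |ldl_beta|; se scales by 1/|ldl_beta|
    (variance by the squared multiplicative inverse — the first-order
    delta-method result, LDL beta treated as fixed).  ``ratio_variance``
    optionally adds the second-order term for uncertainty in the
    denominator: var += beta_out^2 * se_ldl^2 / ldl_beta^4.
    """
    if outcome_estimate.snp_id != ldl_estimate.snp_id:
        raise ConfigError(
            f"SNP mismatch in Wald scaling: outcome {outcome_estimate.snp_id!r} "
            f"vs LDL {ldl_estimate.snp_id!r}"
        )
    d = abs(ldl_estimate.beta)
    if d < weak_instrument_floor:
        raise WeakInstrumentError(
            f"{ldl_estimate.snp_id}: |LDL effect| {d:.4g} mmol/L below the "
            f"weak-instrument floor {weak_instrument_floor:g}"
        )
    beta = outcome_estimate.beta / d
    var = (outcome_estimate.se / d) ** 2
    if ratio_variance:
        var += (outcome_estimate.beta**2) * (ldl_estimate.se**2) / d**4
    se = math.sqrt(var)
    return PooledEstimate(
        snp_id=outcome_estimate.snp_id,
        trait_name=outcome_estimate.trait_name,
        method=outcome_estimate.method,
        beta=beta,
        se=se,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        k=outcome_estimate.k,
        Q=outcome_estimate.Q,
        p_Q=outcome_estimate.p_Q,
        I2=outcome_estimate.I2,
        I2_upper=outcome_estimate.I2_upper,
        tau2=outcome_estimate.tau2,
    )


def unscale(scaled: PooledEstimate, ldl_estimate: PooledEstimate) -> PooledEstimate:
    """Inverse of :func:`wald_scale` (exact round-trip)."""
    d = abs(ldl_estimate.beta)
    beta, se = scaled.beta * d, scaled.se * d
    return PooledEstimate(scaled.snp_id, scaled.trait_name, scaled.method,
                          beta, se, beta - Z975 * se, beta + Z975 * se, scaled.k,
                          scaled.Q, scaled.p_Q, scaled.I2, scaled.I2_upper, scaled.tau2)


def _to_score(pe: PooledEstimate, trait_name: str, method: str, binary: bool) -> ScoreEstimate:
    or_scale = None
    if binary:
        or_scale = (math.exp(pe.beta), math.exp(pe.ci_low), math.exp(pe.ci_high))
    return ScoreEstimate(
        trait_name=trait_name,
        method=method,
        beta_per_mmol=pe.beta,
        se=pe.se,
        ci_low=pe.ci_low,
        ci_high=pe.ci_high,
        k_snps=pe.k,
        Q_snp=pe.Q,
        p_Q=pe.p_Q,
        I2_snp=pe.I2,
        I2_snp_upper=pe.I2_upper,
        tau2=pe.tau2,
        or_scale=or_scale,
    )


def gene_score(
    scaled_estimates: Sequence[PooledEstimate],
    trait_name: Optional[str] = None,
    binary: bool = False,
) -> Dict[str, ScoreEstimate]:
    """IVW combination of per-mmol SNP estimates into the gene-centric
    score; both fixed-effect and (for k >= 2) random-effects versions, with
    between-SNP Q, I^2 and the one-sided upper 97.5% I^2 bound."""
    if not scaled_estimates:
        raise ConfigError("gene_score needs at least one scaled estimate")
    names = {e.trait_name for e in scaled_estimates}
    if len(names) > 1:
        raise ConfigError(f"mixed traits in gene score input: {sorted(names)}")
    trait = trait_name or next(iter(names))
    pooled = meta.pool(scaled_estimates, snp_id="GS", trait_name=trait)
    out = {"fixed": _to_score(pooled["fixed"], trait, "fixed", binary)}
    if "random" in pooled:
        out["random"] = _to_score(pooled["random"], trait, "random", binary)
    return out


def run_trait_analysis(
    pooling_inputs: Dict[str, Sequence],
    ldl_pooling_inputs: Dict[str, Sequence],
    trait_name: str,
    binary: bool = False,
    weak_instrument_floor: float = WEAK_INSTRUMENT_FLOOR,
    ratio_variance: bool = False,
) -> dict:
    """Full three-layer analysis for one trait.

    ``pooling_inputs`` / ``ldl_pooling_inputs`` map snp_id -> list of
    per-study (or consortium) per-allele estimates.  The order is fixed:
    pool across studies first, scale each SNP by its *own* pooled
    (fixed-effect) LDL estimate second, pool across SNPs third.  Returns a
    dict with keys ``per_allele`` (snp -> {method: PooledEstimate}),
    ``scaled`` (snp -> PooledEstimate, fixed-effect based), ``gs``
    ({method: ScoreEstimate}) and ``skipped_snps``.
    """
    per_allele: Dict[str, Dict[str, PooledEstimate]] = {}
    scaled: Dict[str, PooledEstimate] = {}
    skipped: List[dict] = []
    for snp_id, ests in pooling_inputs.items():
        if snp_id not in ldl_pooling_inputs:
            skipped.append({"snp_id": snp_id, "reason": "no LDL pooling input"})
            continue
        pooled = meta.pool(ests, snp_id=snp_id, trait_name=trait_name)
        per_allele[snp_id] = pooled
        ldl_pooled = meta.ivw_fixed(ldl_pooling_inputs[snp_id], snp_id=snp_id,
                                    trait_name="ldl")
        try:
            scaled[snp_id] = wald_scale(pooled["fixed"], ldl_pooled,
                                        weak_instrument_floor, ratio_variance)
        except WeakInstrumentError as exc:
            skipped.append({"snp_id": snp_id, "reason": str(exc)})
    if not scaled:
        raise ConfigError(f"{trait_name}: no SNP survived Wald scaling")
    gs = gene_score(list(scaled.values()), trait_name, binary)
    return {"trait": trait_name, "per_allele": per_allele, "scaled": scaled,
            "gs": gs, "skipped_snps": skipped}
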