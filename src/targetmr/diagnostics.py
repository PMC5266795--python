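"""Cross-cutting sensitivity checks.

Dose-response proportionality between per-allele LDL effects and diabetes
log-odds (inverse-variance weighted correlation/regression with
leave-one-SNP-out), leave-one-out gene scores, the per-SNP Fisher summary
of the additivity likelihood-ratio tests, and the univariable-vs-
multivariable (LD-correction) comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import genescore, meta
from .types import ConfigError, LRTResult, PooledEstimate, ScoreEstimate

__all__ = [
    "DoseResponseResult",
    "weighted_dose_response",
    "leave_one_out_gs",
    "additivity_summary",
    "ld_correction_report",
]


@dataclass
class DoseResponseResult:
    """Weighted correlation/regression of outcome log-odds on LDL effects."""

    r_weighted: float
    slope: float
    intercept: float
    slope_ci: tuple
    p_slope: float
    weights: np.ndarray
    loo: Dict[str, float]  # left-out snp -> recomputed r
    defined: bool = True
    reason: str = ""


def _weighted_corr_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted Pearson correlation and WLS slope/intercept with
    normal-theory (k-2 df) slope inference."""
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cxx = np.sum(w * (x - mx) ** 2)
    cyy = np.sum(w * (y - my) ** 2)
    cxy = np.sum(w * (x - mx) * (y - my))
    r = float(cxy / math.sqrt(cxx * cyy))
    slope = float(cxy / cxx)
    intercept = float(my - slope * mx)
    k = len(x)
    resid = y - intercept - slope * x
    dof = k - 2
    if dof > 0:
        sigma2 = float(np.sum(w * resid**2) * k / dof)
        se = math.sqrt(sigma2 / (k * cxx))
        tcrit = stats.t.ppf(0.975, dof)
        ci = (slope - tcrit * se, slope + tcrit * se)
        p = 2.0 * float(stats.t.sf(abs(slope / se), dof)) if se > 0 else 0.0
    else:
        ci, p = (float("nan"), float("nan")), float("nan")
    return r, slope, intercept, ci, p


def weighted_dose_response(
    ldl_betas: Sequence[float],
    outcome_logors: Sequence[float],
    outcome_vars: Sequence[float],
    snp_ids: Optional[Sequence[str]] = None,
) -> DoseResponseResult:
    """Inverse-variance weighted dose-response check: are per-allele outcome
    log-odds proportional to per-allele LDL effects across SNPs?

    Weights are 1/var(log-odds).  With the LDL-lowering orientation the
    LDL betas are negative and harmful outcome log-odds positive, so perfect
    proportionality gives r -> -1.  ``loo`` recomputes r leaving each SNP
    out (needs >= 3 remaining points to stay defined).
    """
    x = np.asarray(ldl_betas, dtype=float)
    y = np.asarray(outcome_logors, dtype=float)
    v = np.asarray(outcome_vars, dtype=float)
    ids = list(snp_ids) if snp_ids is not None else [f"snp{i}" for i in range(len(x))]
    if np.any(v <= 0):
        raise ConfigError("outcome variances must be positive")
    if len(x) < 3:
        return DoseResponseResult(float("nan"), float("nan"), float("nan"),
                                  (float("nan"), float("nan")), float("nan"),
                                  1.0 / v, {}, defined=False,
                                  reason=f"only {len(x)} SNPs (need >= 3)")
    w = 1.0 / v
    r, slope, intercept, ci, p = _weighted_corr_slope(x, y, w)
    loo = {}
    for i, sid in enumerate(ids):
        keep = np.arange(len(x)) != i
        if keep.sum() >= 3:
            loo[sid] = _weighted_corr_slope(x[keep], y[keep], w[keep])[0]
        else:
            loo[sid] = float("nan")
    return DoseResponseResult(r, slope, intercept, ci, p, w, loo)


def leave_one_out_gs(
    scaled_estimates: Sequence[PooledEstimate],
    binary: bool = False,
) -> Dict[str, Dict[str, ScoreEstimate]]:
    """Recompute the gene score omitting each SNP in turn."""
    if len(scaled_estimates) < 2:
        raise ConfigError("leave-one-out needs k >= 2 scaled estimates")
    out = {}
    for i, e in enumerate(scaled_estimates):
        rest = [s for j, s in enumerate(scaled_estimates) if j != i]
        out[e.snp_id] = genescore.gene_score(rest, binary=binary)
    return out


def additivity_summary(lrt_results: Sequence[LRTResult]) -> pd.DataFrame:
    """Fisher combination of the per-study additivity LRT p-values, per SNP.

    Returns a frame with columns (snp_id, k_studies, X, df, p).
    """
    rows = []
    by_snp: Dict[str, List[float]] = {}
    for r in lrt_results:
        by_snp.setdefault(r.snp_id, []).append(r.p)
    for snp_id, ps in sorted(by_snp.items()):
        X, df, p = meta.fisher_combine(ps)
        rows.append({"snp_id": snp_id, "k_studies": len(ps), "X": X, "df": df, "p": p})
    return pd.DataFrame(rows, columns=["snp_id", "k_studies", "X", "df", "p"])


def ld_correction_report(
    univariable: Dict[str, Dict[str, Sequence]],
    multivariable: Dict[str, Dict[str, Sequence]],
) -> pd.DataFrame:
    """Compare pairwise (univariable) and four-SNP multivariable estimates
    fitted on identical individual-level inputs.

    Inputs map trait -> snp_id -> list of per-study AssociationEstimates.
    For each (trait, SNP) the per-study estimates are pooled (fixed effect)
    in both models; additionally, outcome estimates are scaled to the
    per-1-mmol/L basis by the corresponding model's own pooled LDL effect,
    because the presented results live on that scale and full mediation
    makes the two models agree there even under residual LD.

    Columns: trait, snp_id, beta_uni, se_uni, beta_multi, delta,
    delta_over_se, scaled_uni, scaled_se_uni, scaled_multi, scaled_delta,
    scaled_delta_over_se (scaled_* empty for the LDL rows themselves).
    """
    if set(univariable) != set(multivariable):
        raise ConfigError(
            f"trait coverage mismatch: {sorted(univariable)} vs {sorted(multivariable)}"
        )
    pooled_uni = {t: {s: meta.ivw_fixed(e, s, t) for s, e in d.items()}
                  for t, d in univariable.items()}
    pooled_multi = {t: {s: meta.ivw_fixed(e, s, t) for s, e in d.items()}
                    for t, d in multivariable.items()}
    rows = []
    for trait in sorted(univariable):
        if set(pooled_uni[trait]) != set(pooled_multi[trait]):
            raise ConfigError(f"{trait}: SNP coverage mismatch between analyses")
        for snp_id in pooled_uni[trait]:
            u, m = pooled_uni[trait][snp_id], pooled_multi[trait][snp_id]
            row = {
                "trait": trait, "snp_id": snp_id,
                "beta_uni": u.beta, "se_uni": u.se, "beta_multi": m.beta,
                "delta": m.beta - u.beta,
                "delta_over_se": (m.beta - u.beta) / u.se,
                "scaled_uni": np.nan, "scaled_se_uni": np.nan,
                "scaled_multi": np.nan, "scaled_delta": np.nan,
                "scaled_delta_over_se": np.nan,
            }
            if trait != "ldl" and "ldl" in pooled_uni and snp_id in pooled_uni["ldl"]:
                su = genescore.wald_scale(u, pooled_uni["ldl"][snp_id])
                sm = genescore.wald_scale(m, pooled_multi["ldl"][snp_id])
                row.update({
                    "scaled_uni": su.beta, "scaled_se_uni": su.se,
                    "scaled_multi": sm.beta,
                    "scaled_delta": sm.beta - su.beta,
                    "scaled_delta_over_se": (sm.beta - su.beta) / su.se,
                })
            rows.append(row)
    return pd.DataFrame(rows)
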