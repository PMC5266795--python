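"""Inverse-variance weighted meta-analysis with heterogeneity statistics.

Level 1 of the two-level inference: per-SNP pooling of study estimates
(fixed effect and DerSimonian-Laird random effects), Cochran's Q, the I^2
statistic with its one-sided upper 97.5% bound (Higgins-Thompson test-based
interval on ln H), Fisher's method for combining p-values, Hardy-Weinberg
exclusion, and double-counting-safe merging of consortium summary records
with study-level estimates.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .types import (
    AssociationEstimate,
    ConfigError,
    HWEResult,
    PooledEstimate,
    SummaryStatRecord,
    Z975,
)

__all__ = [
    "ivw_fixed",
    "cochran_q",
    "i_squared",
    "dl_random",
    "fisher_combine",
    "merge_sources",
    "hwe_filter",
    "pool",
]


def _betas_ses(estimates: Sequence) -> Tuple[np.ndarray, np.ndarray, List]:
    """Extract (beta, se) pairs; estimates may be (beta, se) tuples or
    objects with .beta/.se.  Non-positive SEs are rejected with a log."""
    kept, log = [], []
    for e in estimates:
        b, s = (e.beta, e.se) if hasattr(e, "beta") else (e[0], e[1])
        if not (s > 0) or not math.isfinite(s) or not math.isfinite(b):
            log.append(f"rejected estimate beta={b} se={s}: se must be positive finite")
            continue
        kept.append((float(b), float(s)))
    if not kept:
        raise ConfigError("no valid estimates to pool" + ("; " + "; ".join(log) if log else ""))
    arr = np.array(kept)
    return arr[:, 0], arr[:, 1], log


def ivw_fixed(estimates: Sequence, snp_id: str = "", trait_name: str = "") -> PooledEstimate:
    """Fixed-effect inverse-variance pooling: weights 1/se^2, pooled
    se = sqrt(1/sum w), 95% CI beta +/- 1.959964 se."""
    b, s, _ = _betas_ses(estimates)
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    k = len(b)
    Q = p_Q = I2 = I2u = None
    if k >= 2:
        Q, p_Q = cochran_q(estimates)
        I2, I2u = i_squared(Q, k)
    return PooledEstimate(snp_id, trait_name, "fixed", beta, se,
                          beta - Z975 * se, beta + Z975 * se, k, Q, p_Q, I2, I2u, None)


def cochran_q(estimates: Sequence) -> Tuple[float, float]:
    """Cochran's Q against the fixed-effect mean; p from chi-square(k-1)."""
    b, s, _ = _betas_ses(estimates)
    k = len(b)
    if k < 2:
        raise ConfigError("Q-test requires k >= 2 estimates")
    w = 1.0 / s**2
    mu = np.sum(w * b) / np.sum(w)
    Q = float(np.sum(w * (b - mu) ** 2))
    return Q, float(stats.chi2.sf(Q, df=k - 1))


def i_squared(Q: float, k: int) -> Tuple[float, Optional[float]]:
    """I^2 (percent) and its one-sided upper 97.5% bound.

    The bound uses the test-based interval on ln H with
    H^2 = Q/(k-1): se(ln H) = (ln Q - ln(k-1)) / (2 (sqrt(2Q) - sqrt(2k-3)))
    when Q > k, else sqrt(1/(2(k-2)) (1 - 1/(3(k-2)^2))); the upper limit is
    floored at I^2 itself.  For k = 2 with Q <= k no bound is defined and
    None is returned.
    """
    if k < 2 or Q < 0:
        raise ConfigError(f"i_squared needs k >= 2 and Q >= 0 (k={k}, Q={Q})")
    I2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    if Q > k:
        se_ln_h = (math.log(Q) - math.log(k - 1)) / (2.0 * (math.sqrt(2 * Q) - math.sqrt(2 * k - 3)))
    elif k > 2:
        se_ln_h = math.sqrt(1.0 / (2 * (k - 2)) * (1.0 - 1.0 / (3 * (k - 2) ** 2)))
    else:
        return I2, None
    ln_h = 0.5 * math.log(max(Q, 1e-300) / (k - 1)) if Q > 0 else 0.0
    h_u = math.exp(ln_h + Z975 * se_ln_h)
    I2_upper = max(I2, 100.0 * (h_u**2 - 1.0) / h_u**2)
    return I2, I2_upper


def dl_random(estimates: Sequence, snp_id: str = "", trait_name: str = "") -> PooledEstimate:
    """DerSimonian-Laird random-effects pooling:
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)), then IVW with
    weights 1/(se^2 + tau^2).  With Q <= k-1 this reduces exactly to the
    fixed-effect result."""
    b, s, _ = _betas_ses(estimates)
    k = len(b)
    if k < 2:
        raise ConfigError("random-effects pooling requires k >= 2")
    w = 1.0 / s**2
    Q, p_Q = cochran_q(estimates)
    C = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (k - 1)) / C) if C > 0 else 0.0
    wr = 1.0 / (s**2 + tau2)
    beta = float(np.sum(wr * b) / np.sum(wr))
    se = float(math.sqrt(1.0 / np.sum(wr)))
    I2, I2u = i_squared(Q, k)
    return PooledEstimate(snp_id, trait_name, "random", beta, se,
                          beta - Z975 * se, beta + Z975 * se, k, Q, p_Q, I2, I2u, tau2)


def pool(estimates: Sequence, snp_id: str = "", trait_name: str = "") -> Dict[str, PooledEstimate]:
    """Both pooling methods for one input set; random only when k >= 2."""
    fixed = ivw_fixed(estimates, snp_id, trait_name)
    out = {"fixed": fixed}
    if fixed.k >= 2:
        out["random"] = dl_random(estimates, snp_id, trait_name)
    return out


def fisher_combine(p_values: Sequence[float]) -> Tuple[float, int, float]:
    """Fisher's method: X = -2 sum ln p ~ chi-square(2k) under the null.
    Zero p-values are clipped to the smallest positive float."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise ConfigError("fisher_combine needs at least one p-value")
    if np.any((ps < 0) | (ps > 1)):
        raise ConfigError("p-values must lie in [0, 1]")
    if np.any(ps == 0.0):
        warnings.warn("p-value of 0 clipped to the smallest positive float",
                      RuntimeWarning, stacklevel=2)
    tiny = np.nextafter(0.0, 1.0)
    ps = np.clip(ps, tiny, 1.0)
    X = float(-2.0 * np.sum(np.log(ps)))
    df = 2 * ps.size
    return X, df, float(stats.chi2.sf(X, df=df))


def merge_sources(
    study_estimates: Sequence[AssociationEstimate],
    consortium_records: Sequence[SummaryStatRecord],
    overlap_exclusions: Optional[Dict[str, Set[str]]] = None,
) -> Tuple[Dict[Tuple[str, str], list], List[dict]]:
    """Assemble per-(SNP, trait) pooling inputs without double counting.

    ``overlap_exclusions`` maps consortium source_id -> the set of study_ids
    whose participants already contributed to that source; those studies'
    estimates are dropped wherever the consortium record is included.  A
    study claimed by two different included sources is ambiguous provenance
    and a configuration error.  Returns ({(snp, trait): estimates},
    exclusion log).
    """
    overlap_exclusions = overlap_exclusions or {}
    present_sources = {r.source_id for r in consortium_records}
    claimed: Dict[str, str] = {}
    for src, studies in overlap_exclusions.items():
        if src not in present_sources:
            continue
        for st in studies:
            if st in claimed and claimed[st] != src:
                raise ConfigError(
                    f"study {st!r} subsumed by two included sources "
                    f"({claimed[st]!r} and {src!r}): ambiguous provenance"
                )
            claimed[st] = src
    log: List[dict] = []
    merged: Dict[Tuple[str, str], list] = {}
    for e in study_estimates:
        key = (e.snp_id, e.trait_name)
        if e.study_id in claimed:
            log.append({"study_id": e.study_id, "snp_id": e.snp_id,
                        "trait": e.trait_name, "rule": f"subsumed_by:{claimed[e.study_id]}",
                        "p": ""})
            continue
        merged.setdefault(key, []).append(e)
    for r in consortium_records:
        merged.setdefault((r.snp_id, r.trait_name), []).append(r)
    return merged, log


def hwe_filter(
    estimates: Sequence[AssociationEstimate],
    hwe_results: Sequence[HWEResult],
    threshold_p: float = 1e-6,
    strict: bool = True,
) -> Tuple[List[AssociationEstimate], List[dict]]:
    """Drop every estimate from a (study, SNP) pair whose Hardy-Weinberg
    test p-value falls below the threshold; every removal is logged.

    ``strict`` controls what happens when an estimate's (study, SNP) has no
    HWE record: error (default) or keep with a warning entry in the log.
    """
    if not (0 < threshold_p <= 1):
        raise ConfigError(f"hwe threshold must be in (0,1], got {threshold_p}")
    if threshold_p == 1.0:
        warnings.warn("HWE threshold 1.0 excludes every study-SNP pair",
                      RuntimeWarning, stacklevel=2)
    pvals = {(h.study_id, h.snp_id): h.p for h in hwe_results}
    kept, log = [], []
    for e in estimates:
        key = (e.study_id, e.snp_id)
        if key not in pvals:
            if strict:
                raise ConfigError(f"no HWE result for (study={e.study_id}, snp={e.snp_id})")
            log.append({"study_id": e.study_id, "snp_id": e.snp_id,
                        "trait": e.trait_name, "rule": "hwe_missing_kept", "p": ""})
            kept.append(e)
            continue
        p = pvals[key]
        if p < threshold_p:
            log.append({"study_id": e.study_id, "snp_id": e.snp_id,
                        "trait": e.trait_name, "rule": f"hwe_p<{threshold_p:g}", "p": p})
        else:
            kept.append(e)
    return kept, log
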