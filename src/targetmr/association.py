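"""Per-study association estimation and quality tests.

This is the "common analysis script" each participating cohort runs:
additive per-allele linear and logistic fits, Hardy-Weinberg testing,
the additive-vs-genotypic likelihood-ratio test, the four-SNP multivariable
model, and pairwise composite LD.

The estimators are written out explicitly because their numerical contract
is part of the pipeline's definition: OLS via the closed-form normal
equations, logistic regression via Newton/IRLS with a score-based
convergence rule and a divergence (separation) guard.  They are
cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    AssociationEstimate,
    ConfigError,
    DegenerateDataError,
    HWEResult,
    LRTResult,
    SeparationError,
    TraitModel,
    VariantSpec,
)

__all__ = [
    "recode_to_ldl_lowering",
    "fit_linear_additive",
    "fit_logistic_additive",
    "hwe_test",
    "additivity_lrt",
    "fit_multivariable",
    "pairwise_r2",
    "run_study",
]

MIN_CELL_COUNT = 5  # binary-outcome genotype-cell floor (quality flag)
SEPARATION_BOUND = 15.0
MAX_IRLS_ITER = 50


def _check_dosages(g: np.ndarray) -> None:
    finite = g[np.isfinite(g)]
    if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
        bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
        raise ConfigError(f"dosage outside {{0,1,2}}: {bad}")


def recode_to_ldl_lowering(dosages: np.ndarray, variant: VariantSpec | float):
    """Orient dosages so the counted allele is the LDL-lowering one.

    ``variant`` may be a :class:`VariantSpec` or a raw per-allele LDL beta in
    the supplied orientation.  If that beta is positive the counted allele
    *raises* LDL, so dosage g becomes 2-g and the effect-sign convention
    flips.  Returns (coded dosages, flipped flag).
    """
    beta = variant.beta_ldl if hasattr(variant, "beta_ldl") else float(variant)
    g = np.asarray(dosages, dtype=float)
    _check_dosages(g)
    if beta > 0:
        return 2.0 - g, True
    return g.copy(), False


# --- core fitters ----------------------------------------------------------


def _available(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).reshape(len(x), -1)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y) & np.isfinite(x).all(axis=1)
    return x[keep], y[keep]


def _ols(X: np.ndarray, y: np.ndarray):
    """Closed-form OLS with intercept prepended: returns (coef, se, loglik)."""
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    xtx = Xd.T @ Xd
    coef = np.linalg.solve(xtx, Xd.T @ y)
    resid = y - Xd @ coef
    rss = float(resid @ resid)
    dof = n - (p + 1)
    sigma2 = rss / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    # profile Gaussian log-likelihood (MLE variance rss/n)
    ll = -0.5 * n * (math.log(2 * math.pi * max(rss, 1e-300) / n) + 1.0)
    return coef, se, ll


def _irls_logistic(X: np.ndarray, y: np.ndarray):
    """Newton-Raphson (IRLS) logistic fit with intercept prepended.

    Convergence: max |score| < 1e-8 or relative log-likelihood change
    < 1e-10, within 50 iterations.  |coef| exceeding 15 triggers a
    separation error; non-convergence raises with an iteration summary.
    Returns (coef, se, loglik, n_iter).
    """
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    coef = np.zeros(p + 1)
    coef[0] = math.log(max(y.mean(), 1e-8) / max(1 - y.mean(), 1e-8))
    ll_old = -np.inf
    trace = []
    for it in range(1, MAX_IRLS_ITER + 1):
        eta = Xd @ coef
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) +
                          (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
        score = Xd.T @ (y - mu)
        w = mu * (1 - mu)
        info = (Xd * w[:, None]).T @ Xd
        trace.append((it, ll, float(np.max(np.abs(score)))))
        if np.max(np.abs(coef)) > SEPARATION_BOUND:
            raise SeparationError(
                f"logistic fit diverged (|beta| > {SEPARATION_BOUND}): "
                "complete or quasi-complete separation"
            )
        if np.max(np.abs(score)) < 1e-8 or (
            np.isfinite(ll_old) and abs(ll - ll_old) <= 1e-10 * abs(ll_old)
        ):
            cov = np.linalg.inv(info)
            return coef, np.sqrt(np.diag(cov)), ll, it
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise DegenerateDataError(f"singular information matrix: {exc}") from exc
        coef = coef + step
        ll_old = ll
    tail = ", ".join(f"iter {i}: ll={l:.4f} max|score|={s:.2e}" for i, l, s in trace[-3:])
    raise TimeoutError(f"IRLS did not converge in {MAX_IRLS_ITER} iterations ({tail})")


def fit_linear_additive(
    dosages: np.ndarray,
    y: np.ndarray,
    study_id: str = "",
    snp_id: str = "",
    trait_name: str = "",
) -> AssociationEstimate:
    """Additive per-allele linear regression (intercept + dosage), OLS via
    the normal equations, available-case handling of missing values."""
    x, yv = _available(np.asarray(dosages, float), y)
    if len(yv) < 3:
        raise DegenerateDataError(
            f"{study_id}/{snp_id}/{trait_name}: need >= 3 complete observations, have {len(yv)}"
        )
    if np.ptp(x[:, 0]) == 0:
        raise DegenerateDataError(f"{study_id}/{snp_id}: constant dosage")
    coef, se, _ = _ols(x, yv)
    flags = ()
    if se[1] == 0.0:
        flags = ("zero_residual_variance",)
    return AssociationEstimate(study_id, snp_id, trait_name,
                               float(coef[1]), float(se[1]), len(yv), "additive",
                               "per-allele", flags)


def _binary_cell_flags(g: np.ndarray, y: np.ndarray) -> tuple:
    """Flag sparse genotype x outcome cells (rare-allele separation guard)."""
    for gv in (0.0, 1.0, 2.0):
        for yv in (0.0, 1.0):
            if np.sum((g == gv) & (y == yv)) < MIN_CELL_COUNT:
                return ("sparse_cells",)
    return ()


def fit_logistic_additive(
    dosages: np.ndarray,
    y: np.ndarray,
    study_id: str = "",
    snp_id: str = "",
    trait_name: str = "",
) -> AssociationEstimate:
    """Additive per-allele logistic regression via IRLS; log-odds scale."""
    x, yv = _available(np.asarray(dosages, float), y)
    if len(np.unique(yv)) < 2:
        raise DegenerateDataError(f"{study_id}/{snp_id}/{trait_name}: single outcome class")
    if np.ptp(x[:, 0]) == 0:
        raise DegenerateDataError(f"{study_id}/{snp_id}: constant dosage")
    coef, se, _, _ = _irls_logistic(x, yv)
    flags = _binary_cell_flags(x[:, 0], yv)
    return AssociationEstimate(study_id, snp_id, trait_name,
                               float(coef[1]), float(se[1]), len(yv), "additive",
                               "per-allele", flags)


# --- quality tests ---------------------------------------------------------


def hwe_test(counts: Sequence[int], study_id: str = "", snp_id: str = "") -> HWEResult:
    """1-df chi-square goodness-of-fit against Hardy-Weinberg proportions.

    ``counts`` are (n_AA, n_Aa, n_aa) ordered by minor-allele dosage 0,1,2;
    expected counts use the sample allele frequency.  Monomorphic SNPs have
    an expected count of zero and are rejected (callers record the skip).
    """
    n0, n1, n2 = (int(c) for c in counts)
    n = n0 + n1 + n2
    if n <= 0:
        raise DegenerateDataError(f"{study_id}/{snp_id}: empty genotype counts")
    p = (n1 + 2 * n2) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    if np.any(expected == 0):
        raise DegenerateDataError(
            f"{study_id}/{snp_id}: monomorphic SNP, HWE test skipped (expected count zero)"
        )
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    pval = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(study_id, snp_id, (n0, n1, n2), chi2, max(pval, 1e-300))


def additivity_lrt(
    dosages: np.ndarray,
    y: np.ndarray,
    family: str = "gaussian",
    study_id: str = "",
    snp_id: str = "",
    trait_name: str = "",
) -> LRTResult:
    """Likelihood-ratio test of the additive model against a genotypic
    (2-parameter factor) model allowing dominance/recessiveness; 1 df."""
    x, yv = _available(np.asarray(dosages, float), y)
    g = x[:, 0]
    for cls in (0.0, 1.0, 2.0):
        if np.sum(g == cls) < 2:
            raise DegenerateDataError(
                f"{study_id}/{snp_id}/{trait_name}: genotype class {int(cls)} has "
                f"fewer than 2 observations, LRT skipped"
            )
    X_add = g.reshape(-1, 1)
    X_gen = np.column_stack([(g == 1.0).astype(float), (g == 2.0).astype(float)])
    if family == "gaussian":
        *_, ll_add = _ols(X_add, yv)
        *_, ll_gen = _ols(X_gen, yv)
    elif family == "binomial":
        _, _, ll_add, _ = _irls_logistic(X_add, yv)
        _, _, ll_gen, _ = _irls_logistic(X_gen, yv)
    else:
        raise ConfigError(f"unknown family {family!r}")
    stat = 2.0 * (ll_gen - ll_add)
    if stat < -1e-8:
        raise DegenerateDataError(f"negative LRT statistic {stat}: fit failure")
    stat = max(stat, 0.0)
    return LRTResult(study_id, snp_id, trait_name, float(stat), 1,
                     float(stats.chi2.sf(stat, df=1)))


def fit_multivariable(
    dosage_matrix: np.ndarray,
    y: np.ndarray,
    family: str = "gaussian",
    study_id: str = "",
    snp_ids: Optional[Sequence[str]] = None,
    trait_name: str = "",
) -> List[AssociationEstimate]:
    """Conditional per-allele estimates with all SNPs in one model."""
    X, yv = _available(np.asarray(dosage_matrix, float), y)
    m = X.shape[1]
    snp_ids = list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(m)]
    Xd = np.column_stack([np.ones(len(yv)), X])
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        # name the collinear columns via the QR diagonal
        _, R = np.linalg.qr(Xd)
        diag = np.abs(np.diag(R))
        bad = [snp_ids[j - 1] for j in range(1, Xd.shape[1])
               if diag[j] < 1e-8 * diag.max()]
        raise DegenerateDataError(f"{study_id}/{trait_name}: rank-deficient design; "
                                  f"collinear columns: {bad or 'intercept block'}")
    if family == "gaussian":
        coef, se, _ = _ols(X, yv)
    elif family == "binomial":
        coef, se, _, _ = _irls_logistic(X, yv)
    else:
        raise ConfigError(f"unknown family {family!r}")
    out = []
    for j, sid in enumerate(snp_ids):
        flags = ()
        if family == "binomial":
            flags = _binary_cell_flags(X[:, j], yv)
        out.append(AssociationEstimate(study_id, sid, trait_name,
                                       float(coef[j + 1]), float(se[j + 1]),
                                       len(yv), "multivariable", "per-allele", flags))
    return out


def pairwise_r2(dosage_matrix: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of dosage columns (composite genotypic
    LD); entries involving a constant column are NaN, not 0."""
    X = np.asarray(dosage_matrix, dtype=float)
    if X.shape[0] < 2:
        raise DegenerateDataError("need >= 2 individuals for pairwise r^2")
    m = X.shape[1]
    out = np.empty((m, m))
    sd = np.nanstd(X, axis=0)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    out = corr**2
    for j in range(m):
        if sd[j] == 0:
            out[j, :] = np.nan
            out[:, j] = np.nan
        out[j, j] = 1.0 if sd[j] > 0 else np.nan
    return out


# --- the common analysis script --------------------------------------------


def run_study(
    cohort: pd.DataFrame,
    variants: Sequence[VariantSpec],
    traits: Sequence[TraitModel],
    study_id: Optional[str] = None,
    strata: bool = True,
) -> Dict[str, list]:
    """Run the full per-study battery on one cohort frame.

    Returns dict with keys ``estimates`` (univariable additive, LDL plus all
    configured traits; binary traits additionally split into
    ``<trait>_incident`` / ``<trait>_prevalent`` case-restricted analyses
    when ``strata``), ``hwe``, ``lrt``, ``multivariable`` and ``skipped``
    (records that could not be fitted, with reasons).
    """
    sid = study_id or cohort.attrs.get("study_id", "study")
    estimates: List[AssociationEstimate] = []
    hwe: List[HWEResult] = []
    lrt: List[LRTResult] = []
    multi: List[AssociationEstimate] = []
    skipped: List[dict] = []

    def _skip(snp, trait, op, reason):
        skipped.append({"study_id": sid, "snp_id": snp, "trait": trait,
                        "op": op, "reason": str(reason)})

    coded = {}
    for v in variants:
        g, _ = recode_to_ldl_lowering(cohort[v.snp_id].to_numpy(), v)
        coded[v.snp_id] = g
        counts = tuple(int(np.sum(g == k)) for k in (0.0, 1.0, 2.0))
        try:
            hwe.append(hwe_test(counts, sid, v.snp_id))
        except DegenerateDataError as exc:
            _skip(v.snp_id, "", "hwe", exc)

    # outcome vectors: LDL first, then the configured traits
    outcomes: List[Tuple[str, str, np.ndarray]] = [("ldl", "gaussian",
                                                    cohort["ldl"].to_numpy(float))]
    fasting = cohort["fasting"].to_numpy() == 1 if "fasting" in cohort else np.ones(len(cohort), bool)
    for t in traits:
        yv = cohort[t.trait_name].to_numpy(float)
        if t.fasting_only:
            yv = np.where(fasting, yv, np.nan)
        fam = "gaussian" if t.kind == "continuous" else "binomial"
        outcomes.append((t.trait_name, fam, yv))
        if fam == "binomial" and strata and "case_type" in cohort:
            ct = cohort["case_type"].to_numpy()
            for stratum in ("incident", "prevalent"):
                ys = yv.copy()
                ys[(yv == 1) & (ct != stratum)] = np.nan  # other-stratum cases dropped
                outcomes.append((f"{t.trait_name}_{stratum}", "binomial", ys))

    snp_ids = [v.snp_id for v in variants]
    for name, fam, yv in outcomes:
        for v in variants:
            g = coded[v.snp_id]
            try:
                if fam == "gaussian":
                    estimates.append(fit_linear_additive(g, yv, sid, v.snp_id, name))
                else:
                    estimates.append(fit_logistic_additive(g, yv, sid, v.snp_id, name))
            except (DegenerateDataError, SeparationError, TimeoutError) as exc:
                _skip(v.snp_id, name, "fit", exc)
            if name in ("ldl",) or not name.endswith(("_incident", "_prevalent")):
                try:
                    lrt.append(additivity_lrt(g, yv, fam, sid, v.snp_id, name))
                except (DegenerateDataError, SeparationError, TimeoutError) as exc:
                    _skip(v.snp_id, name, "lrt", exc)
        if name.endswith(("_incident", "_prevalent")):
            continue
        try:
            G = np.column_stack([coded[s] for s in snp_ids])
            multi.extend(fit_multivariable(G, yv, fam, sid, snp_ids, name))
        except (DegenerateDataError, SeparationError, TimeoutError) as exc:
            _skip("*", name, "multivariable", exc)

    return {"estimates": estimates, "hwe": hwe, "lrt": lrt,
            "multivariable": multi, "skipped": skipped}
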