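"""Model/Results surface for the drug-target MR analysis.

:class:`DrugTargetMR` is built from per-study individual-level cohorts
(plus optional consortium summary records) and owns the configuration of
the analysis — instruments, trait models, quality thresholds.  ``fit()``
executes the whole two-level inference and returns a
:class:`DrugTargetMRResults` carrying every layer (per-study estimates,
per-SNP pooled per-allele and per-mmol estimates, gene-centric scores) with
uncertainties, heterogeneity diagnostics and exclusion logs, plus the
sensitivity analyses as methods.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from . import association, diagnostics, genescore, meta
from .simulate import SimulationConfig, simulate_all_cohorts
from .types import (
    AssociationEstimate,
    ConfigError,
    PooledEstimate,
    ScoreEstimate,
    SummaryStatRecord,
    TraitModel,
    VariantSpec,
)

__all__ = ["DrugTargetMR", "DrugTargetMRResults"]


def _records_from_frame(df: pd.DataFrame) -> List[SummaryStatRecord]:
    return [
        SummaryStatRecord(r["source_id"], r["snp_id"], r["trait"],
                          r.get("effect_allele", "minor"), float(r["beta"]),
                          float(r["se"]), int(r["n"]))
        for r in df.to_dict("records")
    ]


class DrugTargetMR:
    """Drug-target Mendelian randomisation model.

    Parameters
    ----------
    cohorts : mapping study_id -> DataFrame
        Individual-level data: one dosage column per SNP, ``ldl``, the
        outcome trait columns, ``t2d``/``case_type``/``fasting`` as
        applicable.
    variants : sequence of VariantSpec
        The instruments; dosages are (re)oriented to the LDL-lowering
        allele using each variant's effect sign.
    traits : sequence of TraitModel
        Which outcome columns to analyse and how (continuous/binary,
        fasting-only restriction).  The generative ``theta`` values are not
        used for fitting.
    consortium : DataFrame, optional
        Summary-statistic records (source_id, snp_id, trait, effect_allele,
        beta, se, n) merged into pooling after double-counting resolution.
    overlap_exclusions : mapping source_id -> set of study_ids, optional
        Studies whose participants already contributed to a consortium
        source; their estimates are dropped wherever that source is pooled.
    hwe_threshold_p : float
        Study-SNP pairs with a Hardy-Weinberg p-value below this are
        excluded from all pooling (default 1e-6, conventional GWAS
        practice).
    """

    def __init__(
        self,
        cohorts: Dict[str, pd.DataFrame],
        variants: Sequence[VariantSpec],
        traits: Sequence[TraitModel],
        consortium: Optional[pd.DataFrame] = None,
        overlap_exclusions: Optional[Dict[str, Set[str]]] = None,
        hwe_threshold_p: float = 1e-6,
        weak_instrument_floor: float = genescore.WEAK_INSTRUMENT_FLOOR,
        exclude_flagged: bool = True,
        strata: bool = True,
        ratio_variance: bool = False,
    ) -> None:
        self.cohorts = dict(cohorts)
        self.variants = list(variants)
        self.traits = list(traits)
        self.consortium = consortium
        self.overlap_exclusions = overlap_exclusions or {}
        self.hwe_threshold_p = hwe_threshold_p
        self.weak_instrument_floor = weak_instrument_floor
        self.exclude_flagged = exclude_flagged
        self.strata = strata
        self.ratio_variance = ratio_variance

    @classmethod
    def from_simulation(cls, config: SimulationConfig, **kwargs) -> "DrugTargetMR":
        """Build the model directly from a synthetic-data configuration."""
        cohorts = simulate_all_cohorts(config)
        return cls(cohorts, config.variants, config.traits, **kwargs)

    # -- analysis -----------------------------------------------------------

    def _trait_kind(self, name: str) -> str:
        base = name.removesuffix("_incident").removesuffix("_prevalent")
        if base == "ldl":
            return "continuous"
        for t in self.traits:
            if t.trait_name == base:
                return t.kind
        raise ConfigError(f"unknown trait {name!r}")

    def fit(self) -> "DrugTargetMRResults":
        """Run study-level fits, quality filters, two-level pooling and
        Wald scaling; return the results object."""
        study_out = {"estimates": [], "hwe": [], "lrt": [],
                     "multivariable": [], "skipped": []}
        for sid, frame in self.cohorts.items():
            out = association.run_study(frame, self.variants, self.traits,
                                        study_id=sid, strata=self.strata)
            for key in study_out:
                study_out[key].extend(out[key])

        exclusions: List[dict] = []
        kept, hwe_log = meta.hwe_filter(study_out["estimates"], study_out["hwe"],
                                        self.hwe_threshold_p, strict=False)
        exclusions.extend(hwe_log)
        if self.exclude_flagged:
            unflagged = []
            for e in kept:
                if e.flags:
                    exclusions.append({"study_id": e.study_id, "snp_id": e.snp_id,
                                       "trait": e.trait_name,
                                       "rule": ";".join(e.flags), "p": ""})
                else:
                    unflagged.append(e)
            kept = unflagged

        records = _records_from_frame(self.consortium) if self.consortium is not None else []
        merged, overlap_log = meta.merge_sources(kept, records, self.overlap_exclusions)
        exclusions.extend(overlap_log)

        trait_names = [t.trait_name for t in self.traits]
        if self.strata:
            for t in self.traits:
                if t.kind == "binary":
                    trait_names += [f"{t.trait_name}_incident", f"{t.trait_name}_prevalent"]

        ldl_inputs = {snp: ests for (snp, tr), ests in merged.items() if tr == "ldl"}
        trait_results: Dict[str, dict] = {}
        failures: Dict[str, str] = {}
        for name in trait_names:
            inputs = {snp: ests for (snp, tr), ests in merged.items() if tr == name}
            if not inputs:
                failures[name] = "no estimates available"
                continue
            try:
                trait_results[name] = genescore.run_trait_analysis(
                    inputs, ldl_inputs, name,
                    binary=self._trait_kind(name) == "binary",
                    weak_instrument_floor=self.weak_instrument_floor,
                    ratio_variance=self.ratio_variance,
                )
            except ConfigError as exc:
                failures[name] = str(exc)

        ldl_per_snp = {snp: meta.pool(ests, snp, "ldl") for snp, ests in ldl_inputs.items()}
        return DrugTargetMRResults(self, study_out, kept, merged, exclusions,
                                   ldl_per_snp, trait_results, failures)


class DrugTargetMRResults:
    """Fitted results: every inference layer plus the sensitivity analyses."""

    def __init__(self, model, study_out, kept_estimates, merged, exclusions,
                 ldl_per_snp, trait_results, failures) -> None:
        self.model = model
        self._study_out = study_out
        self.kept_estimates = kept_estimates
        self.merged_inputs = merged
        self.exclusions = exclusions
        self.ldl_per_snp = ldl_per_snp  # snp -> {method: PooledEstimate}
        self.trait_results = trait_results  # trait -> run_trait_analysis dict
        self.failures = failures

    # -- tabular views -------------------------------------------------------

    @property
    def study_estimates(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_dict() for e in self._study_out["estimates"]])

    @property
    def multivariable_estimates(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_dict() for e in self._study_out["multivariable"]])

    @property
    def hwe_table(self) -> pd.DataFrame:
        return pd.DataFrame([h.as_dict() for h in self._study_out["hwe"]])

    @property
    def lrt_table(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self._study_out["lrt"]])

    @property
    def exclusion_table(self) -> pd.DataFrame:
        cols = ["study_id", "snp_id", "trait", "rule", "p"]
        return pd.DataFrame(self.exclusions, columns=cols)

    def gene_score(self, trait: str, method: str = "fixed") -> ScoreEstimate:
        return self.trait_results[trait]["gs"][method]

    @property
    def gene_scores(self) -> pd.DataFrame:
        rows = []
        for trait, res in self.trait_results.items():
            for method, gs in res["gs"].items():
                rows.append(gs.as_dict())
        return pd.DataFrame(rows)

    def forest_table(self) -> pd.DataFrame:
        """Tabular forest plot: per-study rows, per-SNP per-allele and
        per-mmol pooled rows, and the fixed/random gene-score rows, for
        every analysed trait."""
        rows = []
        for e in self.kept_estimates:
            rows.append({"trait": e.trait_name, "level": "study", "unit": e.study_id,
                         "snp_id": e.snp_id, "beta": e.beta, "se": e.se,
                         "ci_low": e.beta - 1.959964 * e.se,
                         "ci_high": e.beta + 1.959964 * e.se, "k": 1,
                         "Q": None, "p_Q": None, "I2": None, "I2_upper": None,
                         "or": None})
        for snp, pooled in self.ldl_per_snp.items():
            pe = pooled["fixed"]
            rows.append({"trait": "ldl", "level": "snp_per_allele", "unit": "pooled",
                         "snp_id": snp, "beta": pe.beta, "se": pe.se,
                         "ci_low": pe.ci_low, "ci_high": pe.ci_high, "k": pe.k,
                         "Q": pe.Q, "p_Q": pe.p_Q, "I2": pe.I2,
                         "I2_upper": pe.I2_upper, "or": None})
        for trait, res in self.trait_results.items():
            binary = self.model._trait_kind(trait) == "binary"
            for snp, pooled in res["per_allele"].items():
                pe = pooled["fixed"]
                rows.append({"trait": trait, "level": "snp_per_allele", "unit": "pooled",
                             "snp_id": snp, "beta": pe.beta, "se": pe.se,
                             "ci_low": pe.ci_low, "ci_high": pe.ci_high, "k": pe.k,
                             "Q": pe.Q, "p_Q": pe.p_Q, "I2": pe.I2,
                             "I2_upper": pe.I2_upper,
                             "or": math.exp(pe.beta) if binary else None})
            for snp, pe in res["scaled"].items():
                rows.append({"trait": trait, "level": "snp_per_mmol", "unit": "pooled",
                             "snp_id": snp, "beta": pe.beta, "se": pe.se,
                             "ci_low": pe.ci_low, "ci_high": pe.ci_high, "k": pe.k,
                             "Q": pe.Q, "p_Q": pe.p_Q, "I2": pe.I2,
                             "I2_upper": pe.I2_upper,
                             "or": math.exp(pe.beta) if binary else None})
            for method, gs in res["gs"].items():
                rows.append({"trait": trait, "level": f"GS_{method}", "unit": "GS",
                             "snp_id": "GS", "beta": gs.beta_per_mmol, "se": gs.se,
                             "ci_low": gs.ci_low, "ci_high": gs.ci_high,
                             "k": gs.k_snps, "Q": gs.Q_snp, "p_Q": gs.p_Q,
                             "I2": gs.I2_snp, "I2_upper": gs.I2_snp_upper,
                             "or": gs.or_scale[0] if gs.or_scale else None})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary of the gene-centric scores."""
        lines = ["Drug-target Mendelian randomisation results",
                 "=" * 44,
                 f"studies: {len(self.model.cohorts)}   "
                 f"SNPs: {len(self.model.variants)}   "
                 f"exclusions: {len(self.exclusions)}",
                 "",
                 "Gene-centric score, per 1 mmol/L lower LDL cholesterol:"]
        df = self.gene_scores
        if not df.empty:
            view = df[["trait_name", "method", "beta_per_mmol", "se",
                       "ci_low", "ci_high", "k_snps", "Q_snp", "I2_snp",
                       "I2_snp_upper", "or", "or_low", "or_high"]]
            lines.append(view.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        for trait, reason in self.failures.items():
            lines.append(f"[not analysed] {trait}: {reason}")
        return "\n".join(lines)

    # -- sensitivity analyses ------------------------------------------------

    def dose_response(self, trait: str = "t2d") -> diagnostics.DoseResponseResult:
        """Per-allele LDL effects vs per-allele outcome associations across
        SNPs, weighted by the inverse outcome variance, with leave-one-out."""
        res = self.trait_results[trait]
        snps = [s for s in res["per_allele"] if s in self.ldl_per_snp]
        x = [self.ldl_per_snp[s]["fixed"].beta for s in snps]
        y = [res["per_allele"][s]["fixed"].beta for s in snps]
        v = [res["per_allele"][s]["fixed"].se ** 2 for s in snps]
        return diagnostics.weighted_dose_response(x, y, v, snps)

    def leave_one_out(self, trait: str = "t2d") -> Dict[str, Dict[str, ScoreEstimate]]:
        res = self.trait_results[trait]
        binary = self.model._trait_kind(trait) == "binary"
        return diagnostics.leave_one_out_gs(list(res["scaled"].values()), binary)

    def additivity(self) -> pd.DataFrame:
        """Per-SNP Fisher combination of the per-study additivity LRTs
        (all traits pooled per SNP are *not* mixed: one row per snp/trait)."""
        frames = []
        by_trait: Dict[str, list] = {}
        for r in self._study_out["lrt"]:
            by_trait.setdefault(r.trait_name, []).append(r)
        for trait, results in sorted(by_trait.items()):
            tab = diagnostics.additivity_summary(results)
            tab.insert(0, "trait", trait)
            frames.append(tab)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["trait", "snp_id", "k_studies", "X", "df", "p"])

    def stratified(self, trait: str = "t2d") -> Dict[str, dict]:
        """Incident/prevalent case-restricted reruns (controls shared)."""
        out = {}
        for stratum in ("incident", "prevalent"):
            name = f"{trait}_{stratum}"
            if name in self.trait_results:
                out[stratum] = self.trait_results[name]
        return out

    def ld_comparison(self) -> pd.DataFrame:
        """Univariable vs multivariable (LD-corrected) per-SNP comparison on
        both the per-allele and the per-1-mmol/L scales."""
        uni: Dict[str, Dict[str, list]] = {}
        for e in self.kept_estimates:
            if e.trait_name.endswith(("_incident", "_prevalent")):
                continue
            uni.setdefault(e.trait_name, {}).setdefault(e.snp_id, []).append(e)
        multi: Dict[str, Dict[str, list]] = {}
        for e in self._study_out["multivariable"]:
            if self.model.exclude_flagged and e.flags:
                continue
            multi.setdefault(e.trait_name, {}).setdefault(e.snp_id, []).append(e)
        traits = sorted(set(uni) & set(multi))
        uni_c, multi_c = {}, {}
        for t in traits:
            snps = sorted(set(uni[t]) & set(multi[t]))
            if snps:
                uni_c[t] = {s: uni[t][s] for s in snps}
                multi_c[t] = {s: multi[t][s] for s in snps}
        return diagnostics.ld_correction_report(uni_c, multi_c)
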