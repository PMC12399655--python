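"""End-to-end synthetic study: plant a signature, then rediscover it.

This thin orchestration layer wires the pipeline stages together in their
canonical order on fully synthetic data:

1. simulate multi-region cohorts, score heterogeneity, classify quadrants
   per cohort and intersect Q1 into the consensus evolution-related set;
2. simulate paired tumor-normal samples and run paired differential
   expression;
3. simulate a survival training cohort and run the univariate Cox screen;
4. intersect the three gene sets into candidates, refine by stability
   selection, and fit the multivariate Cox signature;
5. score an independent validation cohort, dichotomize at the median and
   evaluate (log-rank, high-vs-low hazard ratio, concordance,
   time-dependent AUC).

Because the generating truth is known, the run reports how many planted
signature genes the pipeline recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diffexpr, heterogeneity, signature, simulate, surveval
from .datatypes import SignatureModel, SurvivalCohort
from .simulate import SimTruth

__all__ = ["run_synthetic_study", "StudyResult"]


@dataclass
class StudyResult:
    """Everything a synthetic rediscovery run produced."""

    truth: SimTruth
    consensus: set[str]
    de_genes: set[str]
    surv_genes: set[str]
    candidates: list[str]
    stability: signature.StabilityResult
    model: SignatureModel
    validation: SurvivalCohort = field(repr=False)
    scores: pd.Series = field(repr=False)
    groups: pd.DataFrame = field(repr=False)
    hr_high_vs_low: float
    logrank_stat: float
    logrank_p: float
    c_index: float
    auc: float
    auc_horizon: float
    recovery: float

    def summary(self) -> dict:
        return {
            "n_consensus": len(self.consensus),
            "n_de": len(self.de_genes),
            "n_surv": len(self.surv_genes),
            "n_candidates": len(self.candidates),
            "n_selected": len(self.stability.selected),
            "hr_high_vs_low": self.hr_high_vs_low,
            "logrank_p": self.logrank_p,
            "c_index": self.c_index,
            "auc": self.auc,
            "recovery": self.recovery,
        }


def run_synthetic_study(
    seed: int = 0,
    truth: SimTruth | None = None,
    n_multiregion_cohorts: int = 2,
    n_patients_per_cohort: int = 40,
    n_pairs: int = 50,
    n_train: int = 500,
    n_validation: int = 300,
    n_iter: int = 100,
    freq_min: float = 0.85,
) -> StudyResult:
    """Run the whole discovery-and-validation loop on synthetic data.

    All sources of randomness derive from ``seed``; identical seeds give
    identical results.  The defaults are the scaled-down study size used
    throughout the test suite (two multi-region cohorts of 40 patients,
    500 training / 300 validation samples, 100 stability iterations).
    """
    if truth is None:
        truth = simulate.make_truth(seed=seed)

    # 1. heterogeneity consensus across multi-region cohorts
    tables = []
    for c in range(n_multiregion_cohorts):
        data, _ = simulate.gen_multiregion(
            n_patients_per_cohort, (3, 5), truth, seed=seed * 1000 + c
        )
        scores = heterogeneity.heterogeneity_scores(data)
        tables.append(heterogeneity.classify_quadrants(scores))
    consensus = heterogeneity.consensus_evogenes(tables)

    # 2. paired tumor-normal differential expression
    tumor, normal, _ = simulate.gen_paired_tumor_normal(
        n_pairs, truth, seed=seed * 1000 + 101
    )
    _, de_genes = diffexpr.paired_bulk_de(tumor, normal)

    # 3. univariate Cox screen on the training cohort
    train, _ = simulate.gen_survival_cohort(n_train, truth, seed=seed * 1000 + 201)
    screen = surveval.cox_screen(train)
    surv_genes = set(screen.index[screen["significant"]])

    # 4. candidates -> stability selection -> final signature
    candidates = sorted(signature.candidate_genes(consensus, de_genes, surv_genes))
    stability = signature.stability_select(
        train, candidates, n_iter=n_iter, freq_min=freq_min, seed=seed
    )
    selected = stability.selected
    if not selected:
        raise RuntimeError("stability selection retained no genes")
    model = signature.fit_cox_signature(
        train, selected, meta={"seed": seed, "n_iter": n_iter}
    )

    # 5. independent validation: score, dichotomize, evaluate
    validation, _ = simulate.gen_survival_cohort(
        n_validation, truth, seed=seed * 1000 + 301
    )
    scores = signature.score_samples(model, validation.expr, standardize="cohort")
    groups = signature.dichotomize(scores)
    stat, logrank_p = surveval.logrank(
        validation.time, validation.event, groups["group"]
    )
    df = pd.DataFrame(
        {
            "time": validation.time,
            "event": validation.event,
            "high": (groups["group"] == "high").astype(float).to_numpy(),
        }
    )
    hr = float(surveval.cox_fit(df, ["high"]).summary.loc["high", "hr"])
    c_index = surveval.harrell_c(
        scores.to_numpy(), validation.time, validation.event
    )
    horizon = float(np.quantile(validation.time, 0.5))
    auc = surveval.time_dependent_auc(
        scores.to_numpy(), validation.time, validation.event, horizon
    )

    planted = truth.signature_genes()
    recovery = len(set(selected) & set(planted)) / len(planted) if planted else np.nan
    return StudyResult(
        truth=truth,
        consensus=consensus,
        de_genes=de_genes,
        surv_genes=surv_genes,
        candidates=candidates,
        stability=stability,
        model=model,
        validation=validation,
        scores=scores,
        groups=groups,
        hr_high_vs_low=hr,
        logrank_stat=stat,
        logrank_p=logrank_p,
        c_index=c_index,
        auc=auc,
        auc_horizon=horizon,
        recovery=recovery,
    )
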