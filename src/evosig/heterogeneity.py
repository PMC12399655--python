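"""Per-gene intra- and inter-tumoral heterogeneity scoring.

A gene's *intra* score summarizes how much its expression varies among
regions of the same tumor; its *inter* score measures how much its
tumor-level (patient-mean) expression varies between patients.  Genes high
on both axes — above the 75th percentile of each score — form the Q1
quadrant; intersecting Q1 across independent multi-region cohorts yields
the consensus set of evolution-related genes used as candidates for
prognostic modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MultiRegionMatrix

__all__ = [
    "heterogeneity_scores",
    "classify_quadrants",
    "consensus_evogenes",
    "enrichment_odds_ratio",
    "prognostic_enrichment",
    "EnrichmentResult",
    "PrognosticEnrichment",
    "INTRA_SUMMARIES",
]

#: Registry of summaries pooling per-patient within-tumor SDs into one
#: intra score.  "median" (the default) is robust to one outlier patient;
#: alternatives can be slotted in without touching callers.
INTRA_SUMMARIES: dict[str, Callable[[np.ndarray], float]] = {
    "median": np.median,
    "mean": np.mean,
    "mad": lambda a: float(stats.median_abs_deviation(a, scale="normal")),
}

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")


def heterogeneity_scores(
    data: MultiRegionMatrix,
    min_regions: int = 2,
    intra_summary: str = "median",
) -> pd.DataFrame:
    """Compute per-gene intra- and inter-tumoral heterogeneity scores.

    intra_score_g = summary (default: median) over patients with at least
    ``min_regions`` regions of the sample SD of gene g across that
    patient's regions.  inter_score_g = sample SD across patients of the
    per-patient mean of gene g.  Both are in log2-expression SD units, so
    adding a constant to a gene leaves its scores unchanged and scaling by
    c > 0 scales both scores by c.

    Returns a DataFrame indexed by gene with columns ``intra`` and
    ``inter``; provenance (summary choice, min_regions) is stored in
    ``.attrs``.
    """
    if intra_summary not in INTRA_SUMMARIES:
        raise KeyError(
            f"unknown intra summary {intra_summary!r}; "
            f"known: {sorted(INTRA_SUMMARIES)}"
        )
    summary = INTRA_SUMMARIES[intra_summary]
    patients = data.patient_of
    counts = patients.value_counts()
    qualifying = counts.index[counts >= min_regions]
    if len(qualifying) < 2:
        raise ValueError(
            f"need >= 2 patients with >= {min_regions} regions; "
            f"found {len(qualifying)} among {len(counts)} patients"
        )

    by_patient = data.values.T.groupby(patients)
    # per-patient SD across regions (genes x patients), sample SD (ddof=1)
    sds = by_patient.std(ddof=1).T[qualifying]
    means = by_patient.mean().T  # all patients contribute to inter

    intra = sds.apply(lambda row: summary(row.to_numpy(dtype=float)), axis=1)
    inter = means.std(axis=1, ddof=1)

    out = pd.DataFrame({"intra": intra, "inter": inter})
    out.index.name = "gene"
    out.attrs["intra_summary"] = intra_summary
    out.attrs["min_regions"] = min_regions
    return out


def classify_quadrants(scores: pd.DataFrame, q: float = 0.75) -> pd.DataFrame:
    """Assign heterogeneity quadrants at the ``q``-th percentile.

    Thresholds are the per-metric ``q``-quantiles over all scored genes
    (linear interpolation between order statistics).  A score is "high"
    only if strictly greater than its threshold; ties at the threshold are
    low.  Q1 = both high, Q2 = inter high only, Q3 = both low,
    Q4 = intra high only.
    """
    if not 0 < q < 1:
        raise ValueError("quantile must lie in (0, 1)")
    if len(scores) < 4:
        raise ValueError("need scores for at least 4 genes")
    intra_thr = float(np.quantile(scores["intra"], q, method="linear"))
    inter_thr = float(np.quantile(scores["inter"], q, method="linear"))
    intra_high = scores["intra"].to_numpy() > intra_thr
    inter_high = scores["inter"].to_numpy() > inter_thr
    quadrant = np.where(
        intra_high & inter_high,
        "Q1",
        np.where(inter_high, "Q2", np.where(intra_high, "Q4", "Q3")),
    )
    out = scores.copy()
    out["quadrant"] = quadrant
    out.attrs.update(scores.attrs)
    out.attrs["quantile"] = q
    out.attrs["intra_threshold"] = intra_thr
    out.attrs["inter_threshold"] = inter_thr
    out.attrs["quantile_rule"] = "linear interpolation; high = strictly greater"
    return out


def consensus_evogenes(quadrant_tables: Sequence[pd.DataFrame]) -> set[str]:
    """Intersect Q1 gene sets across cohorts.

    Adding a table can only shrink (never enlarge) the consensus.
    """
    tables = list(quadrant_tables)
    if not tables:
        raise ValueError("need at least one quadrant table")
    consensus: set[str] | None = None
    for tab in tables:
        if "quadrant" not in tab.columns:
            raise ValueError("table lacks quadrant labels; run classify_quadrants")
        q1 = set(tab.index[tab["quadrant"] == "Q1"])
        consensus = q1 if consensus is None else consensus & q1
    assert consensus is not None
    return consensus


@dataclass
class EnrichmentResult:
    odds_ratio: float
    p_value: float
    continuity_corrected: bool = False


def enrichment_odds_ratio(
    k_in: int, n_in: int, k_bg: int, n_bg: int
) -> EnrichmentResult:
    """Sample odds ratio of a foreground proportion against a background.

    OR = (k_in/(n_in-k_in)) / (k_bg/(n_bg-k_bg)).  The background is the
    full expressed-gene set and may contain the foreground; the printed
    arithmetic of enrichment figures (e.g. 28/192 signature genes vs
    449/12,429 expressed genes) follows this convention.  A two-sided
    Fisher exact p-value on the 2x2 counts is reported alongside.  If any
    cell is zero the OR uses a 0.5 continuity correction and is flagged.
    """
    if not (0 <= k_in <= n_in and 0 <= k_bg <= n_bg):
        raise ValueError("counts must satisfy 0 <= k <= n")
    table = np.array(
        [[k_in, n_in - k_in], [k_bg, n_bg - k_bg]], dtype=float
    )
    corrected = bool((table == 0).any())
    t = table + 0.5 if corrected else table
    odds = (t[0, 0] / t[0, 1]) / (t[1, 0] / t[1, 1])
    _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
    return EnrichmentResult(float(odds), float(p), corrected)


@dataclass
class PrognosticEnrichment:
    """Outcome of testing whether a gene set concentrates prognostic signal."""

    shift_statistic: float
    shift_p: float
    odds_ratio: float
    fisher_p: float
    prop_in: float
    prop_out: float
    n_in: int
    n_out: int


def prognostic_enrichment(
    gene_set: Iterable[str],
    cox_p: pd.Series,
    alpha: float = 0.05,
) -> PrognosticEnrichment:
    """Compare univariate Cox screening p-values inside vs outside a set.

    (i) a two-sided Mann-Whitney rank test asks whether p-values of set
    genes are shifted relative to the complement; (ii) the proportion with
    p < ``alpha`` ("prognosis-associated") in each group is compared with
    a sample odds ratio and Fisher exact p.
    """
    gene_set = set(gene_set)
    missing = gene_set - set(cox_p.index)
    if missing:
        raise ValueError(f"genes not screened: {sorted(missing)[:5]}")
    in_mask = cox_p.index.isin(gene_set)
    p_in = cox_p[in_mask].to_numpy(dtype=float)
    p_out = cox_p[~in_mask].to_numpy(dtype=float)
    if len(p_in) < 10 or len(p_out) < 10:
        raise ValueError("need >= 10 genes inside and outside the set")
    stat, shift_p = stats.mannwhitneyu(p_in, p_out, alternative="two-sided")
    k_in = int((p_in < alpha).sum())
    k_out = int((p_out < alpha).sum())
    table = [[k_in, len(p_in) - k_in], [k_out, len(p_out) - k_out]]
    odds, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    # report the unconditional sample OR (with continuity fallback), not
    # scipy's conditional estimate, for consistency with enrichment_odds_ratio
    t = np.array(table, dtype=float)
    if (t == 0).any():
        t = t + 0.5
    sample_or = (t[0, 0] / t[0, 1]) / (t[1, 0] / t[1, 1])
    return PrognosticEnrichment(
        shift_statistic=float(stat),
        shift_p=float(shift_p),
        odds_ratio=float(sample_or),
        fisher_p=float(fisher_p),
        prop_in=k_in / len(p_in),
        prop_out=k_out / len(p_out),
        n_in=len(p_in),
        n_out=len(p_out),
    )
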