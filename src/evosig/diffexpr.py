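"""Differential-expression filters.

Two flavours feed the signature pipeline:

* :func:`paired_bulk_de` — paired tumor vs adjacent-normal bulk log2
  expression, tested gene-wise with a paired Wilcoxon signed-rank test and
  Benjamini-Hochberg correction.  Genes pass with ``|log2FC| > 1`` and
  adjusted p < 0.05.
* :func:`sc_de` — two-group single-cell comparison on library-size
  normalized, log1p-transformed counts with a Wilcoxon rank-sum test,
  mirroring the common marker-test conventions (``min.pct = 0.10``,
  log-fold-change threshold 0.25, minimum 10 cells per group).
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["paired_bulk_de", "sc_de", "normalize_log1p"]

#: library size every cell is scaled to before log1p
TARGET_SUM = 10_000.0


def paired_bulk_de(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    exact_max_pairs: int = 25,
) -> tuple[pd.DataFrame, set[str]]:
    """Paired tumor-normal differential expression on log2 values.

    Per gene, the paired differences (tumor minus normal, matched by
    column) are tested with a two-sided Wilcoxon signed-rank test — exact
    for up to ``exact_max_pairs`` pairs, otherwise a tie-corrected normal
    approximation — and ``log2_fc`` is the mean paired difference.
    P-values are Benjamini-Hochberg adjusted across all tested genes.

    The significant set applies strict inequalities:
    ``|log2_fc| > lfc_min`` and ``p_adjusted < alpha``.

    Returns
    -------
    (table, significant)
        ``table`` has one row per gene (log2_fc, p, p_adjusted,
        significant, degenerate); ``significant`` is the passing gene set.
        All-constant genes (every paired difference zero) get p = 1 and a
        ``degenerate`` flag.
    """
    if not tumor.index.equals(normal.index):
        raise ValueError("tumor and normal matrices must share the gene index")
    if list(tumor.columns) != list(normal.columns):
        raise ValueError("inputs are not paired: column (pair) ids differ")
    n_pairs = tumor.shape[1]
    if n_pairs < 3:
        raise ValueError("need at least 3 pairs")

    diffs = tumor.to_numpy(dtype=float) - normal.to_numpy(dtype=float)
    log2_fc = diffs.mean(axis=1)
    method = "exact" if n_pairs <= exact_max_pairs else "approx"

    pvals = np.ones(diffs.shape[0])
    degenerate = np.zeros(diffs.shape[0], dtype=bool)
    nonzero_any = (diffs != 0).any(axis=1)
    degenerate[~nonzero_any] = True
    idx = np.flatnonzero(nonzero_any)
    if idx.size:
        # wilcoxon supports vectorized input along axis
        res = stats.wilcoxon(
            diffs[idx],
            axis=1,
            alternative="two-sided",
            method=method,
            zero_method="wilcox",
        )
        pvals[idx] = np.atleast_1d(res.pvalue)
    pvals = np.clip(pvals, 0.0, 1.0)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")

    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p": pvals,
            "p_adjusted": p_adj,
            "degenerate": degenerate,
        },
        index=tumor.index,
    )
    table["significant"] = (np.abs(table["log2_fc"]) > lfc_min) & (
        table["p_adjusted"] < alpha
    )
    table.attrs["test"] = f"wilcoxon signed-rank ({method})"
    table.attrs["lfc_min"] = lfc_min
    table.attrs["alpha"] = alpha
    sig = set(table.index[table["significant"]])
    return table, sig


def normalize_log1p(
    counts: np.ndarray, target_sum: float = TARGET_SUM
) -> np.ndarray:
    """Scale each cell (row) to ``target_sum`` total counts, then log1p."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(counts / lib * target_sum)


def _resolve_groups(
    cells: ad.AnnData,
    group_a,
    group_b,
    group_by: str | None,
) -> tuple[np.ndarray, np.ndarray, str, str]:
    if group_by is not None:
        labels = cells.obs[group_by].to_numpy()
        mask_a = labels == group_a
        mask_b = labels == group_b
        return mask_a, mask_b, str(group_a), str(group_b)
    mask_a = np.asarray(group_a)
    mask_b = np.asarray(group_b)
    if mask_a.dtype != bool:
        mask_a = cells.obs_names.isin(mask_a)
    if mask_b.dtype != bool:
        mask_b = cells.obs_names.isin(mask_b)
    return mask_a, mask_b, "A", "B"


def sc_de(
    cells: ad.AnnData,
    group_a,
    group_b,
    group_by: str | None = None,
    min_pct: float = 0.10,
    lfc_min: float = 0.25,
    min_cells: int = 10,
    alpha: float = 0.05,
    correction: str = "fdr",
    target_sum: float = TARGET_SUM,
) -> pd.DataFrame:
    """Two-group single-cell differential expression.

    Counts are normalized per cell to ``target_sum`` and log1p
    transformed.  Genes are tested only if detected (count > 0) in at
    least ``min_pct`` of the cells of one group.  The test is a two-sided
    Wilcoxon rank-sum (Mann-Whitney, mid-ranks with tie correction);
    ``log_fc`` is the difference of group means of the log1p-normalized
    values (group A minus group B).  Multiple testing uses
    Benjamini-Hochberg by default (``correction="fdr"``) or Bonferroni
    (``correction="bonferroni"``); the significance call is
    ``|log_fc| > lfc_min`` and adjusted p < ``alpha``.

    ``group_a`` / ``group_b`` are labels of ``obs[group_by]`` when
    ``group_by`` is given, else boolean masks or cell-id lists.
    """
    mask_a, mask_b, name_a, name_b = _resolve_groups(
        cells, group_a, group_b, group_by
    )
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    for name, n in ((name_a, n_a), (name_b, n_b)):
        if n < min_cells:
            raise ValueError(
                f"group {name!r} has {n} cells; at least {min_cells} required"
            )
    if correction not in ("fdr", "bonferroni"):
        raise ValueError("correction must be 'fdr' or 'bonferroni'")

    counts = np.asarray(cells.X)
    xa_raw, xb_raw = counts[mask_a], counts[mask_b]
    pct_a = (xa_raw > 0).mean(axis=0)
    pct_b = (xb_raw > 0).mean(axis=0)
    tested = (pct_a >= min_pct) | (pct_b >= min_pct)

    xa = normalize_log1p(xa_raw, target_sum)
    xb = normalize_log1p(xb_raw, target_sum)
    log_fc = xa.mean(axis=0) - xb.mean(axis=0)

    genes = cells.var_names
    pvals = np.full(len(genes), np.nan)
    t_idx = np.flatnonzero(tested)
    if t_idx.size:
        res = stats.mannwhitneyu(
            xa[:, t_idx],
            xb[:, t_idx],
            axis=0,
            alternative="two-sided",
            method="asymptotic",
        )
        pvals[t_idx] = np.atleast_1d(res.pvalue)

    table = pd.DataFrame(
        {
            "log_fc": log_fc,
            "p": pvals,
            f"pct_{name_a}": pct_a,
            f"pct_{name_b}": pct_b,
            "tested": tested,
        },
        index=genes,
    )
    table = table[table["tested"]].drop(columns="tested")
    if len(table):
        if correction == "fdr":
            _, p_adj, _, _ = multipletests(table["p"], method="fdr_bh")
        else:
            _, p_adj, _, _ = multipletests(table["p"], method="bonferroni")
        table["p_adjusted"] = p_adj
    else:
        table["p_adjusted"] = pd.Series(dtype=float)
    table["significant"] = (table["log_fc"].abs() > lfc_min) & (
        table["p_adjusted"] < alpha
    )
    table.attrs["normalization"] = f"counts/cell -> {target_sum:g}, log1p"
    table.attrs["correction"] = correction
    table.attrs["groups"] = (name_a, n_a, name_b, n_b)
    return table
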