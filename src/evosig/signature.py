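"""Evolutionary signature construction.

Candidate genes are the three-way intersection of (i) the consensus
high-heterogeneity (Q1) set, (ii) tumor-normal differentially expressed
genes and (iii) genes passing a univariate Cox screen.  Candidates are
then refined by stability selection: the training cohort is repeatedly
subsampled, an L1-penalized Cox model (LASSO) is fitted per subsample with
its penalty chosen by internal cross-validation, and genes selected in
more than a frequency cutoff of iterations (default 0.85, i.e. more than
850 of 1,000) are retained.  The final signature is an unpenalized
multivariate Cox fit on standardized expression; risk scores are the
linear predictor and cohorts are dichotomized at their median score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .datatypes import SignatureModel, SurvivalCohort

__all__ = [
    "candidate_genes",
    "stability_select",
    "StabilityResult",
    "fit_cox_signature",
    "score_samples",
    "dichotomize",
]


def candidate_genes(
    evo: Iterable[str], de: Iterable[str], surv: Iterable[str]
) -> set[str]:
    """Three-way intersection of the heterogeneity, DE and survival filters."""
    return set(evo) & set(de) & set(surv)


def _breslow_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of a fixed linear predictor."""
    order = np.argsort(time, kind="stable")
    t, e, x = time[order], event[order], lp[order]
    # log of the risk-set sum exp(lp) for every suffix, computed stably
    m = x.max() if len(x) else 0.0
    rev = np.log(np.cumsum(np.exp(x - m)[::-1])[::-1]) + m
    # risk set of an event at t_i starts at the first index with time >= t_i
    starts = np.searchsorted(t, t, side="left")
    ev = e.astype(bool)
    return float(np.sum(x[ev] - rev[starts[ev]]))


def _cv_choose_alpha(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    alphas: np.ndarray,
    l1_ratio: float,
    n_folds: int,
    rng: np.random.Generator,
    rule: str = "1se",
) -> float:
    """Pick the penalty by cross-validated partial likelihood.

    Uses the Verweij & van Houwelingen criterion (full-data partial
    likelihood minus training-fold partial likelihood per left-out fold),
    which stays defined even when a held-out fold has few events.

    ``rule="min"`` returns the penalty maximizing the mean CV likelihood;
    ``rule="1se"`` (default) returns the largest penalty whose mean CV
    likelihood is within one standard error of the maximum — the sparser
    conventional choice when the fit is used for support recovery.
    """
    n = len(time)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    y_all = Surv.from_arrays(event.astype(bool), time)
    cv = np.zeros((n_folds, len(alphas)))
    for k, test_idx in enumerate(folds):
        train = np.setdiff1d(perm, test_idx, assume_unique=False)
        xt, tt, et = x[train], time[train], event[train]
        model = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio, alphas=alphas, fit_baseline_model=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(xt, Surv.from_arrays(et.astype(bool), tt))
        coefs = model.coef_  # p x n_fitted_alphas
        fitted = np.asarray(model.alphas_)
        for j, a in enumerate(alphas):
            jj = int(np.argmin(np.abs(fitted - a)))
            beta = coefs[:, jj]
            ll_full = _breslow_loglik(x @ beta, time, event)
            ll_train = _breslow_loglik(xt @ beta, tt, et)
            cv[k, j] = ll_full - ll_train
    mean = cv.mean(axis=0)
    best = int(np.argmax(mean))
    if rule == "min":
        return float(alphas[best])
    se = cv.std(axis=0, ddof=1) / np.sqrt(n_folds)
    ok = np.flatnonzero(mean >= mean[best] - se[best])
    # alphas come sorted descending: the first qualifying index is the
    # largest (sparsest) penalty within one SE of the best
    return float(alphas[ok[0]])


@dataclass
class StabilityResult:
    """Per-candidate selection frequencies and the retained gene set."""

    frequencies: pd.Series
    selected: list[str]
    n_iter: int
    freq_min: float
    n_redraws: int = 0


def stability_select(
    cohort: SurvivalCohort,
    candidates: Sequence[str],
    n_iter: int = 1000,
    freq_min: float = 0.85,
    subsample_frac: float = 0.8,
    l1_ratio: float = 1.0,
    n_folds: int = 5,
    n_alphas: int = 25,
    alpha_min_ratio: float = 0.05,
    cv_rule: str = "1se",
    seed: int = 0,
    max_redraws: int = 10,
) -> StabilityResult:
    """Stability selection with L1-penalized Cox regression.

    Per iteration a subsample of ``subsample_frac`` of the cohort is drawn
    without replacement, candidate genes are standardized on the
    subsample, a penalized Cox path is fitted (pure LASSO by default;
    ``l1_ratio`` exposes the elastic-net mixing) and the penalty is chosen
    by ``n_folds``-fold cross-validated partial likelihood within the
    subsample (``cv_rule="1se"`` keeps the sparsest penalty within one
    standard error of the CV optimum, the conventional choice for support
    recovery; ``"min"`` uses the optimum itself).  Genes with nonzero coefficients at the chosen penalty
    count as selected.  The retained set is
    ``{gene : frequency > freq_min}`` (strictly greater, so the default
    0.85 corresponds to more than 850 of 1,000 iterations).

    Iteration seeds derive deterministically from ``seed`` and the
    iteration index, so results are reproducible and insensitive to
    execution order.
    """
    candidates = list(candidates)
    missing = set(candidates) - set(cohort.genes)
    if missing:
        raise ValueError(f"candidates absent from cohort: {sorted(missing)[:5]}")
    if not candidates:
        raise ValueError("empty candidate set")
    x_full = cohort.expr.loc[candidates].to_numpy(dtype=float).T  # n x p
    time, event = cohort.time, cohort.event
    n = len(time)
    size = max(2, int(round(subsample_frac * n)))

    hits = np.zeros(len(candidates))
    n_redraws = 0
    for it in range(n_iter):
        rng = np.random.default_rng([int(seed), it])
        for attempt in range(max_redraws + 1):
            idx = rng.choice(n, size=size, replace=False)
            if event[idx].sum() > 0:
                break
            n_redraws += 1
        else:
            warnings.warn(f"iteration {it}: no events after {max_redraws} redraws")
            continue
        xs = x_full[idx]
        mu = xs.mean(axis=0)
        sd = xs.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        xs = (xs - mu) / sd
        ts, es = time[idx], event[idx]
        y = Surv.from_arrays(es.astype(bool), ts)
        path = CoxnetSurvivalAnalysis(
            l1_ratio=l1_ratio,
            n_alphas=n_alphas,
            alpha_min_ratio=alpha_min_ratio,
            fit_baseline_model=False,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path.fit(xs, y)
        alphas = np.asarray(path.alphas_)
        best = _cv_choose_alpha(
            xs, ts, es, alphas, l1_ratio, n_folds, rng, rule=cv_rule
        )
        jj = int(np.argmin(np.abs(alphas - best)))
        hits += path.coef_[:, jj] != 0

    freq = pd.Series(hits / n_iter, index=pd.Index(candidates, name="gene"))
    selected = freq.index[freq > freq_min].tolist()
    return StabilityResult(
        frequencies=freq,
        selected=selected,
        n_iter=n_iter,
        freq_min=freq_min,
        n_redraws=n_redraws,
    )


def fit_cox_signature(
    cohort: SurvivalCohort,
    genes: Sequence[str],
    meta: dict | None = None,
) -> SignatureModel:
    """Unpenalized multivariate Cox fit on standardized gene expression.

    Coefficients are per-SD log hazards (Efron tie handling).  The model
    stores the training mean/SD of each gene and the training median risk
    score so external cohorts can be scored and dichotomized consistently.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("need at least one gene")
    missing = set(genes) - set(cohort.genes)
    if missing:
        raise ValueError(f"genes absent from cohort: {sorted(missing)[:5]}")
    x = cohort.expr.loc[genes].T.astype(float)
    sds = x.std(ddof=1)
    constant = sds.index[sds == 0].tolist()
    if constant:
        raise ValueError(f"constant gene(s) cannot be fitted: {constant}")
    if cohort.n_events() <= len(genes):
        raise ValueError(
            f"{cohort.n_events()} events cannot identify {len(genes)} coefficients"
        )
    means = x.mean()
    z = (x - means) / sds
    df = z.copy()
    df["time"] = cohort.time
    df["event"] = cohort.event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise ValueError(f"Cox fit did not converge: {err}") from err
    beta = cph.params_.loc[genes]
    scores = z.to_numpy() @ beta.to_numpy()
    return SignatureModel(
        genes=genes,
        beta=beta,
        mean=means.loc[genes],
        sd=sds.loc[genes],
        train_median_score=float(np.median(scores)),
        meta=dict(meta or {}),
    )


def score_samples(
    model: SignatureModel,
    expr: pd.DataFrame,
    standardize: str = "cohort",
    on_missing: str = "error",
) -> pd.Series:
    """Risk scores ``score_i = sum_g beta_g * z_{g,i}``.

    ``standardize="train"`` reuses the training mean/SD (same-platform
    scoring); ``"cohort"`` re-standardizes each gene within the scored
    cohort, the robust default when weights cross profiling platforms.
    Missing model genes raise by default; ``on_missing="drop"`` scores
    with the remaining genes after a warning.
    """
    if standardize not in ("train", "cohort"):
        raise ValueError("standardize must be 'train' or 'cohort'")
    genes = [g for g in model.genes if g in expr.index]
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        if on_missing == "drop":
            warnings.warn(f"scoring without missing genes: {missing}")
        else:
            raise ValueError(f"model genes missing from matrix: {missing}")
    if not genes:
        raise ValueError("no model genes present in the matrix")
    x = expr.loc[genes].T.astype(float)
    if standardize == "train":
        z = (x - model.mean.loc[genes]) / model.sd.loc[genes]
    else:
        sd = x.std(ddof=1).replace(0.0, np.nan)
        z = (x - x.mean()) / sd
        z = z.fillna(0.0)  # constant gene contributes nothing in-cohort
    scores = z.to_numpy() @ model.beta.loc[genes].to_numpy()
    return pd.Series(scores, index=expr.columns, name="score")


def dichotomize(
    scores: pd.Series, threshold: float | None = None
) -> pd.DataFrame:
    """Split samples into high/low risk at the median score.

    ``threshold`` defaults to the scored cohort's own median (the
    convention for cross-cohort evaluation); pass
    ``model.train_median_score`` to dichotomize against the training
    distribution instead.  Ties at the threshold go to "low".
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 samples")
    thr = float(np.median(scores.to_numpy(dtype=float))) if threshold is None else threshold
    group = np.where(scores.to_numpy(dtype=float) > thr, "high", "low")
    out = pd.DataFrame({"score": scores, "group": group}, index=scores.index)
    out.attrs["threshold"] = thr
    return out
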