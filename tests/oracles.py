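"""Brute-force reference implementations used as independent oracles.

Everything here is deliberately naive (explicit loops, no vectorization,
no shared code with the package) so it can serve as an independent check
of the production implementations.
"""

import numpy as np


def brute_harrell(scores, times, events) -> float:
    """Exhaustive pair enumeration of Harrell's concordance index."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            usable = (events[i] == 1 and times[i] < times[j]) or (
                events[i] == 1 and events[j] == 0 and times[i] == times[j]
            )
            if not usable:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


def brute_censoring_km(times, events, t, left=False) -> float:
    """Product-limit estimate of the censoring distribution at t (or t-)."""
    surv = 1.0
    for u in sorted(set(times)):
        if (u < t) if left else (u <= t):
            d = sum(1 for tt, ee in zip(times, events) if tt == u and ee == 0)
            at_risk = sum(1 for tt in times if tt >= u)
            if d:
                surv *= 1 - d / at_risk
    return surv


def brute_ipcw_auc(scores, times, events, horizon) -> float:
    """Weighted Mann-Whitney computation of the cumulative/dynamic AUC."""
    cases = [i for i in range(len(times)) if times[i] <= horizon and events[i] == 1]
    controls = [j for j in range(len(times)) if times[j] > horizon]
    g_t = brute_censoring_km(times, events, horizon)
    num = den = 0.0
    for i in cases:
        wi = 1.0 / brute_censoring_km(times, events, times[i], left=True)
        for j in controls:
            w = wi * (1.0 / g_t)
            den += w
            if scores[i] > scores[j]:
                num += w
            elif scores[i] == scores[j]:
                num += 0.5 * w
    return num / den


def brute_logrank_two_group(times, events, groups) -> float:
    """Per-event-time hypergeometric accumulation of the log-rank statistic."""
    o_minus_e = 0.0
    var = 0.0
    for u in sorted({t for t, e in zip(times, events) if e == 1}):
        at_risk = [(g, t) for g, t, e in zip(groups, times, events) if t >= u]
        n = len(at_risk)
        n1 = sum(1 for g, _ in at_risk if g == 1)
        d = sum(1 for t, e in zip(times, events) if t == u and e == 1)
        d1 = sum(
            1 for g, t, e in zip(groups, times, events) if t == u and e == 1 and g == 1
        )
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def brute_quadrants(scores, q) -> list[str]:
    """Sort-and-threshold quadrant labelling with the strict-inequality rule."""
    thr_i = np.quantile(np.sort(scores["intra"]), q)
    thr_e = np.quantile(np.sort(scores["inter"]), q)
    out = []
    for _, row in scores.iterrows():
        hi_i, hi_e = row["intra"] > thr_i, row["inter"] > thr_e
        out.append(
            "Q1" if hi_i and hi_e else "Q2" if hi_e else "Q4" if hi_i else "Q3"
        )
    return out


def censored_sample(n, seed, effect=0.0):
    """A small censored survival sample with optional score-linked hazard."""
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=n)
    t_event = rng.exponential(np.exp(-effect * scores))
    t_cens = rng.exponential(1.5, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return scores, time, event
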