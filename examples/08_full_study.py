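"""The whole loop: plant a signature, rediscover it, validate it.

Runs every stage in order on synthetic data — heterogeneity consensus,
paired DE, Cox screen, stability selection, final Cox fit, validation
scoring — and reports how much of the planted truth came back.
"""

import evosig as es

res = es.run_synthetic_study(seed=1)
s = res.summary()
print(f"consensus Q1 genes: {s['n_consensus']}")
print(f"DE genes: {s['n_de']}, survival-screen genes: {s['n_surv']}")
print(f"candidates (3-way intersection): {s['n_candidates']}")
print(f"selected by stability selection: {s['n_selected']}")
print(f"planted signature genes recovered: {s['recovery']:.0%}")
print(
    f"validation: HR(high vs low) = {s['hr_high_vs_low']:.2f}, "
    f"log-rank p = {s['logrank_p']:.1e}, C = {s['c_index']:.3f}, "
    f"AUC = {s['auc']:.3f}"
)
# Recovery near 100% with HR well above 1 on an independent cohort shows
# the pipeline isolates exactly the genes that were simulated to be
# heterogeneous, dysregulated and prognostic.
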