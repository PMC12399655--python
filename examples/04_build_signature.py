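"""Build a risk signature: candidates -> stability selection -> Cox fit.

Candidate genes are the intersection of the heterogeneity consensus, the
DE set and the univariate Cox screen; stability selection (repeated
subsampling + cross-validated LASSO Cox) keeps genes selected in more
than 85% of iterations; the final model is an unpenalized multivariate
Cox fit on standardized expression.
"""

import evosig as es
from evosig.io import save_signature

truth = es.make_truth(seed=4)
cohort, _ = es.gen_survival_cohort(500, truth, seed=4)

evo = set(truth.gene_class.index[truth.gene_class == "Q1"])
de = set(truth.de_genes())
screen = es.cox_screen(cohort)
surv = set(screen.index[screen["significant"]])
candidates = sorted(es.candidate_genes(evo, de, surv))
print(f"candidates: {len(candidates)} genes")

stab = es.stability_select(cohort, candidates, n_iter=100, seed=4)
print(f"selected (frequency > {stab.freq_min}): {stab.selected}")

model = es.fit_cox_signature(cohort, stab.selected)
for g in model.genes:
    print(f"  {g}: beta = {model.beta[g]:+.2f} per SD")
print(f"training median risk score: {model.train_median_score:.3f}")

save_signature(model, "/tmp/evosig_model.json")
print("model written to /tmp/evosig_model.json")
# Positive betas mark genes whose high expression raises the hazard;
# the median score is the training dichotomization threshold.
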