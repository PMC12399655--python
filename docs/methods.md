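# Methods

## Heterogeneity model and scoring

A multi-region cohort provides log2 expression x_{g,p,r} for gene g, patient
p, region r. The two heterogeneity axes are estimated as

- **intra score**: the median over patients (with ≥ `min_regions` regions,
  default 2) of the within-patient sample SD of x across regions. The median
  was chosen over the mean for robustness to a single aberrant patient; the
  pooling statistic is pluggable through the `INTRA_SUMMARIES` registry
  (mean and normal-scaled MAD are provided) because reasonable labs define
  this summary differently.
- **inter score**: the sample SD across patients of per-patient mean
  expression. All patients contribute, including those too thin for the
  intra computation.

Both scores are in log2-expression SD units: adding a constant to a gene
changes neither score, scaling by c > 0 scales both by c.

**Quadrants.** Per cohort, each axis is thresholded at its 75th percentile
(linear-interpolation quantile). "High" means strictly greater than the
threshold, so ties at the threshold fall low — deterministic and
conservative toward calling Q1. Q1 = both high, Q2 = inter only,
Q3 = both low, Q4 = intra only. Only Q1 has a substantive downstream role;
the labels of the other quadrants are a documented convention. Quadrants are
computed per cohort and the Q1 sets intersected, so adding a cohort can only
shrink the consensus.

**Enrichment statistics.** The sample odds ratio of a foreground proportion
against a background uses the background *including* the foreground
(matching the published 28/192-vs-449/12,429 arithmetic, which reproduces
OR = 4.55); a two-sided Fisher exact p accompanies it, with a 0.5 continuity
correction (flagged) when a cell is zero. Prognostic enrichment of a gene
set combines a two-sided Mann–Whitney shift test on univariate Cox p-values
(in-set vs complement) with an odds ratio on the proportion below p < 0.05.

## Differential expression

**Paired bulk.** Per gene, tumor-minus-normal differences on the log2 scale
are tested with a two-sided Wilcoxon signed-rank test — exact for ≤ 25
pairs, tie-corrected normal approximation beyond — and log2FC is the mean
paired difference. BH adjustment runs across all tested genes; the
significant set applies strict |log2FC| > 1 and adjusted p < 0.05. This is a
deliberate departure from negative-binomial count models: the package
implements its own filter on normalized log expression, which is more
conservative on low-count genes; wherever downstream stages consume the DE
set it is an injectable argument, so an externally computed set can be
substituted.

**Single cell.** Counts are scaled per cell to 10,000 and log1p-transformed.
Genes enter testing only if detected in ≥ 10% of cells of one group
(min.pct); the test is a two-sided rank-sum with mid-ranks; logFC is the
difference of group means of the log1p-normalized values. Groups below 10
cells are refused by name. BH is the default correction for the
significance call (|logFC| > 0.25, adjusted p < 0.05), Bonferroni available
by flag — the marker-test tradition states Bonferroni for discovery but an
FDR criterion for the final call, and both readings are supported.

## Signature construction

Candidates are the three-way intersection of the Q1 consensus, the DE set
and the univariate Cox screen (Wald p < 0.05, Efron ties).

**Stability selection.** Per iteration i (seeded deterministically from the
master seed and i, so results do not depend on execution order): draw 80% of
the cohort without replacement (redrawing, bounded, if the subsample has no
events), standardize candidate genes on the subsample, fit an L1-penalized
Cox path (25 penalties, smallest = 5% of the largest; `l1_ratio` exposes
elastic-net mixing, default pure LASSO), choose the penalty by 5-fold
cross-validated partial likelihood and record genes with nonzero
coefficients. The CV criterion is the Verweij–van Houwelingen decomposition
(full-data minus training-fold partial likelihood), which remains defined
when a held-out fold is event-poor. The retained penalty follows the
one-standard-error rule — the sparsest penalty within one SE of the CV
optimum — because the fit is used for support recovery, where the CV-optimal
penalty is known to over-select variables whose chance association with
outcome persists across overlapping subsamples; `cv_rule="min"` restores the
optimum. Genes selected in strictly more than `freq_min` (default 0.85,
i.e. more than 850 of 1,000 iterations) of iterations are retained.

**Final fit and scoring.** The signature is an unpenalized multivariate Cox
partial-likelihood fit (Efron ties) on gene expression standardized to the
training cohort; coefficients are per-SD log hazards. Scores are
Σ β̂_g z_{g,i}. Two standardization modes exist at scoring time: `train`
reuses training means/SDs (same-platform application) and `cohort`
(default) re-standardizes within the scored cohort, which makes scores
invariant to any affine transform applied uniformly to a cohort — the
robust choice when weights trained on sequencing data are applied to
microarray cohorts. Dichotomization is at the scored cohort's median; ties
at the median go to "low", deterministic and conservative toward the
high-risk label. The training median is stored on the model for users who
prefer a fixed threshold.

## Survival evaluation

Kaplan–Meier estimation, the log-rank test and all Cox fitting are delegated
to lifelines (Newton–Raphson, Efron tie handling, Breslow baseline hazard).
The screening mode iterates univariate fits and records per-gene failures
without aborting.

**Harrell's C** counts a pair usable when the member with the shorter
observed time had the event (a tie in time is usable when exactly one member
had the event, the censored one counted as surviving longer); score ties
count one half. **Time-dependent AUC** is the cumulative/dynamic IPCW
estimator: cases are subjects with events by the horizon t weighted
1/G(T⁻), controls are subjects beyond t weighted 1/G(t), with G the
Kaplan–Meier estimate of the censoring distribution; with no censoring it
reduces to the empirical AUC of {T ≤ t} vs {T > t}, and the binary-response
ROC use case is exactly that special case. Both metrics are implemented
in-package with these conventions spelled out, and the test suite checks
them to machine precision against brute-force enumeration and against
scikit-survival's independent implementations. The incident/dynamic AUC
variant is not implemented.

**Meta-analysis** pools log hazard ratios by fixed-effect inverse variance;
DerSimonian–Laird random effects are behind a flag since heterogeneity
models are a reporting choice, not a default.

**Prediction and calibration.** S(t|x) = S₀(t)^exp(lp(x)) with the Breslow
baseline; the covariate-free null model returns the product-limit KM
estimate exactly (the exponentiated Nelson–Aalen baseline would differ
slightly). Horizons beyond follow-up warn and carry the last estimate
forward. A nomogram is this linear predictor rescaled to a 0–100 point
axis; the probabilities it maps to are these values, so no separate drawing
code is provided. Calibration bins samples into quantile groups of
predicted S(t) (default 3 bins, suited to a few hundred samples; heavily
tied predictions collapse bins with a warning), takes per-bin KM at t as
observed, and corrects optimism by the standard bootstrap-refit scheme
(default 1,000 resamples): per resample the model is refitted and the
bin-wise calibration error evaluated on the resample and on the original
data, the mean difference being subtracted from the apparent curve;
percentile bands come from the bootstrap distribution.

## Regional trends

Within one cell type, a gene is sustained-up when its mean log-normalized
expression strictly increases across the ordered zones N → B → T *and* the
change is supported by the single-cell DE machinery: the N-vs-T comparison
in `relaxed` mode, both adjacent steps (N-vs-B and B-vs-T) in `strict` mode,
each with sign consistency. "Sustained" is a qualitative notion in the
field; these two modes bracket its plausible operationalizations, and
strict calls are provably a subset of relaxed calls. Multiple core samples
are pooled into one T zone; patients are pooled by default (per-patient
analysis is possible by subsetting the cell metadata, with the usual caveat
that pooling can confound patient and zone).

## Synthetic data

The generators emulate the study designs the pipeline consumes:

- **Multi-region bulk**: x = μ_g + a_{g,p} + e_{g,p,r}, Gaussian on the log2
  scale, a ~ N(0, σ²_inter), e ~ N(0, σ²_intra) by gene class; 3–5 regions
  per patient by default, drawn uniformly. Class SDs default to 2.0 (high)
  vs 0.3 (low) log2 units — clearly separated, as planted-recovery checks
  assume. μ_g is uniform on 4–9 log2 units. The default class composition
  keeps each axis's high-SD classes under a quarter of all genes so the
  planted classes can fit inside the top quartile that the 75th-percentile
  rule selects; this is a geometric constraint of quantile thresholding,
  not a tuning knob.
- **Survival**: single-biopsy expression with marginal SD
  √(σ²_intra + σ²_inter); hazard h_i = h0·exp(Σ β_g z_{g,i}) with z the
  standardized expression (so β is a per-SD log hazard), exponential event
  times, independent Uniform(0, c_max) censoring. Defaults h0 = 0.1 events
  per time unit and c_max = 20 give roughly 40–45% censoring, in the range
  of observed overall-survival cohorts. The exponential/uniform pair is the
  simplest proportional-hazards model with closed-form checks
  (S(t|x) = exp(−h0 t e^{βx})).
- **Paired tumor-normal**: normal = μ + ε, tumor = μ + δ_g + ε,
  ε ~ N(0, 0.5²) log2 units; planted shifts default to ±2 log2 units.
- **Regional cells**: negative-binomial counts with mean μ_g·m_{g,zone} and
  one shared dispersion (0.5; variance = m + 0.5 m²) — one nuisance
  parameter instead of a per-gene trend, configurable. Gradient genes use
  multipliers (1, 2, 4): a fourfold core-vs-normal change, comfortably above
  the 0.25 logFC threshold at a few hundred cells per zone.

All randomness flows from one integer seed per generator call; identical
seeds give bit-identical outputs. Generators emit log2 values for bulk data;
the normalization of real cohorts is assumed already done upstream.

What the generators do *not* emulate: platform/batch effects, probe
structure, gene-gene correlation (expression draws are independent across
genes), dropout beyond NB dispersion, informative censoring, and competing
risks. Passing tests therefore demonstrate correctness of the algorithms
under the stated models, not robustness to those real-data complications.

## Problem sizes and numerical choices

The test suite and the acceptance script run scaled-down study sizes chosen
to keep Monte-Carlo error small relative to the assertions: two multi-region
cohorts of 40 patients; 500 training / 300 validation survival samples; 100
stability-selection iterations (frequencies are binomial means, so 100
iterations resolve the 0.85 cutoff to ±0.04 SE); 1,000 replicates for the
log-rank type-I rate; 2,000 genes for null false-positive fractions;
2,000 samples for coefficient recovery. Cox fits use tolerance-limited
Newton iterations as implemented by lifelines; rank tests use mid-ranks
with tie correction, exact enumeration for small paired samples; quantiles
interpolate linearly between order statistics everywhere.

## Known limitations

- The bulk DE filter is rank-based on log values, not a count model; very
  low-count genes are treated conservatively.
- Stability-selection frequencies depend on the subsampling fraction (0.8,
  the common choice, without replacement) and on the CV rule; both are
  exposed as arguments. Whether subsampling should be bootstrap instead is
  an open convention — without-replacement subsampling is standard in the
  stability-selection literature.
- `cox_screen` refits per gene and is O(genes); it is intended for
  hundreds-to-thousands of candidates, not whole transcriptomes.
- Calibration's bootstrap refit can drop resamples where the Cox fit fails;
  with very small cohorts the bands are correspondingly optimistic.
- No competing-risks machinery and no proportional-hazards diagnostics.
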