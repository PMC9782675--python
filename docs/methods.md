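# Methods

`txclust` implements an unsupervised phenotype-discovery pipeline for
kidney-transplant registry cohorts: mixed-type clinical variables are
imputed and converted to a Gower dissimilarity, consensus clustering with
subsampling identifies stable recipient phenotypes and the number of
clusters, and the resulting clusters are characterized by standardized mean
differences and compared on post-transplant outcomes.  Because registry
extracts (OPTN/UNOS) are not publicly redistributable, the package ships a
synthetic-registry generator that plants a known cluster structure; every
end-to-end claim the test suite makes is therefore a claim about recovery
of planted structure, not about real registry data.

## Synthetic registry generator

`synthetic_registry.SimulationConfig` draws one row per transplant
recipient.  Cluster labels are sampled from `cluster_weights`; each of the
~20 roster variables is then drawn from that cluster's parameters
(normal for continuous; categorical draws for binary/categorical/ordinal).
Auxiliary columns (`kdpi`, `multi_organ`, `transplant_year`, `unos_region`)
support the inclusion filter and region tabulation but stay outside the
clustering schema.

The default roster emulates the published profile of recipients of
high-KDPI (Kidney Donor Profile Index >= 85%) deceased-donor kidneys: six
phenotypes — young Black hypertensive recipients with long dialysis
vintage; elderly White recipients transplanted preemptively or after short
dialysis from older White donors; sensitized retransplant recipients;
recipients of dual kidneys from pediatric, non-hypertensive donors; a
low-HLA-mismatch group; and a diabetic group.  Two design choices shape
the defaults:

* **Separation.** The raw published per-cluster distributions overlap so
  heavily that no distance-based method could recover the planted labels —
  which would make every downstream test vacuous.  The default therefore
  concentrates each categorical variable on the cluster's *archetype*
  level (the level most over-represented relative to the across-cluster
  average — exactly the direction a standardized-mean-difference profile
  would flag), leaving `PROFILE_NOISE = 0.25` of the mass on the
  registry-calibrated background, and scales continuous within-cluster SDs
  by `SPREAD_SCALE = 0.6`.  This plants clusters that are well separated
  in Gower space but retain smooth within-cluster variation, so
  over-clustering (k above the true 6) remains detectably unstable.
  Setting `profile_noise=1, spread_scale=1` recovers the raw
  registry-calibrated profiles.
* **Cluster weights.** Default `[0.20, 0.20, 0.10, 0.10, 0.16, 0.24]`.
  The published mix has two clusters at 4%; at the default n = 600 that
  would leave ~19 subjects in an 80% subsample, too few for a planted
  cluster to be meaningfully recoverable.  The defaults preserve the
  published size *ordering* while keeping every phenotype at >= 10%.

Missingness is injected MCAR at `missing_rate = 0.05` (each schema cell
masked independently; IDs, auxiliary and outcome columns never masked) —
the simplest mechanism consistent with a "<5% missing" registry
description, and sufficient to exercise chained-equation imputation.  MNAR
mechanisms are out of scope.

Outcomes: the three time-to-event outcomes (death, death-censored graft
failure, all-cause graft failure) are drawn as independent per-cluster
exponentials, administratively censored at `admin_censor_time = 10` years
(censored rows carry the censor time exactly).  The default rates are
back-solved from the published 5-year cluster survival percentages as
lambda = -ln(S5)/5, so e.g. patient-death rates range from 0.020/yr (the
dual-transplant cluster) to 0.095/yr (the retransplant cluster).  The
exponential law is chosen for its closed-form survivor function
S(t) = exp(-lambda t), which gives analytic oracles for the Kaplan-Meier
module.  The three processes are independent — competing risks and the
death/graft-failure coupling of real registries are not emulated.  Binary
outcomes (primary non-function, delayed graft function, 1-year rejection)
are Bernoulli with the published per-cluster incidences.

UNOS region (1-11) is drawn from per-cluster distributions that mildly
tilt each cluster toward the region the published per-region mix ranks
highest; only the tabulation machinery depends on this, not any test of
substance.

All draws flow from `numpy` generators seeded by `SeedSequence([seed,
stream])` with fixed per-purpose stream constants, so cohorts, masks, and
outcomes are reproducible independently of each other.

## Preprocessing

* **Inclusion** (`apply_inclusion`): KDPI >= `kdpi_min` (default 85,
  boundary inclusive), exclusion of multi-organ recipients, transplant
  year within 2010-2019.  Idempotent, order-preserving.
* **Imputation** (`impute_chained`): chained equations producing a single
  completed dataset (the clustering consumes one table; Rubin-style
  pooling is out of scope).  Missing cells are initialized by random
  draws from the column's observed values; then for `n_cycles = 10`
  cycles each incomplete variable is regressed on all others (continuous:
  linear model, imputed as prediction plus a normal residual draw;
  binary/categorical/ordinal: multinomial logistic, imputed as a draw
  from the predicted class probabilities).  Predictors enter as numeric
  values (ordinal as level ranks, categorical one-hot).  Observed cells
  are never altered; a model failure on a cycle falls back to
  observed-value draws with a logged warning; the original missingness
  mask is kept for audit.
* **Distance** (`gower_distance`): Gower dissimilarity — continuous and
  ordinal variables contribute |x_i − x_j| / range (ordinal via integer
  level ranks, preserving the ordering of banded variables such as
  dialysis vintage), binary/categorical contribute 0/1 mismatch,
  averaged over variables.  Zero-range variables contribute 0 with a
  logged warning, keeping degenerate configurations deterministic.
  Gower is used because the cohort mixes ~40 categorical and continuous
  variables and avoids arbitrary one-hot scaling decisions.

## Consensus clustering

`run_consensus` draws `floor(0.8 n)` subjects without replacement per
iteration (100 iterations by default), clusters each subsample at every
k in 2..10, and accumulates for every subject pair the number of joint
inclusions and joint cluster memberships.  The consensus value of a pair
is the ratio of the two counts (pairs never co-sampled: consensus 0, with
a logged count; at the default settings the probability of such a pair is
negligible).  One subsample serves all k, mirroring the standard
consensus-clustering implementation.

The inner clusterer is PAM (partitioning around medoids) on the Gower
dissimilarity by default: greedy BUILD initialization followed by
best-swap passes, vectorized over candidate swaps, deterministic with
lowest-index tie-breaks.  Medoid methods accept arbitrary dissimilarities
natively, which is why PAM is the default; average-linkage hierarchical
clustering is available as `base_clusterer="hierarchical_average"`.

The final k-cluster assignment is obtained by average-linkage clustering
of 1 − consensus cut at k (the consensus matrix, not the raw data, defines
the final partition), and clusters are renumbered by descending size so
reports are stable across runs.

Diagnostics per k (`compute_diagnostics`, all recomputable from the stored
consensus matrices alone):

* empirical CDF of the n(n−1)/2 off-diagonal consensus values on a
  101-point grid over [0, 1], and its trapezoid-rule area;
* delta area: the relative change in that area versus k−1; at the
  smallest k, the area itself;
* PAC (proportion of ambiguously clustered pairs): the fraction of pairs
  with consensus strictly between 0.1 and 0.9 (the conventional
  boundaries; configurable).  Lower is stabler;
* within-cluster consensus score: the mean consensus over pairs inside
  each cluster (singletons score 1 by convention, logged), plus the
  unweighted mean over clusters.

`select_k` offers three explicit rules: argmax of mean within-cluster
consensus (default), argmin PAC, and a composite rank-sum over (high mean
consensus, low PAC, small delta-area gain).  The composite rule is a
codification of the qualitative multi-plot adjudication practitioners
perform; ties resolve to the smallest k.

## Cluster characterization

Standardized mean differences compare each cluster against the overall
cohort *including* the cluster (the literal registry-phenotyping
convention; `comparison="cluster_vs_rest"` is available because the
overlap attenuates SMDs).  Continuous: (m_a − m_b) / sqrt((s_a² + s_b²)/2)
— the two-group quadratic-mean pooled SD.  Binary and categorical
variables expand to one indicator per level with the proportion analogue
(p_a − p_b) / sqrt((p_a(1−p_a) + p_b(1−p_b))/2), matching per-level
bar-chart reporting.  Zero pooled spread marks the entry undefined (NaN,
excluded from key features); both-degenerate equal proportions give 0.
Entries with |SMD| > 0.3 (default cutoff) are flagged as the cluster's key
features.  `region_proportions` tabulates each UNOS region's cluster mix
(rows sum to 1) with per-region transplant counts.

## Outcome comparison

Kaplan-Meier curves (via lifelines) summarize the three time-to-event
outcomes per cluster, reported at 1 and 5 years through a right-continuous
step evaluator that flags extrapolation beyond follow-up; Greenwood
variance is carried for reference.  Ties between events and censorings
resolve events-first.  Clusters are compared with the G-group log-rank
test (statistic ~ chi-squared with G−1 df).  Binary outcomes use Pearson
chi-squared without continuity correction; one-way ANOVA is provided for
continuous comparisons, with explicit degenerate handling (zero
within-group variance: F = 0 for equal means, an infinite-F flag
otherwise).  Death-censored graft failure treats death with a functioning
graft as censoring at the death time; 1-year rejection is binary because
registries record only whether rejection occurred in the first year.
Percentages are reported to one decimal, rounding half-up.  No
multiplicity correction is applied to the primary p-values (matching
common registry reporting); a Bonferroni column across the outcome
comparisons is emitted alongside.

## Numerical conventions and problem sizes

* PAC boundaries (0.1, 0.9) exclusive on both sides; CDF areas by the
  trapezoid rule on the fixed 101-point grid.
* PAM swap passes capped at 60 (convergence is typically < 10 passes);
  all tie-breaks by lowest index.
* Per-iteration subsample seeds derive from `SeedSequence([master_seed,
  10, iteration])`, so iterations are independent and parallelizable.
* The planted-recovery suite runs n = 600 cohorts over 10 seeds at the
  full study settings (80% subsampling, 100 iterations, k = 2..10); null
  calibration suites use 2000 replicates with 50 subjects per group
  (log-rank) and 3 groups of 20 (ANOVA); distribution-recovery checks use
  n = 20000.  These sizes keep the full suite in the minutes range on a
  single core while leaving Monte-Carlo error well inside the asserted
  tolerances.

## Known limitations

* The generator draws variables independently within cluster; the joint
  correlation structure of real registries (and MNAR missingness,
  competing risks, informative censoring) is not emulated.  Passing
  recovery tests therefore demonstrate correctness of the machinery under
  the planted model, not performance on real registry data.
* Consensus clustering on very crisp planted structure is known to keep
  mean cluster-consensus near 1 for k above the truth (stable sub-splits
  of tight clusters); the default generator deliberately leaves
  within-cluster continuous spread so that k-selection behaves the way it
  does on real, noisy cohorts.
* The log-rank chi-squared approximation is slightly anti-conservative
  below ~30 subjects per group; calibration suites use 50.
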