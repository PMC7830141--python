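# Methods

This note documents the models, parameter choices, and numerical
conventions behind `netsi`, and what the synthetic validation does and does
not demonstrate about real imaging data.

## Network construction

Connectivity is plain Pearson correlation of the input node time series;
the package assumes preprocessing (filtering, nuisance regression, motion
handling) has already happened upstream, and its entry point is a cleaned
nodes × timepoints matrix. Constant series are rejected with an error that
names the offending node rather than silently producing NaNs.

Dichotomization conserves the density statistic S = log(N)/log(K) exactly
by construction: the target average degree is K\* = N^(1/S) and exactly
E = round(N·K\*/2) node pairs become edges, rather than searching for a
correlation cutoff. The achieved S then differs from the requested value
only through integer rounding of E (tested to within 0.05 at N = 500). The
default S = 2.5 reflects common practice for voxelwise binary brain graphs.

Edges are ranked by **signed** correlation and, in the default
`mode="positive"`, anticorrelated pairs are never selected; if a matrix has
too few positive correlations to reach the requested density the builder
raises rather than padding with negative edges. `signed` and `absolute`
ranking modes are available as explicit switches, since conventions differ
across labs. Ties at the cutoff are broken by ascending (i, j) node order,
making thresholding fully deterministic.

## Community detection

Partitions maximize Newman–Girvan modularity Q using networkx's seeded
multilevel (Louvain) implementation. Because the optimizer is greedy and
order-dependent, `best_partition` restarts it `n_runs` times (default 100)
with seeds `seed + r`, keeping the highest-Q labeling; ties go to the first
occurrence, and the per-run Q log can be retained. Community labels are
canonicalized to 0, 1, 2, … in order of first appearance so structurally
identical partitions compare equal.

Known limitation: the multilevel move set cannot reach every global
optimum. On small dense unstructured graphs (e.g. some G(8, 0.4)
realizations) the restarts converge to a local optimum a few percent below
the exhaustive-search maximum no matter how many runs are used. On modular
graphs — cliques, rings of cliques, planted blocks with within-p 0.9 /
between-p 0.05 — recovery is exact in our tests, which is the regime the
method is used in.

## Scaled Inclusivity

For reference set R and candidate community C,

    SI(R, C) = |R ∩ C|² / (|R| · |C|).

This squared-overlap normalization lies in [0, 1], equals 1 iff R = C, and
penalizes both fragmentation and dilation. A subject's map assigns every
node the SI of *its own community* against the seed ROI — the declared
reading where multiple overlap conventions exist in the literature — which
gives whole-brain maps one distinct value per community and lets consistent
structure appear outside the original ROI. The group map is the arithmetic
mean over subjects (not the sum), so perfect alignment yields 1 for any
cohort size.

A consequence of the node-own-community reading: an ROI node's per-subject
value is strictly positive (its community always contains it), so a
"completely discordant" subject contributes a small positive value, not 0;
the value approaches 0 only as the node's community dilates toward the
whole brain. Tests assert the exact arithmetic of this behavior.

## Study-specific ROI refinement

Reference ROI SI maps are pooled as a flat mean over every
subject × condition partition (each partition weighted equally), and each
node is reassigned to the argmax ROI. Ties — including nodes where every
pooled map is zero — deterministically go to the lowest ROI id. Refinement
is a single pass; on planted cohorts it is empirically a fixed point
(re-running it on its own output reproduces the assignment), and with zero
jitter and ROIs equal to the planted communities it is the identity. An
artifact ROI can be flagged excluded; downstream statistics iterate only
over analyzable ROIs and refuse to run if none remain.

## Consistency measures and inference

*Global* consistency is the whole-brain mean of the node-wise sum of the
per-ROI SI maps. *Regional* consistency is the ROI mean of the scaled map,
where scaling is a single min-max transform with the minimum and maximum
pooled across all of that subject/condition's analyzable ROI maps — this
removes the global shift between conditions while preserving value order,
and is invariant to any common affine rescaling of the inputs. Scaling is
undefined (and rejected) when all pooled values are identical.

The repeated-measures comparison treats each complete subject's
per-condition outcomes as a multivariate response: coefficients are
estimated by least squares per condition column with a shared
intercept + covariates design, and the residual covariance across
conditions is left unstructured. With complete, balanced data this is the
maximum-likelihood solution of the corresponding mixed model. Least-squares
means evaluate the fit at the sample-mean covariate vector, so each
pairwise β is *exactly* the difference of two adjusted means; Wald t
inference uses n − rank(X) degrees of freedom, with Bonferroni factor 3
(the three pairwise comparisons) applied to both p-values and CIs. The
design matrix is inverted by pseudo-inverse so a covariate that happens to
be constant in a small cohort (e.g. a minority indicator) degrades
gracefully instead of failing. Incomplete subjects are dropped and counted;
fewer than max(3, p + 1) complete subjects is an error. Race enters as a
binary indicator, mirroring typical cohort reporting.

The permutation test for a two-condition regional contrast uses the
difference of group-mean regional consistency as the statistic and swaps
the two condition labels independently within each subject (fair coin per
subject per permutation), with two-sided
p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm). Calibration tests show type-I
error within [0.03, 0.08] at α = 0.05 and near-uniform null p-values at
n_perm = 200.

VAS differences are classified by the sign of easy − hard on the integer
0–100 scores; "zero" means exact equality. Percentages always use the
per-question responder count, with missing-score subjects excluded and
counted.

## Synthetic cohort generator

Each subject/condition time-series matrix follows a latent-factor block
model: node signal = λ_c·(community factor) + λ_g·(global factor) +
noise_sd·ε, all Gaussian. Loadings solve within_r = (λ_g² + λ_c²)/v and
between_r = λ_g²/v with v = noise_sd²/(1 − within_r), so expected within-
and between-community Pearson correlations hit their targets exactly; the
global-factor construction keeps the implied correlation matrix positive
semidefinite. Sample correlations converge to the targets as T grows
(tested at tolerance 0.03 for T = 5000). within_r = 0 (pure noise, with
between_r = 0) is allowed as a degenerate control.

Condition-dependent consistency loss is planted by *jitter*: before signal
synthesis, round(jitter·N) nodes per subject are reassigned to a uniformly
random other community, so the perturbation propagates into the graph
itself. At jitter 1 the agreement with the template falls to the analytic
chance floor of this scheme — a formerly joint pair stays together with
probability 1/(k−1) and a split pair reunites with probability 2/(k−1)²
for k equal communities — which is slightly above independent-relabeling
chance; group SI on the template ROI is monotone decreasing in jitter, the
property the condition contrasts detect. In the rare event that jitter
empties a community on a tiny cohort, one moved node is returned to the
smallest block so the signal model stays well-defined.

Defaults are desk-scale study analogues chosen once: 20 subjects, 200
nodes in 4 equal communities, conditions Rest/Easy/Hard with jitter
0/0.2/0.4, within_r = 0.6, between_r = 0, T = 300, unit noise. Cohorts of
~10⁴ nodes are supported but not default. Synthetic covariates emulate an
older-adult mobility cohort (age ~ N(76.1, 4.3), 55.4% female, 8.3%
African American); synthetic VAS responses are integer 0–100 scores with a
heaping mass at exact easy = hard equality and a configurable
easy-minus-hard location shift.

What the generator does **not** emulate: hemodynamics (no BOLD
convolution), spatial smoothness or 3-D voxel geometry, head motion, or
scanner artifacts. Passing tests therefore demonstrate the correctness and
calibration of the pipeline's computations and statistics under a known
ground truth — not that any particular real-data effect size will
replicate.

## Reproducibility conventions

All randomness flows from integer seeds through numpy `SeedSequence`
spawning (cohorts) or `seed + offset` streams (restart ensembles, pipeline
stages), so a full pipeline run is reproducible byte-for-byte from its run
manifest; outputs contain no timestamps. Node indices are 0-based
internally and in all on-disk tables except edge lists, which are 1-based
with i < j. The `--threads` option is accepted for interface compatibility;
computation is single-threaded and results never depend on it.

Problem sizes used by the validation suite — e.g. 20 subjects × 200 nodes
for the jitter-monotonicity check, 100 cohorts of 100 subjects for CI
coverage, 200 null cohorts for permutation calibration — are the package's
chosen desk-scale study conditions; they keep ground truth exact and runs
reproducible on a laptop.
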