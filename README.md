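# netsi

Cross-subject consistency of brain-network community structure: from node
time series to density-conserving binary graphs, modularity-based community
partitions, **Scaled Inclusivity (SI)** consistency maps, study-specific ROI
refinement, and repeated-measures condition contrasts.

## Who this is for

Researchers comparing the *spatial consistency* of functional brain-network
communities across scan conditions (e.g. rest vs. graded task load) in a
multi-subject cohort. The package implements the full voxelwise/nodewise
graph pipeline and ships a synthetic cohort generator with planted,
condition-dependent community structure, so every stage is testable without
any imaging download.

## The method

1. **Networks.** For each subject and condition, Pearson-correlate all node
   time series and keep exactly the E = round(N·K*/2) most strongly
   correlated pairs as binary edges, where K\* = N^(1/S). This conserves the
   density statistic S = log(N)/log(K) (default **S = 2.5**) across subjects.
2. **Communities.** Partition each graph by maximizing Newman–Girvan
   modularity
   Q = (1/2m) Σ_ij [A_ij − k_i k_j/2m] δ(c_i, c_j)
   with seeded multilevel (Louvain-style) optimization, restarted **100
   times**; the highest-Q partition is kept.
3. **Scaled Inclusivity.** For a reference ROI R and a subject community C,
   SI(R, C) = |R ∩ C|² / (|R|·|C|) ∈ [0, 1]. A subject's SI *map* scores
   every node v with SI(R, C(v)); the group map is the node-wise mean over
   subjects and equals 1 exactly under perfect spatial alignment.
4. **Study-specific ROIs.** Pool each reference ROI's group SI map over all
   subjects and conditions, then reassign every node to the argmax ROI;
   an artifact ROI can be excluded from downstream analysis.
5. **Statistics.** Per subject/condition: *global* consistency (node-wise sum
   of ROI maps, then whole-brain mean) and *regional* consistency (ROI mean
   of jointly min-max-scaled maps). Conditions are compared with a
   repeated-measures linear model (unstructured residual covariance; age,
   sex, race covariates) reporting least-squares means and pairwise
   differences β with Bonferroni-adjusted CIs and p-values, plus a seeded
   within-subject permutation test. Easy-vs-hard visual-analog-scale (VAS)
   self-reports are classified by difference sign.

## Worked example

```python
import netsi

spec = netsi.CohortSpec(
    n_subjects=12, n_nodes=120, community_sizes=(30, 30, 30, 30),
    conditions=(("Rest", 0.0), ("Easy", 0.2), ("Hard", 0.4)),
    n_timepoints=200, seed=1,
)
cfg = netsi.RunConfig(out_dir="run", cohort=spec, n_runs=25, n_perm=500, seed=1)
res = netsi.run_pipeline(cfg)
print(res.comparisons["global"].summary())
```

prints

```
Repeated-measures condition contrasts
  subjects: 12 (dropped incomplete: 0)
  covariates: age, sex, race
  Bonferroni factor: 3   alpha: 0.05

  Least-squares means
    Rest        0.7934
    Easy        0.5418
    Hard        0.3439

  Comparison             beta                95% CI  p (adj.)
  Rest vs. Easy        0.2516    [ 0.1323,  0.3708]    0.0005
  Rest vs. Hard        0.4495    [ 0.3846,  0.5144]    0.0000
  Easy vs. Hard        0.1979    [ 0.1216,  0.2742]    0.0001
```

The synthetic conditions plant increasing community-membership *jitter*
(0 → 0.2 → 0.4), i.e. decreasing cross-subject consistency; the fitted
least-squares means recover that ordering (Rest > Easy > Hard), and every
pairwise β = difference of the two adjusted means, with Bonferroni-adjusted
inference. `run/` additionally contains per-subject edge lists and
partitions, the study-specific ROI map, the consistency table, permutation
tests, and a run manifest sufficient to reproduce every file byte-for-byte.

The same flow is scriptable from the shell:

```bash
netsi simulate --n-subjects 12 --n-nodes 120 --communities 30,30,30,30 --out cohort
netsi run-all --manifest cohort/manifest.yaml --out run
```

(`build-networks`, `detect-communities`, `si-maps`, `refine-rois`,
`compare`, and `vas` run the stages individually.)

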