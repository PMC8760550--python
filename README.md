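# plasmarch

Data-driven stratification of plasma antibody-bead-array proteomics.

`plasmarch` implements the analysis chain used to find subgroups of
women in a prospective breast-cancer risk cohort from their circulating
protein profiles: suspension-bead-array (SBA) median fluorescence
intensities (MFI) are normalized within and between 96-well plates,
antibodies are quality-filtered, protein levels are adjusted for
clinical covariates, participants are clustered by archetypal analysis
with bootstrap stability scoring, the clusters are characterized
clinically and proteomically, and matched case-control status is
modelled by conditional logistic regression. A first-class synthetic
cohort generator plants every effect the pipeline is supposed to
recover, so the whole chain is testable without access to restricted
cohort data.

It is written for biostatisticians and proteomics analysts working with
affinity-proteomics case-control studies.

## The model

**Archetypal analysis.** Given adjusted log-intensities `X` (n samples x
p antibodies), find `Z = beta X` (k archetypes) and coefficients `alpha`
minimizing

```
|| X - alpha Z ||_F^2 ,   alpha_i, beta_a on the probability simplex
```

so archetypes are extreme points of the data's convex hull and each
participant is a convex mixture of them. Fitting alternates two blocks
of simplex-constrained least squares (non-negative least squares with a
weighted sum-to-one row); `k` is chosen at the unit-invariant knee of
the (k, RSS) curve; hard clusters are `argmax alpha`. Stability is the
mean Jaccard index (MJI) between each reference cluster and its best
match over 150 bootstrap re-clusterings.

**Normalization.** Abs-PQN divides each measurement by the median
quotient of the sample's profile against the plate reference, computed
per antibody over its `n_similar` most rank-correlated antibodies
(classical PQN is the `n_similar = p` limit). Between plates, the
difference M of plate-median from global-median log intensity is
lowess-smoothed against the average level A and subtracted.

**QC.** An antibody is excluded when its replicate Spearman rho < 0.7,
its correlation with per-sample IgG levels exceeds 0.5, or its
empty-well MFI exceeds mean + 3 sd of the sample MFI; among antibodies
sharing a target, the most reproducible one is kept.

**Case-control models.** For 1:2 age/site-matched sets, the conditional
likelihood `exp(eta_case) / sum_l exp(eta_l)` is maximized per protein
under three covariate models, with Benjamini-Hochberg correction across
proteins.

## Worked example

```python
from plasmarch import PipelineConfig, run_pipeline

config = PipelineConfig.from_dict({
    "outdir": "run",
    "seed": 1,
    "simulate": {"n_cases": 100, "n_doubles": 25, "n_replicate_pairs": 30,
                 "n_antibodies": 200, "n_duplicate_targets": 30,
                 "n_planted_archetypes": 5,
                 "n_bad_reproducibility": 5, "n_igg_correlated": 5,
                 "n_high_background": 5, "seed": 1},
    "cluster": {"k_min": 2, "k_max": 8, "restarts": 2,
                "max_iter": 100, "tol": 1e-5},
    "stability": {"B": 50},
})
manifest = run_pipeline(config)
```

This simulates a 100-case cohort (300 matched study samples, 25 double
and 30 replicate pairs, 200 antibodies with 15 planted defects and 5
planted archetypes), runs every stage and writes all artifacts into
`run/`. On one CPU it finishes in under a minute and reports, among
other things:

```
selected k = 5                      # the planted archetype count
qc flagged antibodies = 20          # the 15 planted defects + borderline
covariate scan: age 87, BMI 55, entry date 17 of 152 significant
MJI per cluster: 0.50 - 0.80        # bootstrap stability
concordance: replicate 0.90 > double 0.64 > random 0.10
case-control screen: 7.2% nominal, 0 FDR-significant
```

Reading the output: the knee rule recovers the planted number of
archetypes; replicate pairs (technical noise only) land in the same
cluster far more often than doubles (plus biological drift), which beat
random pairs; and with no planted case effect the conditional-logistic
screen shows the expected null pattern — a nominal hit rate near 5% and
nothing surviving FDR correction.

The same stages are available as a CLI (`plasmarch run --config
config.yaml`, plus `simulate`, `normalize`, `qc`, `adjust`, `cluster`,
`casecontrol` subcommands) and as sklearn-style estimators
(`AbsPQN`, `MANormalizer`, `CovariateAdjuster`, `ArchetypalAnalysis`,
`ConditionalLogit`) for use in custom code.

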