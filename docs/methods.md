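# Methods

This note records the statistical procedures implemented in
`plasmarch`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-data experiments do and do not
demonstrate.

## Synthetic cohort generator (`plasmarch.simulate`)

The generator emulates a 1:2 matched case-control study nested in a
mammography-screening cohort, assayed on antibody suspension bead
arrays across 96-well plates.

**Cohort structure.** Each case (age truncated-normal 59.6 ± 9.3 over
39–81, four sampling sites with strongly unequal frequencies) is
matched to two controls with the same site and age within ±2 years (the
matching variable tolerance is a package choice; matching "on age"
admits several conventions). Clinical covariates are drawn from
marginals typical of this population: BMI log-normal 25.6 ± 4.2,
mammographic dense area gamma (mean 27, sd 24 cm²), ~76% postmenopausal
with menopause probability switching at age 51, MHT status
never/before/current ≈ 47/39/13% among postmenopausal women, smoking a
zero-inflated gamma, alcohol gamma, parity 86% ever, PRS standard
normal with a +0.1 shift in cases. Entry dates are uniform over a
600-day window. Missingness is injected completely at random at
per-column rates matching the emulated cohort (BMI 0.7%, dense area
3.6%, statin 32%, ...); the mechanism is a package choice — only the
missing counts, not the mechanism, are knowable from cohort tables.
Doubles (same woman, two draws 11–20 months apart) and replicate pairs
(one draw assayed twice) are generated with shared subject-level
biology; each matched trio, double pair and replicate pair shares a
plate, and every plate carries four plasma-pool aliquots.

**Signal model.** Log MFI of sample i at antibody j:

```
log m_ij = b_j + sum_a alpha_ia d_aj + u_{s(i),j} + x_i' s_j
           + mht_j 1[ever user] + case_j 1[case]
           + plate(p_i, j) + dil_i + eps_ij
```

with baseline `b_j ~ N(6.9, 0.8)`; archetype deviations `d_aj ~ N(0,
(separation * noise_sd)^2)` and per-subject mixture weights `alpha ~
Dirichlet(0.3)` (most samples mixtures, a minority near vertices — the
convex-combination structure archetypal analysis presumes); subject
set-points `u ~ N(0, subject_bio_sd^2)` capturing inter-individual
variation beyond the archetype axes (default 0.25, reflecting that
between-person biological variation in plasma proteins well exceeds the
~10% technical noise — without it, replicate correlations would be
unrealistically low); covariate slopes `s_j` of configurable magnitude
(per covariate SD) on configurable antibody fractions; an MHT
signature of ±`mht_effect_size` (default 0.5) on a configurable protein
fraction for ever-users (the magnitude of a real MHT proteomic effect
is not established, so it is a free parameter, not an asserted value);
per-plate offsets N(0, 0.1²), optionally tilted linearly in `b_j` with
a bounded per-plate slope; per-sample dilution N(0, 0.3²); residual
noise N(0, 0.1²). MFI is exponentiated and floored at 1.

Defective antibodies are planted far past the QC thresholds: inflated
noise on one replicate member (reproducibility), an IgG-proportional
additive load scaled to three times all other variation combined (IgG
correlation), and empty-well values set to mean + 5 sd of the sample
MFI (background). Double pairs get an extra biological drift
N(0, 0.3²) per antibody on the second draw.

The generator does not model bead chemistry (bead counts, saturation,
cross-reactivity kinetics); all effects are planted at the
log-intensity level. Consequently, passing tests demonstrate that the
pipeline recovers planted log-scale structure, not that it would be
robust to assay nonlinearities.

## Normalization (`plasmarch.normalize`)

**Abs-PQN** (within plate). The reference profile is the per-antibody
median over the plate's non-pool samples. For antibody j, the
similarity set is the `n_similar` antibodies with the highest Spearman
correlation to j across the plate (j included; ties broken by column
order for determinism), and the per-sample factor is the median
quotient over that set. Default `n_similar = 50`: small enough to be
antibody-specific, large enough for a stable median. With `n_similar >=
p` the procedure reduces exactly to classical PQN, which the tests
assert against an independently coded oracle. The antibody-specific
internals are a design decision of this package — the median-quotient
family admits several variants and the "per antibody or per antibody
bin" question is left open by the method's descriptions.

**MA normalization** (between plates). Per antibody, M = plate-median
log intensity minus the global median and A = their average; a lowess
fit of M on A per plate (default span 0.3) is subtracted from all of
the plate's samples. Pools are excluded from the reference but
transformed. Requires ≥ 2 plates and ≥ 10 antibodies. A caveat
documented by the tests: when plate effects are intensity-coupled *and*
strong latent biological structure jitters the A axis, the smoother
removes only the systematic component — the calibration experiment
therefore isolates the intensity coupling.

## Antibody QC (`plasmarch.qc`)

Flags: replicate Spearman rho < 0.7 across duplicated assays;
Spearman rho > 0.5 against per-sample IgG; empty-well MFI > mean + 3 sd
of study-sample MFI. Spearman is used for "rho" throughout (the rank
convention for MFI data). QC statistics are computed on normalized
intensities (computing them on raw data would conflate dilution with
irreproducibility); a flag exposes the alternative. De-duplication of
shared targets keeps the antibody with the highest replicate rho (ties
by id) — reproducibility is the primary QC axis, so it is also the
keep rule. Replicate samples are dropped after QC.

## Covariate adjustment (`plasmarch.adjust`)

Per antibody, one joint OLS of log MFI on intercept + BMI + age +
entry date (entry date coded as days since the earliest sample);
per-coefficient two-sided t-tests give the covariate scan. Adjustment
replaces values with the residual plus the fit at the mean covariate
vector, so each antibody's location is preserved exactly and residuals
are exactly orthogonal to the covariates. Held-out samples (doubles,
replicates) are adjusted with coefficients estimated on study samples
only — refitting with held-out samples would leak their structure into
the adjustment. Residuals are carried forward on the log scale.

A calibration caveat: per-antibody OLS p-values are calibrated when
residuals are independent across antibodies. Latent factor structure
(the archetype axes) induces dependence that widens the spread of
significant-count statistics without biasing individual tests; the
null-calibration experiment therefore uses a structureless generator
configuration.

## Archetypal analysis (`plasmarch.archetypes`)

Alternating simplex-constrained least squares: (i) given Z, each
coefficient row solves `min ||Z' a - x||` on the simplex; (ii) given
alpha, the unconstrained update `Z~ = argmin ||X - alpha Z||` is
projected onto the hull by solving each generator row `min ||X' b -
z~||` on the simplex, and `Z = beta X`. The simplex constraint is
enforced by NNLS on an augmented system with a sum-to-one row weighted
`200 * max(|X|, 1)` — large enough that constraint violations are
below solver tolerance, small enough to keep the system well
conditioned; the tests verify RSS agreement within 5% against an
independent projected-gradient solver. The hull-projection step is a
heuristic that can raise RSS marginally near the optimum; when it
does, the previous iterate is kept and iteration stops, so the
reported RSS history is non-increasing. Defaults: tol 1e-6 (relative
RSS), max 200 iterations, 5 restarts from furthest-sum-selected data
rows (seeded); k = 1 has the closed-form solution Z = column mean.

**Choosing k.** Each k in the range (default 2–10) is fitted, each
warm-started from the previous solution plus the worst-fit data row
(which keeps the best-of-restarts RSS curve monotone); the knee is the
point of maximum perpendicular distance to the chord of the curve
after scaling both axes to [0, 1] (unit invariance). Ties and the
degenerate straight-line case resolve to the smallest interior k
(parsimony). Hard labels are `argmax alpha` with ties to the lowest
archetype index. Held-out coefficients are simplex least squares
against the fixed archetypes.

## Stability and concordance (`plasmarch.stability`)

**Bootstrap MJI.** B resamples (default 150) of the n rows with
replacement; refit at the reference k (bootstrapping the clustering,
not the model-size selection); for each reference cluster take the
maximum Jaccard overlap with any bootstrap cluster, computed on the
set of distinct drawn samples (the clusterboot convention; computing
over all samples via prediction is implemented behind a flag). Mean
and SD over repetitions are reported per cluster. Jaccard of two empty
sets is 0 by convention.

**Pair concordance.** Same-cluster indicators for replicate pairs,
double pairs, and seeded random pairs drawn without replacement among
study samples; pairwise two-sided Fisher exact tests on the 2x2
same/different tables (a permutation test is available behind a flag —
the choice of significance method for rate comparisons is a package
decision).

## Cluster characterization (`plasmarch.characterize`)

Continuous clinical variables: Wilcoxon rank-sum, cluster-vs-rest and
all cluster pairs. Categorical: Fisher's exact test on the
cross-tabulation with missing values excluded. The r x c Fisher test
enumerates all fixed-margin tables (two-sided p = total conditional
probability of tables no more probable than observed) when the
enumeration bound is < 1e7 — which covers category-by-case/control
tables at cohort scale, e.g. a 4x2 table over ~550 samples enumerates
~1.4e5 states in under a second — and otherwise falls back to seeded
Monte Carlo over Patefield-sampled tables with an add-one estimator
and reported standard error.

Differential abundance is a Welch t-test (the unequal-variance form is
the safer default when cluster sizes are very unbalanced) per antibody,
cluster vs rest, with BH adjustment across antibodies. Shortlists take,
per direction of change, the union of the m = 25 lowest-p and m = 25
largest-|shift| antibodies (size between m and 2m; directions with
fewer than m fall back to all, with a warning). Median fold change is
the ratio of linear-scale medians r, sign-coded as r when r >= 1 and
-1/r otherwise, computed on normalized pre-adjustment values
(configurable — the scale convention is not standardized). Trait
association regresses BMI/age-adjusted dense area on the z-scored
protein (linear) and MHT ever-use (before or current vs never; a
three-level multinomial is available) on the protein (logistic);
complete separation skips the protein with a warning.

## Conditional logistic regression (`plasmarch.clogit`)

One case per matched set; the conditional likelihood removes the
per-set intercept. Newton–Raphson with step-halving from beta = 0,
convergence |Δ loglik| < 1e-10, max 50 iterations; Wald tests. If no
set has within-set exposure variation the likelihood is flat and beta
= 0 is returned by convention with loglik = -sum log|set|. Sets with
any missing model covariate are dropped whole (keeping the conditional
likelihood well-formed and reproducing per-model sample counts).
Protein levels are z-scored before fitting (configurable). The three
exposure models add, cumulatively: BMI + entry date; dense area +
postmenopausal + MHT ever; smoking + alcohol + parity. The screen
fits every antibody under every model, aggregates per-protein failures
without aborting, and applies BH within model. The 1:1 special case is
verified against paired-difference logistic regression.

## Pipeline (`plasmarch.pipeline`, `plasmarch.cli`)

Stages run in study order; every stage writes CSV/JSON artifacts and
the manifest records versions, seeds, input hashes and shapes. Stage
seeds derive from the master seed by stable hashing (CRC32 of the
stage name), so stages rerun in isolation reproducibly; identical
configs produce byte-identical outputs. Unknown configuration keys are
rejected by name. The characterization target cluster defaults to the
most stable (highest-MJI) cluster.

## Problem sizes used in the checks

The test and acceptance experiments run at reduced scale, chosen as
the smallest sizes at which the statistical properties under test are
comfortably powered: planted-simplex recovery uses ~500 study samples
x 60 antibodies over 20 seeds (restarts 2, tol 1e-5); stability
calibration uses B = 50; concordance uses 60 pairs per type;
FDR-control checks use 100 label permutations on a 150-antibody cohort
and a 200-antibody, 100-trio null case-control screen. The acceptance
script's pipeline run uses 100 trios, 25 doubles, 30 replicate pairs
and 200 antibodies.

## Known limitations

- Archetypal analysis is fitted on a penalty-based NNLS device;
  pathological scaling (|X| >> 1e3) would degrade the sum-to-one
  enforcement. Intensities are logged upstream, where this cannot
  occur.
- The exact r x c Fisher enumeration is exponential in principle;
  tables beyond the enumeration bound are handled by Monte Carlo with
  a reported standard error, not exactly.
- MJI values depend on the bootstrap-refit optimizer finding
  comparable optima; unstable data (by design) yields noisier MJI.
- The generator plants linear covariate effects and log-additive batch
  structure only; nonlinear covariate relationships and
  intensity-dependent variance (common at the assay floor) are not
  emulated, so the adjustment and normalization tests bound behavior
  under those assumptions only.
- Per-antibody missingness in the MFI matrix is not modelled (bead
  arrays report a value for every well); sample-level clinical
  missingness is.
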