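# Methods notes

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic cohort generator does and does not
emulate, and the numerical choices that affect results.

## Dissimilarity between community states

The Kullback-Leibler divergence D_KL(p, q) = Σᵢ pᵢ log(pᵢ/qᵢ) uses the
0·log 0 := 0 convention and returns +∞ whenever q lacks support where p has
mass; the Jensen-Shannon divergence averages the KL divergences of p and q
to their elementwise mean a = (p+q)/2 and is therefore always finite. Logs
are base 2 by default: that is the base for which JSD is bounded by [0, 1]
(the bound fails for base 10, which microbiologists otherwise favour for
abundance work). The base only rescales all divergences by a constant, so
clustering and stability *conclusions* are base-invariant; the printed
distances are not. The pairwise routine uses the equivalent entropy form
H(a) − ½H(p) − ½H(q) for speed, and tests pin it to the two-KL definition
and to an independent library implementation.

Clustering uses the JS *distance* (the square root, a true metric) by
default; the squared divergence is exposed via `metric="js_divergence"`
because published dendrograms in this literature are ambiguous about which
was used and the partition can differ slightly.

## Ward clustering on a precomputed JS matrix

Ward linkage is defined for Euclidean geometry; applying it to a JS
dissimilarity matrix is the established heuristic in the CST literature.
We apply the Lance-Williams Ward recurrence to squared input
dissimilarities (the "ward.D2"-style convention, what scipy's `linkage`
computes on a condensed distance matrix) and cut the tree by
`fcluster(..., criterion="maxclust")`. The number of CSTs k is a parameter
(default 5); no automatic selection is attempted because the canonical CST
count came from a fixed hierarchical choice, not an optimisation.

CST naming is centroid-driven: a cluster whose centroid's top taxon is one
of *L. crispatus*, *L. gasseri*, *L. iners*, *L. jensenii* is named I, II,
III, V respectively (taxon names matched case-insensitively via a
configurable alias map); among the remaining clusters the one with the
largest combined *Atopobium* + *Gardnerella* centroid share is IV-B and
the others IV-A. A single unnamed cluster is IV-B only when that marker
share reaches 0.2, otherwise IV-A. Two clusters claiming the same
Lactobacillus name are disambiguated by dominance with a warning. CST V is
supported but absent from the default generator, matching its rarity in
predominantly African-American cohorts.

## GEE contrasts

CST frequencies: one binomial GEE per CST (indicator vs. rest) on the
group indicator, exchangeable working correlation within subjects, robust
sandwich covariance, Wald test, BH adjustment across CSTs at q < 0.05.
Separation (an empty cell in the response × group table, e.g. a CST never
observed in one group) is flagged on the result rather than silently
reported; flagged fits are excluded from the BH adjustment. Stability
contrasts use the same machinery with a Gaussian family and identity link
on log distances. Natural logs are used on the distance scale so that a
difference of δ log units reads directly as an exp(|δ|)-fold difference.
Distances of exactly zero (a sample identical to its subject mean) are
floored at 1e-6 before the log — below any realistic sampling noise.

The high-Nugent (score ≥ 7, boundary inclusive) association with CST IV-B
membership is fitted as a binomial GEE with subject clustering. A
random-intercept logistic fit is a defensible alternative reading; the GEE
route was chosen for consistency with the CST screen, and no attempt is
made to reproduce any particular published odds ratio for this association
since its exact model specification is not recoverable.

## Count mixed models

For phylotype counts y_ij (subject i, visit j) all three families share the
linear predictor log μ_ij = β₀ + β₁·group_i + b_i + log N_ij with
b_i ~ Normal(0, σ_b²) and N_ij the sample's total reads; β₁ is therefore a
difference in mean log relative abundance. The NB is parameterised by mean
and size θ (NB2). The zero-inflated NB adds an intercept-only mixing
probability π on the logit scale; π has no covariates and no random
effect — the random intercept enters only the NB mean.

The marginal likelihood integrates b_i by adaptive Gauss-Hermite
quadrature: per subject, a damped Newton search (finite-difference
derivatives, 12 iterations, warm-started across optimiser calls) finds the
conditional mode and curvature, and 15 nodes (configurable; estimates move
by < 1e-3 between 15 and 31 nodes on test fixtures) are recentred there.
Optimisation is L-BFGS-B on the unconstrained parameterisation (log σ_b,
log θ, logit π) from a moment-based start plus two jittered restarts; a fit
is declared converged only when the optimiser succeeds and the restart
log-likelihoods agree (relative 1e-3), otherwise AIC is reported as NaN and
the phylotype row carries the failure message. Wald CIs and p-values for
β₁ come from the observed information (central-difference Hessian at the
optimum); profile CIs were not implemented, matching common mixed-model
practice.

AIC = 2k − 2ℓ with k = 3/4/5 free parameters (PLME/NBLME/ZINBLME). The
lowest-AIC converged fit is retained per phylotype; exact ties prefer the
simpler family. The signed fold change is exp(β₁) for β₁ ≥ 0 and −exp(−β₁)
otherwise, so depleted taxa print negative folds; significance requires
BH q < 0.1 and |fold| > 1.5, with the magnitude (not the signed value)
compared against the cutoff.

The prevalence gate keeps phylotypes with at least one read in ≥ 25% of
samples, boundary inclusive, pooled across groups.

## Read-level quality filters

A read passes iff its length is in [200, 400] bp, it contains no N, its
longest homopolymer is ≤ 8 bp, and every 50-bp step-1 sliding window
(including trailing partial windows; reads shorter than the window use one
whole-read window) has mean Phred quality ≥ 25 — the strictest consistent
reading of a sliding-window rule, and reads failing it are discarded, not
truncated. Each rejected read is tallied under its first failing criterion
in that order. Chimera removal and denoising belong to external tools and
are recorded in the report as not applied. Sanger/Phred+33 FASTQ encoding
is assumed.

## Synthetic cohorts

The generator emulates the two-group longitudinal design: 32 non-pregnant
subjects sampled twice weekly for 16 weeks (32 visits) and 22 pregnant
subjects sampled every 4 gestational weeks from week 8 to 24 and every
2 weeks to week 40 (13 visits). Per-sample depth is log-normal with median
2,878 reads (σ = 0.55 on the log scale) — any positive heavy-tailed choice
would do; this one matches the scale of real pyrosequencing runs.

Latent structure: each subject follows a first-order Markov chain over the
five CSTs (per-visit persistence 0.90 non-pregnant, 0.96 pregnant;
pregnant chains move almost exclusively between Lactobacillus-dominated
states). Compositions are Dirichlet draws from per-CST templates
(concentration 150; the variance of real CST compositions is not published
so the concentration is a free scenario parameter): CST I/II/III put
≥ 70% mass on one Lactobacillus species, IV-A is an even anaerobe mix, and
IV-B is *Atopobium*/*Gardnerella*-weighted. Counts are zero-inflated NB
(θ = 3, per-taxon π up to 0.35) around depth × composition. Pregnant
compositions are tilted by exp(β) per taxon and renormalised; because of
the renormalisation the realised log-fold effect differs from β by the log
of the tilt normaliser, which is small when the tilted taxa hold a few
percent of mass — parameter-recovery tests that need the exact likelihood
use `simulate_count_model`, which draws directly from the fitted model's
own generative form. Nugent scores are drawn high (7-10) with
CST-dependent probability (0.85 in IV-B, ~0.01-0.05 in Lactobacillus
CSTs). Default group effects place the four pregnancy-enriched
Lactobacillus phylotypes at their published effect sizes and leave other
taxa at zero, their depletion arising from CST occupancy.

What the generator does **not** emulate: sequencing error and chimeras (no
raw reads are simulated), menstrual-cycle covariates, taxon-taxon
interactions beyond the CST template structure, time-varying effects
within a group, and enrollment variability (visits are complete by
default; a dropout rate parameter exists). Passing tests therefore
demonstrate statistical correctness and calibration of the estimators
under the assumed generative structure, not robustness to real-data
artefacts such as compositional coupling or batch effects.

## Calibration suites and problem sizes

The suite checks, beyond unit oracles: metric axioms and brute-force
equivalence for the divergence core; BH equivalence with a step-up oracle;
ZINB pmf normalisation to 1e-8; ZINBLME effect recovery at 60 subjects ×
10 visits over 100 replicates (mean |bias| < 0.3 for β = 1.549); AIC
family selection ≥ 80% under pronounced overdispersion (θ = 0.6) or zero
inflation (π = 0.5); type-I error of the CST screen ≤ 7% over 500 null
simulations at the two-group cohort size of 54 subjects (robust variances
are anti-conservative with fewer clusters); Ward recovery of the five
planted CSTs at ARI ≥ 0.9; and read-filter equivalence with a naive scan
on 10,000 random reads. End-to-end pipeline tests run on reduced cohorts
(6-14 subjects, shortened schedules), a size chosen to exercise every
stage while keeping the default suite quick.

## Known limitations

- Ward on JS dissimilarities is a heuristic, not a variance decomposition;
  partitions can depend on whether divergence or distance is clustered.
- GEE sandwich variances are anti-conservative below ~40 clusters; no
  small-sample correction is applied.
- The ZINBLME likelihood surface can be flat when zeros are scarce; such
  fits converge with π̂ near 0 and an AIC close to the NBLME's, which the
  tie rule then prefers.
- Quadrature error grows with σ_b; above σ_b ≈ 2 (far beyond microbiome
  practice) more nodes are advisable.
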