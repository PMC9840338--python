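# Methods

## The sorted-cohort generative model

`igaseq.simulate` draws an IgA-seq cohort from an explicit mechanistic
model of the experiment.

**Community.** Each group (control, celiac) has a base composition over
`S` taxa. Taxon base abundances are log-normal (σ = 1.5 by default,
giving the right-skewed rank-abundance profile of 16S data: a few taxa
at several percent, a long rare tail); a symmetric-Dirichlet alternative
is available. Planted presort effects multiply a taxon's celiac
abundance by `2^δ` and renormalize. Each subject draws a personal
composition from `Dirichlet(p_group · c)` with `c = 200`, a moderate
inter-subject variability (per-taxon CV ≈ `1/√(c·p_t)`).

**Coating.** Each taxon carries a latent coating probability
`θ_{t,g} ∈ (0,1)` — the chance a cell of taxon *t* in group *g* is
IgA-bound. By default `θ_control` is Beta-distributed across taxa with
mean 0.0602 and concentration 2 (most taxa lightly coated, a tail of
strong coaters), and `θ_celiac` is the same taxon propensity shifted on
the logit scale to mean 0.128; 6.02% and 12.8% are the study's
flow-cytometry IgA+ fractions for the two groups, so the generator's
per-subject flow fraction `Σ_t p_t θ_t` reproduces them in expectation.
Subjects draw personal coating vectors from `Beta(θκ, (1−θ)κ)` with
κ = 50. Explicit per-group `θ` vectors and per-taxon overrides
(`coating_effects`) replace the default draw for designed experiments.

**Sorting.** Magnetic sorting is modeled as symmetric two-way
cross-contamination with a single impurity `ε ∈ [0, 0.5]`:

    q⁺_t ∝ (1−ε)·p_t·θ_t + ε·p_t·(1−θ_t)
    q⁻_t ∝ (1−ε)·p_t·(1−θ_t) + ε·p_t·θ_t

At `ε = 0` the fractions are perfectly pure; at `ε = 0.5` they both
equal the presort composition and the ICI collapses to 1 — the property
the complete-mixing validation exploits. No purity figure is published
for the assay, so the default is a small `ε = 0.05` and the parameter is
a config knob, never hard-coded into any analysis.

**Sequencing.** Per-sample depth is a rounded log-normal with mean
30,471 reads (the cohort's reported mean) and CV 0.3; counts are a
multinomial draw from `p`, `q⁺` or `q⁻`. Default cohort sizes are the
study's: 16 control / 15 celiac subjects at age 2.5, 13/9 at age 5 (the
age-5 subjects are a persistent subset of the age-2.5 roster), three
fractions per subject — 159 samples, 575 taxa.

**Randomness.** One root seed feeds a `numpy.random.SeedSequence` that
spawns named substreams (composition, coating, depth, counts, flow,
features) in a fixed order; PCG64 is platform-stable, so identical
seeds give identical cohorts everywhere and each stage is individually
reproducible.

**What the generator does not emulate.** Chimeras and sequencing error
(counts are exact multinomials), taxon–taxon ecological interactions
(the Dirichlet induces only compositional correlation), longitudinal
dependence of a subject's composition across ages, read-level artifacts,
and any association between coating and abundance. Passing tests
therefore demonstrate correctness of the estimators and calls under a
clean compositional model — not robustness to real-data artifacts such
as contamination, batch effects, or taxonomic misassignment.

## Estimators and rules

**Relative abundance** adds a pseudocount (default 1 read per cell of
the sorted-fraction tables) before column normalization, keeping every
proportion positive so ICIs are finite. The pseudocount is echoed in all
output provenance. Its cost: under integer rescaling of a sample the
pseudocounted proportion moves by ≈ `(1/p_t − S)/N`, negligible for
abundant taxa and exactly zero without a pseudocount; the test suite
pins both regimes. For rare taxa at finite depth the pseudocount also
shrinks the ICI toward 1 (an attenuation, never a sign flip).

**Group ICI** defaults to the ratio of group-mean IgA+ relative
abundance to group-mean IgA− relative abundance; a per-subject-ICI-
then-median estimator is selectable. The published per-group index does
not state its estimator, so both are offered and labeled; neither is
asserted as "the" published one. The IgA+/IgA− ratio (not IgA+/presort)
is canonical throughout.

**Retention rule.** A taxon is dropped from the heatmap when both group
ICIs are below 1, unless discordant (one side < 1, the other > 1). A
value of exactly 1 is *not lower than 1* and is retained — the boundary
is pinned by test. Row normalization is the z-score with the n−1
standard deviation; constant rows map to zero rather than NaN. The
heatmap matrix carries the two ICI columns and, by default, the group
mean IgA+ relative abundances; its column set is recorded in the output
header.

**High coaters** use the strict inequality ICI > 10.

**Taxon screens.** The two-group test engine is a label-permutation test
of |difference of group means| on per-sample relative abundances. When
the number of distinct label splits is at most 20,000 the engine
enumerates all of them and reports the exact tail fraction (ties count
as extreme; the identity split is part of the enumeration); otherwise it
samples B permutations and reports `(1 + #extreme)/(1 + B)`, which is
never exactly zero. This engine deliberately replaces the
negative-binomial empirical-Bayes quasi-likelihood F-test used in the
original analysis: the permutation test is exactly implementable,
calibratable at desk scale, and assumption-light, and the substitution
is stated in every provenance header. Significance for taxon screens is
conjunctive — BH q < 0.05 **and** raw p < 0.01 — with both knobs
configurable. log2 fold-changes are computed on pseudocounted group
means and are therefore always finite.

**Differential targeting.** "Comparable presort abundance" is
operationalized as non-significance of the presort screen at
q ≥ 0.05; an equivalence bound would be an alternative reading of
"comparable", but none is published, so non-significance is the default
and the floor is a parameter. The coating difference is assessed on the
IgA+ fraction by default, with the IgA− fraction or per-subject ICI
values selectable.

**Volcano screen.** Welch t-tests per feature; volcano significance
requires |log2 FC| > 1.2 and −log10(p) > 0.1. The p gate is permissive
by construction (p < 10^−0.1 ≈ 0.79) — it is the published gate and is
implemented verbatim; BH q-values are reported alongside for the
separate FDR tally. Features constant across all samples get p = 1 and
a warning flag.

**Rank-level screen.** Counts are agglomerated at the requested rank
(taxa with an empty label pool into `unclassified`, conserving read
totals exactly); taxa must exceed 1% overall mean relative abundance
*strictly* to be tested (Welch t + BH).

**Diversity.** Bray–Curtis `1 − 2Σmin(x,y)/(Σx+Σy)` on relative
abundances by default (per-sample depth must not masquerade as
community difference); raw-count mode is available. PERMANOVA partitions
squared distances into among/within sums of squares (pseudo-F, R²) with
the same exhaustive/sampled permutation conventions as the screens.
PCA operates on centered, unscaled relative abundances with an optional
Hellinger transform; axis signs are deterministic. One-way ANOVA is the
classical F; two-way uses Type II sums of squares, the robust choice
for the unbalanced group × age design. NMDS and rarefaction are out of
scope; analyses run on unrarefied counts.

## Designed validation experiments

All validation runs on simulated cohorts with ground truth; problem
sizes are chosen so the whole suite runs in well under a minute each.

* **Closed-form identity** — 100 random `(p, θ)` draws, ε = 0,
  pseudocount 0: pipeline ICI on noiseless compositions matches the
  closed form to 1e-9.
* **Complete-mixing null** — ε = 0.5, depth 1e5, S = 50, 16/15
  subjects: every taxon at ≥ 1% presort abundance has group ICI within
  [0.8, 1.25].
* **Null calibration** — 500 no-effect cohorts (S = 50, 8 vs 8
  subjects; 16 samples makes the engine's exhaustive mode the active
  code path): per-taxon rejection rate at p < 0.05 inside the binomial
  band [0.036, 0.064].
* **Oracle equivalence** — exhaustive permutation test and PERMANOVA
  reproduce brute-force enumeration exactly on all small fixtures; BH
  matches a direct step-up oracle to 1e-12 on 1000 random vectors.
* **Targeting recovery** — the `scenarios.targeting_recovery`
  experiment: background coating identical between groups and spread
  uniformly over (0.05, 0.95) so that coating *ranks* are identifiable
  (a near-degenerate θ distribution would make rank recovery measure
  tie-breaking noise), five planted taxa at presort abundance ≈ 1% with
  θ 0.1 vs 0.8, 16/15 subjects, depth 30,471, 20 seeds. Planted taxa
  are called in ≥ 90% of replicates; group-identical taxa fire within
  the composite false-positive budget; Spearman(θ, group ICI) ≥ 0.9.
* **Determinism** — end-to-end `analyze` reruns with a fixed seed are
  byte-identical.

## Known limitations

* The ICI saturates as a θ estimator: it measures θ relative to the
  community-average coated share, so a uniformly-coated community has
  ICI ≈ 1 everywhere regardless of θ.
* Rare taxa (expected sorted-fraction counts near the pseudocount) have
  ICIs shrunk toward 1 and are effectively untestable at realistic
  depth; this is a property of the data, not of the implementation.
* The permutation engine requires ≥ 2 samples per group and has p-value
  granularity 1/(B+1) in sampled mode; p < 0.01 calls need B ≥ 999.
* BIOM input is read-only (JSON 1.0 and HDF5 2.1 profiles); TSV is the
  canonical interchange format.
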