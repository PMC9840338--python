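# igaseq

Analysis pipeline for **IgA-seq** studies of the developing gut
microbiome — cohorts in which fecal bacteria are sorted into IgA-coated
(IgA+) and non-coated (IgA−) fractions, each fraction is 16S-sequenced,
and the question is *which taxa does the mucosal antibody response single
out, and does that targeting differ between children who later develop
celiac disease and matched healthy controls?*

The package is written for microbiome researchers who have ASV count
tables (e.g. from dada2) for presort, IgA+ and IgA− fractions plus sample
metadata, and for methodologists who want a fully synthetic, ground-truth
version of such a cohort to test analysis choices against.

## The coating index and the targeting call

For taxon *t*, with relative abundances `a⁺_t` in the IgA+ fraction and
`a⁻_t` in the IgA− fraction, the **IgA coating index** is

    ICI_t = a⁺_t / a⁻_t

Group-level indices `ICI_control` and `ICI_celiac` are computed per age
from group-aggregated relative abundances (pseudocount 1 read by
default, so the ratio is always finite). The pipeline applies the
published presentation rules:

* **retention** — taxa with ICI < 1 in both groups are discarded for the
  heatmap, *except* discordant taxa (`ICI_control < 1 and ICI_celiac > 1`,
  or vice versa), which are kept; the heatmap matrix is row z-scored;
* **high coaters** — taxa with group ICI strictly above 10.

Under the package's generative model of the sort (presort composition
`p`, per-taxon coating probability `θ`, symmetric sorting impurity `ε`),
the noiseless group ICI has the closed form

    ICI_t = [θ_t / (1 − θ_t)] · [Σ_u p_u (1 − θ_u) / Σ_u p_u θ_u]   (ε = 0)

which the test suite verifies to 1e-9 and which makes ICI a monotone
readout of `θ`.

**Differentially targeted taxa** are those whose presort abundance is
statistically comparable between groups (screen q ≥ 0.05) while their
IgA+ abundance differs significantly (q < 0.05 **and** p < 0.01, the
study's stringent double threshold). Taxon screens use a two-group
|difference of means| permutation test on per-sample relative abundances
(exact enumeration whenever the number of label splits is ≤ 20,000),
with Benjamini–Hochberg FDR control.

Also included: observed-ASV richness, Bray–Curtis dissimilarity,
PERMANOVA (Anderson's pseudo-F, permutation p), PCA ordination, one-/
two-way ANOVA (Type II), the >1% mean-relative-abundance rank-level
screen, and the plasma-analyte volcano screen
(|log2 FC| > 1.2, −log10 p > 0.1).

## Worked example

```python
from igaseq import differential_targeting, scenarios

cohort, truth, planted = scenarios.targeting_recovery(seed=0)
call = differential_targeting(cohort, age=2.5, seed=0)
print(sorted(planted))
print(sorted(call.targeted_taxa))
```

prints

```
['ASV0005', 'ASV0007', 'ASV0008', 'ASV0019', 'ASV0021']
['ASV0005', 'ASV0007', 'ASV0008', 'ASV0019', 'ASV0021']
```

The scenario plants five taxa with *identical* presort abundance in both
groups but coating probability 0.1 in controls vs 0.8 in progressors
(16 vs 15 subjects, mean depth 30,471 reads); the composite call
recovers exactly the planted taxa — their gut abundance carries no
signal, their IgA coating does. The `examples/` directory has one short
script per capability (simulation, ICI/high coaters, targeting,
diversity, volcano screen, end-to-end run), each printing the numbers it
computes and what they mean.

A thin CLI wraps the same functions:

```sh
igaseq simulate --n-taxa 575 --seed 1 --outdir sim
igaseq analyze --counts sim/counts.tsv --metadata sim/metadata.tsv \
    --seed 1 --outdir out
igaseq report --bundle out
```

Every report table carries `#` provenance lines (version, seed, all
thresholds, pseudocount, test engine, config hash); reruns with the same
inputs and seed are byte-identical.

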