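# Methods

## The question and the model

Holometabolous insects (flies, moths, beetles, bees) rebuild their body plan
during metamorphosis: larval tissues are dismantled and adult organs are
differentiated from set-aside imaginal cells, much as organs are first built
during embryogenesis. If metamorphosis re-runs parts of the embryonic
program, two transcriptome-level signatures follow:

1. **Stage similarity.** Pupal expression profiles should correlate more
   strongly with embryonic profiles than a monotone developmental
   progression (embryo → larva → pupa → adult) would predict, producing an
   off-diagonal embryo–pupa block in the pairwise Spearman correlation
   matrix of samples.
2. **Transition recapitulation.** Per-gene expression changes at the
   pupa→adult transition should correlate positively with the changes at
   the embryo→larva transition: genes switched on when the larva first
   differentiates are switched on again when the adult emerges.

holodev computes both statistics, identifies the genes responsible
("zigzag" trajectories that depart from the embryonic level in the larva
and return to it in the pupa), and asks which functional categories they
belong to.

## Statistics

**Similarity.** All correlations across genes are Spearman rank
correlations of log2(FPKM + 1) values (mid-ranks for ties). Constant
vectors have undefined rank correlation; we return NaN and abort analyses
that would silently consume it rather than substituting 0, which would fake
dissimilarity.

**Stage means.** Replicates are collapsed by arithmetic mean on the log2
scale (the scale of every downstream statistic); stage means with one
replicate reduce to that sample.

**Transition fold changes.** For stage means `m` on the log2 scale, the
fold change of transition s→t is `lfc = m_t − m_s` (a log2 fold change).
Genes with `|lfc| > 1.5` are flagged as strongly changing; 1.5 log2 units
(≈2.8-fold) is the default threshold. The recapitulation statistic is the
Spearman correlation of the embryo→larva and pupa→adult lfc vectors
(Pearson available as an option).

**Resampling null.** To test whether a functional gene subset carries a
statistic (a stage correlation, a recapitulation rho) beyond what any
same-sized set would, B random gene sets of the same size are drawn
uniformly without replacement from all matrix genes and the statistic is
recomputed on each. We report the quantile `#{null ≤ observed}/B`
(ties count as ≤) and the add-one empirical p-value
`(1 + #{null ≥ observed})/(B + 1)`, which is never 0. B defaults to 999.
Sampling is from all matrix genes by default; an expression-positive
reference can be supplied instead for consistency with the enrichment
reference.

**Trajectory templates.** With four stages there are three transitions,
each up/flat/down: 27 templates, each defined by its 4-point level vector
(cumulative step sum starting at 0). A gene's stage-mean profile is scored
against each template by Pearson correlation on the 4 points — Spearman on
4 heavily tied template levels cannot separate the 27 patterns. The flat
template "000" has zero variance, so correlation against it is undefined;
instead, genes whose total dynamic range across the four stage means is at
most `min_range` (default 0.5 log2 units, i.e. less than a 1.4-fold change
over all of development) are called flat and assigned to "000" directly.
This gate is an expression-change threshold, not a numerical-zero test: a
measured profile is never exactly constant, and a trajectory call for a
gene moving less than 1.4-fold total is not meaningful. Score ties are
broken toward the template with fewest non-zero steps, then canonical
order, preferring the simplest pattern. The two strictly alternating
templates "+−+" and "−+−" are the zigzag set; a looser six-template
family (embryo≈pupa with a free third transition) is available behind the
`embryo_pupa_family` criterion because the direction of the third
transition is not intrinsic to the embryo-reversion idea.

**Dense time courses.** Datasets with ≥5 time points are clustered
agglomeratively with distance 1 − Spearman(profile_i, profile_j) (average
linkage by default, complete available), the tree cut to exactly K
clusters. Constant profiles are excluded with a report. Zigzag-like
clusters are selected from per-cluster stage-mean profiles standardized to
z-scores across the four stages: a cluster qualifies when
`|z_embryo − z_pupa| < delta` (default 0.5) and
`|z_larva − z_embryo| > epsilon` (default 1.0).

**Gene subsets from the ontology.** The development-associated subset is
every gene with at least one direct annotation to GO:0032502 ("developmental
process") or any descendant; metabolism uses GO:0008152. Descendant closure
includes the root itself and traverses `is_a` and, by default, `part_of`
edges (configurable — annotation pipelines differ in which relations they
propagate over).

**Enrichment.** Study sets are tested against the reference of all genes
with positive expression in at least one sample. Annotations are first
propagated to all ancestor terms; every term with ≥1 study gene receives a
one-sided Fisher exact test (hypergeometric upper tail) on the
study/non-study × term/non-term table, and p-values are Benjamini–Hochberg
adjusted across the tested terms, with significance at adjusted p ≤ 0.05.
Restricting the family to terms with ≥1 study gene keeps the correction
aligned with informative tests. Only enrichment (not depletion) is
reported.

## The synthetic generator

`holodev.synthetic_data` emulates a four-stage bulk developmental dataset
with planted truth. Per gene, a latent log2 level for each stage is the sum
of a baseline drawn Uniform(2, 8) log2 FPKM and a class-specific offset
(effect size e, default 2 log2 units):

- monotone up/down: ±[0, e/3, 2e/3, e]
- zigzag up/down: ±[0, e, 0, e] (embryo ≈ pupa)
- constant: zeros
- random: cumulative Gaussian steps with sd e/2; the embryo→larva and
  pupa→adult steps are drawn jointly with correlation
  `shared_program_rho`, planting a tunable recapitulation signal

Latent levels are clamped at 0 (expression cannot be negative). Each
replicate observes latent + N(0, noise_sd) on the log2 scale —
multiplicative log-normal noise on FPKM — and is back-transformed as
`max(2^x − 1, 0)`, so the analysis transform log2(FPKM + 1) recovers the
latent levels exactly at zero noise. Optional egg contamination mixes a
fraction of each gene's latent embryo FPKM into adult-female samples,
reproducing the confounder that motivates the female-exclusion QC rule.
A six-term GO subtree (rooted at biological_process, with developmental-
and metabolic-process branches) annotates 80% of zigzag genes as
development-associated and 30% of the rest as metabolism-associated.

Defaults describe one mid-sized study: 2,000 genes; fractions 0.15 for each
monotone and zigzag class, 0.10 constant, 0.30 random; 3 replicates per
stage; noise sd 0.2 log2 units (≈15% multiplicative error, typical of bulk
RNA-seq replicates); shared_program_rho 0.3 (a modest planted signal).

What the generator does **not** model: count-based noise (negative
binomial sampling at low expression), library-size or length biases,
within-stage developmental drift, correlated gene modules beyond the
planted classes, or annotation noise. Passing truth-recovery tests
therefore demonstrates the statistics are implemented correctly and are
calibrated under log-normal noise — not that real datasets will show the
effect, which depends on biology and data quality.

## Numerical and design choices

- Log base 2 and pseudocount 1 (0 → 0) for the FPKM transform; both
  configurable.
- Duplicate-sample QC compares expression columns bit-for-bit (the proxy
  available once reads are gone); only explicit `female` samples are
  removed by the sex filter (`mixed`/`unknown` retained).
- QC refuses to leave any of the four major stages without samples — the
  analysis is undefined without full stage coverage.
- The embryonic reference for similarity profiles is the per-gene mean
  over all embryo samples (the symmetric choice when several exist).
- Hierarchical clustering uses scipy's linkage on a condensed
  1 − Spearman matrix; merge ties resolve to the lowest-index pair
  (scipy's deterministic behaviour), so runs are reproducible given input
  order.
- Resampling, simulation and the pipeline all take explicit integer seeds
  and are bit-reproducible; the pipeline manifest excludes wall-clock
  timings so rerunning a configuration reproduces every output file
  exactly.

## Problem sizes used in the checks

The bundled verification suite runs entirely on generated data: template
recovery at 2,500 genes (500 per planted class, noise sd 0.1),
recapitulation-rho recovery at 2,000 genes for planted correlations
{0, 0.3, 0.6} (tolerance ±0.07), resampling calibration over 500
repetitions at B = 199 (KS uniformity), and oracle cross-checks of the
Spearman, hypergeometric-tail and DAG-closure primitives against
independent brute-force implementations.

## Known limitations

- FPKM is a within-sample normalization; cross-sample comparability
  assumes similar library composition, which the pipeline does not check.
- The 27-template classification uses stage means only; sub-stage dynamics
  are invisible to it (use the hierarchical path for dense series).
- The resampling null ignores gene–gene correlation within the subset
  being tested; quantiles are calibrated for subset *membership*, not for
  co-expression structure.
- Enrichment treats annotations as exact; predicted (e.g.
  sequence-homology-derived) annotations add noise the Fisher test does
  not model.
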