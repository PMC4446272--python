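# Methods

## Study design being modelled

The pipeline targets a two-diet (HFD vs LFD), two-timepoint design:
distinct cohorts of mice profiled after 5 days (10 animals per diet)
and 12 weeks (12 per diet), with a gene × sample log2 expression
matrix, a per-animal physiology table, a biological-process gene-set
collection (GMT) and a TF → target regulon collection (GMT).  All
stages operate within one timepoint; timepoints are analysed
independently and only share the gene universe.

## Differential expression

Equal-variance two-sample contrast on log2 values (HFD − LFD).  The
pooled per-gene variance s_g² (d_g = n_A + n_B − 2 df) is shrunk toward
a prior s₀²:

    s̃² = (d₀·s₀² + d_g·s_g²) / (d₀ + d_g)

with user-settable prior df d₀ (default 4) and s₀² defaulting to the
mean pooled variance across genes.  Two-sided p values use a
t-distribution with d₀ + d_g df; FDR is Benjamini–Hochberg (delegated
to statsmodels).  This is a deliberately simple fixed-prior shrinkage
rather than an empirical-Bayes fit of (d₀, s₀): it is monotone in the
same direction, has an exact limiting behaviour at d₀ = 0 (ordinary
pooled t) and d₀ → ∞ (common-variance t), and downstream stages consume
only t ranks and FDR flags, which bounds sensitivity to the choice.

Calibration: with the generator's constant-variance Gaussian noise the
d₀ = 0 statistic is exactly t-distributed, so the null-uniformity (KS)
check is run there; the moderated default trades that exactness for
stability and keeps the type-I rate at ≈ 0.048 for nominal 0.05
(asserted at n = 10 000 null genes).  Genes with missing values are
dropped from the affected timepoint.  Genes with zero variance and
d₀ = 0 have an undefined statistic and are reported NaN with a warning.

## Preranked enrichment

Genes are ranked by descending t (ties broken lexically by id for
reproducibility).  For a set S, walking the ranking adds
|t|^p/N_R at hits (N_R = Σ_hits |t|^p) and subtracts 1/(N − N_H) at
misses; ES is the running-sum value of maximal |deviation| (an exact
magnitude tie resolves positive).  Defaults: weight exponent p = 1,
set-size window 15–500 (effective size after intersection with the
universe), ≥ 1000 permutations.

The permutation null draws random same-size gene sets from the ranked
universe (the preranked standard; sample-label permutation is not
applicable when only genes and t scores enter the analysis).  p values
use (n_exceed + 1)/(n_tail + 1) smoothing so −log₁₀(p) is finite;
NES = ES / |mean same-sign null ES|; FDR q follows the GSEA
null-vs-observed NES tail-ratio convention.  Nulls are computed
vectorised from hit positions only (the running-sum extrema occur just
after a hit or just before one), which makes 1000 sets × 1000
permutations a ~20 s computation; sets of equal effective size share
one null sample within a run.

Direction labels: the signed ES of the reversed ranking is exactly the
negation of the forward ES, so "significant positive ES in both runs"
can never occur with the two-sided statistic.  Direction
classification therefore runs the forward and reversed rankings with a
one-sided statistic (maximal positive running-sum value,
`GseaConfig(statistic="pos")`): support only in the forward run ⇒
*up*, only in the reversed run ⇒ *down*, in both ⇒ *both* (sets with
members at both extremes).  The node score is −log₁₀ of the supporting
p, negative for down.  Nodes are thresholded on nominal p (default
0.05), configurable.

## Regulator activity

Per TF, targets are intersected with the tested universe; enrichment of
targets among DE genes (FDR < 0.05) is the one-sided hypergeometric
tail P(X ≥ k) (scipy).  Direction is the activation
z = (n_up − n_down)/√(n_up + n_down) over DE targets (0, flagged, when
no target is DE), and the activation score is −log₁₀(p)·sign(z).  TFs
whose *DE-restricted* target sets are identical merge into one cluster
("100 % overlap"); full-target identity is available as an alternative
key.  The member with the smallest p (ties: lexical name) represents
the cluster and becomes the network node; all TFs stay in the output
table.  Only over-representation is tested — depletion of targets among
DE genes is not biologically meaningful here.

## Physiology correlation

Spearman's ρ is computed as the Pearson correlation of average ranks
(ties averaged), with two-sided p from t = ρ√((n−2)/(1−ρ²)) on n − 2
df; |ρ| = 1 reports the smallest positive double rather than 0, and
values within 1e−12 of ±1 are snapped before the p computation.  Pairs
with missing values are dropped (pairwise-complete per parameter);
n ≥ 4 is required and zero rank variance is an error.  Animals of both
diet groups within a timepoint are pooled (maximising n and phenotype
range); per-group analysis is possible by subsetting the inputs.  A
gene backs a parameter when |ρ| > 0.8 and p < 0.05; no multiple-testing
correction is applied on the gene × parameter grid — the dual cutoff is
itself the selection rule.  Note the sample Spearman estimator is
biased low at these n (E ≈ 0.875 at n = 20–24 for population ρ = 0.9),
which is why module recovery is asserted as a multi-seed average.

## Network assembly and topology

Node backing sets: process = full set membership ∩ universe
(enrichment-map convention; leading-edge backing is available),
regulator = DE targets of the cluster representative, physiology =
correlated genes.  Edge similarity defaults to the overlap coefficient
|A∩B|/min(|A|,|B|); Jaccard and a combined k·overlap + (1−k)·Jaccard
are provided because published edge tables of this kind are not always
consistent with a single simple formula.  An edge is kept when the
overlap is ≥ 1 gene and the coefficient meets the layer-pair cutoff,
boundary inclusive: 0.3 for physiology–process pairs, 0.5 otherwise.
Allowed relationships default to process–process, regulator–process,
regulator–physiology and physiology–process; regulator–regulator and
physiology–physiology edges are off.  Node and edge insertion is
sorted, so GraphML/SIF/TSV serialisations are byte-stable.  Topology
uses networkx: degree, unnormalised shortest-path betweenness and local
clustering per node; node/edge counts and density per network.

## Synthetic data generator

Baseline expression is Gaussian on the log2 scale: gene means uniform
on [6, 12], residual SD `noise_sd` (default 0.5) constant across genes.
Planted regulons receive disjoint target blocks, shifted by
direction × `effect_size` (default 1.5, alternating signs) in HFD
samples only.  Planted processes draw half their members from the
planted DE pool; unplanted processes draw a quarter of their members
from a random unplanted regulon's targets so cross-layer overlap edges
exist by construction; set sizes are log-uniform within the allowed
range (more small sets than large, as in curated collections).
Phenotype links use a shared standard-normal latent factor per linked
parameter and cohort: the parameter equals the factor, and each module
gene adds ±b·latent with b = noise_sd·ρ_P/√(1−ρ_P²), where
ρ_P = 2·sin(π·ρ_S/6) inverts the bivariate-normal relation
ρ_S = (6/π)·asin(ρ_P/2) for the target Spearman magnitude (default
0.9); gene signs are random.  Modules are disjoint from planted
targets and from each other.  `effect_size = 0` or
`link_rho_target = 0` yield a pure-null study whose truth manifest
records nothing.

What the generator does *not* emulate: probe-level artifacts,
normalisation and batch effects, gene–gene correlation beyond the
planted structure, heavy-tailed or heteroscedastic per-gene variances,
parameter–parameter correlation, and longitudinal animal overlap
(cohorts are independent, as in the emulated design).  Passing tests
therefore demonstrate correctness and calibration of the statistical
machinery under the assumed model, not robustness to microarray
artifacts.

## Numerical and interface choices

- All randomness flows through `numpy.random.default_rng` seeds; same
  (config, seed) ⇒ byte-identical studies and pipeline outputs.  The
  run manifest records parameters, versions and SHA-256 checksums and
  contains no timestamps, so reruns are bit-for-bit comparable.
- Gene identifiers are matched case-sensitively after whitespace
  trimming.  GMT parsing rejects short lines and duplicate set names
  with line numbers, and deduplicates repeated members with a warning.
- Degenerate inputs fail loudly: groups with < 2 samples, empty
  universes, sets covering the whole universe, all-zero hit weights,
  < 4 correlation pairs, empty networks for topology.
- Problem sizes in the test and acceptance suites (2000–10 000 genes,
  120–1000 sets, 1000 permutations, 10–20 simulation seeds) were chosen
  as the smallest designs at which the calibration and recovery
  properties are stable.

## Known limitations

- The regulator stage is a transparent hypergeometric/z-score stand-in
  for knowledge-base upstream-regulator analytics; it scores
  over-representation and sign consistency, not causal network depth.
- The moderated test's fixed prior df is not estimated from data; for
  strongly heteroscedastic gene variances an empirical-Bayes fit would
  be preferable.
- GSEA FDR q uses the pooled-NES convention and is only as fine-grained
  as the permutation count.
- With small backing sets the overlap coefficient saturates at 1.0
  easily; edge coefficients between tiny sets should be interpreted
  with care.
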