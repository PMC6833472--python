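# Methods

## The model and its assumptions

`copath` analyzes a gene × sample matrix of integer counts from a design
with one fixed reference condition and an ordered series of non-reference
conditions. Everything downstream is built on a deliberately discrete
abstraction: each gene receives, per non-reference condition, a trinary
differential-expression call against the reference, and the tuple of calls
— the *co-expression path* — is the unit of biological interpretation.
This mirrors how injury/treatment series are usually read: what matters is
whether a gene is up, down, or unchanged in each arm relative to the
untouched baseline, not the exact effect size. The approach assumes:

* counts are adequately described by a negative binomial with a per-sample
  depth factor (no batch structure, no covariates);
* one categorical condition label per sample; replicates are exchangeable;
* "restored to baseline" means the call against the *never-injured
  reference* returns to unchanged in the treated arm — not that the
  treated arm differs from the untreated injured arm. This is the stricter
  and more interpretable reading of restoration: a gene halved from a
  4-fold injury response is still elevated, and still counts as persistent.

## Normalization

Median-of-ratios size factors: for each sample, the median over
all-positive genes of the count divided by the gene's geometric mean
across samples, rescaled so the factors' geometric mean is 1. The
estimator assumes most genes are not differentially expressed — satisfied
by construction in the simulator (≤ 30% planted genes) and standard
practice for bulk data. If no gene is positive in every sample the
estimator fails loudly (`NormalizationError`) rather than guessing;
total-count normalization with a pseudocount is the suggested fallback for
such sparse matrices.

## Differential expression

Per contrast, the effect estimate is
`log2FC = log2((mean normalized count + c) / (reference mean + c))` with
pseudocount `c = 1` on the normalized scale, which bounds fold changes for
zero counts. Significance comes from a two-sample t test on
`log2(normalized + 1)` across replicates, BH-adjusted within the contrast,
and the trinary call requires both `|log2FC| ≥ 1` and `q ≤ 0.05`
(thresholds configurable).

The default test moderates the variance. With the 3–4 replicates typical
of these designs, per-gene variance estimates are extremely noisy: a
per-gene Welch t has as few as ~3 degrees of freedom, and a genuinely
4-fold-shifted gene is missed whenever its variance estimate comes out
unluckily large — in our simulations this capped per-contrast sensitivity
at ~94–96% regardless of expression level. The moderated test squeezes
each gene's pooled variance toward the panel-wide mean,
`s²_mod = (d₀·s₀² + d·s²)/(d₀ + d)` with `d = n₁ + n₂ − 2` and prior
weight `d₀ = 4` pseudo-replicates, and refers the t statistic to `d + d₀`
df — the same empirical-Bayes idea the established small-replicate RNA-seq
tools rely on. `s₀²` is the mean pooled variance across analyzed genes;
`d₀ = 4` gives the prior the same weight as one extra 2×3-replicate
experiment and restores sensitivity to ≥ 99% in the planted simulations
while leaving the null false-call rate at ~0. A per-gene Welch t remains
available (`variance_mode="welch"`) for users who distrust the shared-
variance assumption, e.g. with strongly heteroskedastic samples.

Genes with mean normalized count below 5 (configurable) are removed before
testing; the survivors define the *analyzed universe* used by both the
path partition and the enrichment background. Degenerate inputs are
defined, not accidental: a gene with identical values in every sample gets
p = 1 and an unchanged call; single-replicate conditions refuse to run
unless `fold_change_only=True`, which calls by fold change alone and
reports p = q = 1.

BH is implemented as the step-up `q_(i) = min_{j≥i} p_(j)·m/j`, capped at
1, restored to input order; ties are handled by stable sorting and make no
difference to the result. p-values are clipped to `[1e-300, 1]` before
adjustment so log-space underflow can never produce a zero.

## Path classification and restoration sets

Paths are call tuples in the declared condition order, serialized with a
`|` separator. The partition is exhaustive and disjoint by construction; a
missing (gene, contrast) row is an error, never silently imputed. The
all-unchanged path is kept (its genes belong to the enrichment universe)
but flagged flat and excluded from enrichment foregrounds. Output order is
by path size, ties by label, so runs are reproducible.

Restoration sets are pure projections of path labels onto two named
positions (injured-untreated, injured-treated): `up_restored` = up then
unchanged, `up_persistent` = up then up, symmetric for down. A gene that
overshoots (up after injury, *down* under treatment) is deliberately in
neither set. Because only two label positions are read, the sets are
unions of whole paths and invariant to every other position — a property
the test suite checks exhaustively.

## Enrichment

One-sided hypergeometric upper tail per (non-flat path, term): the
over-representation question is the one the confidence heatmap answers;
depletion is not scored. The universe defaults to the analyzed genes (not
all annotated genes), the standard guard against detection bias; annotated
mode is available. Term annotations are intersected with the universe
before computing K. BH runs across the full path × term matrix by default
— the heatmap is read as one screen — with a per-path mode behind a flag.
The confidence transform `-10·log10(p)` floors p at 1e-300 to stay finite.
Gene-set structure (term ancestry, propagation) is not modeled; the GMT is
taken as given.

For heatmap display, terms are ranked by their maximum confidence across
paths (ties broken by term ID) and untested cells shown as 0.

## The synthetic-data generator

The generator emulates the four-condition injury/treatment design:
conditions `NI_vehicle` (reference), `NI_C286`, `SNL_vehicle`, `SNL_C286`,
with n = 4 replicates each (the replicate count of such studies is rarely
large; 4 is a realistic default and configurable). Counts are drawn
NB(μ, α) with `μ_gs = 2^(b_g + Δ_gc) · s_s`:

* `b_g ~ Uniform(5, 10)` log2 baseline, i.e. mean counts 32–1024. This
  places planted genes in the expression regime a 4-replicate design can
  actually interrogate: a Monte-Carlo power analysis of the moderated test
  under the default dispersion showed per-contrast detection of a −2 log2
  shift rises from ~96% at baseline 2⁵ to ~99.9% at 2⁶. Real libraries
  also contain genes below this range, for which recovery would be
  correspondingly lower — the generator is a benchmark of the method's
  behaviour where detection is physically possible, not a library
  simulator.
* `Δ_gc` is the planted log2 effect, ±2 by default, with sign pattern per
  trajectory class over (drug alone, injury alone, injury + drug):
  restored classes are (0, ±e, 0), persistent (0, ±e, ±e), drug-only
  (±e, 0, ±e) — the drug-only pattern applies the effect wherever the drug
  is given, the natural reading of a treatment-intrinsic response. Each
  non-flat class holds 5% of genes; the remaining 70% are flat.
* `α = 0.05` dispersion (`var = μ + αμ²`), a typical bulk value; the
  Poisson limit α → 0 is exercised in tests via the moment identity.
* `s_s ~ log-Uniform(0.5, 2)` depth factors, wide enough to make
  normalization consequential.

Gene sets: 200 terms of 20–100 genes drawn uniformly; one term per
non-flat class is planted by drawing 60% of its members from that class.
The truth manifest records every planted class, effect, and planted term
exactly as generated, so recovery is measured against the generative draw,
never against a re-estimate.

What the generator does **not** emulate: batch effects, replicate-level
covariates, gene–gene correlation, length/GC bias, single-cell zero
inflation, or annotation hierarchies. Passing tests therefore demonstrate
the pipeline's statistical correctness and calibration under its own
model, not robustness to those real-data complications.

## Calibration of the discrete enrichment test

For an exact test on discrete data, `P(p ≤ α) ≤ α` with equality only in
the continuous limit. At the default geometry (terms of 20–100 genes,
paths of a few hundred, universe 10⁴) the attainable p-values near 0.05
are coarse and the observed null rate sits around 0.025–0.03. The
calibration check therefore asserts the property the hypergeometric
actually has — the null p ≤ 0.05 rate is bounded by 0.05 plus Monte-Carlo
slack, is non-degenerate, and BH at q < 0.05 yields essentially nothing —
rather than a two-sided band around 0.05 that a conservative discrete test
cannot satisfy.

## Problem sizes and determinism

The default simulation (10,000 genes, 16 samples, 200 terms) runs the full
pipeline in under a second; the test suite and the acceptance script use
this default for all calibration/recovery checks and smaller variants
(400–2,000 genes) where only plumbing is exercised. All randomness flows
from one `numpy` `default_rng` seed per simulation; a pipeline run's seed
is part of its config, and identical configs produce byte-identical
outputs apart from timestamps.

## Known limitations

* The DE stage is a calibrated screen, not a dispersion-modeling DE method:
  no per-gene NB dispersion estimation, no shrinkage of fold changes, no
  multi-factor designs. The trinary calls are what feed downstream, and
  any reasonably calibrated test with adequate power is sufficient for the
  path abstraction.
* Trinary calls discard effect-size information within a path; two genes
  up 2-fold and 30-fold share a label.
* Restoration is defined against the reference call only; a formal
  equivalence test ("significantly *not* different") is not performed, so
  an underpowered contrast can masquerade as restoration. The planted
  benchmarks quantify exactly this risk under the default design.
* Enrichment treats the GMT as flat and terms as independent in the BH
  step; hierarchical annotations will produce correlated rows.
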