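# Methods

## Scope and design

`sustaindeg` reimplements, as a testable pipeline, the downstream analysis
of a two-stimulus (LPS / IL-4), two-timepoint (12 h / 24 h) bulk RNA-seq
experiment on a microglial cell line: differential expression per
stimulus × timepoint against the matched-timepoint control, sustained-DEG
selection, responder-set classification, over-representation analysis and
cross-dataset concordance. The pipeline starts at the gene × sample count
matrix; alignment and quantification are upstream of its scope, and the
original study's raw data are not publicly deposited, so a synthetic
generator stands in as the test bed for every stage.

## Synthetic count generator

The generator emulates the study design: six conditions (control, LPS,
IL-4 at 12 h and 24 h), five independent replicates each. Counts are
negative binomial via a gamma–Poisson mixture,

    K_gj ~ NB(mean = s_j * mu_g * 2^(delta_g(cond_j)), dispersion alpha_g),

with

- baselines mu_g log-normal, ln mu_g ~ N(4, 2²) (median ≈ 55 counts, a
  heavy low-expression tail, as in real bulk libraries);
- dispersion trend alpha_g = a0/mu_g + a1 with a0 = 3, a1 = 0.05 — the
  asymptotic dispersion 0.05 and the Poisson-dominated low-count regime are
  conventional bulk RNA-seq magnitudes. The study reports no dispersion or
  library-size summaries of its own data, so these are stated conventions,
  not estimates;
- depth factors s_j log-normal, ln s_j ~ N(0, 0.2²);
- planted programs delta_g: signed multiples of the configured effect
  (default |log₂FC| = 2, comfortably past the |log₂FC| > 1 call threshold)
  over the four treated conditions. Fifteen classes cover sustained
  stimulus-specific, common, opposite, transient (one timepoint) and
  direction-flipping programs plus a null class. The default composition at
  2000 genes mirrors the study's proportions (a larger LPS than IL-4
  response, a few dozen common and opposite responders, a handful of
  flips): 391 responder genes, 1609 null.

Labels are assigned to a seeded shuffle of gene indices so class membership
is independent of the baseline draw order. All streams (gene parameters,
assignment, depths, counts) spawn deterministically from one seed; the same
config reproduces bit-identical matrices and fixture files.

What the generator does *not* emulate: read-level noise, UMI structure,
batch effects, correlated gene programs, GC/length biases, and
between-replicate biological variance beyond NB overdispersion. Passing
recovery tests therefore demonstrates correctness of the analysis logic
under the stated noise model, not robustness to artefacts real data may
carry.

## Differential expression engine

A deliberately transparent NB Wald pipeline, not a re-implementation of any
specific release of the established packages:

- **Size factors**: median-of-ratios over genes with all-positive counts;
  if no such gene exists, the same statistic over genes positive in ≥ 50 %
  of samples with geometric means over positive entries only (logged).
- **Dispersions**: per gene, the Cox–Reid-adjusted NB profile likelihood —
  fitted means fixed at per-condition averages of normalized counts — is
  maximized over a 61-point log-spaced grid on [1e-8, 10] with parabolic
  refinement around the grid optimum. The grid search replaces scalar
  per-gene optimization because it is robust (no initialization failure
  modes), trivially vectorized over genes, and accurate to well under the
  sampling error of a gene-wise estimate after refinement. The CR term
  (−½ Σ_cells log Σ_j μ/(1+αμ)) corrects the downward bias of plain ML with
  six fitted means; without it the null type-I error leaves its calibration
  band. All-zero genes are flagged `excluded`, not errors. No shrinkage
  toward a fitted trend is applied.
- **Wald test**: with dispersion fixed, each group's mean is fitted by
  damped Newton on the log scale (the NB log-likelihood is concave there);
  log₂FC is the difference of fitted log-means, SE from observed Fisher
  information (1/I_A + 1/I_B)^½/ln 2, p two-sided normal. A group with all
  zero counts is floored at 0.5 normalized counts, which keeps the fold
  change finite while the information-based SE grows accordingly. Genes
  with zero counts across a whole contrast are reported `ns` with NaN
  statistics.
- **Multiplicity**: Benjamini–Hochberg per contrast (delegated to
  statsmodels behind `adjust_bh`; NaNs propagate with a warning).
- **Calls**: strict `log2fc > 1` / `< −1` and `padj < 0.05`.

Omitted relative to full production DE packages, by design: dispersion and
fold-change shrinkage, independent filtering, outlier (Cook's) handling,
likelihood-ratio tests. The target is reproducibility of the downstream
classification logic; every output header carries a notice of these
simplifications. Exact DEG counts from the original data are consequently
not reproducible and are not asserted anywhere.

A note on scale invariance: rescaling one sample's column together with its
size factor does *not* leave ML estimates unchanged — the rescaled sample's
likelihood weight changes (this is true of any ML fit, including the
Poisson-limit MLE Σk/Σs). The invariance that does hold, and is tested, is
equivariance under rescaling a whole group's columns and size factors,
which leaves the fold-change estimate unchanged in the small-dispersion
limit.

## Sustained selection and responder algebra

Per stimulus, a gene is **sustained up/down** when called in that direction
at both timepoints, **inconsistent** when significant at both timepoints
with opposite signs, else **not sustained**. The classifier then assigns
one label per gene, in decision order: none (nothing sustained anywhere);
common (same direction both stimuli); opposite (both sustained, opposite
signs); ambiguous (sustained one stimulus + inconsistent the other);
specific (sustained exactly one stimulus); remaining inconsistent cases
ambiguous. Three reporting conventions follow the source analysis:

- specific-set *counts* include the opposite responders for that stimulus
  and direction (`specific_up(stim) = sustained_up(stim) − common_up −
  ambiguous_up(stim)` holds exactly);
- the per-direction Venn-style tallies count an inconsistent (flip) gene in
  both directions of its stimulus — a separate report, never part of the
  partition;
- GO input lists exclude common responders and allocate opposite
  responders by direction under each stimulus, so list sizes equal the
  specific counts.

The ambiguous rule (excluded from both common and specific) is the only
reading under which a sustained-down set of 166 with 75 common members and
one inconsistent-under-LPS gene yields 90 specific genes. Genes
inconsistent under both stimuli are ambiguous too: the class must be total
even though no such gene was observed in the source data.

## ORA and concordance

ORA is the standard upper-tail hypergeometric test with BH across all terms
of a run. The enrichment universe defaults to the genes the DE stage
actually tested — the only universe the pipeline can justify internally.
No term-size filters by default; ranking is deterministic by
(padj, p, term_id) so top-K overlaps are reproducible. GO graph structure
(ancestry, redundancy) is out of scope; annotations are taken as given in
the GMT.

Concordance between two DEG tables applies both tables' thresholds first
(a gene shared by id but sub-threshold in one table is not shared),
counts directionality quadrants, reports agreement as
100·(up_up+down_down)/n_shared (half-even rounded to one decimal alongside
the exact value), Spearman r_S of log₂FC via average-rank Pearson (undefined
and reported null below 3 shared genes or for constant vectors), and the
intersection of top-K term lists. Zero shared genes reports agreement as
null with a warning, never 0.

## Numerical choices and degenerate inputs

- Dispersion bounds [1e-8, 10]; group-mean floor 0.5 normalized counts;
  Newton steps clipped to ±5 on the log scale (concavity guarantees
  convergence, clipping guards the first iterations).
- BH p-values outside [0, 1] raise; NaN propagates with a warning count.
- Empty gene lists in ORA give gene_ratio 0 and p 1 per term.
- Degenerate fixtures (all-zero genes, missing controls, universe
  mismatches between call tables, cross-timepoint contrasts) raise typed
  validation errors naming the offending entity; the sustained definition
  is intentionally undefined for a gene observed at only one timepoint.

## Problem sizes and verification

The test suite and the acceptance script run entirely on synthetic or
printed-count inputs: 2000-gene × 30-sample simulations for calibration and
recovery (one to two seeds per check; per-gene tests on disjoint count
vectors are the effective Monte-Carlo replicates, so gene count rather than
run count sets the standard error), 81-combination exhaustive enumeration
for the classifier oracle, N ≤ 12 universes for exact ORA enumeration, and
study-scale membership fixtures (≈1800 genes) for the set-algebra worked
examples. The full suite completes in a few seconds on one CPU.

## Known limitations

- Planted-class recovery under the default generator is limited by
  information, not implementation: ~25 % of planted genes draw baselines
  below ≈15 counts, where the dispersion trend (α ≥ 0.25) makes a 4-fold
  change statistically undetectable at n = 5. Recovery is ≈75 % genome-wide
  but ≈100 % above ≈60 baseline counts; an independent DESeq2 run on the
  identical matrix classifies 75.9 % — the same ceiling. The acceptance
  suite reports the genome-wide figure unmodified.
- The Wald test is mildly anticonservative at n = 5 (null type-I ≈ 0.055
  at nominal 0.05) — the expected behaviour of gene-wise plug-in
  dispersions without shrinkage.
- Agreement percentages and set counts are exact arithmetic; everything
  depending on simulated data inherits Monte-Carlo variability across
  seeds.
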