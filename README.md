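# sustaindeg

Sustained transcriptional response analysis for stimulated microglia-like
cell models.

## The problem

Microglial cell lines challenged with a pro-inflammatory stimulus (LPS) or
an anti-inflammatory stimulus (IL-4) mount transcriptional programs that
partly persist across a 12–24 h window. Characterizing the *sustained*
component of those programs — and separating genes that respond to one
stimulus from genes that respond to both, or in opposite directions —
requires a chain of analyses: per-timepoint differential expression,
sustained-gene selection, set algebra over the two stimuli, functional
enrichment, and comparison against external datasets. `sustaindeg`
implements that chain as a reusable, fully tested pipeline, driven by a
synthetic count generator so every stage can be validated against planted
ground truth without any data download.

It is aimed at computational biologists who want the classification logic
itself — not a particular DE package version — to be reproducible and
testable.

## The model

Counts are modelled as negative binomial, K<sub>gj</sub> ~ NB(μ<sub>gj</sub>, α<sub>g</sub>)
with var = μ + α μ², μ<sub>gj</sub> = s<sub>j</sub> q<sub>g,cond(j)</sub>,
size factors s<sub>j</sub> by median-of-ratios. Each stimulus × timepoint
group is Wald-tested against the matched-timepoint control: gene-wise
dispersions maximize a Cox–Reid-adjusted profile likelihood, the log₂ fold
change is the ML estimate with standard error from observed Fisher
information, and p-values are BH-adjusted per contrast. A DEG satisfies
|log₂FC| > 1 and p<sub>adj</sub> < 0.05 (both strict).

On top of the DEG calls:

- **sustained**: same direction at both 12 h and 24 h; genes significant at
  both timepoints with *opposite* signs are flagged direction-inconsistent
  and excluded from every sustained set;
- **responder classes** (a partition): LPS-specific, IL-4-specific, common
  (same direction under both stimuli), opposite (sustained under both with
  opposite signs), ambiguous (sustained under one stimulus,
  direction-inconsistent under the other — excluded from both common and
  specific sets), or none. Reported specific-set counts include the
  opposite responders for that stimulus and direction;
- **ORA**: upper-tail hypergeometric test of each responder list against
  GMT gene sets, p = P(X ≥ k) for X ~ HG(N, K, n), BH across terms, gene
  ratio k/n, deterministic (p<sub>adj</sub>, p, term id) ranking;
- **concordance**: overlap, directionality quadrants, % agreement, Spearman
  r<sub>S</sub> of log₂FC, and top-K enriched-term overlap between two DEG
  tables thresholded identically.

## Worked example

```python
import sustaindeg as sd

cm, truth = sd.simulate_experiment(sd.SimConfig(seed=7))
result = sd.run_pipeline(cm)
s = result.summary
```

With the default generator (2000 genes, 6 conditions × 5 replicates,
planted |log₂FC| = 2 programs) this prints, via `examples/03_responder_sets.py`:

```
sustained DEGs:
  LPS : 101 up / 87 down
  IL-4: 75 up / 62 down
responder sets (specific counts include opposite responders):
  LPS-specific : 78 up / 66 down
  IL-4-specific: 52 up / 41 down
  common       : 23 up / 21 down
  opposite     : 33 (17 LPSup/IL4down + 16 IL4up/LPSdown)
  ambiguous    : 5
```

101 LPS-sustained-up genes split into 78 LPS-specific and 23 common; the
opposite responders are counted inside the specific sets, and the 5
ambiguous genes (sustained under one stimulus, direction-flipping under the
other) are excluded from both the common and the specific sets. The
`examples/` directory holds one short script per capability (simulation,
DE, responder sets, ORA, concordance), each printing the numbers it
computes and what they mean.

A thin CLI wraps the same pipeline:

```sh
sustaindeg simulate --seed 7 --out fixture/
sustaindeg run --counts fixture/counts.tsv --samples fixture/samples.tsv --out results/
sustaindeg compare --deg-a mine.tsv --deg-b external.tsv --out cmp/
```

## Layout

- `src/sustaindeg/` — `simulate` (synthetic counts + truth), `de` (NB Wald
  engine), `classify` (sustained selection and responder algebra), `ora`,
  `concordance`, `io`, `pipeline`, `cli`, `fixtures` (synthetic stand-ins
  built from published summary counts).
- `docs/methods.md` — models, defaults, numerical choices, limitations.
- `examples/` — narrative scripts, one per capability.
- `tests/` — unit, property-based and acceptance tests.
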