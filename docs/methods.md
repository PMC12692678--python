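# Methods

## The statistic

For one miRNA, each expression experiment contributes a signed log fold
change; the sign is the direction call (negative = underexpressed, zero
excluded by default or split half/half under the `half` policy). Over
`n = n_down + n_up` counted records the membership ratio is

    div = (n_down − n_up) / n,

the maximum-likelihood estimate of `2·p_down − 1` under a per-miRNA Bernoulli
direction model. Its standard error shrinks as `n^{-1/2}`, which motivates
the separation-curve family used for the critical call:

    critical  ⇔  n ≥ n_min  and  |div| ≥ min(1, a / n^b).

With `b = 0.5` the curve follows the binomial noise envelope: a constant-`a`
curve keeps an approximately constant false-call rate for unbiased miRNAs as
`n` varies. Defaults: level I `(a=8, b=0.5, n_min=10)`, II `(4, 0.5, 5)`,
III `(2, 0.5, 3)`. Nestedness (each stricter curve pointwise above the next,
with a larger `n_min`) is validated at configuration load, which guarantees
critical-set inclusion I ⊆ II ⊆ III. Ties on the curve count as critical.
Level III is the default working tier.

The same ratio is applied one level up: a gene's `gene_div` is computed over
its critical regulators (under + over) by default, since neutral regulators
carry no directional information; a config switch divides by all regulators
instead. Duplicate interaction rows (multiple evidence lines for the same
miRNA–gene pair) collapse to a single regulator. Genes with fewer than 20
distinct regulators are excluded before integration — with few regulators
`gene_div` is dominated by ±1 extremes that reflect sampling, not biology
(dropping this filter makes the downstream gene selection fill up with
single-regulator genes, which is exactly the failure the cutoff prevents).

## Integration and selection

Gene mean logFC is the unweighted arithmetic mean across cancer types (no
weighting information is available, and per-cancer sample sizes are not part
of the inputs). Quadrants over (mean logFC, gene_div) are Q1 (+,+), Q2
(−,+), Q3 (−,−), Q4 (+,−); a zero on either axis is non-concordant and falls
into the lowest-numbered compatible quadrant. Concordant genes (Q1/Q3) match
the de-repression expectation: regulators predominantly depleted ⇒ gene up.

"Combined magnitude" for critical-gene selection is deliberately
unit-free: the default score is the sum of the rank-normalised |mean logFC|
and |gene_div| (a raw sum would mix a log-ratio with a bounded ratio;
rank-sum is invariant to monotone rescaling of either axis). A raw
`product` and a `z_sum` rule are selectable. Ties break lexicographically by
gene id, making the selection order-invariant and reproducible. The top-200
cutoff, the ≥20-regulator filter and the ≥10-critical-genes re-selection
cutoff are configuration defaults, not hard-coded.

## Complementarity scoring

The similarity coefficient between two mature sequences is the maximal
global-alignment score under match 1 / mismatch 0 / gap −0.5 (linear gap),
divided by the longer sequence length — 1.0 for identical sequences, with
mean ≈ 0.37 ± 0.07 for unrelated random 20–24-nt RNA. Alignment is
`Bio.Align.PairwiseAligner` in global mode; the unit tests verify it against
an independent recursive implementation of the recurrence on small
alphabets, itself checked against exhaustive enumeration of all alignments.
Normalisation by mean length or by alignment columns is available; the
length-based normalisations keep the score symmetric. Scores are clamped to
[0, 1] (the raw optimum can be slightly negative for very unequal lengths).
"Complementarity" is computed as sequence similarity (substitution
semantics); a reverse-complement mode exists for base-pairing semantics and
is off by default. FASTA ingest uppercases, maps T→U and rejects IUPAC
ambiguity codes with a named error.

Per plant miRNA, `AvgComp` against a human set is the arithmetic mean over
the set's `N` members, and `diff = AvgComp_under − AvgComp_over`; ranking is
by |diff| descending with ties by plant id.

## Synthetic study conditions

The generator is the package's test surface; its defaults are fixed study
conditions, not tuning knobs.

- **Expression compendium**: 400 miRNAs × 20,000 records. Per-miRNA counts
  are `1 + multinomial` with Pareto-like weights `u^{−d}` (`d = 1`), giving
  the observed many-miRNAs-few-experiments shape with a guaranteed minimum
  of one. Direction biases come from the mixture 35% `p_down = 0.9`, 35%
  `p_down = 0.1`, 30% `p_down = 0.5` — roughly 70% stably directional with
  near-equal down/up totals, matching the reported qualitative structure of
  such compendia. logFC magnitude is lognormal(0, 1) (the magnitude
  distribution is not otherwise constrained); the sign carries direction.
- **Interactions**: gene in-degree follows a discrete power law (exponent
  1.1, truncated to [1, n_mirnas]); regulators are sampled without
  replacement with Pareto-like miRNA popularity weights (exponent 1.5),
  producing the heavy-tailed miRNA out-degrees of curated catalogues.
- **Gene expression**: gene latent mean
  `c · div_true · effect_scale + (1−c) · ε`, `ε ~ N(0, 1)`, per-cancer noise
  N(0, 0.5) across 12 cancer types; `div_true` is the membership ratio of
  the gene's regulators' planted biases and `c = 0.8` by default. Positive
  coupling encodes de-repression (down regulators ⇒ gene up), so planted
  structure surfaces as Q1/Q3 concordance.
- **Sequences**: 200 plant and 400 human random RNA sequences of 20–24 nt;
  the human ids are the compendium's miRNA ids so the complementarity stage
  can use the pipeline's own reselected sets. Ten plant sequences are
  near-copies (0–3 substitutions at distinct positions) of down-biased human
  miRNAs.
- **Seeding**: one integer seed fans out via `SeedSequence.spawn` into an
  independent substream per generator; all outputs are byte-reproducible.

What the generator does *not* emulate: real cancer-type effects (labels are
exchangeable), experiment-type effects (opaque column), correlated
miRNA–miRNA co-regulation, sequence composition biases or conservation
structure, and the 10–40× larger scale of the real resources. Passing tests
therefore demonstrate correct recovery of planted structure under the stated
noise model — not performance on real databases.

## Problem sizes in tests

The planted-pair detection test uses human under/over sets of two sequences
each. This mirrors the down-scaling of the plant library (200 synthetic vs
~10,900 real plant sequences, about 1/54, applied to the ~115/93 human
sets): averaging over a set dilutes a single planted similarity by `1/N`,
so detectability at 200 plant sequences requires proportionally small human
sets. The selection-oracle and concordance tests run at 300–500 genes and
200–300 miRNAs, where brute-force recounts are instant. The acceptance
script runs the full default conditions (400 miRNAs, 800 genes, 20,000
records) in a few seconds.

## Numerical choices and degenerate inputs

- Quantiles use linear interpolation; whiskers sit at the most extreme
  observations within 1.5·IQR of the quartiles (clamped to the data range).
- Zero logFC: excluded by default (`half` splits it 0.5/0.5); a miRNA whose
  records are all excluded yields no profile.
- `gene_div` is 0 for genes with no critical regulator; mean logFC drops
  genes with no finite value, with a warning.
- Empty tabular inputs produce empty outputs, not errors; unknown
  identifiers (a summary request for an unprofiled miRNA, an interaction
  referencing an unlabelled miRNA) raise errors naming the offender.
- Multiple optimal alignments are irrelevant: the score, not the alignment
  path, is consumed.

## Known limitations

- The separation-curve family and the combined-magnitude score rule are
  principled defaults for an under-specified step; both are
  config-exposed so alternatives can be swapped in without touching the
  stages around them.
- At the default synthetic density the re-selection step retains every
  critical miRNA (each targets ≥10 of the 200 critical genes); the pruning
  behaviour of that step is exercised separately in sparser test instances.
- Direction is derived from the logFC sign; compendia that pre-label
  direction independently of sign are not modelled.
- No meta-analytic pooling, p-values, or multiple-testing correction: the
  method is deliberately count-based.
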