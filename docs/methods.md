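# Methods

## Problem and model

The package analyses inducible-knockdown quantitative proteomics of an
organellar protein-import machinery. When an essential translocase subunit
is depleted by RNAi, proteins that depend on it for import fail to
accumulate in the organelle; comparing induced (+Tet) against uninduced
(−Tet) cultures by stable-isotope labelling (SILAC or dimethyl) yields a
per-protein heavy/light ratio per biological replicate. Proteins whose
oriented log2 (+Tet/−Tet) ratio is significantly negative in the organellar
fraction constitute the *importome* of that machinery.

The statistical model is deliberately minimal: each protein has one true
log2 effect (negative for import substrates, zero otherwise) observed
through independent, approximately normal per-replicate noise. No
replicate-by-protein interaction, ratio compression or intensity-dependent
variance is modelled.

## Ratio orientation

Search engines report heavy/light ratios; the replicate design records
which channel received the inducer in each replicate (label switches).
At read time, `log2(H/L)` is taken as-is when the induced sample was heavy
and negated when it was light, so all downstream statistics work on a
common +Tet/−Tet direction. Raw ratios must be strictly positive; zero or
negative values are rejected as table corruption rather than coerced.
A missing cell means "not quantified", never "ratio 1"; nothing is imputed.

## Identification and quantification filter

A protein is considered reliably quantified when it was identified with at
least `min_peptides` peptides (default 2), at least one of them unique, and
quantified in at least `min_quantified_replicates` biological replicates
(default 2). For gradient-purified organelle datasets an optional rescue
clause additionally admits proteins identified by a single unique peptide
when they were quantified in *all* replicates and the identification rests
on fragment (MS/MS) spectra — not match-between-runs transfer — in at least
two replicates. Failing proteins are retained with a flag so every input
row is accounted for in exports.

## Per-protein statistics

The summary per protein is the mean of the non-missing oriented log2 ratios
and the p-value of a two-sided one-sample Student t-test of those ratios
against zero (df = n−1). Only ratios are available, so a paired or
two-sample reading of the test is not possible. Degenerate zero-variance
samples use the limit of the t statistic: p = 1 when the mean is also zero,
p = 0 otherwise; this keeps quantized toy data computable. Two quantified
replicates (df = 1) are allowed because the default filter admits them.
No multiple-testing correction is applied to these per-protein p-values;
the α = 0.05 gate is used as-is for classification, and FDR control lives
only in the enrichment module.

## Threshold derivation (dual-reference F1 scan)

Two disjoint reference proteomes anchor the threshold: an organellar set
expected to be depleted and a non-organellar set expected unaffected. For
candidate thresholds θ on a 0.01-wide log2 grid, proteins of the two sets
with mean ratio ≤ θ are "called depleted"; precision TP/(TP+FP),
sensitivity TP/(TP+FN) and their harmonic mean F1 are computed per grid
point. Proteins outside both sets never enter the confusion counts — they
are the unlabeled pool being classified.

The organellar-reference curve yields t2 (its argmax-F1 grid value); the
mirrored curve for the non-organellar reference — where "called" means mean
ratio > θ — yields t1. The adopted significance threshold is min(t1, t2),
the more stringent cut. Numerical choices:

* grid values are carried as integer hundredths so the 0.01 increments are
  exact decimals; comparisons of computed means against grid values use a
  1e−9 absolute slack to absorb binary-float drift;
* ties at the maximal F1 are broken toward the most negative grid value,
  the conservative choice for importome calling;
* the default scan starts at the lowest ratio at which at least one TP and
  one FP exist (for the mirrored curve this condition is satisfied from the
  lowest observed ratio on, so that curve spans the full observed range);
  a `start_rule="full"` option evaluates the whole range instead, which
  matters only when a perfectly separating threshold exists below the
  first false positive;
* a `candidates="observed"` option scans the observed mean ratios instead
  of the regular grid.

## Importome calling

A filter-passing protein is *imported* when mean log2 ≤ threshold (gate
inclusive) and p < α (gate strict), *unaffected* otherwise, and
*unquantifiable* when the statistics are undefined or the filter failed.
Every classifiable protein is exactly one of imported/unaffected. The
fixed-fold mode replaces the derived threshold with a symmetric log2(fold)
cut (1.5-fold for whole-cell experiments, 2-fold for disulfide-relay
knockdowns) and reports a direction (down/up/none). New candidates are
imported proteins absent from the positive reference set; imported members
of the *negative* reference set are flagged with their membership but kept
in the importome rather than removed.

## Twin-CxnC motif scan

Classical disulfide-relay (MIA) substrates are small intermembrane-space
proteins carrying twin C-x(3)-C or C-x(9)-C motifs (x = any residue except
cysteine). The scanner is greedy, left-to-right and non-overlapping: after
a hit it resumes after the closing cysteine, so one cysteine never serves
two motifs and runs of clustered cysteines are not inflated into twins.
A protein is predicted as a substrate when its average molecular mass is
strictly below 50 kDa and it carries at least two motifs *of the same type*
(the classical twin arrangement); a `count_mode="total"` switch counts
across types instead, since either reading of "two or more Cx3C or Cx9C
motifs" is defensible. Average mass is the sum of Expasy average residue
masses plus one water (18.0153 Da); X counts as the mean standard residue,
and sequences with more than 10% X are flagged.

## Enrichment statistics

Overrepresentation of a property inside a hit set is tested with the
two-sided Fisher exact test against the background of all quantified,
filter-passing proteins of the same experiment — never the whole genome.
Families of term tests are corrected by Benjamini–Hochberg step-up;
terms with no hit-set member are not tested (they cannot be enriched and
would only dilute the family); their count is logged. Term hierarchies are
collapsed onto a slim vocabulary by transitive ancestor closure before
testing. Each term is tested independently (classic per-term Fisher);
no elim/weight-style decorrelation of nested terms is performed, so
p-values of related terms are correlated. The reported odds ratio is the
unconditional cross-product ratio, infinite when a zero cell makes it so;
it is for interpretation only.

## Synthetic data generator

`simulate_quant_dataset` emulates the knockdown experiment under the model
above. The default scenario is 800 organellar + 800 other proteins, four
replicates with the last one label-switched, true organellar effects
~ Normal(−1.5, 0.5²) log2 units, replicate noise SD 0.4, 5% missing
ratios, and reference sets covering 60% of each class (the uncovered
remainder plays the role of the unannotated pool). Peptide counts follow
1 + NegBin(r = 1.2, p = 0.25) — heavy-tailed, with roughly a fifth of
proteins at a single peptide so the rescue clause is genuinely exercised —
and quantified replicates carry MS/MS evidence with probability 0.85
(match-between-runs otherwise). Raw H/L columns are emitted with the label
switch applied in reverse, so reading the table back through the oriented
reader is an exact round trip.

What the generator does *not* emulate: intensity-dependent variance,
ratio compression, correlated replicates, contaminant co-purification
gradients, and mis-annotated reference entries. Passing tests on this
generator therefore demonstrate the correctness and calibration of the
algorithms under the stated model, not robustness to every pathology of
real MS data.

`simulate_proteome_sequences` plants 2–3 disjoint same-type twin motifs
into cysteine-free random backbones for substrate proteins (mass kept
below 50 kDa) and at most one motif — or a deliberately mis-spaced
C-x(5)-C pair — into non-substrates. Inter-motif gaps of exactly 3 or 9
residues are avoided because the closing cysteine of one motif and the
opening cysteine of the next would otherwise form an accidental cross
motif of the other type; with that exclusion the greedy scanner provably
recovers exactly the planted coordinates.

`analytic_import_call_probability` gives the closed-form-up-to-quadrature
probability that a protein of the model is called imported at a given
threshold: the sample mean is normal, the sample SD is an independent
scaled chi distribution, and the t-test gate translates into an SD bound
given the mean; the product integrates numerically over the mean. The
validation suite compares empirical sensitivity/specificity among
classifiable proteins against this expectation (mixed over the observed
per-protein replicate counts) minus three binomial standard errors.

## Problem sizes used in validation

The validation suite runs at desk scale by design: 100 random datasets of
up to 200 labelled proteins for scan-vs-brute-force equivalence, every 2×2
table with margins ≤ 12 for the Fisher oracle, 10,000 null proteins for
t-test calibration, 100 seeded runs of the 1,600-protein default scenario
for threshold recovery, and 1,000 random plus 300 planted-motif sequences
for the scanner. These sizes give stable statistics while keeping the
whole suite in the low minutes.

## Known limitations

* Reference-set quality is taken on faith; mis-annotated members bias the
  F1 curves in ways the synthetic scenario does not probe.
* The one-sample t-test assumes approximately normal log2 ratios; with
  n = 2 replicates the test is valid but very weak (df = 1).
* The F1 grid resolution (0.01) bounds how finely the threshold can be
  placed; the observed-candidates mode removes this bound but no longer
  matches the grid convention.
* No variance moderation or imputation is offered by design; datasets with
  many near-empty ratio vectors will lose those proteins at the filter.
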