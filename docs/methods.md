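# Methods

This note documents the models and procedures `gofeat` implements, the
defaults that matter, what the synthetic data does and does not emulate,
and the design decisions taken where the design was genuinely open.

## Ontology handling

The GO is represented as a DAG over non-obsolete terms restricted to
`is_a` edges; `part_of` and other relations are ignored, so "annotation
implies ancestor annotation" always means is_a ancestry here. Each of the
three domain roots (molecular_function, biological_process,
cellular_component) is a parentless node. Obsolete stanzas are flagged and
excluded from the DAG; `alt_id`s map silently (debug-logged) to canonical
ids. Parsing is delegated to `obonet`, cycle detection to `networkx`.

Two propagation closures exist on purpose:

- `propagate()` returns the ancestor closure **minus the roots** — the form
  used to build predicted and reference sets for evaluation;
- `AnnotationTable.propagate(include_roots=True)` keeps the roots — the
  form used for annotation counting, so that N({root}) equals the number
  of proteins annotated in that domain and the information content of a
  root's direct child reduces to −log₂(N({child})/N(∅)).

Information content follows the conditional (Bayesian) estimator
IC(t) = −log N({t} ∪ P(t)) / N(P(t)) with P(t) the direct is_a parents and
N(S) the number of proteins annotated with every term in S. The logarithm
base defaults to 2 (bits) and is configurable; along a chain the IC
telescopes to −log₂ of the leaf's annotation frequency, which the tests
exploit as an exact oracle.

## Feature encoding

A sequence maps to 258 scalars in 14 named groups: amino-acid composition
(20), residue-class dipeptide composition (49, 7 conjoint-triad classes),
global physicochemical summaries (9, via Biopython's `ProteinAnalysis`),
predicted secondary structure (8, windowed Chou–Fasman propensities),
transmembrane helices (5, Kyte–Doolittle windows of 21 at threshold 1.6),
intrinsic disorder (6, TOP-IDP windows of 15 at threshold 0), signal
peptide (3, N-terminal charge + hydrophobic-core heuristic),
low-complexity (3, Shannon entropy in windows of 12 below 2.2 bits),
N-glycosylation motifs (2), phosphorylation motifs (4), coiled-coil heptad
periodicity (3), Eisenberg hydrophobic moments at 100°/160° (4), charge
patterning (6), and Moreau–Broto autocorrelation of 8 standardized residue
property scales at lags 1–17 (136).

All extractors are deterministic, alignment-free propensity-scale
approximations of the structure-prediction tools usually used for this
encoding; they reproduce the *kind* of signal (windowed hydropathy,
disorder propensity, motif counts), not the numerics of any specific
external predictor. `register_external_group` swaps any group for a lookup
table of externally computed values when fidelity matters. Window lengths
and thresholds are module constants with the defaults above.

Composition-type groups sum to 1 (±1e-9); every value must be finite.
Sequences must use the 20 standard residues and be at least 15 residues
long — the same lower bound the isoform filters use.

## Per-term classifier training

For a candidate term, positives are the proteins annotated with it after
propagation; negatives are proteins annotated in the same GO domain but
with neither the term nor any descendant. Terms with fewer than `min_pos`
(default 50) positives are rejected. The labelled set splits 70/30
(stratified) into training and validation.

The fold count k is the largest of {5, 4, 3} leaving at least
`min_fold_size` (default 10) positives per stratified fold; folds are
equally sized within one instance. Model selection runs backward
elimination over feature *groups*: the full group set is scored first (best
mean cross-validated MCC over the hyperparameter grid), then each group's
removal is scored with a fresh grid search, and the best removal is
committed **only when it strictly improves** the mean CV MCC, iterating to
convergence or a single remaining group. Requiring strict improvement
keeps redundant-but-informative groups (correlated feature families are
the norm in this encoding) and guarantees the selected set never scores
below the full set.

The default grid is C ∈ {1, 10, 100} with the data-dependent "scale"
kernel width; the kernel is RBF; class imbalance is handled with error
weights inversely proportional to class frequency. Features are scaled to
[−1, 1] per column using training-fold statistics (constant columns map to
0; out-of-range values at prediction time are clipped at ±3).

The winning configuration is refit on the full training split and scored
once on the held-out 30%: classifiers with validation MCC ≥ 0.05 are
retained. Retained classifiers are refit on all labelled data and
calibrated with a Platt sigmoid fitted to *cross-validated* decision
values (3-fold), so the sigmoid never sees in-sample scores; the
calibration was deliberately not fit on validation decision values so the
validation MCC stays an untouched selection statistic. Posteriors are
reported rounded to 3 decimals. A single-class fold triggers one reshuffle
with an incremented seed, then rejection. Everything — split, folds,
reshuffles, tie sampling — derives from one integer seed, making training
bit-reproducible.

Models are stored as explicit RBF expansions (support vectors, dual
coefficients, intercept, kernel width) in per-term JSON files plus a
manifest, so a stored library is independent of the fitting library's
serialization format.

## Baselines

*Naive*: raw annotations are filtered to the evidence codes
{EXP, IDA, IPI, IMP, IGI, IEP, IC, TAS}, "protein binding" (GO:0005515)
is dropped, counts are propagated, and each domain's counts are divided by
its root count and rounded to 3 decimals; every query receives the whole
table. Scores are therefore anti-monotone along is_a paths with the root
at 1.000.

*BLAST transfer*: hits are kept when their E-value falls in
(`evalue_min`, `evalue_max`]; the default window (E-value **above** 10⁻³,
no upper bound) deliberately restricts transfers to remote homologs —
the regime in which feature-based prediction is meant to compete. Both
bounds are exposed so the conventional strong-hit direction is equally
available. Transferred scores are percent identity / 100, maximum per
(query, term), rounded to 3 decimals, invariant to hit order.

## Evaluation

Benchmarks keep annotations with evidence codes
{EXP, IDA, IMP, IGI, IEP, TAS, IC} (note: no IPI, unlike the baselines'
code set), drop GO:0005515, propagate, strip roots and split by domain.
At threshold v, the predicted set is the propagated closure of terms
scoring ≥ v; precision is averaged over the n proteins with at least one
prediction ≥ v, recall over all m benchmark proteins, and F(v) is their
harmonic mean; Fmax is the maximum over the grid. The default threshold
grid is the union of all distinct prediction scores with the 0.01-spaced
lattice — predictions are 3-decimal scores, so the union loses nothing
that a finer fixed lattice would see.

Top-*l* evaluation trims each protein's ranked list to
l ∈ {1, 2, 3, 4, 5, n} (n = the protein's reference annotation count).
Rank ties at the cutoff are resolved by uniform sampling without
replacement, 1,000 replicates by default; per-protein statistics
(precision, recall, F, summed true-positive IC) are averaged over
replicates, then over proteins. Proteins without ties at the cutoff are
evaluated in a single deterministic pass — the replicate average is exact
there. A report is emitted only when at least 25 proteins have ≥ l
predictions and ≥ l reference annotations (configurable; the floor applies
to top-l reports only, not to PR curves).

## Splicing statistics

Isoforms are retained when the sequence is known, 15–1500 residues long,
uses standard residues only, and is not recorded in a separate database
entry; losing a main isoform removes its alternatives (the cascade rule).
The filters commute — the retained dataset is order-independent.

Predicted posteriors become calls at `call_threshold` (default 0.5 — a
posterior is treated as a call exactly when the function is more likely
than not), screened against the is_a closure of the entry-level curated
annotations, so an isoform can only carry terms its gene is curated (or
implied) to have.

For a term G: *conservation* is the fraction of covered entries (≥ 1
isoform carrying G) where every isoform carries G, reported only at ≥ 20
covered entries; *primarity* is δ_G = m_G/n − a_G/(m−n) with m_G/a_G the
main/alternative isoform counts carrying G, n the entry count and m the
isoform total — +1, 0, −1 at the main-only, uniform, and alternative-only
extremes, and invariant under entry duplication. *Feature enrichment* maps
the median feature value of annotated isoforms to its lowest percentile p̂
within the classifier's positive-training distribution and reports
E = (p̂ − 50)/50 ∈ [−1, 1], exactly 0 at equal medians (the equal-median
case is special-cased so finite-sample percentile granularity cannot
produce a spurious sign). A constant training distribution with unequal
medians degenerates to ±1 and is debug-logged. Feature–score association
is the Pearson correlation between feature values and posteriors, missing
("grey cell") below 3 pairs or at zero variance; group-level summaries
take the median across a group's scalars.

The δ_G and E_{g,f} functional forms above are the unique simple forms
satisfying all their stated sign/zero/extreme cases; they are adopted as
the package's definitions.

## Synthetic data

The generators emulate the *shape* of real inputs — OBO documents with one
root per domain, GAFs with mixed evidence codes (including IEA, so both
evidence filters have work to do), FASTA proteomes, blast-outfmt6-style
hit tables, isoform catalogues with a flagged canonical variant — plus a
truth manifest for every decision.

Planted rules tie a GO term to a biophysical predicate. The disorder rule
samples positives with 55–85% of residues from a disorder-promoting pool
(P, E, S, Q, K) and negatives with 5–35%, verifies the predicate (disorder
fraction > 0.4) through the real feature extractor with bounded
resampling, and flips labels at the rule's noise rate (default 0.1). A
complement term can be attached to the predicate-negatives so every
protein stays annotated in the domain — giving the term a clean negative
set and the Naive baseline a meaningful prevalence table. Sequence lengths
are uniform on [50, 600], inside the [15, 1500] retention window.

What passing tests on this data shows: the training protocol finds a real
feature–function signal at realistic noise, the retention rule rejects
chance, and the evaluation machinery orders methods sensibly. What it does
not show: performance on real proteomes, where feature–function
relationships are weaker, many terms overlap, and the built-in feature
approximations diverge from dedicated structure predictors.

## Experiment sizes and the retention control

The planted-rule experiment trains on 200 proteins and evaluates on an
independent 120-protein benchmark — large enough for a stable validation
MCC and Fmax gap, small enough that the full pipeline (feature extraction,
two per-term classifiers with backward elimination over all 14 groups,
three-way evaluation) completes in well under a minute.

The permuted-label control needs more care: with labels assigned at
random, the validation MCC is approximately normal with standard deviation
≈ 1/√n_val, so the probability of chance retention (MCC ≥ 0.05) is driven
entirely by the validation-set size. At 200 proteins (60 validation),
chance retention occurs in roughly a third of runs — the control would say
nothing. The control therefore uses 4,500 random-composition sequences
(1,350 validation, null SD ≈ 0.027, chance-retention probability ≈ 3%),
restricted to the disorder group and a single grid point; neither
restriction touches the retention decision under test, they only keep the
control affordable. This sizing was fixed by the power analysis above, not
by inspecting outcomes.

## Known limitations

- Feature extractors are propensity-scale approximations; absolute values
  are not comparable with PSIPRED/DISOPRED/TMHMM outputs (use
  `register_external_group` to substitute real predictor outputs).
- The default feature registry fixes one reasonable realization of the
  14-group/258-scalar contract; classifiers depend only on the registry
  contract, not this particular list.
- Backward elimination is greedy; it does not explore group subsets beyond
  single removals per step.
- Term-centric (per-GO-term ROC) evaluation and semantic-similarity
  metrics beyond the IC weighting are out of scope, as is statistical
  significance testing of conservation differences.
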