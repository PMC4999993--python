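# gofeat

Homology-free Gene Ontology (GO) term prediction for protein sequences,
with the baseline predictors, the protein-centric evaluation machinery, and
the splice-isoform divergence statistics that go with it.

## The problem

When a protein has no detectable homology to characterized sequences,
annotation transfer breaks down. Function can still be predicted from the
sequence's *biophysical* attributes — amino-acid composition, secondary
structure, transmembrane helices, intrinsically disordered regions, signal
peptides, short functional motifs — under the assumption that proteins with
similar functions share similar biophysical profiles even without sequence
similarity. `gofeat` implements this approach end to end for researchers
who want to study, benchmark or extend feature-based function prediction:

- **features** — each sequence is encoded as 258 scalars in 14 named
  feature groups (fast propensity-scale approximations, with a pluggable
  interface for external predictor outputs);
- **term_svm** — one binary RBF-kernel SVM per GO term, trained with
  backward elimination over feature groups, k-fold cross-validated grid
  search (k ∈ {3,4,5}) maximizing the Matthews correlation coefficient
  (MCC), a 70/30 train/validation split, retention of classifiers with
  validation MCC ≥ 0.05, and Platt-scaled posteriors rounded to 3 decimals;
- **ontology** — OBO parsing, `is_a` propagation, annotation counting
  N(·), and term information content
  IC(t) = −log₂ N({t} ∪ P(t)) / N(P(t)) with P(t) the parent set;
- **baselines** — a Naive predictor scoring terms by annotation prevalence,
  and a BLAST-style transfer scoring terms by percent identity / 100 from
  remote hits (E-value > 10⁻³ by default);
- **evaluation** — protein-centric precision/recall averaged as in the
  CAFA protocol, Fmax, and top-*l* trimmed lists with 1,000-replicate
  random tie resolution and information-content weighting of true
  positives;
- **splicing** — per-term conservation across splice isoforms, *primarity*
  δ_G = m_G/n − a_G/(m−n), feature enrichment E_{g,f} = (p̂ − 50)/50, and
  feature–score Pearson correlations;
- **fixtures** — synthetic ontologies, proteomes with planted
  feature→function rules, hit tables and isoform catalogues, so the whole
  pipeline runs and is tested fully offline.

## Worked example

Train classifiers on a synthetic proteome in which a planted rule ties a GO
term to intrinsic disorder (disorder fraction > 0.4, labels flipped at a
10% noise rate), then benchmark the library against the Naive baseline on
an independently generated held-out set:

```python
from gofeat.workflows import planted_rule_experiment

exp = planted_rule_experiment(seed=1)
print(f"validation MCC       {exp.validation_mcc:.3f}")
print(f"disorder group kept  {'disorder' in exp.selected_groups}")
print(f"Fmax (SVM library)   {exp.fmax_svm:.3f}")
print(f"Fmax (Naive)         {exp.fmax_naive:.3f}")
```

```
validation MCC       0.868
disorder group kept  True
Fmax (SVM library)   0.919
Fmax (Naive)         0.659
```

The classifier recovers the planted signal well above the 0.05 retention
floor, backward elimination keeps the disorder group, and the trained
library clearly outranks the frequency baseline under the protein-centric
Fmax — the qualitative behaviour expected from a feature-based predictor
when homology is unavailable.

The same steps are available from the shell:

```bash
gofeat fixtures --out data --n-proteins 200 --seed 1
gofeat train    --annotations data/annotations.gaf \
                --sequences data/proteome.fasta \
                --obo data/ontology.obo --out models --seed 1
gofeat predict  --models models --sequences data/proteome.fasta --out preds.tsv
gofeat evaluate --predictions preds.tsv --annotations data/annotations.gaf \
                --obo data/ontology.obo --domain MF --out metrics.tsv
```

plus `naive`, `blast-transfer` and `splicing` subcommands for the baselines
and the isoform survey.

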