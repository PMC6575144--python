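# ltcnlp

Identify deaths associated with residential long-term care (LTC) from
free-text death-investigation narratives. The package implements a full,
testable surveillance pipeline:

1. **`synthetic_data`** — generate NVDRS-like corpora with known ground
   truth (narrative phrase banks, calibrated covariate marginals, location
   code error structure) plus simulated annotators with a tunable error
   rate; real narrative corpora of this kind are restricted-access.
2. **`corpus_io`** — JSONL/CSV record I/O, analytic-sample exclusions
   (age ≥ 55, eligible manner of death, nonempty narrative) and recodes.
3. **`seed_annotate`** — keyword candidate discovery, random sampling for
   annotation, and labeled-set management with majority-vote adjudication.
4. **`nlp_classifier`** — unigram+bigram tf-idf featurization and a
   1500-tree balanced random forest; classification at a strict > 0.50
   threshold; stratified cross-validation.
5. **`active_loop`** — iterative retraining with decile-stratified sampling
   of ambiguous cases (probability band 0.10–0.90, batches of 41).
6. **`categorize`** — four-way categorization of classifier positives
   (in LTC / transitioning / otherwise associated / not associated) and
   stage-accounted final label assembly.
7. **`agreement`** — contingency tables, Cohen's κ with the
   Fleiss–Cohen–Everitt standard error, sensitivity/specificity with exact
   binomial CIs, for validating structured location codes.
8. **`characterize`** — decedent characterization tables with
   Kruskal–Wallis / Pearson χ² group tests and small-cell suppression.
9. **`trend`** — annual counts restricted to early-reporting states and a
   hand-rolled IRLS Poisson trend regression with Wald inference.

## CLI

The `ltcnlp` entry point chains the whole pipeline on synthetic data:

```bash
ltcnlp simulate --n-records 20000 --out sim --seed 17
ltcnlp prepare --corpus sim/corpus.jsonl --out prep
ltcnlp seed --analytic prep/analytic.jsonl --truth sim/truth.csv \
    --out seeded --n 367 --seed 17
ltcnlp train --analytic prep/analytic.jsonl --labels seeded/labeled.csv \
    --out trained --trees 500 --seed 17
ltcnlp iterate --analytic prep/analytic.jsonl --labels seeded/labeled.csv \
    --truth sim/truth.csv --out looped --rounds 1 --batch 41 --trees 500 --seed 17
ltcnlp categorize --probs looped/probs.csv --labels looped/labeled.csv \
    --truth sim/truth.csv --out cat
ltcnlp agree --analytic prep/analytic.jsonl --final cat/final_labels.csv --out agree
ltcnlp characterize --analytic prep/analytic.jsonl --final cat/final_labels.csv --out char
ltcnlp trend --analytic prep/analytic.jsonl --final cat/final_labels.csv \
    --states sim/states.csv --out trend
```

`simulate` accepts a YAML config overriding any generator field (record
count, category prevalence, narrative length moments, code error rates,
blank-narrative fraction, states/years).

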