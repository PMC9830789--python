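# clinneg

Negation detection for annotated medical terms in clinical free text.

Clinical notes constantly mention findings in order to rule them out
("no signs of infection"). Given documents with standoff entity annotations
(character spans of medical terms), this toolkit decides per entity whether
it is *negated* or *not negated*, using three method families plus an
ensemble, and ships the evaluation and error-analysis harness to compare
them — together with a synthetic corpus generator so everything is testable
without access to restricted clinical data.

## What's inside

| Module | Purpose |
| --- | --- |
| `clinneg.corpus` | Document/entity/prediction types, jsonl + brat standoff I/O, record-exclusion filters |
| `clinneg.rules` | ConText-style rule engine: trigger lexicons (forward/backward/pseudo/termination), sentence- or word-count-bounded scopes |
| `clinneg.subword` | Byte-pair-encoding subword tokenizer (from scratch, deterministic) |
| `clinneg.embeddings` | CBOW embedding pretraining (numpy) |
| `clinneg.recurrent` | Bidirectional LSTM + fully-connected head, hand-derived backprop (numpy, no deep-learning framework) |
| `clinneg.neural` | Entity-placeholder abstraction, 15-left/10-right token windows, training/prediction, model persistence |
| `clinneg.transformer` | Entity-centered token windows under a 512-token limit, subword→word score aggregation, pluggable external scorer interface |
| `clinneg.evaluation` | Shared k-fold assignment, majority-voting ensemble, per-category precision/recall/F1, error-set intersections, error taxonomy, Cohen's kappa |
| `clinneg.synthetic` | Labeled synthetic clinical-like corpora with ground-truth traces and controllable noise (minus shorthand, missing whitespace, punctuation) |

The packaged Dutch trigger lexicon (`clinneg/lexicons/dutch_default.tsv`)
is illustrative, not a reproduction of any published rule set.

## CLI

```bash
# generate a labeled synthetic corpus + ground-truth traces
clinneg generate-synthetic --out corpus.jsonl --traces traces.jsonl --n-docs 400 --seed 1

# rule-based annotation (packaged lexicon by default)
clinneg annotate --input corpus.jsonl --output rule.jsonl

# train and apply the recurrent classifier
clinneg train-bilstm --input corpus.jsonl --model-dir model/ --seed 1
clinneg predict --model model/ --input corpus.jsonl --output bilstm.jsonl

# majority vote over exactly three prediction files
clinneg ensemble --inputs rule.jsonl --inputs bilstm.jsonl --inputs other.jsonl \
    --output ensemble.jsonl

# metrics (per record category + overall) and error tables
clinneg evaluate --gold corpus.jsonl --pred rule.jsonl --output metrics.csv
clinneg error-report --gold corpus.jsonl --pred rule.jsonl --output errors.csv
```

Corpus files are one JSON object per line (`doc_id`, `category`, `text`,
`entities` with 0-based half-open character spans); predictions share a
jsonl schema (`doc_id`, `entity_index`, `label`, optional `probability`,
`method`). A brat-style dialect (`.txt` + `.ann`) is supported via
`load_corpus(path, format="brat")`.

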