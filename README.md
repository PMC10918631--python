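# entnorm

Fast, dictionary-based normalization of biomedical entity names — drug
names against ChEMBL-style synonym tables, cancer types against Disease
Ontology subtrees — using a short-circuiting cascade of matchers of
increasing cost:

1. **exact** — hash lookup of the canonicalized name (lowercase,
   alphanumeric tokens, single spaces);
2. **token** — equality of lexicographically sorted tokens, making the
   match order-invariant;
3. **ngram** — word-n-gram containment in either direction (default
   bigrams), catching names embedded in longer phrases and truncations;
4. **partial** — normalized Levenshtein distance
   (`edits / max(len)`) to every reference name, accepting the nearest
   entries at or below a threshold (default 0.2).

Later steps only run when earlier ones find nothing, so dictionary hits
cost a single lookup.

## Library usage

```python
from entnorm import build_dictionary, normalize, MatchConfig

d = build_dictionary([("Imatinib", "CHEMBL:941"), ("Gleevec", "CHEMBL:941")])
trace = normalize("imatinab", d, MatchConfig(partial_threshold=0.2))
trace.result.identifiers   # frozenset({'CHEMBL:941'})
trace.result.step          # 'partial'
trace.result.distance      # 0.125
trace.steps_attempted      # ['exact', 'token', 'ngram', 'partial']
```

Reference dictionaries can be loaded from OBO ontologies (with `is_a`
subtree restriction, e.g. everything under a cancer root term) or from
delimited synonym tables via `entnorm.loaders`. `entnorm.evaluation`
scores predictions against two-column gold standards (`query<TAB>id`,
literal `NONE` marking expected no-matches) with precision/recall/F1 and
seeded bootstrap resampling. `entnorm.synthetic` generates seeded
dictionaries and perturbation-based gold standards (case/punctuation
variants, token shuffles, phrase embeddings, character typos,
unmatchable negatives) with known ground truth per cascade step.

## Command line

```bash
# normalize a query list against an ontology subtree
entnorm normalize --obo disease.obo --root DOID:162 \
    --queries names.txt --output results.tsv

# ... or against a synonym table
entnorm normalize --synonyms chembl_synonyms.tsv --id-col 0 --name-col 1 \
    --queries names.txt --threshold 0.2 --ngram-size 2

# score against a gold standard, with 100 bootstrap replicates
entnorm evaluate --synonyms dictionary.tsv --gold gold.tsv \
    --bootstrap 100 --seed 1 --output metrics.json

# generate a seeded synthetic dictionary + gold standard
entnorm make-fixtures --outdir fixtures/ --n-entries 100 \
    --n-records 200 --seed 7
```

Cascade steps can be disabled individually with `--no-token`,
`--no-ngram` and `--no-partial`.

## Tests and acceptance report

```bash
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script re-runs the full verification pipeline from
scratch — exhaustive edit-distance oracle comparison, 500-name
self-normalization, step attribution on a 1000-record synthetic gold
standard, threshold monotonicity, worked distance values, metric and
bootstrap identities, and OBO subtree filtering — and writes the
machine-readable target report (empty: no externally published number is
reproducible without downloading the original gold standards and full
reference databases).
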