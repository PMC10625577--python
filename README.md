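# occucode

Decision support for coding free-text job descriptions into hierarchical
occupational/activity classifications. The package trains gradient-boosted
classification models over summed sentence embeddings of short job
descriptions, attaches a class-probability confidence score to every code
suggestion, routes suggestions into automatic vs expert-review queues at a
configurable confidence threshold, estimates the resulting workload
reduction, evaluates inter-coder agreement (accuracy and Cohen's kappa per
coding level), and assesses exposure via continuous and ordinal job-exposure
matrices (JEMs).

## Layout

| module | contents |
| --- | --- |
| `occucode.schemes` | hierarchical scheme definitions, code parsing/truncation, placeholder-incomplete codes; built-in NAF2008 / PCS2003 / ISCO-88 / ISCO-68 approximations |
| `occucode.textprep` | normalization (tokenize, strip punctuation, lowercase, stem), pluggable embedders, summation fusion of input classes |
| `occucode.stemming` | self-contained Porter stemmer |
| `occucode.coder` | viability filtering, 60/30/10 splits, coding-index augmentation, boosted-tree training with early stopping, top-k suggestions, exhaustive wrapper input-class selection |
| `occucode.decision_support` | threshold routing, 5% confidence bins, minimum-workload-reduction estimate |
| `occucode.evaluation` | accuracy, Cohen's kappa, per-level and per-major-group metrics, human-vs-model t-test comparison (Shapiro-Wilk, Levene, pooled/Welch, Hedges g) |
| `occucode.jem` | continuous (probability x intensity x frequency) and ordinal (0/1/2 per agent) matrices plus their evaluation protocols (exact, dichotomous, Kendall tau-b, per-agent, per-level, exposed-only) |
| `occucode.synthdata` | synthetic schemes, corpora, coding indexes and JEMs emulating the structure of restricted cohort data |
| `occucode.cli` | `occucode` command-line entry point |

The default embedder is a deterministic hashed bag-of-stems (no downloads);
an optional adapter for pretrained sentence-embedding models is provided but
not required.

## CLI

```bash
# synthesize a dataset (scheme, episodes, coding index, JEMs)
occucode synth --out demo/ --level-sizes 5,10,20 --n-entries 1000 --seed 1

# train (60/30/10 split, early stopping, coding-index augmentation)
occucode train --data demo/episodes.csv --scheme demo/scheme.yaml \
    --index demo/index.csv --input-classes occupation,sector \
    --out demo/model.bin --test-out demo/test.csv --seed 1

# suggest codes with confidence scores
occucode code --model demo/model.bin --in demo/test.csv --topk 10 \
    --out demo/suggestions.csv

# per-level accuracy/kappa, per-group accuracy, confidence bins
occucode evaluate --pred demo/suggestions.csv --gold demo/test.csv \
    --scheme demo/scheme.yaml --out demo/report.json

# threshold routing and workload reduction (>= threshold auto-codes)
occucode workload --suggestions demo/suggestions.csv --gold demo/test.csv \
    --scheme demo/scheme.yaml --threshold 0.95 --out demo/workload.json

# exposure assessment against a JEM
occucode jem-apply --jem demo/jem_continuous.csv --kind continuous \
    --gold demo/test.csv --pred demo/suggestions.csv \
    --scheme demo/scheme.yaml --out demo/jem_report.json

# human-vs-model kappa comparison (CSV columns: level,kappa)
occucode compare-humans --human-kappas human.csv --model-kappas model.csv
```

Real coded cohorts use the same CSV formats: episodes
(`entry_id`, one column per input class, optional `gold_code`), suggestions
(`entry_id`, `rank`, `code`, `confidence`), continuous JEMs
(`occupation_code`, optional `sector_code`/`period_start`/`period_end`,
`probability`, `intensity`, `frequency`) and ordinal JEMs
(`occupation_code` plus one column per agent).

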