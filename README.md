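# policytextpanel

Measure locally heterogeneous insurance-reform effort from policy-document
corpora and estimate its effect on individual out-of-pocket (OOP) health
spending.

The pipeline has two halves:

1. **Text-as-data measurement.** Pre-tokenized policy documents are filtered
   for health relevance by title tokens, the top-5 TF-IDF keywords are
   extracted per document (raw tf × ln(N/df), deterministic tie-break),
   scheme documents are identified by a marker token in the title or the
   extracted keywords, and keyword occurrences are assigned to four reform
   categories (benefit expansion, cost containment, service delivery,
   pharmaceutical). Semantically neutral keywords (e.g. `reimbursement_rate`)
   only count when a collocation word (`increase`, `improve`, ...) appears
   within a configurable token window. Counts are aggregated per
   prefecture-year and cumulated from each prefecture's scheme launch year,
   with structural zeros before launch.
2. **Panel estimation.** The exposure table is merged into an individual
   panel; outcomes are ln(deflated OOP + 1). Models: two-way fixed-effects
   OLS (within-individual demeaning + year dummies, equal to explicit LSDV),
   fixed-effects 2SLS with two prefecture-level penetration instruments
   (first-stage F, Hansen J, regression-based Wu–Hausman), linear-combination
   tests, interaction marginal-effects grids, and a two-part
   (probit + log-linear) robustness model.

Because the real corpus and survey are not redistributable, the package ships
a first-class synthetic generator (`policytextpanel.synthetic`) that emits a
document corpus and an unbalanced individual panel with fully known ground
truth: planted per-document category counts, a true exposure table, true
spending-equation coefficients, an endogenous enrolment process driven by two
instruments, and a latent confounder. Every pipeline stage is tested against
that truth.

## Command-line usage

End-to-end run (simulation mode; writes corpus, keyword sets, exposure table,
panel, fitted models and a hash manifest into the output directory):

```bash
policytextpanel run --config run.yaml
```

with a config such as

```yaml
mode: simulate
out_dir: run_output
seed: 7
corpus_spec: {n_prefectures: 20}
panel_spec: {n_individuals_per_prefecture_wave: 12}
divisor: 100
```

In `mode: files` the corpus (JSONL), category lexicon (YAML), panel (CSV),
launch years (CSV) and an optional deflator table are supplied by the user.
Individual stages are also exposed:

```bash
policytextpanel corpus filter --input corpus.jsonl --output relevant.jsonl --relevance-file tokens.txt
policytextpanel corpus keywords --input relevant.jsonl --output keywords.jsonl --k 5
policytextpanel corpus select-uebmi --input relevant.jsonl --keywords keywords.jsonl \
    --output scheme.jsonl --token uebmi
policytextpanel fit fe --spec model.yaml --data analysis.csv
policytextpanel fit iv --spec model_iv.yaml --data analysis.csv
policytextpanel fit twopart --spec model.yaml --data analysis.csv
policytextpanel margins --spec model.yaml --data analysis.csv \
    --focal benefit_expansion --moderator cost_containment --grid 0:max:20
```

A model spec YAML lists `outcome`, `regressors` (names containing `:` are
built as interaction products), optional `endogenous` + `instruments`,
`fe` (`[individual, year]`), `cluster` (`none` / `prefecture` / `individual`)
and `sample_filter` (`all` / `enrolled` / `uninsured`), plus optional
`lincoms` expressions such as
`uebmi_enrolled + uebmi_enrolled:cost_containment`.

## Package layout

| module | contents |
| --- | --- |
| `synthetic` | corpus/panel generators with ground truth (`CorpusSpec`, `PanelSpec`, `Beta`, `Alpha`) |
| `corpus` | `PolicyDocument`, relevance filter, TF-IDF keyword extraction, scheme-document selection |
| `exposure` | `CategoryLexicon`, collocation-qualified counting, aggregation, cumulation, rescaling |
| `panel` | deflate-and-log outcome, exposure merge, listwise-deletion logging, summaries |
| `estimators` | `fit_twoway_fe`, `fit_fe_2sls`, `lincom`, `marginal_effects`, `fit_two_part` |
| `pipeline` / `cli` | `RunConfig`, staged orchestration with hash manifest, `policytextpanel` CLI |

## Notes on conventions

- TF-IDF uses the plain textbook variant (raw tf × ln(N/df), no smoothing or
  normalization); a smoothed-idf switch exists for sensitivity analysis.
- Exposure counts are integers; the regression-scale divisor (default 100) is
  a pure units choice recorded in the table metadata and output manifest.
- Cluster-robust (CR1) and HC1 corrections count only explicit design
  columns; absorbed individual effects are nested within either cluster
  level, so with singleton clusters CR1 collapses exactly to HC1.
- The two-part model's binary part uses prefecture + year dummies instead of
  individual fixed effects (incidental-parameters problem in probit).
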