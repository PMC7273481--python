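# ihcminer

Rule-based text mining of free-text pathology reports for metastatic
breast cancer. The package

* parses plain-text report exports into structured reports (line-wise
  diagnosis column, paragraph-wise description column) and persists them
  in a single-file SQLite store (`corpus_io`),
* labels each report as regional or distant metastatic breast cancer with
  a four-step phrase-matching protocol and parses the metastatic site
  (`case_finder`, driven by the configurable phrase sets in `lexicon`),
* locates immunohistochemistry-bearing description paragraphs and parses
  ER, PR and HER2 results in the 2013 CAP reporting patterns
  (`ihc_extractor`), recording one CSV row per case
  (`case_id, metastatic_site, ER, PR, HER2`; failed extractions as the
  literal `None`),
* scores runs against gold annotations with both the source convention's
  metric names and standard precision/recall/F1 (`evaluation`),
* compares receptor status between site groups with Yates-corrected 2x2
  and plain Pearson r x c chi-squared tests (`stats`), and
* generates fully labelled synthetic corpora — three supported IHC
  reporting dialects, an unsupported narrative dialect, benign filler and
  the three known false-positive confounder report types — so everything
  is testable without patient data (`synth_corpus`).

## CLI

Each pipeline stage is a subcommand; `run` chains them; `demo` generates
a synthetic corpus and runs everything on it:

```sh
ihcminer synth --out work/synth --seed 1 --confounders
ihcminer run --input work/synth/corpus.txt --gold work/synth/gold.csv \
             --out work/run --seed 1
ihcminer demo --out work/demo --seed 1
```

`run` writes `reports.sqlite`, `calls.json`, `results.csv`,
`evaluation.txt`, `stats.csv` and a `manifest.json`; identical input,
config and seed reproduce the artifacts byte-for-byte. Individual stages
(`ingest`, `find-cases`, `extract-ihc`, `evaluate`, `stats`) accept the
previous stage's output. A YAML/JSON lexicon config passed with
`--lexicon` extends the shipped phrase sets and organ vocabulary.

## Percent-formatting conventions

The reference detection/extraction percentages follow truncation to one
decimal (83/131 → 63.3, 64/65 → 98.4), while receptor-positivity
percentages follow half-up rounding (198/308 → 64.3). Both conventions
are implemented explicitly in `evaluation.format_percent`. One published
3x2 chi-squared value (and two others like it) cannot be derived from its
own printed counts; `tests/test_stats.py` and
`tests/test_acceptance.py` pin our independently verified values instead.
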