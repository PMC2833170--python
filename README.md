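# crthedge

Search-filter ("hedge") evaluation toolkit for **cluster randomized
trials (CRTs)** in MEDLINE-format citation corpora.

Systematic reviewers who study CRTs — trials that randomize intact groups
such as schools, medical practices or villages rather than individuals —
need electronic search strategies that find these trials in bibliographic
databases. MEDLINE has no publication type for CRTs, and only about half
of trial reports flag the clustered design in the title or abstract, so
filters must combine the indexer-assigned "randomized controlled trial"
publication type with design-related textwords and MeSH headings.
`crthedge` makes the whole evaluation pipeline reproducible offline:

* **MEDLINE I/O** — read/write tagged-format (nbib-style) corpora and
  per-citation gold-standard label files;
* **query engine** — an executable Ovid-style dialect with numbered
  lines, truncation (`$`, `?`), phrases, proximity (`adjN`), field scopes
  (`.tw.`, `.pt.`), MeSH heading lines and Boolean line combinations,
  plus an independent brute-force oracle for verification;
* **built-in filters** — the canonical 18-line CRT strategy family
  (`rct_pt`, `cluster_terms`, `broad_terms`, `combined_terms`,
  `highest_sensitivity`, `highest_precision`);
* **evaluation** — contingency metrics, relative recall, reporting-trend
  statistics, inter-rater kappa, screening-workload estimates,
  identifiability classification and term-frequency analysis;
* **simulation** — a seeded generator of labelled synthetic corpora with
  the statistical structure of a hand-searched gold-standard pool.

## The statistics at the core

Scoring a filter against a gold standard reduces to the 2×2 table with
cells *a* (eligible retrieved), *b* (ineligible retrieved), *c* (eligible
missed), *d* (ineligible missed), *N = a+b+c+d*:

| quantity | formula | meaning |
|---|---|---|
| sensitivity (recall) | a/(a+c) | share of CRTs the filter finds |
| fall-out (1−specificity) | b/(b+d) | share of non-CRTs it drags in |
| precision | a/(a+b) | share of hits that are CRTs |
| number needed to read | (a+b)/a | citations screened per CRT found |

Around these sit: *relative recall* (share of an independently assembled
trial set retrieved), the Wald interval for a difference of two
proportions, a trend test for the yearly proportion of clearly identified
trials (proportions-regression z by default, Cochran–Armitage as an
alternative — see `docs/methods.md`), Cohen's κ with an asymptotic CI,
and screening hours = target × NNR × minutes / 60.

## Worked example

Retrieval metrics from a published-style set of counts — 25,707 articles
hand-searched, 162 CRTs among them; three filters' retrieval counts:

```bash
python examples/02_metrics_from_counts.py
```

```
publication-type filter  sensitivity  93.8%  fall-out   6.0%  precision   9.0%  NNR  11.2
terms OR pt-filter       sensitivity  99.4%  fall-out  17.3%  precision   3.5%  NNR  28.5
terms AND pt-filter      sensitivity  90.1%  fall-out   2.5%  precision  18.4%  NNR   5.4
```

The publication-type filter alone is sensitive but imprecise (one CRT per
~11 citations read). ANDing it with cluster design-related terms halves
the number needed to read to 5.4 at a modest sensitivity cost; ORing
maximises sensitivity (99.4%) but forces ~28 citations read per CRT.
Other examples cover the built-in filters on a simulated corpus
(`01_run_builtin_filters.py`), the reporting trend with its pooled-period
confidence interval (`03_reporting_trend.py`), screening workload
(`04_screening_workload.py`) and the identifiability classifier
(`05_classify_identifiability.py`).

The same machinery is scriptable from the shell:

```bash
hedge simulate --seed 7 --n 5000 --out corpus.nbib --labels labels.csv
hedge eval --builtin highest_precision --corpus corpus.nbib \
           --labels labels.csv --report report.json
hedge trend --labels labels.csv --exclude-year 2006
hedge workload --strategy-report report.json --target 300 --minutes 3
hedge list-builtins
```

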