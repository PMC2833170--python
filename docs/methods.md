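# Methods

This note documents the models, conventions and design choices behind
`crthedge`: what exactly the query dialect means, how each statistic is
computed, what the synthetic corpus generator does and does not emulate,
and where genuinely open design questions were settled.

## Query dialect semantics

The engine executes numbered-line strategies in an Ovid-style dialect.
Historical Ovid behaviour varies across interface versions, so the
semantics are fixed here and verified against an independent brute-force
oracle (`crthedge.oracle`), a deliberately unoptimized exhaustive scan
kept free of the engine's data structures.

* **Tokenization.** Lowercased maximal alphanumeric runs; hyphens,
  slashes and all punctuation separate tokens; positions are 1-based
  consecutive integers; no stopword removal, no stemming.
* **`.tw.` (textword).** Title and abstract only, each searched
  independently — a pattern never matches across the title/abstract
  boundary. Real Ovid "textword" can cover more fields; title + abstract
  is what an exported evaluation corpus reliably contains.
* **`.pt.` (publication type).** Whole-value, case-insensitive
  comparison against each publication-type entry; a multi-word `.pt.`
  phrase is a whole field value, not a token phrase, so "randomized
  controlled trial" does not match "Randomized Controlled Trial
  Protocol".
* **MeSH lines** (`heading/`). Descriptor equality after stripping the
  leading `*` major-topic marker and any `/subheading` qualifiers.  No
  tree explosion: `cluster analysis/` is the unexploded heading.
* **`adjN`.** Two operands (single terms or phrases; a phrase's position
  is its first token) match if some pair of start positions p, q in the
  same field satisfies |p − q| ≤ N, in either order.  `adj` without a
  number means N = 1.  `adjN` is restricted to `.tw.` scope — proximity
  within a whole-value publication type has no meaning.
* **Truncation.** `$` is unlimited right-truncation (prefix match); `?`
  allows the bare stem or the stem plus exactly one extra character, so
  `intervention?` covers "intervention" and "interventions" but not
  "interventional".  This reading of `?` is an assumption; it is the one
  under which the broad-terms block behaves sensibly.
* **Field-suffix binding.** A trailing `.tw.`/`.pt.` binds to the
  largest preceding pure term-level expression: `cluster$ adj2
  randomi$.tw.` scopes the entire adjacency, `((x) OR (y)).tw.` the whole
  group, while in `1 AND cluster$.tw.` the suffix cannot cross the line
  reference.  Every term-level node must end up under exactly one field
  scope; a bare term line without a suffix is a parse error rather than
  an implicit default.
* **Line combinations.** `AND`/`OR`/`NOT` on earlier line numbers are
  plain set algebra (`a NOT b` = difference), left-associative, with
  precedence OR < AND < NOT < adj.  References must point to strictly
  earlier lines; lines are evaluated in ascending order and cached, so
  evaluation is deterministic and idempotent.

## Accuracy metrics

All metrics derive from the 2×2 contingency of retrieval × eligibility.
Undefined values (zero denominators) are explicit `None` markers, never
silent zeros.  Percentages are reported to one decimal place, matching
the conventions of filter-performance tables; full-precision proportions
are always retained.

Two NNR conventions exist in print: the raw-count value (a+b)/a, and the
reciprocal of the precision *after* rounding to one decimal percentage
point (1/3.5% = 28.6 where raw counts give 28.5).  Both are exposed
(`nnr`, `nnr_from_rounded_precision`); raw is the default.

Screening workload is target × NNR × minutes/60 with NNR from raw
counts: to confirm one eligible trial a reviewer screens NNR citations on
average.

## Trend test

`trend_test` offers two statistics, both signed normal deviates with
two-sided normal p-values, both invariant to shifting all year scores.

* `proportions` (default): unweighted OLS regression of the yearly
  proportions on calendar year, z = slope/SE(slope).  Weighting years
  equally damps the influence of a single heavily sampled year, which
  matters when one year of the gold-standard pool comes from a journal
  subset three times the size of the other years' samples.  On the
  shipped yearly table this reproduces the published headline pair
  (z = 3.6, p = 0.0003) to printed precision.
* `cochran-armitage`: the classical score test with equally spaced
  integer year scores, weighting years by their trial counts (cross-
  checked in the tests against R's `prop.trend.test`).  On the same
  table it gives z = 4.16 — a *stronger* trend signal, so the choice of
  default is conservative.

For the re-analysis excluding the oversampled year, the published
exclusion removed a journal subset whose per-trial composition is not
public; recomputing from the yearly counts alone lands at p ≈ 0.0015
versus the published 0.0012.  The residual gap is attributable to the
unknown composition of the excluded subset and is documented rather than
tuned away.

The difference in pooled-period proportions uses the Wald interval
without continuity correction (z = 1.96 at 95%); this is the
construction under which the published interval (32.0 pp, 17.2–46.9)
reproduces exactly.  Cohen's κ uses the asymptotic large-sample standard
error sqrt(p₀(1−p₀)/(n(1−pₑ)²)), clipped to [−1, 1].

## Identifiability classifier

`classify_identifiability` is a deterministic, configurable rule system,
not a learned model:

* **CLEAR** — a design noun (cluster/group/community, singular or
  plural) immediately followed by a `randomis*`/`randomiz*` token in
  title or abstract.  Tokenization makes hyphens and British/American
  spellings transparent.
* **UNIT** — otherwise, a unit noun within 4 tokens of a randomization
  anchor (`randomi[sz]*`, or `random`/`randomly` followed by
  `allocat*`/`assign*`).  The window (default 4) and the unit-noun
  lexicon (schools, physicians, practices, hospitals, communities,
  villages, wards, teams, churches, with plural forms) are configuration:
  cluster units are open-ended, so the lexicon is user-extensible and the
  defaults are the unit nouns quoted in published examples.
* **NONE** — neither signal.

The window deliberately misses distant constructions ("High schools
(N = 24) paired on enrolment size … were randomized"): widening it
sweeps in individually randomized multicentre trials ("patients in the
participating hospitals were randomly assigned"), which is exactly the
precision failure that makes unit-of-randomization searching infeasible
as a filter.  Fields are scanned separately, mirroring the engine's
no-cross-boundary rule.

## Synthetic corpus generator

`generate_corpus` emulates the structure of a hand-searched gold-standard
pool; it is the package's test bed, not a language model.  Defaults are
the study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_articles` | 25,707 | size of the hand-searched pool |
| `crt_prevalence` | 162/25,707 | CRTs per article examined |
| `crt_year_weights` | 14,16,9,19,15,20,52,17 over 2000–2007 | yearly CRT totals |
| `clear_prob_by_year` | 28.6% → 64.7% | yearly clear-identification proportions |
| `unit_share_of_unclear` | 46/84 | UNIT : NONE split of non-clear CRTs |
| `pt_tag_sensitivity` | 0.938 | probability a trial carries the RCT publication type |
| `noncrt_mix` | 6.5% / 15% / 78.5% | individually randomized trials / health-promotion / unrelated |

The non-CRT side is calibrated so the filters behave qualitatively as on
real data: individually randomized trials carry the publication type at
the same 0.938 rate (6.5% of non-CRTs ⇒ pt-filter fall-out ≈ 6%), and
health-promotion articles carry the broad MeSH headings and
"intervention" textwords at rates that give the broad block double-digit
fall-out.  A small `noncrt_false_clear_rate` (0.2%) plants design-phrase
mentions in non-trial articles, because textword filters do retrieve
methodological mentions.  An optional `oversample_2006` flag mimics a
single-year journal-subset bulge in the non-CRT year distribution (off
by default; CRT year weights already encode it).

Text is assembled from a fixed phrase bank under a seeded
`numpy.random.default_rng`; generation is byte-deterministic given config
+ seed.  Every generated CRT's text classifies exactly as its label
(checked exhaustively in the tests), and distractor templates never
classify CLEAR.

**What passing tests on synthetic corpora do show:** the engine's
semantics, the set identities among the built-ins, and that measured
prevalence, tagging sensitivity, class proportions and the qualitative
precision ordering (AND-combination > pt-filter > OR-combination) are
recovered within 3-σ binomial bounds.  **What they cannot show:** real
MEDLINE retrieval totals, real phrasing diversity (templates are far
cleaner than prose), indexing-policy drift over time, or the absolute
precision of any filter on a database with different CRT abundance.

## Numerical and degenerate-input conventions

* Term-table ties in `term_frequency` break by ratio, then relevant
  count, then alphabetically (stable sort); terms absent from the
  complement get an `inf` ratio sentinel.
* Empty abstracts participate normally (no matches); strategies ending
  on a pure MeSH or `.pt.` line are legal.
* Unique identifiers are opaque strings; the canonical 8-digit form is
  validated with a warning, not an error, so synthetic schemes remain
  usable.  Duplicate uids are always errors.
* Label files: a missing identifiability for a non-CRT maps to NA; a
  class on a non-CRT, an unknown class token, or a CRT without a class
  are validation errors.  Unmatched label uids are reported and block
  evaluation; they are never silently dropped.
* I/O is UTF-8 with undecodable bytes replaced; writers are
  byte-deterministic, and write→read is the identity on valid corpora.

## Problem sizes

The test suite works at reduced scale where full scale adds nothing:
engine/oracle agreement uses corpora of ≤ 60 citations over a vocabulary
rich in shared prefixes (100 random strategy/corpus pairs in the
acceptance tests), statistical-structure checks use 20,000–25,707-article
corpora once per session, and label/text consistency is checked
exhaustively on a 3,000-article corpus at elevated prevalence.  The
acceptance script runs the generator at the full default size.

## Known limitations

* The query dialect covers exactly the operators the built-in strategies
  need (`adjN`, `$`, `?`, `.tw.`, `.pt.`, MeSH lines, Boolean line
  algebra); `exp` (tree explosion), frequency operators and limits are
  out of scope.
* Bare integers in a query line are always line references, so a purely
  numeric search term cannot be expressed.
* The kappa routine ships the estimator and CI only; the underlying
  dual-review agreement data of any particular study is typically
  unpublished, so no reference value is asserted.
* The proportions-regression trend default assumes yearly proportions
  are roughly equally informative; with strongly unequal yearly samples
  and no oversampling concerns, `cochran-armitage` is the better choice.
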