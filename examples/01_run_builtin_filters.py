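"""Simulate a labelled corpus and score every built-in filter against it.

Generates a 5,000-article synthetic MEDLINE corpus (about 8% cluster
randomized trials so the small corpus still carries enough of them),
runs each packaged search strategy, and prints sensitivity (share of
CRTs retrieved), fall-out (share of non-CRTs retrieved), precision
(share of hits that are CRTs) and the number needed to read (citations
screened per CRT found).
"""

from crthedge import (
    GeneratorConfig,
    builtin_strategy,
    compute_metrics,
    evaluate_strategy,
    generate_corpus,
    list_builtins,
    make_contingency,
)

corpus, labels = generate_corpus(
    GeneratorConfig(n_articles=5000, crt_prevalence=0.08, seed=42)
)
crts = labels.crt_uids()
print(f"corpus: {len(corpus)} articles, {len(crts)} CRTs\n")
print(f"{'strategy':22s} {'hits':>5s} {'sens%':>6s} {'fall%':>6s} {'prec%':>6s} {'NNR':>6s}")
for info in list_builtins():
    result = evaluate_strategy(builtin_strategy(info.name), corpus)
    m = compute_metrics(make_contingency(set(result.retrieved), crts, len(corpus)))
    nnr = f"{m.nnr:.1f}" if m.nnr else "-"
    print(
        f"{info.name:22s} {len(result.retrieved):5d} {m.sensitivity_pct:6.1f} "
        f"{m.one_minus_specificity_pct:6.1f} {m.precision_pct:6.1f} {nnr:>6s}"
    )
print(
    "\nThe AND combination (highest_precision) trades a few percentage points"
    "\nof sensitivity for the best precision; the OR combination maximises"
    "\nsensitivity at the cost of reading more citations per trial found."
    "\nAbsolute precision depends strongly on CRT prevalence: at the ~0.6%"
    "\nprevalence of a real journal pool all precisions are far lower, but"
    "\nthe ordering between strategies is the same."
)
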