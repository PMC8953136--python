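# litfilter

Tools for the *objective* development and validation of boolean literature
search filters, with the published deprescribing filters for Medline (via
PubMed) and Embase (via Embase.com) bundled as executable queries.

## The problem

Systematic reviewers need search filters — pre-tested boolean query
fragments — that retrieve essentially every article on a topic from a
bibliographic database while discarding most of the rest.  Deprescribing
(the supervised tapering or withdrawal of inappropriate long-term
medications) is a young, fast-growing literature whose subject headings
(`Deprescriptions` in MeSH, `Deprescription` in Emtree) were only created in
2016 and are inconsistently applied, so heading-only searches miss a large
share of relevant work.

The "objective" route to a filter replaces expert intuition with frequency
analysis of a hand-labeled *reference set*:

1. **Reference set** — articles labeled relevant/non-relevant, randomly
   split (stratified on the label) into a development and a validation set.
   The required validation size follows n = ⌈z²·p(1−p)/d²⌉; for an
   anticipated sensitivity p = 0.90 estimated to a half-width d = 0.05 at
   the 95% level this gives **139** articles.
2. **Term mining** — for every token, phrase, truncation stem and subject
   heading, the class-conditional *document frequency* (fraction of articles
   of a class containing it).  Candidates are screened in two tiers
   (≥ 20% of relevant and ≤ 2% of non-relevant articles; then ≥ 10% / ≤ 3%)
   after excluding generic, methodological, population and setting terms via
   editable lexicons.
3. **Greedy filter building** — seed with the most frequent tier-1
   candidate, then repeatedly OR in the candidate with the largest gain in
   development-set sensitivity until no candidate adds a newly retrieved
   relevant article; hand-nominated topical terms (e.g. `taper*`,
   `"dose reduction"`) come last.  Every trial line is logged.
4. **Validation** — sensitivity tp/(tp+fn), specificity tn/(fp+tn) and
   precision tp/(tp+fp) on the held-out set, with exact (Clopper–Pearson)
   binomial 95% confidence intervals.

Because no labeled reference corpus of that scale is publicly deposited, the
package also ships a synthetic-corpus generator with the same statistical
structure (class-conditional Bernoulli term planting, incomplete heading
indexing, abstract-less records), under which every pipeline stage has an
analytic ground truth.

## Worked example

```python
>>> from litfilter import (performance_from_counts, ConfusionCounts,
...                        sample_size, load_medline_filter, evaluate, Article)
>>> rep = performance_from_counts(ConfusionCounts(tp=69, fn=6, fp=777, tn=7062))
>>> rep.sensitivity.display(), rep.specificity.display(), rep.precision.display()
('92 (83-97)', '90 (89-91)', '8 (6-10)')
>>> sample_size(0.90, 0.05).n
139
>>> article = Article(id="x", title="Deprescribing benzodiazepines in older adults",
...                   abstract="A tapering protocol was evaluated.")
>>> evaluate(load_medline_filter(), article)
True
```

The first call reproduces a published validation row: retrieving 69 of 75
relevant and 777 of 7,839 non-relevant articles means 92% sensitivity
(exact 95% CI 83–97%), 90% specificity and 8% precision.  The last two lines
run the bundled Medline filter — the `deprescrib*` truncation matches the
title — exactly as it would behave in PubMed's title/abstract fields.

A full synthetic run from the shell:

```sh
litfilter pipeline --out run/ --seed 1
```

writes the split corpora, the screened candidate table, the complete build
log (every search line with its retrieval counts), the finished filter
string and a JSON validation report with exact CIs, plus a manifest
recording seeds and config hash.  `litfilter --help` lists the individual
stages (`corpus`, `query`, `mine`, `build`, `validate`, `simulate`).

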