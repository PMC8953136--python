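# Methods

This note records the models, conventions and numerical choices behind
`litfilter`, and what the synthetic experiments do and do not establish.

## Query semantics

Queries are boolean trees over five atom types.  Evaluation is defined on a
fixed tokenization: text is lowercased and split into maximal runs of ASCII
letters and digits, so hyphens, slashes and all other punctuation separate
tokens (`dose-reduction` tokenizes as `dose`, `reduction` and therefore
matches the phrase `"dose reduction"`).  Semantics per atom:

* **term** — some token of the title or abstract equals the pattern
  (prefix-equals when truncated with `*`); any occurrence suffices.
* **phrase** — the token sequence occurs contiguously within one field
  (title or abstract; a phrase never spans the field boundary); trailing
  truncation applies to the last token.
* **heading** — exact case-insensitive string match against the record's
  MeSH or Emtree heading list.  No vocabulary-tree explosion is performed:
  live PubMed auto-explodes MeSH terms to their narrower descendants, so
  retrieval against a live database can only be broader than this engine's.
  This is a deliberate fidelity gap — shipping and maintaining the heading
  hierarchies is out of scope.
* **proximity** (`NEAR/n`, Embase dialect only) — token positions of a
  left-side and right-side alternative differ by at most *n*, in either
  order, within one field.  Fixing the counting convention to
  |pos(left) − pos(right)| ≤ n makes the operator exactly testable; database
  vendors do not publish their exact counting rule.
* An absent abstract contributes no tokens, which is distinct from an empty
  abstract string at the data-model level.

PubMed `[Title/Abstract]` is interpreted as title+abstract only; the live
field also covers author keywords, which the article model does not carry.
Parsing preserves the printed grouping (parenthesized sub-disjunctions stay
nested), which is what makes serialization byte-stable: the two bundled
filter strings round-trip identically through parse ∘ serialize.  The
bundled Embase string is stored with straight single quotes (the dialect's
actual syntax); typographic quotes are accepted on input.

## Corpus handling

Records come from MEDLINE nbib files (via Bio.Medline), RIS files (a
minimal built-in tag parser; RIS keywords are treated as Emtree-style
headings, the convention of Embase RIS exports) or delimited tables.
Publication types collapse to article / review / other (review outranks
article; editorials, letters, notes and similar types become `other` with
the raw type retained as a subtype).  Relevance labels always travel with
the data — in-file or as a sidecar id→label table — and are never inferred.

Deduplication is exact-key only (id, or case-folded title+year for
cross-database merges), first occurrence kept.  The development/validation
split is stratified on the relevance label; each stratum contributes
round-half-up(fraction × stratum size) articles drawn by a seeded
`numpy.random.default_rng` permutation, so the same seed always reproduces
the same membership and the two outputs exactly partition the input.  The
default development fraction is 0.7; the reference-set emulation uses 2/3
(a 2:1 randomization ratio), which is the unique fraction reproducing a
149/75 and 15,678/7,839 split of 224 relevant and 23,517 non-relevant
articles under round-half-up allocation.

All percentage displays round half-up (one decimal in corpus summaries,
integer percent in performance tables, two decimals for prevalence-scale
fractions).

## Term mining

Document frequency — the fraction of a class's articles containing a term
at least once — is the screening statistic throughout; within-article
repetition never counts.  Free-text statistics are computed over
title+abstract; heading statistics over the heading lists, tagged by
vocabulary; the two are kept separate.

Contextual (collocation) analysis starts from seed tokens at ≥ 10% relevant
document frequency.  Morphological variants are tokens sharing a common
prefix of at least 5 characters with the seed (shorter stems degenerate;
the shortest useful published stems, like `taper*` and `reduc*`, are
5 characters), and the emitted truncation stem is the longest prefix common
to all variants.  Candidate phrases are contiguous bigrams/trigrams
containing a seed or variant; n-grams differing only in a stem-sharing
final token are pooled into one truncated phrase (`medication review` +
`medication reviews` → `medication review*`) *before* the frequency screen,
so singleton variants still support their pooled form.  Phrase discovery
scans the relevant class only (a phrase must clear a relevant-class
frequency threshold to matter) and the survivors are recounted over both
classes in one pass; this keeps the step near-linear in corpus size.

Screening is two-tiered: tier 1 keeps terms at ≥ 20% relevant and ≤ 2%
non-relevant document frequency; tier 2 applies a 10% / 3% rule to the
remainder.  The tier-2 rule is conjunctive by default: a literal "or"
reading would admit every sufficiently rare term (any term in ≤ 3% of
non-relevant articles qualifies regardless of its relevant-class
frequency), which cannot be what a sensitivity screen intends; the literal
disjunctive reading remains available via `tier2_combiner="or"`.
Exclusions (generic / methodological / population / setting) are
lexicon-driven rather than hard-coded — the original exclusion judgments
were manual and are not reproducible — and the shipped starter lexicons are
plain editable word lists; the screen reports what each lexicon removed.

## Greedy filter building

The builder maximizes development-set sensitivity only.  It seeds with the
tier-1 candidate of highest relevant-class document frequency, then
repeatedly ORs in the candidate with the largest integer gain in retrieved
relevant articles, phase by phase (tier 1, tier 2, manual additions),
stopping a phase when no candidate gains a single article.  Stopping uses
strict integer improvement — sensitivity is a count ratio, so no tolerance
is involved.  Ties break by (1) fewer non-relevant articles retrieved by
the combined query, (2) higher relevant-class document frequency,
(3) lexicographic surface form: reproducibility with a preference for
precision at equal sensitivity.  With the tie-break fixed, the build is a
pure function of its inputs, and the log records every search line tried
with its retrieval counts.

Because OR-retrieval is monotone, the greedy loop always terminates at the
coverage of the union of all useful candidates — i.e. at the maximum
sensitivity attainable by *any* candidate subset — so exhaustive-search
comparisons are equality checks, not bounds.

Manual additions are atoms below the mining thresholds but topically
essential; they are appended when they add sensitivity, or unconditionally
when flagged force-include (the mechanism used for topical headings kept
for conceptual coverage despite zero gain).  Force-included entries are the
one sanctioned exception to the strictly-increasing-sensitivity property of
accepted log entries and are marked `manual-forced` in the log.

## Validation statistics

Confidence intervals are exact Clopper–Pearson, computed from beta
quantiles: lower = Beta(α/2; x, n−x+1), upper = Beta(1−α/2; x+1, n−x), with
the degenerate ends pinned to 0 and 1.  The exact method is the only
standard interval that reproduces every published bound from its counts
(Wilson, for instance, gives 84–96 rather than 83–97 for 69/75); its
coverage is conservative (at least nominal).  Precision on an empty
retrieval is reported as undefined with an explicit flag, never as 0 or
NaN.  The sample-size rule n = ⌈z²·p(1−p)/d²⌉ computes z from the normal
quantile at the requested level rather than hard-coding 1.96.

## Synthetic corpus generator

The generator emulates a reference set as a token soup with planted
signal.  Defaults describe a deprescribing-like corpus: 224 relevant and
23,517 non-relevant articles (0.94% prevalence), eight journals with
class-specific weights, a 2011–2020 year range with the recent period
over-represented among relevant articles, publication-type mixtures per
class, topical-heading indexing of only 1/3 (MeSH) and 1/5 (Emtree) of
relevant articles, and abstract-less records concentrated in the `other`
publication type (20% versus 1% for articles and reviews).

Each vocabulary term is included per article as an independent Bernoulli
draw with its class-conditional document frequency; multi-token terms are
inserted contiguously, proximity pairs with a uniform random gap of
1..max_gap background tokens, and an included text term lands in the title
with probability 0.35, else in the abstract — where it is lost if the
record carries no abstract.  Background text is Zipf-distributed
(exponent 1.1) over a 2,000-token vocabulary whose tokens (`bg0000`…)
cannot collide with any planted term or query atom.  Signal-term
frequencies are chosen to reflect how this literature actually talks: the
`deprescrib*` stem in about half of relevant articles (realized as
*deprescribing*/*deprescribed*/*deprescription* — note the last does not
share the 10-character stem, deliberately), `polypharmacy` ~30%,
`discontinu*` ~36%, `medication review` ~20%, tapering and dose-reduction
phrasing rare (8%, 6%) but topical, all with non-relevant frequencies at or
below 2%; noise terms (`study`, `patients`, `older`, `hospital`, …) are
frequent in both classes and belong to the starter exclusion lexicons.

Under term independence, the probability that a query retrieves an article
is 1 − Π_t (1 − df_t · vis_t · q_t), mixed over publication types, where
vis accounts for title placement versus abstract loss and q_t is the
probability that the term's realization triggers the query.  This closed
form (`expected_performance`) is the oracle for every end-to-end test.  Two
approximations are documented: conjunctive atoms satisfied by tokens from
*two different* planted terms are neglected (slightly understating
retrieval of AND-groups), and a later insertion can in principle split an
earlier phrase (probability ≲ 1% per article).  Both are far below the
binomial noise at the corpus sizes used.

**What passing synthetic tests shows — and does not.**  The generator
validates the machinery: that frequencies are counted as defined, that the
greedy builder finds the maximal-coverage disjunction, that observed
performance matches analytic ground truth within binomial error, and that
abstract-less records are missed at an elevated rate (the failure mode
reported for real filters).  It does not validate the linguistic choices a
real corpus would stress — correlated terms, polysemy, real morphology —
because term occurrences are independent by construction.  A
correlated-topic stress mode is a natural extension; the published filters
themselves are shipped as fixed strings precisely because their exact
term membership is a property of the original labeled corpus, which is not
deposited.

## Problem sizes and determinism

End-to-end runs use the full emulated reference-set scale (23,741 articles;
generation ~2 s, mining ~10 s, building ~6 s on one CPU).  Unit tests use
scaled-down corpora (tens to thousands of articles) with fixed seeds; all
randomness flows from explicit integer seeds through
`numpy.random.default_rng` or `random.Random`, and pipeline reruns with the
same seed produce byte-identical candidate tables, build logs and filter
strings.
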