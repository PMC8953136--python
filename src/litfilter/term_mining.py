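"""Candidate search-term mining from a labeled development corpus.

The "objective" route to a search filter starts from frequencies, not expert
intuition: every token, phrase, truncation stem and subject heading is scored
by its *document frequency* in each relevance class (the fraction of articles
of that class containing it at least once), candidates are screened against
sensitivity/specificity thresholds, and terms that are generic or that pin
the filter to a population, setting or study design are excluded via
user-editable lexicons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .corpus_io import CorpusError, LabeledCorpus, Relevance
from .query_engine import tokenize


@dataclass(frozen=True)
class TermStats:
    """A candidate term with class-conditional document frequencies.

    ``surface`` is the display form: a token, a space-joined phrase, a
    truncation stem ending in ``*``, or a heading string.  ``kind`` is one of
    ``token``, ``phrase``, ``truncation``, ``heading``; headings additionally
    carry their ``vocabulary`` (``mesh``/``emtree``).
    """

    surface: str
    kind: str
    n_relevant: int
    n_nonrelevant: int
    df_relevant: float
    df_nonrelevant: float
    vocabulary: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in {"token", "phrase", "truncation", "heading"}:
            raise ValueError(f"unknown term kind {self.kind!r}")
        for f in (self.df_relevant, self.df_nonrelevant):
            if not 0.0 <= f <= 1.0:
                raise ValueError("document frequencies must lie in [0, 1]")

    @classmethod
    def from_counts(
        cls,
        surface: str,
        kind: str,
        n_relevant: int,
        n_nonrelevant: int,
        class_sizes: tuple[int, int],
        vocabulary: Optional[str] = None,
    ) -> "TermStats":
        n_rel_total, n_non_total = class_sizes
        return cls(
            surface=surface,
            kind=kind,
            n_relevant=n_relevant,
            n_nonrelevant=n_nonrelevant,
            df_relevant=n_relevant / n_rel_total,
            df_nonrelevant=n_nonrelevant / n_non_total,
            vocabulary=vocabulary,
        )


@dataclass(frozen=True)
class ScreeningThresholds:
    """Two-tier candidate screening thresholds.

    Tier 1 keeps terms that are both sensitive and specific: document
    frequency at least ``tier1_min_relevant`` among relevant articles *and*
    at most ``tier1_max_nonrelevant`` among non-relevant ones.  Tier 2 is the
    looser fallback applied to the remainder; ``tier2_combiner`` chooses
    whether its two conditions are conjoined (default) or either suffices.
    """

    tier1_min_relevant: float = 0.20
    tier1_max_nonrelevant: float = 0.02
    tier2_min_relevant: float = 0.10
    tier2_max_nonrelevant: float = 0.03
    tier2_combiner: str = "and"

    def __post_init__(self) -> None:
        vals = (
            self.tier1_min_relevant,
            self.tier1_max_nonrelevant,
            self.tier2_min_relevant,
            self.tier2_max_nonrelevant,
        )
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.tier1_min_relevant < self.tier2_min_relevant:
            raise ValueError("tier1_min_relevant must be >= tier2_min_relevant")
        if self.tier2_combiner not in {"and", "or"}:
            raise ValueError("tier2_combiner must be 'and' or 'or'")


@dataclass(frozen=True)
class Lexicon:
    """An exclusion word list: name, category and a set of lowercase entries.

    Categories mirror the reasons a term may bias a topic filter: ``generic``
    (too broad to carry the concept alone), ``methodological`` (study design),
    ``population``, ``setting``.
    """

    name: str
    category: str
    entries: frozenset[str]

    CATEGORIES = ("generic", "methodological", "population", "setting")

    def __post_init__(self) -> None:
        if self.category not in self.CATEGORIES:
            raise ValueError(f"unknown exclusion category {self.category!r}")
        object.__setattr__(self, "entries", frozenset(e.lower() for e in self.entries))


def load_lexicon(path: str | Path, category: Optional[str] = None, name: Optional[str] = None) -> Lexicon:
    """Load a lexicon file: one lowercase entry per line, ``#`` comments.

    When ``category`` is omitted it is inferred from the file stem.
    """
    path = Path(path)
    entries = set()
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            entries.add(line)
    stem = path.stem.lower()
    return Lexicon(
        name=name or path.stem, category=category or stem, entries=frozenset(entries)
    )


def builtin_lexicons() -> list[Lexicon]:
    """The starter exclusion lexicons shipped with the package."""
    out = []
    pkg = resources.files("litfilter") / "lexicons"
    for category in Lexicon.CATEGORIES:
        with resources.as_file(pkg / f"{category}.txt") as p:
            out.append(load_lexicon(p, category=category, name=category))
    return out


# ---------------------------------------------------------------------------
# Document frequencies
# ---------------------------------------------------------------------------

def _class_articles(corpus: LabeledCorpus):
    rel = corpus.subset(Relevance.RELEVANT)
    non = corpus.subset(Relevance.NON_RELEVANT)
    if not rel or not non:
        raise CorpusError("term mining requires at least one article in each relevance class")
    return rel, non


def _article_tokens(article) -> tuple[list[str], list[str]]:
    """Title and abstract token lists (free-text stats never touch headings)."""
    return tokenize(article.title), (
        tokenize(article.abstract) if article.abstract is not None else []
    )


def document_frequencies(
    corpus: LabeledCorpus,
    min_df_relevant: float = 0.10,
    include_headings: bool = True,
) -> list[TermStats]:
    """Per-token (and per-heading) class-conditional document frequencies.

    An article counts once per term no matter how often the term occurs in it.
    Free-text tokens are counted over title+abstract; headings over the
    record's heading lists, tagged with their vocabulary.  Only terms with
    ``df_relevant >= min_df_relevant`` are returned, sorted by descending
    relevant-class frequency then surface.
    """
    rel, non = _class_articles(corpus)
    sizes = (len(rel), len(non))

    def count(arts, extractor) -> dict:
        counts: dict = {}
        for a in arts:
            for key in extractor(a):
                counts[key] = counts.get(key, 0) + 1
        return counts

    def token_keys(a):
        title, abstract = _article_tokens(a)
        return set(title) | set(abstract)

    def heading_keys(a):
        keys = {("mesh", h.casefold()) for h in a.mesh_headings}
        keys |= {("emtree", h.casefold()) for h in a.emtree_headings}
        return keys

    stats: list[TermStats] = []
    rel_tok, non_tok = count(rel, token_keys), count(non, token_keys)
    for token, n_rel in rel_tok.items():
        if n_rel / sizes[0] >= min_df_relevant:
            stats.append(
                TermStats.from_counts(token, "token", n_rel, non_tok.get(token, 0), sizes)
            )
    if include_headings:
        rel_h, non_h = count(rel, heading_keys), count(non, heading_keys)
        for (vocab, heading), n_rel in rel_h.items():
            if n_rel / sizes[0] >= min_df_relevant:
                stats.append(
                    TermStats.from_counts(
                        heading, "heading", n_rel, non_h.get((vocab, heading), 0),
                        sizes, vocabulary=vocab,
                    )
                )
    stats.sort(key=lambda s: (-s.df_relevant, s.surface))
    return stats


# ---------------------------------------------------------------------------
# Collocation and truncation analysis
# ---------------------------------------------------------------------------

def _common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


MIN_STEM_LENGTH = 5  # shorter stems are degenerate (match half the lexicon)


def _doc_sets(corpus: LabeledCorpus):
    """id -> (relevance, token set, list of per-field token lists)."""
    rel, non = _class_articles(corpus)
    records = []
    for a in list(rel) + list(non):
        title, abstract = _article_tokens(a)
        records.append((a.relevance, set(title) | set(abstract), (title, abstract)))
    return records, (len(rel), len(non))


def collocation_candidates(
    corpus: LabeledCorpus,
    seed_terms: Sequence[str],
    window: int = 3,
    min_relevant_docs: int = 2,
) -> list[TermStats]:
    """Contextual analysis of seed tokens: phrases and truncation stems.

    This emits

    * **truncation stems** — per seed, the longest common prefix (at least
      ``MIN_STEM_LENGTH`` characters) shared by the seed's morphological
      variants present in the corpus (tokens sharing that prefix with the
      seed); the stem's document frequency counts any variant; emitted only
      when at least two distinct variants occur;
    * **phrases** — contiguous n-grams (lengths 2..``window``) containing a
      seed or one of its variants, occurring in at least
      ``min_relevant_docs`` relevant articles.  N-grams that differ only in
      their final token, where those final tokens themselves share a stem,
      are pooled into a single truncated phrase (e.g. ``medication review``
      and ``medication reviews`` pool into ``medication review*``).

    Phrase discovery scans the relevant class only (candidates must clear a
    relevant-class frequency screen anyway); the surviving phrases are then
    recounted over both classes in one corpus pass.  Unknown seeds (absent
    from the corpus) are skipped with a warning.
    """
    records, sizes = _doc_sets(corpus)
    vocab: set[str] = set()
    for _, toks, _ in records:
        vocab |= toks

    out: list[TermStats] = []
    seen_surfaces: set[str] = set()
    all_matchers: set[str] = set()
    for seed in dict.fromkeys(s.lower() for s in seed_terms):
        if seed not in vocab:
            warnings.warn(f"seed term {seed!r} not found in corpus; skipped", stacklevel=2)
            continue
        variants = sorted(
            t for t in vocab if _common_prefix_len(t, seed) >= MIN_STEM_LENGTH
        )
        if len(variants) >= 2:
            stem = variants[0]
            for v in variants[1:]:
                stem = stem[: _common_prefix_len(stem, v)]
            if len(stem) >= MIN_STEM_LENGTH:
                surface = stem + "*"
                if surface not in seen_surfaces:
                    seen_surfaces.add(surface)
                    n_rel = n_non = 0
                    for relevance, toks, _ in records:
                        if any(t.startswith(stem) for t in toks):
                            if relevance is Relevance.RELEVANT:
                                n_rel += 1
                            else:
                                n_non += 1
                    out.append(
                        TermStats.from_counts(surface, "truncation", n_rel, n_non, sizes)
                    )
        else:
            variants = [seed]
        all_matchers.update(variants)
        all_matchers.add(seed)

    # Pass A: n-gram discovery over relevant articles only.
    gram_rel_docs: dict[tuple[str, ...], set[int]] = {}
    for doc_i, (relevance, _, fields) in enumerate(records):
        if relevance is not Relevance.RELEVANT:
            continue
        for toks in fields:
            matched = [t in all_matchers for t in toks]
            for n in range(2, max(2, window) + 1):
                for i in range(len(toks) - n + 1):
                    if any(matched[i : i + n]):
                        gram_rel_docs.setdefault(tuple(toks[i : i + n]), set()).add(doc_i)

    # Pool n-grams differing only in a stem-sharing final token (pooling
    # happens before the frequency screen, so singleton variants still
    # contribute to their pooled truncated phrase).
    groups: dict[tuple[str, ...], list[tuple[str, ...]]] = {}
    for gram in gram_rel_docs:
        groups.setdefault(gram[:-1], []).append(gram)
    pooled: list[tuple[str, tuple[str, ...], str, bool]] = []  # surface, prefix, last, truncated
    for prefix, grams in groups.items():
        by_stem: dict[str, list[tuple[str, ...]]] = {}
        for g in sorted(grams):
            placed = False
            for stem in list(by_stem):
                if _common_prefix_len(g[-1], stem) >= MIN_STEM_LENGTH:
                    new_stem = stem[: _common_prefix_len(g[-1], stem)]
                    by_stem[new_stem] = by_stem.pop(stem) + [g]
                    placed = True
                    break
            if not placed:
                by_stem[g[-1]] = [g]
        for stem, members in by_stem.items():
            rel_docs = set().union(*(gram_rel_docs[g] for g in members))
            if len(rel_docs) < min_relevant_docs:
                continue
            if len(members) > 1:
                pooled.append((" ".join(prefix) + " " + stem + "*", prefix, stem, True))
            else:
                pooled.append((" ".join(members[0]), prefix, stem, False))

    # Pass B: recount surviving (pooled) phrases over the whole corpus.
    by_prefix: dict[tuple[str, ...], list[int]] = {}
    for idx, (_, prefix, _, _) in enumerate(pooled):
        by_prefix.setdefault(prefix, []).append(idx)
    counts = [[0, 0] for _ in pooled]
    max_n = max((len(p) + 1 for _, p, _, _ in pooled), default=2)
    for relevance, _, fields in records:
        cls = 0 if relevance is Relevance.RELEVANT else 1
        hit: set[int] = set()
        for toks in fields:
            for n in range(2, max_n + 1):
                for i in range(len(toks) - n + 1):
                    cands = by_prefix.get(tuple(toks[i : i + n - 1]))
                    if not cands:
                        continue
                    last = toks[i + n - 1]
                    for c in cands:
                        _, _, stem, truncated = pooled[c]
                        if last.startswith(stem) if truncated else last == stem:
                            hit.add(c)
        for c in hit:
            counts[c][cls] += 1

    for idx, (surface, _, _, _) in enumerate(pooled):
        if surface in seen_surfaces:
            continue
        seen_surfaces.add(surface)
        out.append(
            TermStats.from_counts(surface, "phrase", counts[idx][0], counts[idx][1], sizes)
        )

    out.sort(key=lambda s: (-s.df_relevant, s.surface))
    return out


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenResult:
    """Outcome of threshold screening: the two candidate tiers, the excluded
    terms with their category and lexicon, and per-category tallies."""

    tier1: tuple[TermStats, ...]
    tier2: tuple[TermStats, ...]
    excluded: tuple[tuple[TermStats, str, str], ...]  # (term, category, lexicon name)
    category_counts: Mapping[str, int]


def _lexicon_hit(term: TermStats, lexicons: Sequence[Lexicon]) -> Optional[tuple[str, str]]:
    base = term.surface.rstrip("*").strip()
    for lex in lexicons:
        if base in lex.entries:
            return lex.category, lex.name
    return None


def screen(
    stats: Sequence[TermStats],
    thresholds: ScreeningThresholds = ScreeningThresholds(),
    lexicons: Sequence[Lexicon] = (),
) -> ScreenResult:
    """Partition candidates into tier 1, tier 2 and excluded.

    Exclusion (lexicon match, first matching lexicon wins) is applied before
    the frequency thresholds; the result is deterministic and
    order-independent up to the ordering of its inputs.
    """
    if not stats:
        raise ValueError("screen requires a non-empty candidate list")
    tier1, tier2, excluded = [], [], []
    counts = {c: 0 for c in Lexicon.CATEGORIES}
    for t in stats:
        hit = _lexicon_hit(t, lexicons)
        if hit is not None:
            category, lexname = hit
            excluded.append((t, category, lexname))
            counts[category] += 1
            continue
        if t.df_relevant >= thresholds.tier1_min_relevant and (
            t.df_nonrelevant <= thresholds.tier1_max_nonrelevant
        ):
            tier1.append(t)
            continue
        lo = t.df_relevant >= thresholds.tier2_min_relevant
        hi = t.df_nonrelevant <= thresholds.tier2_max_nonrelevant
        keep = (lo and hi) if thresholds.tier2_combiner == "and" else (lo or hi)
        if keep:
            tier2.append(t)
    return ScreenResult(
        tier1=tuple(tier1),
        tier2=tuple(tier2),
        excluded=tuple(excluded),
        category_counts=counts,
    )
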