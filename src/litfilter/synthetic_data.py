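"""Synthetic labeled corpora with the statistical structure the filter
methodology assumes.

Each article is a token soup: background tokens drawn from a Zipf-like
vocabulary, plus planted signal terms included class-conditionally and
independently per article (Bernoulli with the term's document frequency in
that class).  Multi-token terms are inserted contiguously; proximity pairs
are inserted with a bounded random token gap; subject headings are sampled
onto the record's heading lists.  A configurable fraction of records per
publication type carries no abstract at all — those records drop every
abstract token, which is exactly the failure mode that makes abstract-less
articles hard for text filters to retrieve.

Because term inclusions are independent, the retrieval probability of any
disjunction of planted terms has a closed form
(``1 − Π(1 − df·visibility)``, mixed over publication types), so every
pipeline stage can be checked against an analytic oracle
(:func:`expected_performance`).

The default :class:`GeneratorConfig` emulates a deprescribing reference set:
224 relevant and 23,517 non-relevant articles (0.94% prevalence), one in
three relevant articles indexed with the topical MeSH heading and one in
five with the topical Emtree heading, and journal/period/publication-type
mixtures matching such a corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .corpus_io import Article, LabeledCorpus, PubType, Relevance
from .query_engine import (
    And,
    HeadingAtom,
    Or,
    PhraseAtom,
    QueryNode,
    TermAtom,
    evaluate,
    or_all,
)


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedTerm:
    """One vocabulary entry with class-conditional document frequencies.

    ``kind``:

    * ``token``/``phrase`` — ``realizations`` is a distribution over the
      token sequences actually inserted (morphological variants), e.g. the
      stem ``discontinu*`` realized as *discontinuation* / *discontinued* /
      *discontinuing*;
    * ``heading`` — ``heading``/``vocabulary`` name a subject heading; a
      ``df_relevant`` of None inherits the config's topical
      ``heading_indexing_probability``;
    * ``pair`` — ``left`` and ``right`` tokens inserted with a uniform
      random gap of 1..``max_gap`` intervening background tokens.

    ``in_filter`` marks the term as part of the planted high-signal filter
    whose analytic performance is the simulation ground truth.
    """

    name: str
    kind: str
    df_relevant: Optional[float]
    df_nonrelevant: float
    realizations: tuple[tuple[float, tuple[str, ...]], ...] = ()
    heading: str = ""
    vocabulary: str = "mesh"
    left: str = ""
    right: str = ""
    max_gap: int = 0
    in_filter: bool = False

    def __post_init__(self) -> None:
        if self.kind not in {"token", "phrase", "heading", "pair"}:
            raise GeneratorError(f"unknown planted term kind {self.kind!r}")
        for df in (self.df_relevant, self.df_nonrelevant):
            if df is not None and not 0.0 <= df <= 1.0:
                raise GeneratorError(f"{self.name}: document frequencies must lie in [0, 1]")
        if self.kind in {"token", "phrase"}:
            if not self.realizations:
                object.__setattr__(self, "realizations", ((1.0, (self.name.rstrip("*"),)),))
            total = sum(p for p, _ in self.realizations)
            if abs(total - 1.0) > 1e-9:
                raise GeneratorError(f"{self.name}: realization probabilities must sum to 1")
        if self.kind == "heading" and not self.heading:
            object.__setattr__(self, "heading", self.name)
        if self.kind == "pair" and (not self.left or not self.right or self.max_gap < 1):
            raise GeneratorError(f"{self.name}: pair terms need left, right and max_gap >= 1")

    def atom(self, dialect: str = "pubmed") -> Optional[QueryNode]:
        """Canonical query atom matching this term (None if inexpressible)."""
        if self.kind == "heading":
            if (self.vocabulary == "mesh") != (dialect == "pubmed"):
                return None
            return HeadingAtom(self.heading, vocabulary=self.vocabulary)
        if self.kind == "pair":
            return And(
                (
                    TermAtom(_stem(self.left), truncated=True),
                    TermAtom(_stem(self.right), truncated=True),
                )
            )
        surface = self.name
        truncated = surface.endswith("*")
        tokens = surface.rstrip("*").split()
        if len(tokens) == 1:
            return TermAtom(tokens[0], truncated=truncated)
        return PhraseAtom(tuple(tokens), truncated=truncated)


def _stem(token: str, length: int = 7) -> str:
    return token[:length] if len(token) > length else token


_REL = Relevance.RELEVANT.value
_NON = Relevance.NON_RELEVANT.value

#: Signal and noise vocabulary emulating a deprescribing reference set.
#: Frequencies are class-conditional document frequencies; signal-term values
#: reflect how deprescribing papers actually talk (the stem ``deprescrib*``
#: in roughly half of relevant articles, ``polypharmacy`` in ~30%,
#: ``medication review`` in ~20%, tapering/dose-reduction phrasing rare but
#: topical), noise terms are frequent in both classes and belong to the
#: generic/methodological/population/setting exclusion categories.
DEFAULT_VOCABULARY: tuple[PlantedTerm, ...] = (
    PlantedTerm(
        "deprescrib*", "token", 0.50, 0.0008,
        realizations=((0.7, ("deprescribing",)), (0.2, ("deprescribed",)), (0.1, ("deprescription",))),
        in_filter=True,
    ),
    PlantedTerm("polypharmacy", "token", 0.30, 0.018, in_filter=True),
    PlantedTerm(
        "discontinu*", "token", 0.36, 0.020,
        realizations=((0.6, ("discontinuation",)), (0.3, ("discontinued",)), (0.1, ("discontinuing",))),
        in_filter=True,
    ),
    PlantedTerm(
        "medication review*", "phrase", 0.20, 0.012,
        realizations=((0.75, ("medication", "review")), (0.25, ("medication", "reviews"))),
        in_filter=True,
    ),
    PlantedTerm(
        "inappropriate medication*", "phrase", 0.30, 0.020,
        realizations=(
            (0.5, ("inappropriate", "medications")),
            (0.3, ("inappropriate", "medication")),
            (0.2, ("potentially", "inappropriate", "medication")),
        ),
        in_filter=True,
    ),
    PlantedTerm(
        "medication reduction", "pair", 0.18, 0.020,
        left="medication", right="reduction", max_gap=4, in_filter=True,
    ),
    PlantedTerm(
        "medication withdrawal", "pair", 0.24, 0.018,
        left="medication", right="withdrawal", max_gap=3, in_filter=True,
    ),
    PlantedTerm("cessation", "token", 0.14, 0.010, in_filter=True),
    PlantedTerm(
        "stopp*", "token", 0.12, 0.008,
        realizations=((0.7, ("stopping",)), (0.3, ("stopped",))),
        in_filter=True,
    ),
    PlantedTerm(
        "taper*", "token", 0.08, 0.002,
        realizations=((0.6, ("tapering",)), (0.4, ("tapered",))),
        in_filter=True,
    ),
    PlantedTerm(
        "dose reduction", "phrase", 0.06, 0.003,
        realizations=((1.0, ("dose", "reduction")),),
        in_filter=True,
    ),
    # Topical headings: incompletely indexed (None inherits the config's
    # heading_indexing_probability for the relevant class).
    PlantedTerm("deprescriptions", "heading", None, 0.0004, vocabulary="mesh", in_filter=True),
    PlantedTerm("inappropriate prescribing", "heading", 0.15, 0.004, vocabulary="mesh", in_filter=True),
    PlantedTerm("deprescription", "heading", 0.20, 0.0003, vocabulary="emtree", in_filter=True),
    PlantedTerm("drug withdrawal", "heading", 0.15, 0.005, vocabulary="emtree", in_filter=True),
    # Noise vocabulary: frequent in both classes, matched by the starter
    # exclusion lexicons (generic / methodological / population / setting).
    PlantedTerm("study", "token", 0.85, 0.80),
    PlantedTerm("patients", "token", 0.75, 0.65),
    PlantedTerm("older", "token", 0.55, 0.30),
    PlantedTerm("randomized", "token", 0.22, 0.18),
    PlantedTerm("hospital", "token", 0.25, 0.22),
    PlantedTerm("care", "token", 0.45, 0.40),
    PlantedTerm("outcomes", "token", 0.50, 0.45),
    PlantedTerm("use", "token", 0.60, 0.55),
    PlantedTerm("intervention", "token", 0.40, 0.25),
)

_JOURNALS = (
    "Age and Ageing",
    "British Journal of Clinical Pharmacology",
    "British Journal of General Practice",
    "Drugs and Aging",
    "European Journal of Clinical Pharmacology",
    "International Journal of Clinical Pharmacy",
    "JAMA Internal Medicine",
    "Journal of the American Geriatrics Society",
)
_JOURNAL_MIX = {
    _REL: (15, 23, 23, 48, 17, 31, 21, 46),
    _NON: (1535, 2940, 3667, 866, 2039, 1599, 5605, 5266),
}
_PUBTYPE_MIX = {
    _REL: {"article": 132 / 224, "review": 50 / 224, "other": 42 / 224},
    _NON: {"article": 12647 / 23517, "review": 1693 / 23517, "other": 9177 / 23517},
}
_RECENT_PERIOD_PROB = {_REL: 169 / 224, _NON: 12211 / 23517}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic reference set (defaults emulate a
    deprescribing corpus; see module docstring)."""

    n_relevant: int = 224
    n_nonrelevant: int = 23517
    vocabulary: tuple[PlantedTerm, ...] = DEFAULT_VOCABULARY
    background_vocab_size: int = 2000
    zipf_exponent: float = 1.1
    title_mean_tokens: int = 9
    abstract_mean_tokens: int = 110
    title_placement_probability: float = 0.35
    heading_indexing_probability: float = 1.0 / 3.0
    missing_abstract_probability: Mapping[str, float] = field(
        default_factory=lambda: {"article": 0.01, "review": 0.01, "other": 0.20}
    )
    pub_type_mixture: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(m) for c, m in _PUBTYPE_MIX.items()}
    )
    journals: tuple[str, ...] = _JOURNALS
    journal_mixture: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {c: tuple(m) for c, m in _JOURNAL_MIX.items()}
    )
    recent_period_probability: Mapping[str, float] = field(
        default_factory=lambda: dict(_RECENT_PERIOD_PROB)
    )
    year_range: tuple[int, int] = (2011, 2020)
    recent_from: int = 2016
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_relevant < 1 or self.n_nonrelevant < 1:
            raise GeneratorError("class sizes must be at least 1")
        probs = [
            self.title_placement_probability,
            self.heading_indexing_probability,
            *self.missing_abstract_probability.values(),
            *self.recent_period_probability.values(),
        ]
        for mix in self.pub_type_mixture.values():
            probs.extend(mix.values())
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise GeneratorError("publication-type mixture must sum to 1")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise GeneratorError("all probabilities must lie in [0, 1]")

    def df(self, term: PlantedTerm, relevance: str) -> float:
        if relevance == _REL:
            if term.df_relevant is None:
                return self.heading_indexing_probability
            return term.df_relevant
        return term.df_nonrelevant


@dataclass(frozen=True)
class PlantedTruth:
    """Generation ground truth: the config and the planted high-signal filter."""

    config: GeneratorConfig

    def signal_terms(self) -> tuple[PlantedTerm, ...]:
        return tuple(t for t in self.config.vocabulary if t.in_filter)

    def planted_filter(self, dialect: str = "pubmed") -> QueryNode:
        atoms = [t.atom(dialect) for t in self.signal_terms()]
        atoms = [a for a in atoms if a is not None]
        if not atoms:
            raise GeneratorError("no planted terms are expressible in this dialect")
        return or_all(atoms)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_FILLER = "qfill"  # gap filler for proximity pairs; never matches a query


def _zipf_cdf(size: int, exponent: float) -> np.ndarray:
    weights = 1.0 / np.arange(1, size + 1, dtype=float) ** exponent
    return np.cumsum(weights / weights.sum())


def generate(config: GeneratorConfig) -> tuple[LabeledCorpus, PlantedTruth]:
    """Sample a labeled corpus from the config; same seed, same corpus."""
    rng = np.random.default_rng(config.seed)
    cdf = _zipf_cdf(config.background_vocab_size, config.zipf_exponent)
    bg_words = np.array([f"bg{i:04d}" for i in range(config.background_vocab_size)])

    articles: list[Article] = []
    for relevance, n, prefix in (
        (_REL, config.n_relevant, "R"),
        (_NON, config.n_nonrelevant, "N"),
    ):
        ptypes = list(config.pub_type_mixture[relevance])
        pprobs = np.array([config.pub_type_mixture[relevance][p] for p in ptypes])
        jprobs = np.asarray(config.journal_mixture[relevance], dtype=float)
        jprobs = jprobs / jprobs.sum()

        pub_idx = rng.choice(len(ptypes), size=n, p=pprobs)
        journal_idx = rng.choice(len(config.journals), size=n, p=jprobs)
        recent = rng.random(n) < config.recent_period_probability[relevance]
        y0, y1 = config.year_range
        years = np.where(
            recent,
            rng.integers(config.recent_from, y1 + 1, size=n),
            rng.integers(y0, config.recent_from, size=n),
        )
        title_len = np.maximum(rng.poisson(config.title_mean_tokens, size=n), 3)
        abstract_len = np.maximum(rng.poisson(config.abstract_mean_tokens, size=n), 20)
        miss_prob = np.array(
            [config.missing_abstract_probability.get(ptypes[k], 0.0) for k in pub_idx]
        )
        has_abstract = rng.random(n) >= miss_prob

        # background tokens for the whole class at once
        total = int(title_len.sum() + abstract_len.sum())
        bg_idx = np.searchsorted(cdf, rng.random(total))
        cursor = 0

        include = {
            t.name: rng.random(n) < config.df(t, relevance) for t in config.vocabulary
        }

        for i in range(n):
            tl, al = int(title_len[i]), int(abstract_len[i])
            title_tokens = list(bg_words[bg_idx[cursor : cursor + tl]])
            cursor += tl
            abstract_tokens = list(bg_words[bg_idx[cursor : cursor + al]])
            cursor += al

            mesh: list[str] = []
            emtree: list[str] = []
            for term in config.vocabulary:
                if not include[term.name][i]:
                    continue
                if term.kind == "heading":
                    (mesh if term.vocabulary == "mesh" else emtree).append(term.heading)
                    continue
                if term.kind == "pair":
                    gap = int(rng.integers(1, term.max_gap + 1))
                    fillers = list(
                        bg_words[np.searchsorted(cdf, rng.random(gap - 1))]
                    )
                    segment = [term.left] + fillers + [term.right]
                else:
                    r = rng.random()
                    acc = 0.0
                    segment = list(term.realizations[-1][1])
                    for p, toks in term.realizations:
                        acc += p
                        if r < acc:
                            segment = list(toks)
                            break
                in_title = rng.random() < config.title_placement_probability
                target = title_tokens if in_title else abstract_tokens
                pos = int(rng.integers(0, len(target) + 1))
                target[pos:pos] = segment

            articles.append(
                Article(
                    id=f"{prefix}{i + 1:06d}",
                    title=" ".join(title_tokens),
                    abstract=" ".join(abstract_tokens) if has_abstract[i] else None,
                    mesh_headings=tuple(mesh),
                    emtree_headings=tuple(emtree),
                    journal=config.journals[journal_idx[i]],
                    year=int(years[i]),
                    pub_type=PubType(ptypes[pub_idx[i]]),
                    relevance=Relevance(relevance),
                )
            )

    corpus = LabeledCorpus(
        tuple(articles), provenance=f"synthetic seed={config.seed}"
    )
    return corpus, PlantedTruth(config=config)


# ---------------------------------------------------------------------------
# Analytic oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpectedPerformance:
    sensitivity: float
    specificity: float
    precision: float


def _realization_article(tokens: Sequence[str], term: PlantedTerm) -> Article:
    if term.kind == "heading":
        return Article(
            id="x",
            mesh_headings=(term.heading,) if term.vocabulary == "mesh" else (),
            emtree_headings=(term.heading,) if term.vocabulary == "emtree" else (),
        )
    return Article(id="x", title="", abstract=" ".join(tokens))


def _trigger_probability(term: PlantedTerm, node: QueryNode) -> float:
    """P(the term's realization makes the query true), conditional on the
    term being included and visible."""
    if term.kind == "heading":
        return 1.0 if evaluate(node, _realization_article((), term)) else 0.0
    if term.kind == "pair":
        hits = 0
        for gap in range(1, term.max_gap + 1):
            toks = [term.left] + [_FILLER] * (gap - 1) + [term.right]
            if evaluate(node, _realization_article(toks, term)):
                hits += 1
        return hits / term.max_gap
    q = 0.0
    for p, toks in term.realizations:
        if evaluate(node, _realization_article(toks, term)):
            q += p
    return q


def expected_performance(
    truth: PlantedTruth,
    node: Optional[QueryNode] = None,
    n_relevant: Optional[int] = None,
    n_nonrelevant: Optional[int] = None,
) -> ExpectedPerformance:
    """Closed-form retrieval probabilities of a query under the generator.

    Term inclusions are independent, so the per-class retrieval probability
    is ``1 − Π_t (1 − df_t · visibility_t · q_t)`` mixed over publication
    types, where ``q_t`` is the probability that the term's realization
    triggers the query and visibility accounts for title placement versus
    abstract loss.  Cross-term coincidences (a conjunction satisfied by
    tokens from two different planted terms) are neglected, which slightly
    understates retrieval of conjunctive atoms.  ``node`` defaults to the
    planted filter.
    """
    cfg = truth.config
    if node is None:
        node = truth.planted_filter()
    n_rel = n_relevant if n_relevant is not None else cfg.n_relevant
    n_non = n_nonrelevant if n_nonrelevant is not None else cfg.n_nonrelevant

    triggers = {t.name: _trigger_probability(t, node) for t in cfg.vocabulary}

    def class_probability(relevance: str) -> float:
        mix = cfg.pub_type_mixture[relevance]
        total = 0.0
        for ptype, weight in mix.items():
            miss = cfg.missing_abstract_probability.get(ptype, 0.0)
            vis_text = cfg.title_placement_probability + (
                1.0 - cfg.title_placement_probability
            ) * (1.0 - miss)
            p_none = 1.0
            for t in cfg.vocabulary:
                vis = 1.0 if t.kind == "heading" else vis_text
                p_none *= 1.0 - cfg.df(t, relevance) * vis * triggers[t.name]
            total += weight * (1.0 - p_none)
        return total

    p_rel = class_probability(_REL)
    p_non = class_probability(_NON)
    denom = n_rel * p_rel + n_non * p_non
    precision = (n_rel * p_rel / denom) if denom > 0 else float("nan")
    return ExpectedPerformance(
        sensitivity=p_rel, specificity=1.0 - p_non, precision=precision
    )
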