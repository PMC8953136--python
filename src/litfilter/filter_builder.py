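"""Greedy sensitivity-maximizing construction of a boolean search filter.

Starting from the screened candidate terms, the builder seeds the filter
with the most frequent tier-1 candidate and then repeatedly ORs in the
candidate giving the largest gain in development-set sensitivity, stopping
a phase when no candidate adds a single newly retrieved relevant article.
Tier-2 candidates are tried the same way once tier 1 is exhausted, and
manually nominated terms (typically topical terms below the mining
threshold) come last — optionally force-included even at zero gain, the way
critical topical headings are sometimes kept for conceptual coverage.

Every trial — accepted or not — is logged with the query line and its
retrieval counts, so the whole construction is auditable and exactly
reproducible: with the tie-break fixed, identical inputs give an identical
log.  Tie-break order at equal sensitivity gain: fewer non-relevant
retrieved by the combined query, then higher relevant-class document
frequency, then lexicographically smaller surface form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .corpus_io import CorpusError, LabeledCorpus, Relevance
from .query_engine import (
    CorpusIndex,
    HeadingAtom,
    PhraseAtom,
    QueryNode,
    TermAtom,
    or_all,
    parse_query,
    serialize,
)
from .term_mining import ScreeningThresholds, TermStats


class BuildError(ValueError):
    pass


@dataclass(frozen=True)
class Candidate:
    """A query atom (or pre-composed AND-group) entering the greedy loop."""

    surface: str
    node: QueryNode
    stats: Optional[TermStats] = None

    @property
    def df_relevant(self) -> float:
        return self.stats.df_relevant if self.stats is not None else 0.0


def candidate_from_stats(ts: TermStats, dialect: str) -> Candidate:
    """Turn a mined term into a query atom for the given dialect.

    Raises :class:`BuildError` for a heading from the other database's
    vocabulary (a PubMed query cannot address Emtree headings and vice
    versa); use :func:`candidates_for_dialect` to drop those wholesale.
    """
    if ts.kind == "heading":
        vocab = ts.vocabulary or ("mesh" if dialect == "pubmed" else "emtree")
        if vocab != ("mesh" if dialect == "pubmed" else "emtree"):
            raise BuildError(
                f"{ts.surface!r}: {vocab} heading is not expressible in the {dialect} dialect"
            )
        node: QueryNode = HeadingAtom(ts.surface, vocabulary=vocab)
    elif ts.kind == "truncation":
        node = TermAtom(ts.surface.rstrip("*"), truncated=True)
    elif ts.kind == "phrase":
        truncated = ts.surface.endswith("*")
        tokens = tuple(ts.surface.rstrip("*").split())
        node = PhraseAtom(tokens, truncated=truncated)
    else:
        node = TermAtom(ts.surface)
    return Candidate(surface=ts.surface, node=node, stats=ts)


def candidates_for_dialect(terms: Sequence[TermStats], dialect: str) -> list[Candidate]:
    """Candidates for every term expressible in the dialect (headings from
    the other database's vocabulary are skipped)."""
    out = []
    for ts in terms:
        try:
            out.append(candidate_from_stats(ts, dialect))
        except BuildError:
            continue
    return out


@dataclass(frozen=True)
class ManualAddition:
    """A hand-nominated atom, written in the target dialect.

    ``force_include`` appends it even when it does not increase sensitivity.
    """

    text: str
    force_include: bool = False


@dataclass(frozen=True)
class BuildConfig:
    thresholds: ScreeningThresholds = ScreeningThresholds()
    manual_additions: tuple[ManualAddition, ...] = ()
    dialect: str = "pubmed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "manual_additions", tuple(self.manual_additions))
        if self.dialect not in {"pubmed", "embase"}:
            raise BuildError(f"unknown dialect {self.dialect!r}")


@dataclass(frozen=True)
class LogEntry:
    step: int
    phase: str  # 'seed' | 'tier1' | 'tier2' | 'manual' | 'manual-forced'
    candidate: str
    query: str
    n_relevant_retrieved: int
    n_nonrelevant_retrieved: int
    accepted: bool


@dataclass
class FilterBuildLog:
    """Ordered record of every search line tried during the build."""

    entries: list[LogEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def accepted(self) -> list[LogEntry]:
        return [e for e in self.entries if e.accepted]


@dataclass(frozen=True)
class BuiltFilter:
    """The finished filter with its development-set metrics and audit log."""

    query: QueryNode
    dialect: str
    dev_sensitivity: float
    dev_precision: Optional[float]
    log: FilterBuildLog
    missed_ids: tuple[str, ...]
    accepted_candidates: tuple[Candidate, ...]
    candidate_pool: tuple[Candidate, ...]


def _match_sets(candidates: Sequence[Candidate], index: CorpusIndex):
    out = []
    for c in candidates:
        r = index.retrieve(c.node)
        rel = frozenset(
            v.article.id
            for v in index.views
            if v.article.relevance is Relevance.RELEVANT and v.article.id in r.ids
        )
        non = r.ids - rel
        out.append((c, rel, non))
    return out


def greedy_build(
    dev: LabeledCorpus,
    tier1: Sequence[Candidate],
    tier2: Sequence[Candidate] = (),
    config: BuildConfig = BuildConfig(),
) -> BuiltFilter:
    """Build a filter on the development set by greedy incremental OR-ing.

    Phases: (1) seed with the tier-1 candidate of highest relevant-class
    document frequency; (2) greedily add tier-1 candidates by sensitivity
    gain until none helps; (3) same over tier-2 candidates; (4) manual
    additions, appended when they increase sensitivity or are force-included.
    Stopping is strict integer improvement (at least one newly retrieved
    relevant article).  Every trial is logged.
    """
    if not tier1:
        raise BuildError("greedy_build requires a non-empty tier-1 candidate list")
    n_rel = dev.n_relevant
    n_non = dev.n_non_relevant
    if n_rel == 0 or n_non == 0:
        raise BuildError("development corpus must contain both relevance classes")

    index = CorpusIndex(dev)
    manual_candidates = []
    for m in config.manual_additions:
        node = parse_query(m.text, config.dialect)
        manual_candidates.append(
            (Candidate(surface=m.text, node=node), m.force_include)
        )

    tier1_sets = _match_sets(tier1, index)
    tier2_sets = _match_sets(tier2, index)
    manual_sets = [
        (c, rel, non, force)
        for ((c, rel, non), (_, force)) in zip(
            _match_sets([c for c, _ in manual_candidates], index), manual_candidates
        )
    ]

    log = FilterBuildLog()
    accepted: list[Candidate] = []
    covered_rel: frozenset[str] = frozenset()
    covered_non: frozenset[str] = frozenset()
    step = 0

    def query_string(extra: Optional[Candidate] = None) -> str:
        nodes = [c.node for c in accepted] + ([extra.node] if extra is not None else [])
        return serialize(or_all(nodes), config.dialect)

    def accept(entry_phase: str, cand: Candidate, rel, non) -> None:
        nonlocal covered_rel, covered_non, step
        accepted.append(cand)
        covered_rel = covered_rel | rel
        covered_non = covered_non | non
        log.entries.append(
            LogEntry(
                step=step,
                phase=entry_phase,
                candidate=cand.surface,
                query=query_string(),
                n_relevant_retrieved=len(covered_rel),
                n_nonrelevant_retrieved=len(covered_non),
                accepted=True,
            )
        )
        step += 1

    # Phase 1 seed: highest df_relevant, ties by surface.
    seed_c, seed_rel, seed_non = min(
        tier1_sets, key=lambda t: (-t[0].df_relevant, t[0].surface)
    )
    accept("seed", seed_c, seed_rel, seed_non)

    def run_phase(phase: str, pool: list) -> None:
        nonlocal step
        remaining = [t for t in pool if t[0] is not seed_c]
        while remaining:
            trials = []
            for cand, rel, non in remaining:
                new_rel = covered_rel | rel
                new_non = covered_non | non
                gain = len(new_rel) - len(covered_rel)
                log.entries.append(
                    LogEntry(
                        step=step,
                        phase=phase,
                        candidate=cand.surface,
                        query=query_string(cand),
                        n_relevant_retrieved=len(new_rel),
                        n_nonrelevant_retrieved=len(new_non),
                        accepted=False,
                    )
                )
                trials.append((gain, len(new_non), cand, rel, non))
            best = min(
                trials,
                key=lambda t: (-t[0], t[1], -t[2].df_relevant, t[2].surface),
            )
            gain, _, cand, rel, non = best
            if gain <= 0:
                break
            accept(phase, cand, rel, non)
            remaining = [t for t in remaining if t[0] is not cand]

    run_phase("tier1", tier1_sets)
    run_phase("tier2", tier2_sets)

    # Phase 4: manual additions, in the order given.
    for cand, rel, non, force in manual_sets:
        new_rel = covered_rel | rel
        gain = len(new_rel) - len(covered_rel)
        take = gain > 0 or force
        log.entries.append(
            LogEntry(
                step=step,
                phase="manual-forced" if (force and gain <= 0) else "manual",
                candidate=cand.surface,
                query=query_string(cand),
                n_relevant_retrieved=len(new_rel),
                n_nonrelevant_retrieved=len(covered_non | non),
                accepted=take,
            )
        )
        if take:
            accepted.append(cand)
            covered_rel = new_rel
            covered_non = covered_non | non
        step += 1

    tp = len(covered_rel)
    fp = len(covered_non)
    retrieved = tp + fp
    missed = tuple(
        a.id for a in dev if a.relevance is Relevance.RELEVANT and a.id not in covered_rel
    )
    return BuiltFilter(
        query=or_all([c.node for c in accepted]),
        dialect=config.dialect,
        dev_sensitivity=tp / n_rel,
        dev_precision=(tp / retrieved) if retrieved else None,
        log=log,
        missed_ids=missed,
        accepted_candidates=tuple(accepted),
        candidate_pool=tuple(list(tier1) + list(tier2)),
    )


@dataclass(frozen=True)
class MissedArticle:
    """A missed relevant article and the screened candidates it contains.

    An empty candidate list across all missed articles is the stopping
    condition: no supplementary relevant terms remain to be added.
    """

    id: str
    has_abstract: bool
    matching_candidates: tuple[str, ...]


def inspect_missed(
    built: BuiltFilter,
    dev: LabeledCorpus,
    candidates: Optional[Sequence[Candidate]] = None,
) -> list[MissedArticle]:
    """For each relevant development article the filter misses, list which
    screened candidates would have matched it."""
    pool = tuple(candidates) if candidates is not None else built.candidate_pool
    missed_set = set(built.missed_ids)
    index = CorpusIndex(dev)
    reports = []
    for view in index.views:
        a = view.article
        if a.id not in missed_set:
            continue
        from .query_engine import _eval  # internal reuse on the cached view

        matches = tuple(c.surface for c in pool if _eval(c.node, view))
        reports.append(
            MissedArticle(id=a.id, has_abstract=a.abstract is not None, matching_candidates=matches)
        )
    return reports
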