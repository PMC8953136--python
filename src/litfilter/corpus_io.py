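"""Reading, labeling, deduplicating, summarizing and splitting bibliographic corpora.

A *reference set* for search-filter work is a corpus of bibliographic records,
each hand-labeled relevant or non-relevant to the topic of interest.  This
module provides the :class:`Article` record type, corpus construction from
MEDLINE nbib flat files, RIS files or delimited tables, exact-key
deduplication, relevance-stratified random splitting into development and
validation sets, and Table-1-style characteristic summaries.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up


class CorpusError(ValueError):
    """Raised when a corpus violates a structural precondition."""


class PubType(str, enum.Enum):
    """Three-way publication-type grouping.

    ``other`` collects editorials, letters, notes, short surveys and similar
    front-matter types that are not original articles or reviews.
    """

    ARTICLE = "article"
    REVIEW = "review"
    OTHER = "other"


class Relevance(str, enum.Enum):
    RELEVANT = "relevant"
    NON_RELEVANT = "non_relevant"
    UNLABELED = "unlabeled"


@dataclass(frozen=True)
class Article:
    """One bibliographic record.

    ``abstract is None`` means the record has no abstract (distinct from an
    empty abstract string) — abstract-less records are a known failure mode of
    text-based filters and are tracked explicitly throughout the toolkit.
    """

    id: str
    title: str = ""
    abstract: Optional[str] = None
    mesh_headings: tuple[str, ...] = ()
    emtree_headings: tuple[str, ...] = ()
    journal: str = ""
    year: int = 0
    pub_type: PubType = PubType.OTHER
    pub_subtype: Optional[str] = None
    relevance: Relevance = Relevance.UNLABELED

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusError("article id must be a non-empty string")
        object.__setattr__(self, "pub_type", PubType(self.pub_type))
        object.__setattr__(self, "relevance", Relevance(self.relevance))
        object.__setattr__(self, "mesh_headings", tuple(self.mesh_headings))
        object.__setattr__(self, "emtree_headings", tuple(self.emtree_headings))


@dataclass(frozen=True)
class LabeledCorpus:
    """An ordered collection of articles with a provenance note.

    Construction does not reject duplicate ids (``deduplicate`` must be able
    to accept corpora aggregated from several sources); readers that promise
    unique ids call :meth:`validate_unique_ids` themselves.
    """

    articles: tuple[Article, ...]
    provenance: str = ""
    removed_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "articles", tuple(self.articles))
        object.__setattr__(self, "removed_ids", tuple(self.removed_ids))

    def __len__(self) -> int:
        return len(self.articles)

    def __iter__(self) -> Iterator[Article]:
        return iter(self.articles)

    def validate_unique_ids(self) -> None:
        seen: set[str] = set()
        dups: list[str] = []
        for a in self.articles:
            if a.id in seen:
                dups.append(a.id)
            seen.add(a.id)
        if dups:
            raise CorpusError(f"duplicate article ids: {sorted(set(dups))}")

    def ids(self) -> list[str]:
        return [a.id for a in self.articles]

    def subset(self, relevance: Relevance) -> tuple[Article, ...]:
        return tuple(a for a in self.articles if a.relevance is relevance)

    @property
    def n_relevant(self) -> int:
        return len(self.subset(Relevance.RELEVANT))

    @property
    def n_non_relevant(self) -> int:
        return len(self.subset(Relevance.NON_RELEVANT))

    def prevalence(self) -> float:
        """Fraction of labeled articles that are relevant."""
        labeled = self.n_relevant + self.n_non_relevant
        if labeled == 0:
            raise CorpusError("corpus has no labeled articles")
        return self.n_relevant / labeled


@dataclass(frozen=True)
class SplitConfig:
    """Development/validation split: fraction assigned to development.

    The default 0.7 mirrors the conventional 70/30 split; a 2:1 ratio
    (fraction 2/3) is common as well.  Allocation within each relevance
    stratum is round-half-up of ``fraction × stratum size``.
    """

    development_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.development_fraction < 1.0:
            raise CorpusError("development_fraction must lie strictly in (0, 1)")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_PUBTYPE_REVIEW = {"review", "systematic review", "meta-analysis", "revw"}
_PUBTYPE_ARTICLE = {
    "journal article",
    "article",
    "clinical trial",
    "randomized controlled trial",
    "multicenter study",
    "comparative study",
    "observational study",
    "jour",
}


def _classify_pub_type(raw_types: Sequence[str]) -> tuple[PubType, Optional[str]]:
    """Collapse raw publication-type strings into the three-way grouping.

    Review outranks article (a record tagged both is a review); anything else
    (editorial, letter, note, comment, short survey...) is ``other`` with the
    raw string retained as subtype.
    """
    lowered = [t.strip().lower() for t in raw_types if t.strip()]
    if any(t in _PUBTYPE_REVIEW for t in lowered):
        return PubType.REVIEW, None
    if any(t in _PUBTYPE_ARTICLE for t in lowered):
        return PubType.ARTICLE, None
    subtype = lowered[0] if lowered else None
    return PubType.OTHER, subtype


def _parse_year(raw: str) -> int:
    for piece in str(raw).replace("/", " ").replace("-", " ").split():
        if piece.isdigit() and len(piece) == 4:
            return int(piece)
    return 0


_RELEVANCE_ALIASES = {
    "relevant": Relevance.RELEVANT,
    "1": Relevance.RELEVANT,
    "true": Relevance.RELEVANT,
    "yes": Relevance.RELEVANT,
    "non_relevant": Relevance.NON_RELEVANT,
    "non-relevant": Relevance.NON_RELEVANT,
    "nonrelevant": Relevance.NON_RELEVANT,
    "0": Relevance.NON_RELEVANT,
    "false": Relevance.NON_RELEVANT,
    "no": Relevance.NON_RELEVANT,
    "unlabeled": Relevance.UNLABELED,
    "": Relevance.UNLABELED,
}


def _coerce_relevance(raw) -> Relevance:
    if isinstance(raw, Relevance):
        return raw
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return Relevance.UNLABELED
    key = str(raw).strip().lower()
    if key not in _RELEVANCE_ALIASES:
        raise CorpusError(f"unrecognized relevance label {raw!r}")
    return _RELEVANCE_ALIASES[key]


def read_labels(path: str | Path) -> dict[str, Relevance]:
    """Read a sidecar label table: two delimited columns, id and relevance."""
    path = Path(path)
    labels: dict[str, Relevance] = {}
    with path.open(newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample else ","
        reader = csv.reader(fh, delimiter=delim)
        for row in reader:
            if not row or row[0].strip().lower() in {"id", "#id"}:
                continue
            if len(row) < 2:
                raise CorpusError(f"{path}: label row {row!r} lacks a relevance column")
            labels[row[0].strip()] = _coerce_relevance(row[1])
    return labels


def _read_medline_nbib(path: Path) -> list[Article]:
    from Bio import Medline

    articles = []
    with path.open() as fh:
        for rec in Medline.parse(fh):
            pmid = rec.get("PMID")
            if not pmid:
                raise CorpusError(f"{path}: record without PMID near article {len(articles) + 1}")
            pub_type, subtype = _classify_pub_type(rec.get("PT", []))
            ab = rec.get("AB")
            articles.append(
                Article(
                    id=str(pmid),
                    title=rec.get("TI", ""),
                    abstract=ab if ab is not None else None,
                    mesh_headings=tuple(h.lstrip("*") for h in rec.get("MH", [])),
                    journal=rec.get("JT", rec.get("TA", "")),
                    year=_parse_year(rec.get("DP", "")),
                    pub_type=pub_type,
                    pub_subtype=subtype,
                )
            )
    return articles


def _read_ris(path: Path) -> list[Article]:
    """Minimal RIS reader: ``XX  - value`` tag lines, records closed by ``ER``.

    Keyword (KW) entries are stored as Emtree-style headings — RIS exports
    from Embase carry index terms there.  Repeated TI/AB lines of one record
    are joined (RIS wraps long fields onto continuation lines).
    """
    articles: list[Article] = []
    current: dict[str, list[str]] = {}
    last_tag: Optional[str] = None

    def flush(lineno: int) -> None:
        nonlocal current
        if not current:
            return
        rid = (current.get("ID") or current.get("AN") or [""])[0].strip()
        if not rid:
            raise CorpusError(f"{path}:{lineno}: RIS record without ID/AN tag")
        pub_type, subtype = _classify_pub_type(current.get("TY", []) + current.get("M3", []))
        abstract_parts = current.get("AB") or current.get("N2")
        articles.append(
            Article(
                id=rid,
                title=" ".join(current.get("TI", current.get("T1", []))),
                abstract=" ".join(abstract_parts) if abstract_parts else None,
                emtree_headings=tuple(current.get("KW", [])),
                journal=(current.get("JO") or current.get("JF") or current.get("T2") or [""])[0],
                year=_parse_year((current.get("PY") or current.get("Y1") or [""])[0]),
                pub_type=pub_type,
                pub_subtype=subtype,
            )
        )
        current = {}

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if len(line) >= 6 and line[2:6] == "  - " and line[:2].strip():
                tag, value = line[:2], line[6:].strip()
                if tag == "ER":
                    flush(lineno)
                    last_tag = None
                else:
                    current.setdefault(tag, []).append(value)
                    last_tag = tag
            elif last_tag is not None:
                current[last_tag][-1] += " " + line.strip()
            else:
                raise CorpusError(f"{path}:{lineno}: malformed RIS line {line!r}")
    flush(-1)
    return articles


_DELIMITED_COLUMNS = {
    "id", "title", "abstract", "mesh_headings", "emtree_headings",
    "journal", "year", "pub_type", "pub_subtype", "relevance",
}


def _split_headings(cell) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell) == "":
        return ()
    return tuple(h.strip() for h in str(cell).split(";") if h.strip())


def _read_delimited(path: Path) -> list[Article]:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str})
    if "id" not in df.columns:
        raise CorpusError(f"{path}: delimited corpus must have an 'id' column")
    unknown = set(df.columns) - _DELIMITED_COLUMNS
    if unknown:
        raise CorpusError(f"{path}: unrecognized columns {sorted(unknown)}")
    articles = []
    for _, row in df.iterrows():
        ab = row.get("abstract")
        absent = ab is None or (isinstance(ab, float) and np.isnan(ab))
        articles.append(
            Article(
                id=str(row["id"]),
                title="" if pd.isna(row.get("title")) else str(row.get("title", "")),
                abstract=None if absent else str(ab),
                mesh_headings=_split_headings(row.get("mesh_headings")),
                emtree_headings=_split_headings(row.get("emtree_headings")),
                journal="" if pd.isna(row.get("journal")) else str(row.get("journal", "")),
                year=0 if pd.isna(row.get("year")) else int(row.get("year", 0)),
                pub_type=PubType(str(row.get("pub_type", "other")))
                if not pd.isna(row.get("pub_type"))
                else PubType.OTHER,
                pub_subtype=None if pd.isna(row.get("pub_subtype")) else str(row.get("pub_subtype")),
                relevance=_coerce_relevance(row.get("relevance")),
            )
        )
    return articles


def read_corpus(
    path: str | Path,
    format: str,
    labels: Optional[str | Path | Mapping[str, Relevance]] = None,
    provenance: Optional[str] = None,
) -> LabeledCorpus:
    """Read a corpus from ``path`` in the named format.

    ``format`` is one of ``medline_nbib``, ``ris`` or ``delimited``.
    ``labels`` optionally supplies relevance labels from a sidecar two-column
    table (path) or a mapping, keyed by article id; in-file labels (delimited
    ``relevance`` column) are used when no sidecar is given.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"corpus file not found: {path}")
    readers = {
        "medline_nbib": _read_medline_nbib,
        "ris": _read_ris,
        "delimited": _read_delimited,
    }
    if format not in readers:
        raise CorpusError(f"unknown corpus format {format!r}; choose from {sorted(readers)}")
    articles = readers[format](path)

    if labels is not None:
        table = read_labels(labels) if isinstance(labels, (str, Path)) else dict(labels)
        articles = [
            replace(a, relevance=table.get(a.id, a.relevance)) for a in articles
        ]

    corpus = LabeledCorpus(tuple(articles), provenance=provenance or f"{format}:{path.name}")
    corpus.validate_unique_ids()
    return corpus


def write_corpus(corpus: LabeledCorpus, path: str | Path) -> None:
    """Write a corpus as a tab-separated table (the ``delimited`` format)."""
    rows = []
    for a in corpus:
        rows.append(
            {
                "id": a.id,
                "title": a.title,
                "abstract": a.abstract if a.abstract is not None else np.nan,
                "mesh_headings": ";".join(a.mesh_headings),
                "emtree_headings": ";".join(a.emtree_headings),
                "journal": a.journal,
                "year": a.year,
                "pub_type": a.pub_type.value,
                "pub_subtype": a.pub_subtype or "",
                "relevance": a.relevance.value,
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Deduplication, splitting, summaries
# ---------------------------------------------------------------------------

def deduplicate(corpus: LabeledCorpus, key: str = "id") -> LabeledCorpus:
    """Drop exact-key duplicates, keeping the first occurrence in input order.

    ``key`` is ``id`` or ``title_year`` (case-folded title plus year, for
    merging exports that do not share an id space).  Removed ids are attached
    to the returned corpus as ``removed_ids``.
    """
    if key not in {"id", "title_year"}:
        raise CorpusError(f"unknown deduplication key {key!r}")
    seen: set = set()
    kept: list[Article] = []
    removed: list[str] = []
    for a in corpus:
        k = a.id if key == "id" else (a.title.strip().lower(), a.year)
        if k in seen:
            removed.append(a.id)
        else:
            seen.add(k)
            kept.append(a)
    return LabeledCorpus(tuple(kept), provenance=corpus.provenance, removed_ids=tuple(removed))


def stratified_split(
    corpus: LabeledCorpus, config: SplitConfig
) -> tuple[LabeledCorpus, LabeledCorpus]:
    """Randomly split the corpus into development and validation sets.

    Randomization is stratified on the relevance label so both sets preserve
    class balance; within each stratum the development set receives
    round-half-up(fraction × stratum size) articles chosen uniformly at
    random.  The same seed always yields the same membership, and the two
    outputs partition the input exactly.
    """
    strata: dict[Relevance, list[int]] = {}
    for i, a in enumerate(corpus):
        strata.setdefault(a.relevance, []).append(i)
    if Relevance.RELEVANT not in strata or Relevance.NON_RELEVANT not in strata:
        raise CorpusError("stratified_split requires both relevant and non-relevant articles")

    rng = np.random.default_rng(config.seed)
    dev_idx: set[int] = set()
    for rel in sorted(strata, key=lambda r: r.value):  # deterministic stratum order
        idx = strata[rel]
        if len(idx) < 2:
            raise CorpusError(
                f"stratum {rel.value!r} has {len(idx)} article(s); need at least 2 to split"
            )
        k = int(round_half_up(config.development_fraction * len(idx)))
        chosen = rng.permutation(len(idx))[:k]
        dev_idx.update(idx[j] for j in chosen)

    dev = [a for i, a in enumerate(corpus) if i in dev_idx]
    val = [a for i, a in enumerate(corpus) if i not in dev_idx]
    tag = f"split f={config.development_fraction} seed={config.seed}"
    return (
        LabeledCorpus(tuple(dev), provenance=f"{corpus.provenance} [development {tag}]"),
        LabeledCorpus(tuple(val), provenance=f"{corpus.provenance} [validation {tag}]"),
    )


@dataclass(frozen=True)
class CorpusSummary:
    """Characteristics of a labeled corpus, by relevance class.

    Each mapping goes ``class -> {category: (count, percent-or-None)}``;
    percentages are within-class, rounded half-up to one decimal, and ``None``
    when the class is empty.  ``prevalence_percent`` is the relevant fraction
    of the whole corpus as a percentage with two decimals.
    """

    totals: Mapping[str, int]
    journals: Mapping[str, Mapping[str, tuple[int, Optional[float]]]]
    periods: Mapping[str, Mapping[str, tuple[int, Optional[float]]]]
    pub_types: Mapping[str, Mapping[str, tuple[int, Optional[float]]]]
    prevalence_percent: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for section, table in (
            ("journal", self.journals),
            ("period", self.periods),
            ("pub_type", self.pub_types),
        ):
            for cls, cats in table.items():
                for cat, (count, pct) in cats.items():
                    rows.append(
                        {"section": section, "class": cls, "category": cat,
                         "count": count, "percent": pct}
                    )
        return pd.DataFrame(rows)


def _period_label(year: int, period_length: int, anchor: int) -> str:
    if year <= 0:
        return "unknown"
    start = anchor + ((year - anchor) // period_length) * period_length
    return f"{start}-{start + period_length - 1}"


def summarize(corpus: LabeledCorpus, period_length: int = 5, period_anchor: int = 2011) -> CorpusSummary:
    """Tabulate per-journal, per-period and per-publication-type counts.

    Percentages are computed within each relevance class (each class column
    sums to 100 up to rounding).  All articles must be labeled.
    """
    if any(a.relevance is Relevance.UNLABELED for a in corpus):
        bad = [a.id for a in corpus if a.relevance is Relevance.UNLABELED][:5]
        raise CorpusError(f"summarize requires a fully labeled corpus; unlabeled ids include {bad}")

    classes = {
        Relevance.RELEVANT.value: corpus.subset(Relevance.RELEVANT),
        Relevance.NON_RELEVANT.value: corpus.subset(Relevance.NON_RELEVANT),
    }
    totals = {cls: len(arts) for cls, arts in classes.items()}

    def tabulate(keyfun) -> dict[str, dict[str, tuple[int, Optional[float]]]]:
        out: dict[str, dict[str, tuple[int, Optional[float]]]] = {}
        categories = sorted({keyfun(a) for arts in classes.values() for a in arts})
        for cls, arts in classes.items():
            n = len(arts)
            counts = {c: 0 for c in categories}
            for a in arts:
                counts[keyfun(a)] += 1
            out[cls] = {
                c: (k, round_half_up(100.0 * k / n, 1) if n else None)
                for c, k in counts.items()
            }
        return out

    labeled_total = sum(totals.values())
    prevalence = (
        round_half_up(100.0 * totals[Relevance.RELEVANT.value] / labeled_total, 2)
        if labeled_total
        else None
    )
    return CorpusSummary(
        totals=totals,
        journals=tabulate(lambda a: a.journal or "unknown"),
        periods=tabulate(lambda a: _period_label(a.year, period_length, period_anchor)),
        pub_types=tabulate(lambda a: a.pub_type.value),
        prevalence_percent=prevalence,
    )
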