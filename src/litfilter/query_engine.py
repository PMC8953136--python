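"""Boolean search-filter queries: parsing, evaluation, serialization.

Search filters are boolean queries over bibliographic records, written in a
database-specific dialect.  Two dialects are supported:

* **pubmed** — double-quoted terms/phrases with a bracketed field tag, e.g.
  ``"deprescrib*"[Title/Abstract]`` or ``"deprescriptions"[MeSH Terms]``.
* **embase** — single-quoted terms with ``:ab,ti`` (title/abstract) or
  ``/de`` (Emtree heading) suffixes, plus the order-free proximity operator
  ``NEAR/n``, e.g. ``((review* NEAR/3 medication*):ab,ti)``.

Queries are parsed into a small immutable AST (:class:`TermAtom`,
:class:`PhraseAtom`, :class:`HeadingAtom`, :class:`ProximityAtom`,
:class:`And`, :class:`Or`) and evaluated against :class:`~litfilter.corpus_io.Article`
records with documented, testable semantics:

* text is lowercased and tokenized into maximal runs of letters and digits
  (hyphens, slashes and other punctuation separate tokens, so the phrase
  ``"dose reduction"`` matches ``dose-reduction``);
* a truncated term (trailing ``*``) prefix-matches tokens;
* phrases match contiguous token sequences; headings match the record's
  heading list exactly (case-insensitive, no vocabulary-tree explosion);
* ``NEAR/n`` is satisfied when a left-term position and a right-term
  position differ by at most *n* tokens, in either order;
* an absent abstract contributes no tokens.

The two published deprescribing filters are bundled verbatim as
``MEDLINE_FILTER`` (PubMed dialect) and ``EMBASE_FILTER`` (Embase dialect).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

from .corpus_io import Article, LabeledCorpus


class QueryError(ValueError):
    """Base class for query construction/serialization errors."""


class ParseError(QueryError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UnsupportedFeatureError(QueryError):
    """A construct that the target dialect cannot express."""


class FieldSpec(str, enum.Enum):
    TITLE_ABSTRACT = "title_abstract"
    HEADING = "heading"


DIALECTS = ("pubmed", "embase")

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split into maximal runs of letters/digits."""
    return _TOKEN_RE.findall(text.lower())


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermAtom:
    """A single token pattern; ``truncated`` makes it a prefix match."""

    token: str
    truncated: bool = False
    field: Optional[str] = FieldSpec.TITLE_ABSTRACT.value

    def __post_init__(self) -> None:
        if not self.token:
            raise QueryError("term token must be non-empty")
        if "*" in self.token:
            raise QueryError("truncation is expressed via the 'truncated' flag, not '*' in the token")


@dataclass(frozen=True)
class PhraseAtom:
    """A contiguous token sequence; optional truncation on the last token."""

    tokens: tuple[str, ...]
    truncated: bool = False
    field: Optional[str] = FieldSpec.TITLE_ABSTRACT.value

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        if len(self.tokens) < 2:
            raise QueryError("a phrase needs at least two tokens (use TermAtom otherwise)")
        if any("*" in t or not t for t in self.tokens):
            raise QueryError("phrase tokens must be non-empty and '*'-free")


@dataclass(frozen=True)
class HeadingAtom:
    """An exact subject-heading match against the record's heading list."""

    heading: str
    vocabulary: str  # 'mesh' | 'emtree'

    def __post_init__(self) -> None:
        if self.vocabulary not in {"mesh", "emtree"}:
            raise QueryError(f"unknown heading vocabulary {self.vocabulary!r}")
        if not self.heading:
            raise QueryError("heading must be non-empty")


@dataclass(frozen=True)
class ProximityAtom:
    """Order-free proximity: some left-alternative and right-alternative token
    positions differ by at most ``max_distance`` (Embase ``NEAR/n``).

    Each side is one or more alternative terms; the atom is true when any
    pair of alternatives satisfies the distance bound.
    """

    left: tuple[TermAtom, ...]
    right: tuple[TermAtom, ...]
    max_distance: int
    field: Optional[str] = FieldSpec.TITLE_ABSTRACT.value

    def __post_init__(self) -> None:
        object.__setattr__(self, "left", tuple(self.left))
        object.__setattr__(self, "right", tuple(self.right))
        if not self.left or not self.right:
            raise QueryError("proximity requires terms on both sides")
        if self.max_distance < 0:
            raise QueryError("proximity distance must be non-negative")


@dataclass(frozen=True)
class And:
    children: tuple["QueryNode", ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(self.children))
        if len(self.children) < 2:
            raise QueryError("And requires at least two children")


@dataclass(frozen=True)
class Or:
    children: tuple["QueryNode", ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(self.children))
        if len(self.children) < 2:
            raise QueryError("Or requires at least two children")


QueryNode = Union[TermAtom, PhraseAtom, HeadingAtom, ProximityAtom, And, Or]


def or_all(nodes: Sequence[QueryNode]) -> QueryNode:
    """Disjunction of ``nodes``; a single node is returned as-is."""
    nodes = list(nodes)
    if not nodes:
        raise QueryError("cannot build an empty disjunction")
    return nodes[0] if len(nodes) == 1 else Or(tuple(nodes))


# ---------------------------------------------------------------------------
# Lexing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Tok:
    kind: str
    value: str
    pos: int


_WS_RE = re.compile(r"\s+")
_PUBMED_PATTERNS = [
    ("QUOTED", re.compile(r'"([^"]*)"')),
    ("FIELD", re.compile(r"\[([^\[\]]*)\]")),
    ("LPAREN", re.compile(r"\(")),
    ("RPAREN", re.compile(r"\)")),
    ("WORD", re.compile(r'[^\s()\[\]"]+')),
]
_EMBASE_PATTERNS = [
    ("QUOTED", re.compile(r"['‘’]([^'‘’]*)['‘’]")),
    ("FIELD_ABTI", re.compile(r":ab,ti")),
    ("FIELD_DE", re.compile(r"/de\b")),
    ("NEAR", re.compile(r"NEAR/(\d+)", re.IGNORECASE)),
    ("LPAREN", re.compile(r"\(")),
    ("RPAREN", re.compile(r"\)")),
    ("WORD", re.compile(r"[^\s()'‘’:/]+")),
]


def _lex(text: str, dialect: str) -> list[_Tok]:
    patterns = _PUBMED_PATTERNS if dialect == "pubmed" else _EMBASE_PATTERNS
    toks: list[_Tok] = []
    i, n = 0, len(text)
    while i < n:
        m = _WS_RE.match(text, i)
        if m:
            i = m.end()
            continue
        for kind, pat in patterns:
            m = pat.match(text, i)
            if m:
                value = m.group(1) if pat.groups else m.group(0)
                toks.append(_Tok(kind, value, i))
                i = m.end()
                break
        else:
            ch = text[i]
            if ch in "\"'‘’":
                raise ParseError("unterminated quote", i)
            if ch == "[":
                raise ParseError("unterminated field tag", i)
            raise ParseError(f"unexpected character {ch!r}", i)
    return toks


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_PUBMED_FIELDS = {"title/abstract": "title_abstract", "mesh terms": "mesh"}


class _Parser:
    """Recursive-descent parser shared by the two dialects.

    Precedence: parentheses > NEAR (embase) > AND > OR; bare sequences
    associate left, and parenthesized groups are preserved as explicit AST
    nodes (no flattening across parentheses), so printed grouping survives a
    parse/serialize round trip.
    """

    def __init__(self, text: str, dialect: str):
        self.text = text
        self.dialect = dialect
        self.toks = _lex(text, dialect)
        self.i = 0

    def peek(self) -> Optional[_Tok]:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> _Tok:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of query", len(self.text))
        self.i += 1
        return tok

    def at_keyword(self, word: str) -> bool:
        tok = self.peek()
        return tok is not None and tok.kind == "WORD" and tok.value.upper() == word

    def parse(self) -> QueryNode:
        node = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise ParseError(f"unexpected trailing {tok.value!r}", tok.pos)
        return node

    def parse_or(self) -> QueryNode:
        parts = [self.parse_and()]
        while self.at_keyword("OR"):
            self.next()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and(self) -> QueryNode:
        parts = [self.parse_operand()]
        while self.at_keyword("AND"):
            self.next()
            parts.append(self.parse_operand())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_operand(self) -> QueryNode:
        node = self.parse_primary()
        tok = self.peek()
        if tok is not None and tok.kind == "NEAR":
            if self.dialect != "embase":
                raise ParseError("NEAR is an Embase-only operator", tok.pos)
            self.next()
            right = self.parse_primary()
            return ProximityAtom(
                left=self._as_alternatives(node, tok.pos),
                right=self._as_alternatives(right, tok.pos),
                max_distance=int(tok.value),
                field=None,
            )
        return node

    @staticmethod
    def _as_alternatives(node: QueryNode, pos: int) -> tuple[TermAtom, ...]:
        if isinstance(node, TermAtom):
            return (replace(node, field=None),)
        if isinstance(node, Or) and all(isinstance(c, TermAtom) for c in node.children):
            return tuple(replace(c, field=None) for c in node.children)
        raise ParseError("a NEAR operand must be a term or an OR-group of terms", pos)

    def parse_primary(self) -> QueryNode:
        tok = self.peek()
        if tok is None:
            raise ParseError("unexpected end of query", len(self.text))
        if tok.kind == "LPAREN":
            self.next()
            node = self.parse_or()
            closer = self.peek()
            if closer is None or closer.kind != "RPAREN":
                raise ParseError("unbalanced parenthesis", tok.pos)
            self.next()
            return self._maybe_field_suffix(node)
        if tok.kind == "QUOTED":
            self.next()
            return self._quoted_atom(tok)
        if tok.kind == "WORD":
            if tok.value.upper() in {"OR", "AND"}:
                raise ParseError(f"operator {tok.value!r} where a term was expected", tok.pos)
            if self.dialect == "embase":
                self.next()
                return self._bare_term(tok)
            raise ParseError(
                f"bare word {tok.value!r}: PubMed terms must be double-quoted", tok.pos
            )
        if tok.kind == "RPAREN":
            raise ParseError("unbalanced parenthesis", tok.pos)
        raise ParseError(f"unexpected {tok.value!r}", tok.pos)

    def _maybe_field_suffix(self, node: QueryNode) -> QueryNode:
        tok = self.peek()
        if self.dialect == "embase" and tok is not None and tok.kind == "FIELD_ABTI":
            self.next()
            return _apply_field(node, FieldSpec.TITLE_ABSTRACT.value, tok.pos)
        return node

    @staticmethod
    def _split_quoted(raw: str, pos: int) -> tuple[list[str], bool]:
        content = raw.strip().lower()
        if not content:
            raise ParseError("empty quoted term", pos)
        truncated = content.endswith("*")
        content = content.rstrip("*")
        if "*" in content:
            raise ParseError("truncation '*' is only allowed at the end of a term", pos)
        tokens = content.split()
        if not tokens or any(not t for t in tokens):
            raise ParseError(f"malformed quoted term {raw!r}", pos)
        return tokens, truncated

    def _quoted_atom(self, tok: _Tok) -> QueryNode:
        suffix = self.peek()
        if self.dialect == "pubmed":
            if suffix is None or suffix.kind != "FIELD":
                raise ParseError("a quoted term must carry a [field] tag", tok.pos)
            self.next()
            field = _PUBMED_FIELDS.get(suffix.value.strip().lower())
            if field is None:
                raise ParseError(f"unknown field tag [{suffix.value}]", suffix.pos)
            if field == "mesh":
                return HeadingAtom(tok.value.strip().lower(), vocabulary="mesh")
            return self._text_atom(tok, FieldSpec.TITLE_ABSTRACT.value)
        # embase
        if suffix is None or suffix.kind not in {"FIELD_ABTI", "FIELD_DE"}:
            raise ParseError("a quoted term must carry :ab,ti or /de", tok.pos)
        self.next()
        if suffix.kind == "FIELD_DE":
            return HeadingAtom(tok.value.strip().lower(), vocabulary="emtree")
        return self._text_atom(tok, FieldSpec.TITLE_ABSTRACT.value)

    def _text_atom(self, tok: _Tok, field: str) -> QueryNode:
        tokens, truncated = self._split_quoted(tok.value, tok.pos)
        if len(tokens) == 1:
            return TermAtom(tokens[0], truncated=truncated, field=field)
        return PhraseAtom(tuple(tokens), truncated=truncated, field=field)

    def _bare_term(self, tok: _Tok) -> TermAtom:
        word = tok.value.lower()
        truncated = word.endswith("*")
        word = word.rstrip("*")
        if not word or "*" in word or not _TOKEN_RE.fullmatch(word):
            raise ParseError(f"malformed term {tok.value!r}", tok.pos)
        return TermAtom(word, truncated=truncated, field=None)


def _apply_field(node: QueryNode, fieldvalue: str, pos: int) -> QueryNode:
    """Assign a field suffix to every field-less text atom in ``node``.

    Proximity alternatives keep field None (the field lives on the
    ProximityAtom itself); headings inside a :ab,ti group are rejected.
    """
    if isinstance(node, TermAtom) or isinstance(node, PhraseAtom):
        return replace(node, field=fieldvalue) if node.field is None else node
    if isinstance(node, ProximityAtom):
        return replace(node, field=fieldvalue) if node.field is None else node
    if isinstance(node, HeadingAtom):
        raise ParseError("a heading cannot take a :ab,ti suffix", pos)
    if isinstance(node, (And, Or)):
        cls = type(node)
        return cls(tuple(_apply_field(c, fieldvalue, pos) for c in node.children))
    raise QueryError(f"unknown node {node!r}")


def _check_fields(node: QueryNode, text: str) -> None:
    if isinstance(node, (TermAtom, PhraseAtom, ProximityAtom)):
        if node.field is None:
            raise ParseError("term lacks a field tag/suffix", len(text))
    elif isinstance(node, (And, Or)):
        for c in node.children:
            _check_fields(c, text)


def parse_query(text: str, dialect: str) -> QueryNode:
    """Parse a query string in the named dialect into an AST."""
    if dialect not in DIALECTS:
        raise QueryError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    if not text or not text.strip():
        raise ParseError("empty query", 0)
    node = _Parser(text, dialect).parse()
    _check_fields(node, text)
    return node


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

class _ArticleView:
    """Tokenized article: built once, evaluated against many queries."""

    __slots__ = ("title_tokens", "abstract_tokens", "mesh", "emtree", "article")

    def __init__(self, article: Article):
        self.article = article
        self.title_tokens = tokenize(article.title)
        self.abstract_tokens = tokenize(article.abstract) if article.abstract is not None else []
        self.mesh = {h.casefold() for h in article.mesh_headings}
        self.emtree = {h.casefold() for h in article.emtree_headings}


def _term_matches(token: str, term: TermAtom) -> bool:
    return token.startswith(term.token) if term.truncated else token == term.token


def _positions(tokens: list[str], alts: Sequence[TermAtom]) -> list[int]:
    return [i for i, t in enumerate(tokens) if any(_term_matches(t, a) for a in alts)]


def _phrase_in(tokens: list[str], atom: PhraseAtom) -> bool:
    k = len(atom.tokens)
    head, last = atom.tokens[:-1], atom.tokens[-1]
    for i in range(len(tokens) - k + 1):
        if tuple(tokens[i : i + k - 1]) != head:
            continue
        tail = tokens[i + k - 1]
        if tail.startswith(last) if atom.truncated else tail == last:
            return True
    return False


def _eval(node: QueryNode, view: _ArticleView) -> bool:
    if isinstance(node, TermAtom):
        return any(
            any(_term_matches(t, node) for t in toks)
            for toks in (view.title_tokens, view.abstract_tokens)
        )
    if isinstance(node, PhraseAtom):
        return _phrase_in(view.title_tokens, node) or _phrase_in(view.abstract_tokens, node)
    if isinstance(node, HeadingAtom):
        pool = view.mesh if node.vocabulary == "mesh" else view.emtree
        return node.heading.casefold() in pool
    if isinstance(node, ProximityAtom):
        for toks in (view.title_tokens, view.abstract_tokens):
            lp = _positions(toks, node.left)
            if not lp:
                continue
            rp = _positions(toks, node.right)
            if any(abs(i - j) <= node.max_distance for i in lp for j in rp):
                return True
        return False
    if isinstance(node, And):
        return all(_eval(c, view) for c in node.children)
    if isinstance(node, Or):
        return any(_eval(c, view) for c in node.children)
    raise QueryError(f"unknown node {node!r}")


def evaluate(node: QueryNode, article: Article) -> bool:
    """True iff the query matches the article under the documented semantics."""
    return _eval(node, _ArticleView(article))


@dataclass(frozen=True)
class RetrievalResult:
    """Ids retrieved by a query, with per-relevance-class counts."""

    ids: frozenset[str]
    class_counts: dict[str, int]

    @property
    def n_relevant(self) -> int:
        return self.class_counts.get("relevant", 0)

    @property
    def n_non_relevant(self) -> int:
        return self.class_counts.get("non_relevant", 0)

    def __len__(self) -> int:
        return len(self.ids)


class CorpusIndex:
    """Tokenizes a corpus once so many queries can be run against it cheaply."""

    def __init__(self, corpus: LabeledCorpus):
        self.corpus = corpus
        self.views = [_ArticleView(a) for a in corpus]

    def retrieve(self, node: QueryNode) -> RetrievalResult:
        ids = []
        counts: dict[str, int] = {}
        for v in self.views:
            if _eval(node, v):
                ids.append(v.article.id)
                key = v.article.relevance.value
                counts[key] = counts.get(key, 0) + 1
        return RetrievalResult(ids=frozenset(ids), class_counts=counts)


def retrieve(node: QueryNode, corpus: LabeledCorpus) -> RetrievalResult:
    """Evaluate the query on every article; deterministic in corpus order."""
    return CorpusIndex(corpus).retrieve(node)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _ser_term_body(term: TermAtom) -> str:
    return term.token + ("*" if term.truncated else "")


def _ser_prox_side(alts: tuple[TermAtom, ...]) -> str:
    if len(alts) == 1:
        return _ser_term_body(alts[0])
    return "(" + " OR ".join(_ser_term_body(a) for a in alts) + ")"


def _ser(node: QueryNode, dialect: str) -> str:
    if isinstance(node, TermAtom):
        if node.field is None:
            raise QueryError("cannot serialize a term without a field")
        body = _ser_term_body(node)
        return f'"{body}"[Title/Abstract]' if dialect == "pubmed" else f"'{body}':ab,ti"
    if isinstance(node, PhraseAtom):
        if node.field is None:
            raise QueryError("cannot serialize a phrase without a field")
        body = " ".join(node.tokens) + ("*" if node.truncated else "")
        return f'"{body}"[Title/Abstract]' if dialect == "pubmed" else f"'{body}':ab,ti"
    if isinstance(node, HeadingAtom):
        if dialect == "pubmed":
            if node.vocabulary != "mesh":
                raise UnsupportedFeatureError("PubMed queries cannot address Emtree headings")
            return f'"{node.heading}"[MeSH Terms]'
        if node.vocabulary != "emtree":
            raise UnsupportedFeatureError("Embase queries cannot address MeSH headings")
        return f"'{node.heading}'/de"
    if isinstance(node, ProximityAtom):
        if dialect == "pubmed":
            raise UnsupportedFeatureError("PubMed has no proximity (NEAR) operator")
        if node.field is None:
            raise QueryError("cannot serialize a proximity atom without a field")
        inner = f"{_ser_prox_side(node.left)} NEAR/{node.max_distance} {_ser_prox_side(node.right)}"
        return f"(({inner}):ab,ti)"
    if isinstance(node, (And, Or)):
        sep = " AND " if isinstance(node, And) else " OR "
        parts = []
        for c in node.children:
            s = _ser(c, dialect)
            parts.append(f"({s})" if isinstance(c, (And, Or)) else s)
        return sep.join(parts)
    raise QueryError(f"unknown node {node!r}")


def serialize(node: QueryNode, dialect: str) -> str:
    """Render the AST in the target dialect.

    ``parse_query(serialize(x), dialect)`` is structurally identical to ``x``;
    the bundled filters serialize byte-identically to their canonical strings.
    """
    if dialect not in DIALECTS:
        raise QueryError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    return _ser(node, dialect)


# ---------------------------------------------------------------------------
# Bundled filters (canonical strings)
# ---------------------------------------------------------------------------

#: Published deprescribing search filter for Medline via PubMed.
MEDLINE_FILTER = (
    '"deprescrib*"[Title/Abstract] OR "deprescriptions"[MeSH Terms] OR '
    '(("medication*"[Title/Abstract] OR "prescribing"[Title/Abstract]) AND '
    '"inappropriate"[Title/Abstract]) OR "polypharmacy"[Title/Abstract] OR '
    '"discontinu*"[Title/Abstract] OR ("withdraw*"[Title/Abstract] AND '
    '"medication*"[Title/Abstract]) OR (("medication*"[Title/Abstract] OR '
    '"drugs"[Title/Abstract] OR "prescribing"[Title/Abstract] OR '
    '"inappropriate"[Title/Abstract]) AND "reduc*"[Title/Abstract]) OR '
    '"inappropriate prescribing"[MeSH Terms] OR ("review*"[Title/Abstract] AND '
    '"medication"[Title/Abstract]) OR ("dose reduction"[Title/Abstract] OR '
    '"taper*"[Title/Abstract])'
)

#: Published deprescribing search filter for Embase via Embase.com
#: (stored with straight quotes; the parser also accepts typographic quotes).
EMBASE_FILTER = (
    "'deprescrib*':ab,ti OR ((review* NEAR/3 medication*):ab,ti) OR "
    "(((medication* OR medicines OR prescribing) NEAR/4 inappropriate):ab,ti) OR "
    "'potentially inappropriate':ab,ti OR ((reduc* NEAR/5 medication*):ab,ti) OR "
    "'polypharmacy':ab,ti OR 'discontinu*':ab,ti OR 'withdraw*':ab,ti OR "
    "((reducing NEAR/1 (drug* OR inappropriate OR frid)):ab,ti) OR "
    "'polypharmacy'/de OR 'medication therapy management'/de OR "
    "'dose reduction':ab,ti OR 'taper*':ab,ti OR 'drug withdrawal'/de OR "
    "'deprescription'/de OR 'inappropriate prescribing'/de"
)


def load_medline_filter() -> QueryNode:
    """The bundled Medline/PubMed deprescribing filter, parsed."""
    return parse_query(MEDLINE_FILTER, "pubmed")


def load_embase_filter() -> QueryNode:
    """The bundled Embase deprescribing filter, parsed."""
    return parse_query(EMBASE_FILTER, "embase")
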