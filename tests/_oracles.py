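"""Independent oracles used by the test suite.

Everything here deliberately avoids the library's own evaluation/CI code
paths: query matching is re-derived from regex scans over the raw field
text, Clopper–Pearson bounds from direct bisection of binomial tails, and
best-subset sensitivity from exhaustive enumeration.
"""

from __future__ import annotations

import itertools
import re

import numpy as np
from scipy import stats as sps

from litfilter.query_engine import (
    And,
    HeadingAtom,
    Or,
    PhraseAtom,
    ProximityAtom,
    TermAtom,
)

_B = r"(?<![a-z0-9])"
_E = r"(?![a-z0-9])"


def _term_regex(token: str, truncated: bool) -> str:
    return _B + re.escape(token) + (r"[a-z0-9]*" + _E if truncated else _E)


def _field_texts(article):
    texts = [article.title or ""]
    if article.abstract is not None:
        texts.append(article.abstract)
    return [t.lower() for t in texts]


def _token_index_positions(text: str, pattern: str) -> list[int]:
    """Token index = number of [a-z0-9]+ runs strictly before the match."""
    token_starts = [m.start() for m in re.finditer(r"[a-z0-9]+", text)]
    out = []
    for m in re.finditer(pattern, text):
        out.append(sum(1 for s in token_starts if s < m.start()))
    return out


def regex_evaluate(node, article) -> bool:
    """Regex re-implementation of query semantics over the raw field text."""
    if isinstance(node, TermAtom):
        pat = _term_regex(node.token, node.truncated)
        return any(re.search(pat, t) for t in _field_texts(article))
    if isinstance(node, PhraseAtom):
        parts = [_B + re.escape(t) for t in node.tokens]
        joined = r"[^a-z0-9]+".join(
            re.escape(t) for t in node.tokens[:-1]
        )
        last = re.escape(node.tokens[-1]) + (r"[a-z0-9]*" if node.truncated else "")
        pat = _B + (joined + r"[^a-z0-9]+" if joined else "") + last + (
            "" if node.truncated else _E
        )
        return any(re.search(pat, t) for t in _field_texts(article))
    if isinstance(node, HeadingAtom):
        pool = article.mesh_headings if node.vocabulary == "mesh" else article.emtree_headings
        return any(h.lower() == node.heading.lower() for h in pool)
    if isinstance(node, ProximityAtom):
        for text in _field_texts(article):
            lp = []
            for alt in node.left:
                lp += _token_index_positions(text, _term_regex(alt.token, alt.truncated))
            rp = []
            for alt in node.right:
                rp += _token_index_positions(text, _term_regex(alt.token, alt.truncated))
            if any(abs(i - j) <= node.max_distance for i in lp for j in rp):
                return True
        return False
    if isinstance(node, And):
        return all(regex_evaluate(c, article) for c in node.children)
    if isinstance(node, Or):
        return any(regex_evaluate(c, article) for c in node.children)
    raise TypeError(node)


def bisect_clopper_pearson(x: int, n: int, level: float = 0.95, iters: int = 60):
    """CI bounds by direct bisection of the binomial tail probabilities."""
    alpha = 1.0 - level

    def solve(f, lo, hi):
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            if f(mid):
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    if x == 0:
        lower = 0.0
    else:
        # P(X >= x; p) increases in p; lower bound where it equals alpha/2
        lower = solve(lambda p: 1.0 - sps.binom.cdf(x - 1, n, p) < alpha / 2.0, 0.0, 1.0)
    if x == n:
        upper = 1.0
    else:
        # P(X <= x; p) decreases in p; upper bound where it equals alpha/2
        upper = solve(lambda p: sps.binom.cdf(x, n, p) > alpha / 2.0, 0.0, 1.0)
    return lower, upper


def best_subset_sensitivity(candidate_rel_sets, n_relevant: int) -> float:
    """Maximum sensitivity over every non-empty OR-subset of candidates."""
    best = 0
    for r in range(1, len(candidate_rel_sets) + 1):
        for combo in itertools.combinations(candidate_rel_sets, r):
            best = max(best, len(frozenset().union(*combo)))
    return best / n_relevant


# ---------------------------------------------------------------------------
# Random article / AST generation for agreement checks
# ---------------------------------------------------------------------------

_VOCAB = [
    "deprescribing", "deprescribed", "medication", "medications", "review",
    "reviews", "polypharmacy", "inappropriate", "withdrawal", "dose",
    "reduction", "taper", "tapering", "older", "adults", "trial", "drug",
    "drugs", "stopping", "use",
]
_HEADINGS = ["deprescriptions", "inappropriate prescribing", "drug withdrawal"]
_PUNCT = [" ", " ", " ", ", ", "; ", "-", "/", ". "]


def random_article(rng, i: int):
    from litfilter.corpus_io import Article

    def text(n_tokens):
        parts = []
        for _ in range(n_tokens):
            parts.append(rng.choice(_VOCAB))
            parts.append(rng.choice(_PUNCT))
        return "".join(parts)

    return Article(
        id=f"r{i}",
        title=text(rng.randint(0, 8)),
        abstract=text(rng.randint(0, 40)) if rng.random() < 0.8 else None,
        mesh_headings=tuple(h for h in _HEADINGS if rng.random() < 0.3),
        emtree_headings=tuple(h for h in _HEADINGS if rng.random() < 0.3),
    )


def random_atom(rng):
    kind = rng.random()
    if kind < 0.4:
        w = rng.choice(_VOCAB)
        cut = rng.randint(min(4, len(w)), len(w)) if rng.random() < 0.5 else len(w)
        return TermAtom(w[:cut], truncated=cut < len(w) or rng.random() < 0.2)
    if kind < 0.6:
        toks = tuple(rng.choice(_VOCAB) for _ in range(rng.randint(2, 3)))
        return PhraseAtom(toks, truncated=rng.random() < 0.3)
    if kind < 0.75:
        return HeadingAtom(rng.choice(_HEADINGS), vocabulary=rng.choice(["mesh", "emtree"]))
    left = tuple(
        TermAtom(rng.choice(_VOCAB), truncated=rng.random() < 0.3, field=None)
        for _ in range(rng.randint(1, 2))
    )
    right = tuple(
        TermAtom(rng.choice(_VOCAB), truncated=rng.random() < 0.3, field=None)
        for _ in range(rng.randint(1, 2))
    )
    return ProximityAtom(left, right, max_distance=rng.randint(0, 5))


def random_ast(rng, depth: int = 2):
    if depth == 0 or rng.random() < 0.4:
        return random_atom(rng)
    cls = And if rng.random() < 0.5 else Or
    return cls(tuple(random_ast(rng, depth - 1) for _ in range(rng.randint(2, 3))))
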