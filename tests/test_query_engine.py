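import pytest
from hypothesis import given, settings, strategies as st

from litfilter.corpus_io import Article, LabeledCorpus, Relevance
from litfilter.query_engine import (
    And,
    EMBASE_FILTER,
    HeadingAtom,
    MEDLINE_FILTER,
    Or,
    ParseError,
    PhraseAtom,
    ProximityAtom,
    QueryError,
    TermAtom,
    UnsupportedFeatureError,
    evaluate,
    load_embase_filter,
    load_medline_filter,
    parse_query,
    retrieve,
    serialize,
    tokenize,
)

from _oracles import random_article, random_ast, regex_evaluate
from conftest import make_article


class TestParsing:
    def test_medline_filter_structure(self):
        node = load_medline_filter()
        assert isinstance(node, Or)
        assert node.children[0] == TermAtom("deprescrib", truncated=True)
        assert node.children[1] == HeadingAtom("deprescriptions", vocabulary="mesh")
        # the printed grouping of the final (dose reduction OR taper*) group
        # survives as a nested Or under the top-level Or
        last = node.children[-1]
        assert isinstance(last, Or)
        assert last.children == (
            PhraseAtom(("dose", "reduction")),
            TermAtom("taper", truncated=True),
        )
        # AND-groups keep their inner OR grouping
        and_group = node.children[2]
        assert isinstance(and_group, And)
        assert isinstance(and_group.children[0], Or)
        assert and_group.children[1] == TermAtom("inappropriate")

    def test_embase_filter_structure(self):
        node = load_embase_filter()
        assert isinstance(node, Or)
        prox = node.children[1]
        assert isinstance(prox, ProximityAtom)
        assert prox.left == (TermAtom("review", truncated=True, field=None),)
        assert prox.right == (TermAtom("medication", truncated=True, field=None),)
        assert prox.max_distance == 3
        assert HeadingAtom("drug withdrawal", vocabulary="emtree") in node.children
        # alternative group on the right-hand side of NEAR/1
        alt = node.children[8]
        assert isinstance(alt, ProximityAtom) and alt.max_distance == 1
        assert {a.token for a in alt.right} == {"drug", "inappropriate", "frid"}

    def test_typographic_quotes_accepted(self):
        node = parse_query("‘deprescrib*’:ab,ti", "embase")
        assert node == TermAtom("deprescrib", truncated=True)

    @pytest.mark.parametrize("text,dialect", [
        ('"a"[Title/Abstract', "pubmed"),       # unterminated field tag
        ('"unclosed[Title/Abstract]', "pubmed"),  # unterminated quote
        ('("a"[Title/Abstract]', "pubmed"),     # unbalanced parenthesis
        ('"a"[Nowhere]', "pubmed"),             # unknown field tag
        ('bare[Title/Abstract]', "pubmed"),     # unquoted term
        ("'a':ab,ti OR 'b'", "embase"),         # missing suffix
        ("(a NEAR/x b):ab,ti", "embase"),       # malformed NEAR distance
        ("'a'[Title/Abstract]", "pubmed"),      # wrong quote style
        ("", "pubmed"),
    ])
    def test_parse_errors(self, text, dialect):
        with pytest.raises(ParseError):
            parse_query(text, dialect)

    def test_near_rejected_in_pubmed(self):
        with pytest.raises(ParseError):
            parse_query('("a"[Title/Abstract] NEAR/3 "b"[Title/Abstract])', "pubmed")


class TestEvaluation:
    def test_title_match_via_truncation(self):
        node = load_medline_filter()
        a = Article(id="1", title="Deprescribing in frail older people")
        assert evaluate(node, a) is True

    def test_blank_article_matches_nothing(self):
        a = Article(id="1", title="", abstract=None)
        assert evaluate(load_medline_filter(), a) is False
        assert evaluate(load_embase_filter(), a) is False

    @pytest.mark.parametrize("abstract,expected", [
        ("review of each medication", True),    # token positions 0 and 3
        ("review of one more such medication", False),  # positions 0 and 5
        ("medication under review", True),      # order-free
    ])
    def test_proximity_distance(self, abstract, expected):
        node = parse_query("((review* NEAR/3 medication*):ab,ti)", "embase")
        a = Article(id="1", abstract=abstract)
        assert evaluate(node, a) is expected

    def test_phrase_crosses_hyphen(self):
        node = parse_query('"dose reduction"[Title/Abstract]', "pubmed")
        assert evaluate(node, Article(id="1", abstract="a dose-reduction plan"))
        assert not evaluate(node, Article(id="1", abstract="reduction of the dose"))

    def test_absent_abstract_contributes_no_tokens(self):
        node = parse_query('"taper*"[Title/Abstract]', "pubmed")
        assert not evaluate(node, Article(id="1", title="x", abstract=None))
        assert evaluate(node, Article(id="1", title="x", abstract="tapering"))

    def test_heading_exact_case_insensitive(self):
        node = parse_query('"deprescriptions"[MeSH Terms]', "pubmed")
        assert evaluate(node, Article(id="1", mesh_headings=("Deprescriptions",)))
        assert not evaluate(node, Article(id="1", mesh_headings=("Deprescriptions and more",)))
        assert not evaluate(node, Article(id="1", emtree_headings=("Deprescriptions",)))


class TestRetrieval:
    def test_single_planted_match(self):
        arts = [make_article(i, Relevance.NON_RELEVANT, abstract="background text")
                for i in range(99)]
        arts.append(make_article(99, Relevance.RELEVANT, abstract="polypharmacy care"))
        corpus = LabeledCorpus(tuple(arts))
        r = retrieve(parse_query('"polypharmacy"[Title/Abstract]', "pubmed"), corpus)
        assert r.ids == frozenset({"a99"}) and r.n_relevant == 1

    def test_or_union_and_intersection(self, rng):
        corpus = LabeledCorpus(tuple(random_article(rng, i) for i in range(120)))
        for _ in range(25):
            q1, q2 = random_ast(rng, 1), random_ast(rng, 1)
            r1, r2 = retrieve(q1, corpus).ids, retrieve(q2, corpus).ids
            assert retrieve(Or((q1, q2)), corpus).ids == r1 | r2
            assert retrieve(And((q1, q2)), corpus).ids == r1 & r2

    def test_or_monotonicity(self, rng):
        corpus = LabeledCorpus(tuple(random_article(rng, i) for i in range(120)))
        for _ in range(25):
            q, atom = random_ast(rng, 2), random_ast(rng, 0)
            assert retrieve(Or((q, atom)), corpus).ids >= retrieve(q, corpus).ids


class TestSerialization:
    def test_bundled_filters_round_trip_byte_identical(self):
        for text, dialect in ((MEDLINE_FILTER, "pubmed"), (EMBASE_FILTER, "embase")):
            node = parse_query(text, dialect)
            assert serialize(node, dialect) == text
            assert parse_query(serialize(node, dialect), dialect) == node

    def test_random_ast_round_trip(self, rng):
        for _ in range(200):
            node = random_ast(rng, 2)
            for dialect in ("pubmed", "embase"):
                try:
                    text = serialize(node, dialect)
                except UnsupportedFeatureError:
                    continue  # proximity/foreign headings are dialect-bound
                assert parse_query(text, dialect) == node

    def test_proximity_unsupported_in_pubmed(self):
        node = parse_query("((review* NEAR/3 medication*):ab,ti)", "embase")
        with pytest.raises(UnsupportedFeatureError):
            serialize(node, "pubmed")

    def test_fieldless_term_rejected(self):
        with pytest.raises(QueryError, match="field"):
            serialize(TermAtom("x", field=None), "pubmed")


class TestOracleAgreement:
    def test_matches_regex_oracle(self, rng):
        """Structured evaluator agrees with an independent regex scan."""
        for i in range(300):
            article = random_article(rng, i)
            node = random_ast(rng, 2)
            assert evaluate(node, article) == regex_evaluate(node, article), (
                node,
                article,
            )


def test_bundled_medline_filter_on_emulated_validation_corpus():
    """On a validation-set-sized synthetic corpus (75 relevant / 7,839
    non-relevant, planted class-conditional term model), the bundled Medline
    filter's Monte-Carlo sensitivity matches the generator's analytic value
    within three binomial standard errors, and stays in the highly sensitive
    regime."""
    import math

    from litfilter.synthetic_data import GeneratorConfig, expected_performance, generate

    cfg = GeneratorConfig(n_relevant=75, n_nonrelevant=7839, seed=21)
    corpus, truth = generate(cfg)
    node = load_medline_filter()
    ep = expected_performance(truth, node, n_relevant=75, n_nonrelevant=7839)
    sens = retrieve(node, corpus).n_relevant / 75
    se = math.sqrt(ep.sensitivity * (1 - ep.sensitivity) / 75)
    assert abs(sens - ep.sensitivity) <= 3 * se
    assert sens >= 0.85


@given(st.text())
@settings(max_examples=200, deadline=None)
def test_tokenize_only_lowercase_alnum_runs(text):
    for tok in tokenize(text):
        assert tok and all(c.islower() or c.isdigit() for c in tok)
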