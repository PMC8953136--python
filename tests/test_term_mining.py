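import random

import pytest

from litfilter.corpus_io import LabeledCorpus, Relevance
from litfilter.query_engine import tokenize
from litfilter.term_mining import (
    Lexicon,
    ScreeningThresholds,
    TermStats,
    builtin_lexicons,
    collocation_candidates,
    document_frequencies,
    load_lexicon,
    screen,
)

from conftest import make_article


def _corpus(rel_texts, non_texts, rel_headings=None):
    arts = []
    for i, t in enumerate(rel_texts):
        mesh = (rel_headings or {}).get(i, ())
        arts.append(make_article(f"r{i}", Relevance.RELEVANT, abstract=t, mesh=mesh))
    for i, t in enumerate(non_texts):
        arts.append(make_article(f"n{i}", Relevance.NON_RELEVANT, abstract=t))
    return LabeledCorpus(tuple(arts))


class TestDocumentFrequencies:
    def test_document_not_occurrence_frequency(self):
        rel = ["taper taper taper taper taper"] + ["taper x"] * 3 + ["other words"] * 6
        corpus = _corpus(rel, ["background only"] * 5)
        stats = {s.surface: s for s in document_frequencies(corpus, 0.10)}
        assert stats["taper"].df_relevant == pytest.approx(0.40)
        assert stats["taper"].n_relevant == 4

    def test_absent_from_non_relevant_is_zero(self):
        corpus = _corpus(["polypharmacy study"] * 4, ["unrelated text"] * 4)
        stats = {s.surface: s for s in document_frequencies(corpus, 0.10)}
        assert stats["polypharmacy"].df_nonrelevant == 0.0

    def test_headings_counted_separately(self):
        corpus = _corpus(
            ["deprescribing"] * 3, ["x y"] * 3,
            rel_headings={0: ("Deprescriptions",), 1: ("Deprescriptions",)},
        )
        heads = [s for s in document_frequencies(corpus, 0.1) if s.kind == "heading"]
        assert heads[0].surface == "deprescriptions"
        assert heads[0].vocabulary == "mesh"
        assert heads[0].df_relevant == pytest.approx(2 / 3)

    def test_matches_naive_recount(self, rng):
        vocab = ["alpha", "beta", "gamma", "delta", "polypharmacy"]
        rel = [" ".join(rng.choices(vocab, k=rng.randint(1, 12))) for _ in range(15)]
        non = [" ".join(rng.choices(vocab, k=rng.randint(1, 12))) for _ in range(25)]
        corpus = _corpus(rel, non)
        stats = {s.surface: s for s in document_frequencies(corpus, 0.0)
                 if s.kind == "token"}
        for token in vocab:
            n_rel = sum(token in set(tokenize(t)) for t in rel)
            n_non = sum(token in set(tokenize(t)) for t in non)
            if n_rel:
                assert stats[token].n_relevant == n_rel
                assert stats[token].n_nonrelevant == n_non

    def test_invariant_under_text_duplication(self):
        rel = ["dose reduction protocol"] * 4 + ["other"] * 4
        doubled = [t + " " + t for t in rel]
        c1 = document_frequencies(_corpus(rel, ["x"] * 4), 0.1)
        c2 = document_frequencies(_corpus(doubled, ["x"] * 4), 0.1)
        assert {(s.surface, s.df_relevant) for s in c1} == {
            (s.surface, s.df_relevant) for s in c2
        }

    def test_empty_class_rejected(self):
        corpus = LabeledCorpus((make_article(1, Relevance.RELEVANT, abstract="x"),))
        with pytest.raises(Exception, match="each relevance class"):
            document_frequencies(corpus)


class TestCollocation:
    def test_truncation_stem_from_variants(self):
        rel = ["discontinue the drug", "therapy was discontinued",
               "rates of discontinuation", "discontinuation again", "no match here"]
        corpus = _corpus(rel, ["background text"] * 5)
        cands = collocation_candidates(corpus, ["discontinuation"])
        stems = [c for c in cands if c.kind == "truncation"]
        assert stems and stems[0].surface == "discontinu*"
        assert stems[0].n_relevant == 4  # any variant counts the document

    def test_phrase_pooling_over_plural(self):
        rel = ["a medication review was done", "structured medication reviews help",
               "medication review again", "unrelated text"]
        corpus = _corpus(rel, ["background words"] * 4)
        cands = collocation_candidates(corpus, ["medication"])
        pooled = {c.surface: c for c in cands if c.kind == "phrase"}
        assert "medication review*" in pooled
        assert pooled["medication review*"].n_relevant == 3

    def test_seed_without_variants_or_neighbors(self):
        rel = ["zzyzx alone", "nothing shared", "entirely different words"]
        corpus = _corpus(rel, ["background"] * 3)
        assert collocation_candidates(corpus, ["zzyzx"]) == []

    def test_unknown_seed_warns_and_skips(self):
        corpus = _corpus(["some words"] * 3, ["other words"] * 3)
        with pytest.warns(UserWarning, match="not found"):
            out = collocation_candidates(corpus, ["absentterm"])
        assert out == []


def _ts(surface, df_rel, df_non, kind="token"):
    return TermStats(surface, kind, int(df_rel * 100), int(df_non * 100),
                     df_rel, df_non)


class TestScreen:
    def test_tier_assignment(self):
        stats = [
            _ts("strong", 0.25, 0.01),     # tier 1
            _ts("borderline", 0.12, 0.05),  # fails tier 2 under AND
            _ts("fallback", 0.12, 0.02),   # tier 2
            _ts("weak", 0.05, 0.001),      # below tier-2 relevant floor
        ]
        res = screen(stats, ScreeningThresholds())
        assert [t.surface for t in res.tier1] == ["strong"]
        assert [t.surface for t in res.tier2] == ["fallback"]

    def test_literal_or_combiner_admits_rare_terms(self):
        stats = [_ts("borderline", 0.12, 0.05), _ts("rare", 0.01, 0.0)]
        res = screen(stats, ScreeningThresholds(tier2_combiner="or"))
        assert {t.surface for t in res.tier2} == {"borderline", "rare"}

    def test_exclusion_categories_tallied(self):
        """A 242-candidate pool with 180 planted lexicon matches: 96 generic,
        49 methodological, 15 population, 20 setting."""
        planted = {"generic": 96, "methodological": 49, "population": 15, "setting": 20}
        stats, lexicons = [], []
        for cat, count in planted.items():
            words = [f"{cat}{i}" for i in range(count)]
            lexicons.append(Lexicon(cat, cat, frozenset(words)))
            stats += [_ts(w, 0.30, 0.01) for w in words]
        stats += [_ts(f"keep{i}", 0.30, 0.01) for i in range(62)]
        assert len(stats) == 242
        res = screen(stats, ScreeningThresholds(), lexicons)
        assert len(res.excluded) == 180
        assert dict(res.category_counts) == planted
        assert len(res.tier1) == 62

    def test_truncation_surface_matches_lexicon_base(self):
        lex = Lexicon("generic", "generic", frozenset({"review"}))
        res = screen([_ts("review*", 0.3, 0.01, kind="truncation")],
                     ScreeningThresholds(), [lex])
        assert res.excluded and res.excluded[0][1] == "generic"

    def test_order_independence(self, rng):
        stats = [_ts(f"t{i}", rng.random() * 0.4, rng.random() * 0.05)
                 for i in range(40)]
        res_a = screen(stats, ScreeningThresholds())
        shuffled = stats[:]
        random.Random(3).shuffle(shuffled)
        res_b = screen(shuffled, ScreeningThresholds())
        assert {t.surface for t in res_a.tier1} == {t.surface for t in res_b.tier1}
        assert {t.surface for t in res_a.tier2} == {t.surface for t in res_b.tier2}

    def test_tier1_rule_stronger_than_tier2_under_and(self):
        th = ScreeningThresholds()
        for t in [_ts(f"x{i}", i / 100, 0.015) for i in range(5, 40)]:
            res = screen([t], th)
            if res.tier1:  # anything in tier 1 would also satisfy tier-2 AND rule
                assert t.df_relevant >= th.tier2_min_relevant
                assert t.df_nonrelevant <= th.tier2_max_nonrelevant


def test_builtin_lexicons_load_all_categories():
    lexes = builtin_lexicons()
    assert {l.category for l in lexes} == set(Lexicon.CATEGORIES)
    assert all(l.entries for l in lexes)


def test_load_lexicon_ignores_comments(tmp_path):
    p = tmp_path / "generic.txt"
    p.write_text("# comment\nalpha\nBETA  # trailing\n\n")
    lex = load_lexicon(p)
    assert lex.entries == frozenset({"alpha", "beta"}) and lex.category == "generic"
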