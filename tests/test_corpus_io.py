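import textwrap

import pytest

from litfilter.corpus_io import (
    Article,
    CorpusError,
    LabeledCorpus,
    PubType,
    Relevance,
    SplitConfig,
    deduplicate,
    read_corpus,
    stratified_split,
    summarize,
    write_corpus,
)

from conftest import make_article


def _light_corpus(n_rel, n_non):
    arts = [make_article(f"r{i}", Relevance.RELEVANT) for i in range(n_rel)]
    arts += [make_article(f"n{i}", Relevance.NON_RELEVANT) for i in range(n_non)]
    return LabeledCorpus(tuple(arts))


class TestReaders:
    def test_delimited_round_trip(self, toy_corpus, tmp_path):
        path = tmp_path / "corpus.tsv"
        write_corpus(toy_corpus, path)
        back = read_corpus(path, "delimited")
        assert len(back) == len(toy_corpus)
        for orig, rt in zip(toy_corpus, back):
            assert rt.id == orig.id
            assert rt.title == orig.title
            assert rt.abstract == orig.abstract  # absent stays absent
            assert rt.mesh_headings == orig.mesh_headings
            assert rt.relevance == orig.relevance
            assert rt.pub_type == orig.pub_type

    def test_absent_abstract_distinct_from_missing_field(self, toy_corpus):
        no_ab = [a for a in toy_corpus if a.abstract is None]
        assert no_ab and all(a.abstract is None for a in no_ab)

    def test_medline_nbib(self, tmp_path):
        nbib = textwrap.dedent("""\
            PMID- 12345
            TI  - Deprescribing in older adults.
            AB  - A tapering protocol was evaluated.
            MH  - *Deprescriptions
            MH  - Polypharmacy
            JT  - Drugs and Aging
            DP  - 2019 Mar
            PT  - Journal Article

            PMID- 12346
            TI  - A letter without abstract.
            JT  - Age and Ageing
            DP  - 2012
            PT  - Letter
            """)
        path = tmp_path / "records.nbib"
        path.write_text(nbib)
        corpus = read_corpus(path, "medline_nbib",
                             labels={"12345": Relevance.RELEVANT,
                                     "12346": Relevance.NON_RELEVANT})
        a, b = corpus.articles
        assert a.id == "12345"
        assert a.mesh_headings == ("Deprescriptions", "Polypharmacy")
        assert a.year == 2019 and a.pub_type is PubType.ARTICLE
        assert a.relevance is Relevance.RELEVANT
        assert b.abstract is None
        assert b.pub_type is PubType.OTHER and b.pub_subtype == "letter"

    def test_ris(self, tmp_path):
        ris = textwrap.dedent("""\
            TY  - JOUR
            ID  - 77
            TI  - Polypharmacy reduction study
            AB  - We examined withdrawal of
            long-term therapy.
            KW  - deprescription
            JO  - Test Journal
            PY  - 2020
            ER  -
            """)
        path = tmp_path / "records.ris"
        path.write_text(ris)
        corpus = read_corpus(path, "ris")
        (a,) = corpus.articles
        assert a.id == "77"
        assert "long-term therapy" in a.abstract
        assert a.emtree_headings == ("deprescription",)
        assert a.year == 2020

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("id,title,relevance\nx,one,relevant\nx,two,non_relevant\n")
        with pytest.raises(CorpusError, match="duplicate"):
            read_corpus(path, "delimited")

    def test_unknown_format(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("id\n1\n")
        with pytest.raises(CorpusError, match="unknown corpus format"):
            read_corpus(path, "parquet")


class TestDeduplicate:
    def test_identical_ids_collapse(self):
        a = make_article("x", Relevance.RELEVANT, title="first")
        b = make_article("x", Relevance.RELEVANT, title="second")
        out = deduplicate(LabeledCorpus((a, b)))
        assert len(out) == 1 and out.articles[0].title == "first"
        assert out.removed_ids == ("ax",) or out.removed_ids == (a.id,)

    def test_no_duplicates_identity(self, toy_corpus):
        out = deduplicate(toy_corpus)
        assert out.articles == toy_corpus.articles and out.removed_ids == ()

    def test_idempotent(self, toy_corpus):
        once = deduplicate(toy_corpus)
        twice = deduplicate(once)
        assert twice.articles == once.articles

    def test_reference_set_scale(self):
        """23,792 aggregated records with 51 planted duplicates leave 23,741."""
        arts = [make_article(f"u{i}", Relevance.NON_RELEVANT) for i in range(23741)]
        dups = [arts[i * 7] for i in range(51)]
        corpus = LabeledCorpus(tuple(arts + dups))
        assert len(corpus) == 23792
        out = deduplicate(corpus)
        assert len(out) == 23741 and len(out.removed_ids) == 51

    def test_title_year_key(self):
        a = make_article(1, Relevance.RELEVANT, title="Same Title", year=2019)
        b = make_article(2, Relevance.RELEVANT, title="same title", year=2019)
        c = make_article(3, Relevance.RELEVANT, title="Same Title", year=2020)
        out = deduplicate(LabeledCorpus((a, b, c)), key="title_year")
        assert [x.id for x in out.articles] == ["a1", "a3"]


class TestStratifiedSplit:
    def test_allocation_arithmetic(self):
        corpus = _light_corpus(10, 100)
        dev, val = stratified_split(corpus, SplitConfig(0.7, seed=5))
        assert dev.n_relevant == 7 and dev.n_non_relevant == 70
        assert val.n_relevant == 3 and val.n_non_relevant == 30

    def test_determinism(self):
        corpus = _light_corpus(10, 100)
        a = stratified_split(corpus, SplitConfig(0.7, seed=11))
        b = stratified_split(corpus, SplitConfig(0.7, seed=11))
        assert [x.id for x in a[0]] == [x.id for x in b[0]]
        assert [x.id for x in a[1]] == [x.id for x in b[1]]

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_partition_exact(self, seed):
        corpus = _light_corpus(9, 31)
        dev, val = stratified_split(corpus, SplitConfig(0.61, seed=seed))
        ids = sorted(dev.ids() + val.ids())
        assert ids == sorted(corpus.ids())

    def test_two_to_one_ratio_reproduces_reference_counts(self):
        """A 2:1 development:validation ratio on 224/23,517 gives the
        149/15,678 versus 75/7,839 split sizes."""
        corpus = _light_corpus(224, 23517)
        dev, val = stratified_split(corpus, SplitConfig(2.0 / 3.0, seed=1))
        assert (dev.n_relevant, dev.n_non_relevant) == (149, 15678)
        assert (val.n_relevant, val.n_non_relevant) == (75, 7839)

    def test_tiny_stratum_rejected(self):
        corpus = LabeledCorpus((
            make_article(1, Relevance.RELEVANT),
            make_article(2, Relevance.NON_RELEVANT),
            make_article(3, Relevance.NON_RELEVANT),
        ))
        with pytest.raises(CorpusError, match="at least 2"):
            stratified_split(corpus, SplitConfig(0.5, seed=0))

    def test_invalid_fraction(self):
        with pytest.raises(CorpusError):
            SplitConfig(1.0, seed=0)


class TestSummarize:
    def _reference_like(self):
        arts = []
        for i in range(224):
            arts.append(make_article(
                f"r{i}", Relevance.RELEVANT,
                journal="Drugs and Aging" if i < 48 else "Other J",
                year=2016 if i < 169 else 2012,
            ))
        for i in range(23517):
            arts.append(make_article(f"n{i}", Relevance.NON_RELEVANT, journal="Other J"))
        return LabeledCorpus(tuple(arts))

    def test_within_class_percentages(self):
        s = summarize(self._reference_like())
        count, pct = s.journals["relevant"]["Drugs and Aging"]
        assert (count, pct) == (48, 21.4)
        count, pct = s.periods["relevant"]["2016-2020"]
        assert (count, pct) == (169, 75.4)

    def test_margins_conserved(self, toy_corpus):
        s = summarize(toy_corpus)
        for table in (s.journals, s.periods, s.pub_types):
            for cls, cats in table.items():
                assert sum(c for c, _ in cats.values()) == s.totals[cls]

    def test_prevalence(self):
        s = summarize(self._reference_like())
        assert s.prevalence_percent == 0.94

    def test_unlabeled_rejected(self):
        corpus = LabeledCorpus((make_article(1, Relevance.UNLABELED),))
        with pytest.raises(CorpusError, match="fully labeled"):
            summarize(corpus)
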