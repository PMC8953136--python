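import random

import pytest

from litfilter.corpus_io import Article, LabeledCorpus, PubType, Relevance


def make_article(i, relevance, title="", abstract=None, mesh=(), emtree=(),
                 journal="J", year=2018, pub_type=PubType.ARTICLE):
    return Article(
        id=f"a{i}",
        title=title,
        abstract=abstract,
        mesh_headings=mesh,
        emtree_headings=emtree,
        journal=journal,
        year=year,
        pub_type=pub_type,
        relevance=relevance,
    )


@pytest.fixture
def toy_corpus():
    """Six relevant + eight non-relevant hand-written articles."""
    rel = [
        make_article(1, Relevance.RELEVANT, title="Deprescribing in frail older people",
                     abstract="a structured deprescribing intervention", mesh=("Deprescriptions",)),
        make_article(2, Relevance.RELEVANT, title="Polypharmacy and inappropriate medication",
                     abstract="review of each medication in older adults"),
        make_article(3, Relevance.RELEVANT, title="Discontinuation of benzodiazepines",
                     abstract="tapering and dose reduction protocol"),
        make_article(4, Relevance.RELEVANT, title="Withdrawal of preventive medication",
                     abstract="medication withdrawal trial"),
        make_article(5, Relevance.RELEVANT, title="Stopping statins late in life",
                     abstract=None, pub_type=PubType.OTHER),
        make_article(6, Relevance.RELEVANT, title="Medication review in nursing homes",
                     abstract="pharmacist led medication reviews"),
    ]
    non = [
        make_article(10 + i, Relevance.NON_RELEVANT,
                     title=f"Background paper {i}",
                     abstract=f"unrelated clinical topic number {i}")
        for i in range(8)
    ]
    return LabeledCorpus(tuple(rel + non), provenance="toy")


@pytest.fixture
def rng():
    return random.Random(20240901)
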