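import pytest

from taxolink.citation_model import AliasTable, Work
from taxolink.identifiers import IdKind, PersistentIdentifier
from taxolink.synth import CorpusSpec, generate_corpus


@pytest.fixture
def aliases():
    return AliasTable([
        ("Front. Microbiol.", "Frontiers in Microbiology"),
        ("IMA Fungus", "IMA Fungus"),
        ("MycoKeys", "MycoKeys"),
    ])


@pytest.fixture
def mycokeys_work():
    """A MycoKeys volume-83 article whose page range contains page 166."""
    return Work(
        work_id="mycokeys-83-72325", container="MycoKeys", volume="83",
        page_start=161, page_end=175, year=2021,
        title="A new species of Cordyceps",
        authors=("Hu", "Dai", "Zhao"),
        identifiers=frozenset({
            PersistentIdentifier(IdKind.DOI, "10.3897/mycokeys.83.72325")}))


@pytest.fixture
def frontiers_work():
    """A continuous-numbering article whose DOI tail is the article number."""
    return Work(
        work_id="fmicb-737541", container="Frontiers in Microbiology",
        volume="12", page_start=1, page_end=12, year=2021,
        article_number="737541",
        identifiers=frozenset({
            PersistentIdentifier(IdKind.DOI, "10.3389/fmicb.2021.737541")}))


@pytest.fixture
def small_corpus():
    return generate_corpus(CorpusSpec(n_journals=4, volumes_per_journal=2,
                                      articles_per_volume=5, names_per_article=2,
                                      continuous_numbering_fraction=0.25, seed=11))
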