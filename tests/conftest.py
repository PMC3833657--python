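import pytest

from oncorel import AnnotationUnit, Corpus, Span
from oncorel.catalog import NOT_ANNOTATED


def make_unit(
    unit_id="u1",
    cge="increased",
    ccs="normal->cancer",
    ige="unchanged",
    pt="observation",
    gene="Cdc25B",
    keyword="overexpressed",
    cancer="prostate cancer",
    cancer_type="prostate",
    pmid="",
):
    """Build a structurally valid unit around a fixed sentence frame."""
    if ccs == "unidentifiable":
        ige = pt = NOT_ANNOTATED
    sentence = f"{gene} is frequently {keyword} in human {cancer} tissues"
    g0 = sentence.index(gene)
    k0 = sentence.index(keyword, g0 + len(gene))
    c0 = sentence.index(cancer, k0 + len(keyword))
    return AnnotationUnit(
        unit_id=unit_id,
        pmid=pmid,
        cancer_type=cancer_type,
        sentence=sentence,
        gene=Span(gene, g0, g0 + len(gene)),
        expression_keywords=[Span(keyword, k0, k0 + len(keyword))],
        cancer_terms=[Span(cancer, c0, c0 + len(cancer))],
        cge=cge,
        ccs=ccs,
        ige=ige,
        pt=pt,
    )


@pytest.fixture
def unit_factory():
    return make_unit


@pytest.fixture
def worked_example_units():
    """The three classic worked examples: biomarker, tumor suppressor, oncogene."""
    return [
        make_unit("w1", "increased", "normal->cancer", "unchanged", "observation",
                  gene="Cdc25B", keyword="overexpressed"),
        make_unit("w2", "decreased", "normal->cancer", "unidentifiable", "causality",
                  gene="protein kinase C", keyword="Downregulation",
                  cancer="prostatic carcinoma"),
        make_unit("w3", "decreased", "cancer->normal", "up-regulated", "causality",
                  gene="CLU", keyword="suppression"),
    ]


@pytest.fixture
def small_corpus(worked_example_units):
    return Corpus(units=list(worked_example_units))
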