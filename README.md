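# oncorel

A toolkit for multi-faceted annotation of gene–cancer relations in
biomedical text, aimed at corpus builders and text-mining developers who
work with sentence-level mentions of gene expression changes in cancer.

## The annotation scheme and the inference rules

Each **annotation unit** is one mention of a gene expression change that
co-occurs with at least one cancer-related term in a sentence. A unit
carries character-offset spans (gene name, expression keywords, cancer
terms) and four orthogonal concept values:

| concept | values | meaning |
|---|---|---|
| CGE | increased, decreased | direction of the expression change |
| CCS | normal→normal, normal→cancer, cancer→cancer, cancer→normal, unidentifiable | how the cell's cancerous properties change |
| IGE | up-regulated, down-regulated, unchanged, unidentifiable | expression level before the change, relative to a normal cell |
| PT | observation, causality | whether causality is claimed or the two changes are merely co-reported |

IGE and PT are skipped (distinct from "unidentifiable") when CCS is
"unidentifiable".

Ten pattern rules map a value tuple to a **gene class** — oncogene, tumor
suppressor gene or biomarker; no matching rule means *not related to
cancer*. The rationale: a causal expression change driving cancer
progression or regression identifies an oncogene or tumor suppressor;
causality may also be *deduced* when the initial level and the change
revert a cancer-associated deviation (IGE up-regulated with CGE decreased,
or the mirror case); a co-reported change without causality is a
biomarker. When IGE is unidentifiable, the class asserting the *weakest*
gene–cancer relation among the concrete possibilities is assigned
(not_related < biomarker < oncogene = tumor suppressor).
`first_principles_class` implements this derivation directly and
`derive_rule_table` recompresses it into the 10-rule table; both are
checked exhaustively against the built-in table over all 80 value tuples.

The package also reproduces the corpus analytics that accompany such a
resource: value distributions, contingency tables with Pearson residuals
(O−E)/√E, chi-square and Cochran–Mantel–Haenszel tests, odds ratios,
inter-annotator agreement (simple agreement, Cohen's κ = (p_o−p_e)/(1−p_e),
G-index = (p_o−1/k)/(1−1/k)), rule-validation scoring (full/one/no match,
micro and macro rates), and a seeded synthetic-corpus generator whose
default distributions are the published summary counts of an 821-unit
reference corpus on prostate, breast and ovarian cancers.

## Worked example

```python
from oncorel import AnnotationUnit, Span, classify_unit

unit = AnnotationUnit(
    unit_id="ex1", cancer_type="prostate",
    sentence="Cdc25B is frequently overexpressed in human prostate cancer tissues",
    gene=Span("Cdc25B", 0, 6),
    expression_keywords=[Span("overexpressed", 21, 34)],
    cancer_terms=[Span("prostate cancer", 44, 59)],
    cge="increased", ccs="normal->cancer", ige="unchanged", pt="observation",
)
result = classify_unit(unit)
print(result.rule_id, result.gene_class)   # 7 biomarker
```

Rule 7 fires because the increase is merely co-reported with cancer
progression (PT = observation): the gene is evidence of a biomarker, not
of an oncogene. See `examples/` for runnable scripts covering
classification, contingency statistics (residuals 2.65 / 6.30 and odds
ratios 6.5 / 7.8 on the published counts), agreement metrics and corpus
simulation, and `oncorel --help` for the command-line interface
(validate / classify / stats / agreement / simulate / derive-rules).

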