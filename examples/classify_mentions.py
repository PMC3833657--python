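"""Classify gene mentions from their four annotation concept values.

Builds three annotation units — the canonical worked examples of the
scheme — and runs the rule engine on each.  The printed rule id and class
say which pattern fired: a co-reported expression increase with cancer
progression is only a biomarker signal; a causal claim (explicit, or
deduced from the initial expression level) pins down tumor suppressor or
oncogene.
"""

from oncorel import AnnotationUnit, Span, classify_unit, render_marked_sentence


def unit(unit_id, sentence, gene, keyword, cancer, cge, ccs, ige, pt):
    find = sentence.index
    g, k, c = find(gene), find(keyword), find(cancer)
    return AnnotationUnit(
        unit_id=unit_id,
        cancer_type="prostate",
        sentence=sentence,
        gene=Span(gene, g, g + len(gene)),
        expression_keywords=[Span(keyword, k, k + len(keyword))],
        cancer_terms=[Span(cancer, c, c + len(cancer))],
        cge=cge, ccs=ccs, ige=ige, pt=pt,
    )


units = [
    unit("ex1", "Cdc25B is frequently overexpressed in human prostate cancer tissues",
         "Cdc25B", "overexpressed", "prostate cancer",
         "increased", "normal->cancer", "unchanged", "observation"),
    unit("ex2", "Downregulation of protein kinase C suppresses induction of apoptosis "
         "in human prostatic carcinoma cells",
         "protein kinase C", "Downregulation", "prostatic carcinoma",
         "decreased", "normal->cancer", "unidentifiable", "causality"),
    unit("ex3", "Suppression of CLU expression sensitizes prostate cancer cells "
         "to chemotherapeutic drugs",
         "CLU", "Suppression", "prostate cancer",
         "decreased", "cancer->normal", "up-regulated", "causality"),
]

for u in units:
    result = classify_unit(u)
    print(render_marked_sentence(u))
    print(f"  (CGE={u.cge}, CCS={u.ccs}, IGE={u.ige}, PT={u.pt})")
    print(f"  -> rule {result.rule_id}: {result.gene_class}\n")

print("Rule 7 fires on any co-reported change with cancer progression (biomarker);")
print("rule 4 on a causal decrease driving progression (tumor suppressor); rule 3")
print("deduces causality from an up-regulated initial level being decreased (oncogene).")
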