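"""Pre-specified annotation concept values.

Every annotation unit carries four semantically orthogonal concepts:

CGE
    Change in Gene Expression — direction of the expression-level change
    of the gene in the mention.
CCS
    Change in Cell State — how the cancerous properties of the cell or
    tissue change alongside the gene expression change.
IGE
    Initial Gene Expression level — the gene's expression level before
    the change, relative to a normal cell.
PT
    Proposition Type — whether causality between the gene change and the
    cell change is claimed, or the two are merely co-reported.

The admissible values per concept are fixed by the annotation scheme and
never extended at run time.  ``NOT_ANNOTATED`` (``None``) is distinct from
the value ``"unidentifiable"``: the latter is an annotator's judgment that
the sentence gives no information, the former means the concept was skipped
per the scheme's rules (IGE and PT are not annotated when CCS is
"unidentifiable").
"""

from __future__ import annotations

from typing import Optional

#: Marker for a concept skipped by the annotation scheme (JSONL: null).
NOT_ANNOTATED: Optional[str] = None

CGE = "CGE"
CCS = "CCS"
IGE = "IGE"
PT = "PT"

CONCEPTS = (CGE, CCS, IGE, PT)

CGE_VALUES = ("increased", "decreased")
CCS_VALUES = (
    "normal->normal",
    "normal->cancer",
    "cancer->cancer",
    "cancer->normal",
    "unidentifiable",
)
IGE_VALUES = ("up-regulated", "down-regulated", "unchanged", "unidentifiable")
PT_VALUES = ("observation", "causality")

VALUES = {CGE: CGE_VALUES, CCS: CCS_VALUES, IGE: IGE_VALUES, PT: PT_VALUES}

DEFINITIONS = {
    (CGE, "increased"): "Expression level of the gene is increased.",
    (CGE, "decreased"): "Expression level of the gene is decreased.",
    (CCS, "normal->normal"): "The cell or tissue remains normal after the "
    "change in the gene's expression level.",
    (CCS, "normal->cancer"): "The cell or tissue acquires or strengthens "
    "cancerous properties as the gene expression level changes.",
    (CCS, "cancer->cancer"): "No change in the cancerous properties of the "
    "cell or tissue despite the change in gene expression level.",
    (CCS, "cancer->normal"): "The cell or tissue loses or weakens cancerous "
    "properties as the gene expression level changes.",
    (CCS, "unidentifiable"): "Whether the gene expression change accompanies "
    "a cell-state change is not stated.",
    (IGE, "up-regulated"): "Initial expression level is higher than in the "
    "normal state.",
    (IGE, "down-regulated"): "Initial expression level is lower than in the "
    "normal state.",
    (IGE, "unchanged"): "Initial expression level is comparable to the "
    "normal state.",
    (IGE, "unidentifiable"): "Initial expression level is not stated.",
    (PT, "observation"): "Cell change and gene expression change are "
    "co-reported without a claim of causality.",
    (PT, "causality"): "Causality between gene expression change and cell "
    "change is claimed.",
}


def category_count(concept: str) -> int:
    """Number of pre-specified categories k for *concept* (2, 5, 4 or 2)."""
    return len(VALUES[concept])


def is_admissible(concept: str, value: Optional[str], *, allow_skip: bool = False) -> bool:
    """Whether *value* is an admissible token for *concept*.

    ``allow_skip=True`` additionally accepts :data:`NOT_ANNOTATED`, which the
    scheme permits only for IGE/PT (and only when CCS is "unidentifiable";
    that joint constraint is checked at the unit level, not here).
    """
    if concept not in VALUES:
        raise KeyError(f"unknown annotation concept: {concept!r}")
    if value is NOT_ANNOTATED:
        return allow_skip and concept in (IGE, PT)
    return value in VALUES[concept]
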