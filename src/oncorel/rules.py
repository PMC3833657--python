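"""Rule-based gene classification from annotation concept values.

A gene mention is classified as oncogene, tumor suppressor gene or
biomarker from its four concept values (CGE, CCS, IGE, PT) via a table of
ten pattern rules; when no rule applies the gene is classified as not
related to cancer.  The rationale: a causal link between an expression
change and cancer progression/regression pins down oncogene vs tumor
suppressor; a mere co-reported change yields biomarker; causality may also
be *deduced* when the initial expression level (IGE) and the direction of
change (CGE) together show the cancer-associated deviation being reverted
(IGE up-regulated with CGE decreased, or down-regulated with increased).

:func:`first_principles_class` re-derives the class for any complete value
tuple directly from that rationale — including the weakest-relation
resolution used when IGE is "unidentifiable" — and
:func:`derive_rule_table` compresses the plausible derivations back into a
rule table; both are checked exhaustively against :func:`builtin_rules`
over all 2x5x4x2 = 80 complete tuples.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Tuple

from . import catalog
from .catalog import NOT_ANNOTATED
from .corpus import AnnotationUnit, Corpus, validate_unit

__all__ = [
    "WILDCARD",
    "NONE",
    "ONCOGENE",
    "TUMOR_SUPPRESSOR",
    "BIOMARKER",
    "NOT_RELATED",
    "GENE_CLASSES",
    "class_strength",
    "InferenceRule",
    "ClassificationResult",
    "EvidenceSummary",
    "builtin_rules",
    "match_rule",
    "classify_unit",
    "classify_corpus",
    "first_principles_class",
    "derive_rule_table",
    "aggregate_evidence",
    "rules_to_tsv",
]

#: Pattern wildcard (prints as "*" in the rule table).
WILDCARD = "*"
#: Sentinel rule id when no rule applies.
NONE = None

ONCOGENE = "oncogene"
TUMOR_SUPPRESSOR = "tumor_suppressor_gene"
BIOMARKER = "biomarker"
NOT_RELATED = "not_related"

GENE_CLASSES = (ONCOGENE, TUMOR_SUPPRESSOR, BIOMARKER, NOT_RELATED)

#: Strength of the gene-cancer relation each class asserts.  "not related"
#: is the weakest; oncogene and tumor suppressor tie as the strongest.
_STRENGTH = {NOT_RELATED: 0, BIOMARKER: 1, ONCOGENE: 2, TUMOR_SUPPRESSOR: 2}


def class_strength(gene_class: str) -> int:
    """Rank of *gene_class* in the weakest-to-strongest relation order."""
    return _STRENGTH[gene_class]


@dataclass(frozen=True)
class InferenceRule:
    """One pattern rule: fixed or wildcard per concept, plus an output class.

    CCS is always fixed (never wildcard, never "unidentifiable") — a rule
    only fires when the direction of the cell-state change is known.
    """

    rule_id: int
    cge: str
    ccs: str
    ige: str
    pt: str
    gene_class: str

    def __post_init__(self):
        if self.ccs == WILDCARD or self.ccs == "unidentifiable":
            raise ValueError(f"rule {self.rule_id}: CCS must be a concrete, identifiable value")
        if self.gene_class == NOT_RELATED:
            raise ValueError(f"rule {self.rule_id}: rules never output 'not_related'")

    def matches(self, cge: str, ccs: str, ige: str, pt: str) -> bool:
        return (
            (self.cge == WILDCARD or self.cge == cge)
            and self.ccs == ccs
            and (self.ige == WILDCARD or self.ige == ige)
            and (self.pt == WILDCARD or self.pt == pt)
        )


_BUILTIN: Tuple[InferenceRule, ...] = (
    InferenceRule(1, "increased", "normal->cancer", WILDCARD, "causality", ONCOGENE),
    InferenceRule(2, "decreased", "cancer->normal", "unidentifiable", "causality", ONCOGENE),
    InferenceRule(3, "decreased", "cancer->normal", "up-regulated", WILDCARD, ONCOGENE),
    InferenceRule(4, "decreased", "normal->cancer", WILDCARD, "causality", TUMOR_SUPPRESSOR),
    InferenceRule(5, "increased", "cancer->normal", "unidentifiable", "causality", TUMOR_SUPPRESSOR),
    InferenceRule(6, "increased", "cancer->normal", "down-regulated", WILDCARD, TUMOR_SUPPRESSOR),
    InferenceRule(7, WILDCARD, "normal->cancer", WILDCARD, "observation", BIOMARKER),
    InferenceRule(8, WILDCARD, "cancer->normal", "unidentifiable", "observation", BIOMARKER),
    InferenceRule(9, "decreased", "cancer->cancer", "up-regulated", "observation", BIOMARKER),
    InferenceRule(10, "increased", "cancer->cancer", "down-regulated", "observation", BIOMARKER),
)


def builtin_rules() -> List[InferenceRule]:
    """The ten built-in inference rules, in rule-id order."""
    return list(_BUILTIN)


def _check_values(cge, ccs, ige, pt) -> None:
    if not catalog.is_admissible(catalog.CGE, cge):
        raise ValueError(f"inadmissible CGE value: {cge!r}")
    if not catalog.is_admissible(catalog.CCS, ccs):
        raise ValueError(f"inadmissible CCS value: {ccs!r}")
    skip_ok = ccs == "unidentifiable"
    if not catalog.is_admissible(catalog.IGE, ige, allow_skip=skip_ok):
        raise ValueError(f"inadmissible IGE value: {ige!r}")
    if not catalog.is_admissible(catalog.PT, pt, allow_skip=skip_ok):
        raise ValueError(f"inadmissible PT value: {pt!r}")


def match_rule(
    cge: str,
    ccs: str,
    ige: Optional[str],
    pt: Optional[str],
    rules: Optional[List[InferenceRule]] = None,
) -> Optional[int]:
    """Return the id of the unique matching rule, or ``None``.

    Units with "unidentifiable" CCS (IGE/PT skipped) never match.  More
    than one match would violate the table's mutual exclusivity and raises.
    """
    _check_values(cge, ccs, ige, pt)
    if ccs == "unidentifiable":
        return NONE
    rules = _BUILTIN if rules is None else rules
    hits = [r.rule_id for r in rules if r.matches(cge, ccs, ige, pt)]
    if len(hits) > 1:
        raise AssertionError(f"rule table not mutually exclusive: rules {hits} all match")
    return hits[0] if hits else NONE


@dataclass(frozen=True)
class ClassificationResult:
    unit_id: str
    gene_class: str
    rule_id: Optional[int]


def classify_unit(unit: AnnotationUnit) -> ClassificationResult:
    """Classify one annotation unit; ``not_related`` when no rule applies."""
    problems = validate_unit(unit)
    if problems:
        raise ValueError(f"cannot classify invalid unit {unit.unit_id!r}: {problems}")
    rid = match_rule(unit.cge, unit.ccs, unit.ige, unit.pt)
    if rid is NONE:
        return ClassificationResult(unit.unit_id, NOT_RELATED, NONE)
    gene_class = next(r.gene_class for r in _BUILTIN if r.rule_id == rid)
    return ClassificationResult(unit.unit_id, gene_class, rid)


def classify_corpus(corpus: Corpus) -> List[ClassificationResult]:
    return [classify_unit(u) for u in corpus]


# ---------------------------------------------------------------------------
# First-principles derivation


def _deduced_causality(cge: str, ige: str) -> bool:
    """Causality deduced from initial level + direction of change.

    A gene initially up-regulated in a cancer cell whose expression then
    decreases (or down-regulated, then increases) reverts the deviation, so
    the change can be credited causally even without an explicit claim.
    """
    return (ige == "up-regulated" and cge == "decreased") or (
        ige == "down-regulated" and cge == "increased"
    )


def _implausible(cge: str, ccs: str, ige: str, pt: str) -> bool:
    """Concrete-tuple plausibility filter.

    Reports of a cancer regressing while the gene's initial level is stated
    but does not corroborate the change (no deduced causality) are rarely
    found in the literature; such combinations are excluded from the rule
    table even when the rationale would assign a class.
    """
    return (
        ccs == "cancer->normal"
        and ige in ("up-regulated", "down-regulated", "unchanged")
        and not _deduced_causality(cge, ige)
    )


def _concrete_class(cge: str, ccs: str, ige: str, pt: str) -> str:
    """Class for a tuple with a concrete (non-"unidentifiable") IGE."""
    if ccs in ("unidentifiable", "normal->normal"):
        return NOT_RELATED
    if ccs == "normal->cancer":
        if pt == "causality":
            return ONCOGENE if cge == "increased" else TUMOR_SUPPRESSOR
        return BIOMARKER
    if ccs == "cancer->normal":
        if pt == "causality" or _deduced_causality(cge, ige):
            # regression caused by the change: decreased expression implies
            # the gene was driving the cancer (oncogene), increased implies
            # it was restraining it (tumor suppressor)
            return ONCOGENE if cge == "decreased" else TUMOR_SUPPRESSOR
        return BIOMARKER
    # cancer->cancer: no cell change; only an initial deviation being
    # reverted without effect marks the gene as cancer-associated
    if pt == "observation" and _deduced_causality(cge, ige):
        return BIOMARKER
    return NOT_RELATED


def first_principles_class(
    cge: str, ccs: str, ige: Optional[str], pt: Optional[str]
) -> Tuple[str, bool]:
    """Derive (gene_class, plausible) for a value tuple without the table.

    When IGE is "unidentifiable" the class is resolved by considering every
    concrete IGE value and keeping the class asserting the *weakest*
    gene-cancer relation (weakest-relation resolution).  The boolean flags
    whether the combination is one plausibly reported in the literature;
    implausible-or-rare combinations carry a class but no rule.
    """
    _check_values(cge, ccs, ige, pt)
    if ccs == "unidentifiable" or ccs == "normal->normal":
        return NOT_RELATED, True
    if ige == "unidentifiable":
        candidates = [
            _concrete_class(cge, ccs, concrete, pt)
            for concrete in ("up-regulated", "down-regulated", "unchanged")
        ]
        cls = min(candidates, key=class_strength)
        return cls, True  # no concrete initial level is asserted
    cls = _concrete_class(cge, ccs, ige, pt)
    if cls == NOT_RELATED:
        return cls, True
    return cls, not _implausible(cge, ccs, ige, pt)


def _all_tuples():
    return product(
        catalog.CGE_VALUES, catalog.CCS_VALUES, catalog.IGE_VALUES, catalog.PT_VALUES
    )


def derive_rule_table() -> List[InferenceRule]:
    """Re-derive the rule table from :func:`first_principles_class`.

    Enumerates all 80 complete value tuples, keeps the plausible tuples
    with a class other than ``not_related``, and compresses each class's
    tuple set into maximally wildcarded, mutually exclusive patterns (CCS
    always fixed).  The result is pattern-equivalent to
    :func:`builtin_rules` and renumbered in (class, CCS, pattern) order.
    """
    survivors: Dict[Tuple[str, str, str, str], str] = {}
    for tup in _all_tuples():
        cls, plausible = first_principles_class(*tup)
        if plausible and cls != NOT_RELATED:
            survivors[tup] = cls

    patterns: List[Tuple[str, str, str, str, str]] = []
    by_class_ccs: Dict[Tuple[str, str], set] = defaultdict(set)
    for tup, cls in survivors.items():
        by_class_ccs[(cls, tup[1])].add(tup)

    for (cls, ccs), tuples in by_class_ccs.items():
        # candidate patterns: every fix/wildcard choice over CGE/IGE/PT whose
        # expansion lies entirely inside this class's surviving tuple set
        candidates = []
        for cge_p in (WILDCARD,) + catalog.CGE_VALUES:
            for ige_p in (WILDCARD,) + catalog.IGE_VALUES:
                for pt_p in (WILDCARD,) + catalog.PT_VALUES:
                    expansion = {
                        (g, ccs, i, p)
                        for g in (catalog.CGE_VALUES if cge_p == WILDCARD else (cge_p,))
                        for i in (catalog.IGE_VALUES if ige_p == WILDCARD else (ige_p,))
                        for p in (catalog.PT_VALUES if pt_p == WILDCARD else (pt_p,))
                    }
                    if expansion <= tuples:
                        candidates.append(((cge_p, ccs, ige_p, pt_p), frozenset(expansion)))
        # greedy exact cover, most general pattern first
        candidates.sort(key=lambda c: (-len(c[1]), c[0]))
        covered: set = set()
        for pat, expansion in candidates:
            if not (expansion <= covered):
                patterns.append((cls, *pat))
                covered |= expansion
        assert covered == tuples

    order = {ONCOGENE: 0, TUMOR_SUPPRESSOR: 1, BIOMARKER: 2}
    ccs_order = {v: i for i, v in enumerate(catalog.CCS_VALUES)}
    patterns.sort(key=lambda p: (order[p[0]], ccs_order[p[2]], p[1], p[3], p[4]))
    return [
        InferenceRule(i, cge, ccs, ige, pt, cls)
        for i, (cls, cge, ccs, ige, pt) in enumerate(patterns, start=1)
    ]


# ---------------------------------------------------------------------------
# Evidence aggregation


@dataclass
class EvidenceSummary:
    """Per-(gene, cancer type) tally of classified annotation units.

    One unit is one piece of textual evidence; the inferred classes are
    hypotheses to be weighed across many units, not definite labels.
    """

    gene: str
    cancer_type: str
    counts: Dict[str, int] = field(default_factory=dict)
    unit_ids: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return sum(self.counts.values())


def aggregate_evidence(corpus: Corpus) -> List[EvidenceSummary]:
    """Group classifications by (case-normalized gene text, cancer type)."""
    grouped: Dict[Tuple[str, str], EvidenceSummary] = {}
    for unit in corpus:
        result = classify_unit(unit)
        key = (unit.gene.text.casefold(), unit.cancer_type)
        summary = grouped.get(key)
        if summary is None:
            summary = grouped[key] = EvidenceSummary(
                gene=key[0],
                cancer_type=unit.cancer_type,
                counts={c: 0 for c in GENE_CLASSES},
                unit_ids={c: [] for c in GENE_CLASSES},
            )
        summary.counts[result.gene_class] += 1
        summary.unit_ids[result.gene_class].append(unit.unit_id)
    return sorted(grouped.values(), key=lambda s: (s.gene, s.cancer_type))


def rules_to_tsv(rules: Optional[List[InferenceRule]] = None) -> str:
    """Export a rule table as TSV (rule #, CGE, CCS, IGE, PT, gene class)."""
    rules = builtin_rules() if rules is None else rules
    lines = ["rule\tCGE\tCCS\tIGE\tPT\tgene_class"]
    for r in rules:
        lines.append(f"{r.rule_id}\t{r.cge}\t{r.ccs}\t{r.ige}\t{r.pt}\t{r.gene_class}")
    return "\n".join(lines) + "\n"
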