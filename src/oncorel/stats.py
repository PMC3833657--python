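"""Descriptive and inferential statistics over an annotated corpus.

Covers the analyses a corpus release reports: per-concept value
distributions (by cancer type and overall), pairwise contingency tables
with Pearson residuals and a chi-square independence test, selected odds
ratios, a stratified (Cochran–Mantel–Haenszel) conditional-independence
test, and the distribution of applied inference rules.

Display conventions follow the conventions of the reference tables:
integer percentages are rounded half-up, odds ratios are truncated (not
rounded) to one decimal by the parity formatter, and p-values below the
double-precision floor print as ``<2.2e-16``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from statsmodels.stats.contingency_tables import StratifiedTable

from . import catalog
from .catalog import CCS, CGE, IGE, NOT_ANNOTATED, PT
from .corpus import Corpus
from .rules import NOT_RELATED, builtin_rules, classify_unit

__all__ = [
    "DistributionTable",
    "ContingencyTable",
    "TestResult",
    "RuleDistribution",
    "value_distribution",
    "contingency",
    "pearson_residuals",
    "chi_square_test",
    "odds_ratio",
    "stratified_independence_test",
    "rule_distribution",
    "percent_round_half_up",
    "truncate_1dp",
    "format_p_value",
]

P_FLOOR = 2.2e-16  # double-precision display floor used in reports


def percent_round_half_up(count: int, denominator: int) -> int:
    """``100*count/denominator`` rounded half-up to an integer (exact arithmetic)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return (200 * count + denominator) // (2 * denominator)


def truncate_1dp(x: float) -> float:
    """Truncate toward zero at one decimal (6.56 -> 6.5), for report parity."""
    return math.trunc(x * 10) / 10


def format_p_value(p: float) -> str:
    return "<2.2e-16" if p < P_FLOOR else f"{p:.3g}"


# ---------------------------------------------------------------------------
# Value distributions


@dataclass
class DistributionTable:
    """Counts and integer percentages of one concept's values in one group."""

    concept: str
    group: str  # cancer type or "Total"
    counts: Dict[str, int]
    denominator: int

    @property
    def percentages(self) -> Dict[str, int]:
        return {v: percent_round_half_up(c, self.denominator) for v, c in self.counts.items()}

    def to_tsv_row(self) -> str:
        cells = [self.group] + [
            f"{self.counts[v]}({self.percentages[v]}%)" for v in self.counts
        ]
        return "\t".join(cells)


def value_distribution(
    corpus: Corpus, concept: str, group_by_cancer_type: bool = False
) -> List[DistributionTable]:
    """Tally one concept's values; skipped (NOT_ANNOTATED) units are excluded.

    The denominator is therefore the number of units with the concept
    annotated — for IGE/PT, the units with identifiable CCS.
    """
    if concept not in catalog.CONCEPTS:
        raise ValueError(f"unknown concept: {concept!r}")
    values = catalog.VALUES[concept]

    groups: Dict[str, Dict[str, int]] = {}
    for unit in corpus:
        v = unit.concept_value(concept)
        if v is NOT_ANNOTATED:
            continue
        for g in ([unit.cancer_type] if group_by_cancer_type else []) + ["Total"]:
            groups.setdefault(g, {val: 0 for val in values})[v] += 1

    out = []
    for g, counts in groups.items():
        denom = sum(counts.values())
        out.append(DistributionTable(concept=concept, group=g, counts=counts, denominator=denom))
    # Total last, cancer types alphabetical
    out.sort(key=lambda t: (t.group == "Total", t.group))
    return out


# ---------------------------------------------------------------------------
# Contingency analysis


@dataclass
class TestResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float
    method: str
    n_dropped_strata: int = 0

    def format_p(self) -> str:
        return format_p_value(self.p_value)


@dataclass
class ContingencyTable:
    """Observed counts with derived expected counts and Pearson residuals."""

    row_concept: str
    col_concept: str
    row_labels: List[str]
    col_labels: List[str]
    observed: np.ndarray

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("observed shape does not match labels")

    @classmethod
    def from_counts(
        cls,
        observed: Sequence[Sequence[float]],
        row_labels: Sequence[str],
        col_labels: Sequence[str],
        row_concept: str = "",
        col_concept: str = "",
    ) -> "ContingencyTable":
        return cls(row_concept, col_concept, list(row_labels), list(col_labels), np.asarray(observed))

    @property
    def n(self) -> float:
        return float(self.observed.sum())

    @property
    def expected(self) -> np.ndarray:
        rows = self.observed.sum(axis=1, keepdims=True)
        cols = self.observed.sum(axis=0, keepdims=True)
        return rows * cols / self.n

    def cell(self, row_label: str, col_label: str) -> float:
        return float(
            self.observed[self.row_labels.index(row_label), self.col_labels.index(col_label)]
        )

    def to_tsv(self, residuals: bool = True) -> str:
        res = pearson_residuals(self) if residuals else None
        lines = ["\t".join([f"{self.row_concept}\\{self.col_concept}"] + self.col_labels)]
        for i, rl in enumerate(self.row_labels):
            cells = [rl]
            for j in range(len(self.col_labels)):
                o = int(self.observed[i, j])
                cells.append(f"{o} ({res[i, j]:.2f})" if residuals else str(o))
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"


def contingency(
    corpus: Corpus,
    row_concept: str,
    col_concept: str,
    ccs_filter: Optional[Sequence[str]] = None,
) -> ContingencyTable:
    """Cross-tabulate two concepts over the qualifying units.

    When either concept is IGE or PT, *ccs_filter* must be given and must
    exclude "unidentifiable" (those units carry no IGE/PT value).  Rows and
    columns whose value is never observed are dropped, so degrees of freedom
    reflect the values actually in play.
    """
    if row_concept == col_concept:
        raise ValueError("row and column concepts must differ")
    for c in (row_concept, col_concept):
        if c not in catalog.CONCEPTS:
            raise ValueError(f"unknown concept: {c!r}")
    if IGE in (row_concept, col_concept) or PT in (row_concept, col_concept):
        if ccs_filter is None or "unidentifiable" in ccs_filter:
            raise ValueError(
                "contingency over IGE/PT requires a ccs_filter excluding 'unidentifiable'"
            )

    row_values = list(catalog.VALUES[row_concept])
    col_values = list(catalog.VALUES[col_concept])
    counts = np.zeros((len(row_values), len(col_values)))
    for unit in corpus:
        if ccs_filter is not None and unit.ccs not in ccs_filter:
            continue
        rv = unit.concept_value(row_concept)
        cv = unit.concept_value(col_concept)
        if rv is NOT_ANNOTATED or cv is NOT_ANNOTATED:
            continue
        counts[row_values.index(rv), col_values.index(cv)] += 1

    keep_rows = [i for i, _ in enumerate(row_values) if counts[i].sum() > 0]
    keep_cols = [j for j, _ in enumerate(col_values) if counts[:, j].sum() > 0]
    if not keep_rows or not keep_cols:
        raise ValueError("contingency table is empty after filtering")
    return ContingencyTable(
        row_concept=row_concept,
        col_concept=col_concept,
        row_labels=[row_values[i] for i in keep_rows],
        col_labels=[col_values[j] for j in keep_cols],
        observed=counts[np.ix_(keep_rows, keep_cols)],
    )


def pearson_residuals(table: ContingencyTable) -> np.ndarray:
    """Cell-wise (O - E)/sqrt(E); squares sum to the chi-square statistic."""
    if table.n <= 0:
        raise ValueError("empty table")
    rows = table.observed.sum(axis=1)
    cols = table.observed.sum(axis=0)
    for label, total in list(zip(table.row_labels, rows)) + list(zip(table.col_labels, cols)):
        if total == 0:
            raise ValueError(f"zero marginal total for label {label!r}")
    expected = table.expected
    return (table.observed - expected) / np.sqrt(expected)


def chi_square_test(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    res = pearson_residuals(table)
    statistic = float((res ** 2).sum())
    df = (len(table.row_labels) - 1) * (len(table.col_labels) - 1)
    p = float(_chi2_dist.sf(statistic, df))
    return TestResult(statistic=statistic, degrees_of_freedom=df, p_value=p, method="pearson-chi2")


def odds_ratio(
    table: ContingencyTable,
    rows: Optional[Tuple[str, str]] = None,
    cols: Optional[Tuple[str, str]] = None,
    haldane: bool = False,
) -> float:
    """Cross-product odds ratio over a selected 2x2 sub-table.

    Full precision is returned; :func:`truncate_1dp` reproduces the
    one-decimal report convention.  ``haldane=True`` applies the
    Haldane–Anscombe +0.5 correction, required when a selected cell is zero.
    """
    rows = tuple(table.row_labels[:2]) if rows is None else rows
    cols = tuple(table.col_labels[:2]) if cols is None else cols
    a = table.cell(rows[0], cols[0])
    b = table.cell(rows[0], cols[1])
    c = table.cell(rows[1], cols[0])
    d = table.cell(rows[1], cols[1])
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b == 0 or c == 0:
        raise ZeroDivisionError(
            "zero cell in odds-ratio denominator; pass haldane=True for the +0.5 correction"
        )
    return (a * d) / (b * c)


def stratified_independence_test(
    corpus: Corpus,
    concept_a: str,
    concept_b: str,
    stratify_by: Sequence[str],
) -> TestResult:
    """Cochran–Mantel–Haenszel test of conditional independence.

    Tests whether *concept_a* and *concept_b* (both binary, e.g. CGE and PT)
    are independent within each CCS stratum, pooling evidence across the
    strata in *stratify_by*.  Strata with a zero marginal are dropped and
    counted in ``n_dropped_strata``.
    """
    a_values = catalog.VALUES[concept_a]
    b_values = catalog.VALUES[concept_b]
    if len(a_values) != 2 or len(b_values) != 2:
        raise ValueError("stratified test requires two binary concepts (CGE, PT)")
    if not stratify_by:
        raise ValueError("at least one stratum required")

    tables = []
    dropped = 0
    for ccs_value in stratify_by:
        counts = np.zeros((2, 2))
        for unit in corpus:
            if unit.ccs != ccs_value:
                continue
            av = unit.concept_value(concept_a)
            bv = unit.concept_value(concept_b)
            if av is NOT_ANNOTATED or bv is NOT_ANNOTATED:
                continue
            counts[a_values.index(av), b_values.index(bv)] += 1
        if counts.sum() == 0 or (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
            dropped += 1
            continue
        tables.append(counts)
    if not tables:
        raise ValueError("no usable stratum for the stratified test")

    st = StratifiedTable(tables)
    bunch = st.test_null_odds(correction=False)
    return TestResult(
        statistic=float(bunch.statistic),
        degrees_of_freedom=1,
        p_value=float(bunch.pvalue),
        method="cochran-mantel-haenszel",
        n_dropped_strata=dropped,
    )


# ---------------------------------------------------------------------------
# Rule-application distribution


@dataclass
class RuleDistribution:
    """Counts of applied rules per group, plus class-level shares.

    ``class_counts`` is derived from the rule table's rule -> class mapping
    (plus a ``not_related`` row for units no rule covers), never hard-coded.
    """

    groups: List[str]  # cancer types present, then "Total"
    rule_counts: Dict[str, Dict[object, int]] = field(default_factory=dict)
    class_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def totals(self, group: str = "Total") -> int:
        return sum(self.rule_counts[group].values())

    def rule_percent(self, rule_id, group: str = "Total") -> int:
        return percent_round_half_up(self.rule_counts[group][rule_id], self.totals(group))

    def class_percent(self, gene_class: str, group: str = "Total") -> int:
        return percent_round_half_up(self.class_counts[group][gene_class], self.totals(group))

    def to_tsv(self) -> str:
        rule_ids = list(range(1, 11)) + ["no_rule"]
        lines = ["rule\t" + "\t".join(self.groups)]
        for rid in rule_ids:
            cells = [str(rid)]
            for g in self.groups:
                c = self.rule_counts[g][rid]
                cells.append(f"{c}({self.rule_percent(rid, g)}%)")
            lines.append("\t".join(cells))
        lines.append(
            "Total\t" + "\t".join(f"{self.totals(g)}(100%)" for g in self.groups)
        )
        return "\n".join(lines) + "\n"


def rule_distribution(corpus: Corpus) -> RuleDistribution:
    """Distribution of applied inference rules by cancer type and overall."""
    rule_class = {r.rule_id: r.gene_class for r in builtin_rules()}
    rule_keys = list(range(1, 11)) + ["no_rule"]
    class_keys = sorted(set(rule_class.values()), key=list(rule_class.values()).index)
    class_keys.append(NOT_RELATED)

    groups: Dict[str, Dict[object, int]] = {}
    classes: Dict[str, Dict[str, int]] = {}

    def bucket(g: str):
        if g not in groups:
            groups[g] = {k: 0 for k in rule_keys}
            classes[g] = {k: 0 for k in class_keys}
        return groups[g], classes[g]

    for unit in corpus:
        result = classify_unit(unit)
        key = result.rule_id if result.rule_id is not None else "no_rule"
        for g in (unit.cancer_type, "Total"):
            rc, cc = bucket(g)
            rc[key] += 1
            cc[result.gene_class] += 1
    if "Total" not in groups:
        bucket("Total")

    ordered = sorted(g for g in groups if g != "Total") + ["Total"]
    return RuleDistribution(groups=ordered, rule_counts=groups, class_counts=classes)
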