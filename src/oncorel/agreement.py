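"""Inter-annotator agreement and inference-rule validation scoring.

Three pairwise agreement measures are provided:

* simple agreement — the proportion of units the two annotators label
  identically;
* Cohen's kappa — chance-corrected using the empirical label marginals,
  known to collapse toward zero (or become undefined) when one category
  dominates;
* G-index — chance-corrected with chance fixed at ``1/k`` for the ``k``
  pre-specified categories of the concept, hence robust to skew.

Rule validation compares the class inferred by the rule engine against two
independent human class annotations per unit: a *full* match (both agree
with the inference), *one* match, or *no* match.  The summary reports a
per-rule agreement rate (full + one)/total, a micro average over all
records, and a macro average over the populated rows (including the
"no rule applied" row).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from . import catalog

__all__ = [
    "UNDEFINED",
    "AgreementPairSet",
    "ValidationRecord",
    "ValidationSummary",
    "simple_agreement",
    "cohen_kappa",
    "g_index",
    "score_validation",
    "validation_summary",
]

#: Sentinel for an agreement coefficient that is undefined (rendered "N/A"),
#: e.g. kappa when both annotators use a single category everywhere.
UNDEFINED = None


@dataclass
class AgreementPairSet:
    """Paired labels of two annotators for one concept over the same units."""

    concept: str
    pairs: List[Tuple[str, str]]
    k: Optional[int] = None  # category count; defaults to the concept's catalog k

    def __post_init__(self):
        if self.k is None:
            self.k = catalog.category_count(self.concept)
        if self.k < 2:
            raise ValueError("at least two categories required")
        if self.concept in catalog.VALUES:
            for a, b in self.pairs:
                if a not in catalog.VALUES[self.concept] or b not in catalog.VALUES[self.concept]:
                    raise ValueError(
                        f"label pair ({a!r}, {b!r}) not admissible for {self.concept}"
                    )

    def _require_pairs(self):
        if not self.pairs:
            raise ValueError("empty pair set")


def simple_agreement(pairs: AgreementPairSet) -> float:
    """Proportion of units on which the two annotators agree."""
    pairs._require_pairs()
    return sum(a == b for a, b in pairs.pairs) / len(pairs.pairs)


def cohen_kappa(pairs: AgreementPairSet) -> Optional[float]:
    """Cohen's kappa; ``UNDEFINED`` when expected chance agreement is 1.

    kappa = (po - pe)/(1 - pe) with pe the sum over categories of the
    product of the two annotators' marginal proportions.
    """
    pairs._require_pairs()
    n = len(pairs.pairs)
    po = simple_agreement(pairs)
    marg_a = Counter(a for a, _ in pairs.pairs)
    marg_b = Counter(b for _, b in pairs.pairs)
    pe = sum(marg_a[c] * marg_b[c] for c in set(marg_a) | set(marg_b)) / (n * n)
    if pe >= 1.0 - 1e-12:
        return UNDEFINED
    return (po - pe) / (1.0 - pe)


def g_index(pairs: AgreementPairSet) -> float:
    """G-index: chance agreement is 1/k over the k pre-specified categories.

    Unlike kappa, k counts the concept's full pre-specified category set
    (CGE 2, CCS 5, IGE 4, PT 2), not just the categories observed.
    """
    pairs._require_pairs()
    po = simple_agreement(pairs)
    chance = 1.0 / pairs.k
    return (po - chance) / (1.0 - chance)


# ---------------------------------------------------------------------------
# Rule validation


@dataclass(frozen=True)
class ValidationRecord:
    unit_id: str
    rule_id: Optional[int]  # None = no rule applied
    inferred_class: str
    annot1_class: str
    annot2_class: str

    @property
    def match_level(self) -> str:
        hits = (self.annot1_class == self.inferred_class) + (
            self.annot2_class == self.inferred_class
        )
        return {2: "full", 1: "one", 0: "none"}[hits]


def score_validation(
    records: Sequence[Tuple[Optional[int], str, str, str]]
) -> List[ValidationRecord]:
    """Build scored records from (rule_id, inferred, annot1, annot2) tuples."""
    from .rules import GENE_CLASSES

    out = []
    for i, (rule_id, inferred, a1, a2) in enumerate(records):
        for cls in (inferred, a1, a2):
            if cls not in GENE_CLASSES:
                raise ValueError(f"record {i}: inadmissible gene class {cls!r}")
        out.append(ValidationRecord(f"r{i}", rule_id, inferred, a1, a2))
    return out


@dataclass
class ValidationSummary:
    """Per-rule match counts with micro/macro agreement rates.

    Row keys are rule ids 1-10 plus ``"no_rule"``; a row's agreement rate is
    (full + one)/total, undefined (``None``) for empty rows.  micro pools
    all records; macro is the unweighted mean over the populated rows.
    """

    rows: Dict[object, Dict[str, int]] = field(default_factory=dict)

    def rate(self, key) -> Optional[float]:
        row = self.rows[key]
        total = row["full"] + row["one"] + row["none"]
        if total == 0:
            return None
        return (row["full"] + row["one"]) / total

    @property
    def micro(self) -> float:
        full = sum(r["full"] for r in self.rows.values())
        one = sum(r["one"] for r in self.rows.values())
        total = sum(r["full"] + r["one"] + r["none"] for r in self.rows.values())
        return (full + one) / total

    @property
    def macro(self) -> float:
        rates = [self.rate(k) for k in self.rows if self.rate(k) is not None]
        return sum(rates) / len(rates)

    def to_tsv(self) -> str:
        lines = ["rule\tfull\tone\tnone\ttotal\tagreement_rate"]
        for key in list(range(1, 11)) + ["no_rule"]:
            row = self.rows.get(key, {"full": 0, "one": 0, "none": 0})
            total = row["full"] + row["one"] + row["none"]
            rate = self.rate(key) if key in self.rows else None
            rate_s = "n/a" if rate is None else f"{rate:.2f}"
            lines.append(f"{key}\t{row['full']}\t{row['one']}\t{row['none']}\t{total}\t{rate_s}")
        lines.append(
            "Total\t{}\t{}\t{}\t{}\t{:.2f} (micro), {:.2f} (macro)".format(
                sum(r["full"] for r in self.rows.values()),
                sum(r["one"] for r in self.rows.values()),
                sum(r["none"] for r in self.rows.values()),
                sum(r["full"] + r["one"] + r["none"] for r in self.rows.values()),
                self.micro,
                self.macro,
            )
        )
        return "\n".join(lines) + "\n"


def validation_summary(records: Sequence[ValidationRecord]) -> ValidationSummary:
    """Summarize scored validation records per applied rule."""
    if not records:
        raise ValueError("no validation records")
    rows: Dict[object, Dict[str, int]] = {}
    for rec in records:
        key = rec.rule_id if rec.rule_id is not None else "no_rule"
        row = rows.setdefault(key, {"full": 0, "one": 0, "none": 0})
        row[rec.match_level] += 1
    return ValidationSummary(rows=rows)
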