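"""Synthetic annotated corpora with the reference corpus's statistics.

The generator emulates the published summary of an 821-unit corpus of
prostate, breast and ovarian cancer sentences: concept values are sampled
from the empirical CGE x CCS joint distribution, and IGE and PT are drawn
conditionally independently given CCS from their empirical conditionals
(the reference analysis itself found no residual dependence between the
remaining pairs once CCS is conditioned on).  Sentences are realized from
a small template pool with exact character spans for the gene name, the
expression keyword and the cancer term, so every generated unit passes the
full structural validation and the downstream modules run on synthetic
corpora unchanged.

All randomness derives from a single seed, split into named substreams
(values / templates / perturbation) so extending one feature does not
shift the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import catalog
from .catalog import CCS, CGE, IGE, NOT_ANNOTATED, PT
from .agreement import AgreementPairSet
from .corpus import AnnotationUnit, Corpus, Span

__all__ = [
    "GeneratorConfig",
    "default_config_from_tables",
    "generate_corpus",
    "perturb_annotations",
]

# Empirical counts from the published corpus summary (821 units total).
_CANCER_TYPE_COUNTS = {"prostate": 310, "breast": 255, "ovarian": 256}

# CGE x CCS joint counts over the columns (normal->cancer, cancer->normal,
# unidentifiable); normal->normal and cancer->cancer were never assigned.
_CGE_CCS_COUNTS = {
    ("increased", "normal->cancer"): 318,
    ("increased", "cancer->normal"): 45,
    ("increased", "unidentifiable"): 204,
    ("decreased", "normal->cancer"): 79,
    ("decreased", "cancer->normal"): 76,
    ("decreased", "unidentifiable"): 99,
}

# IGE given CCS ("unchanged" occurs only with normal->cancer; the only two
# "up-regulated" units have cancer->normal CCS).
_IGE_GIVEN_CCS_COUNTS = {
    "normal->cancer": {"up-regulated": 0, "down-regulated": 0, "unchanged": 212, "unidentifiable": 185},
    "cancer->normal": {"up-regulated": 2, "down-regulated": 0, "unchanged": 0, "unidentifiable": 119},
}

# PT given CCS.
_PT_GIVEN_CCS_COUNTS = {
    "normal->cancer": {"observation": 311, "causality": 86},
    "cancer->normal": {"observation": 43, "causality": 78},
}

_GENE_POOL = (
    "TGFB1", "PTEN", "BRCA1", "BRCA2", "ERBB2", "CCND1", "AKT1", "MYC",
    "VEGFA", "ESR1", "CDKN1B", "BCL2", "PAK1", "NKX3-1", "CAV1", "JUN",
    "FOS", "SRC", "MMP2", "IGFBP3",
)

_CANCER_TERMS = {
    "prostate": ("prostate cancer", "prostatic carcinoma"),
    "breast": ("breast cancer", "breast carcinoma"),
    "ovarian": ("ovarian cancer", "ovarian carcinoma"),
}

_KEYWORDS = {
    "increased": ("overexpressed", "up-regulated", "increased"),
    "decreased": ("downregulated", "suppressed", "decreased"),
}

# Placeholders: {gene}, {kw}, {cancer}.
_TEMPLATES = (
    "{gene} is frequently {kw} in human {cancer} tissues.",
    "Expression of {gene} was {kw} in {cancer} cells.",
    "We found that {gene} is {kw} in patients with {cancer}.",
    "{kw} levels of {gene} were detected in {cancer} samples.",
)


def _normalize(counts: Dict, keys: Sequence) -> np.ndarray:
    arr = np.array([float(counts[k]) for k in keys])
    return arr / arr.sum()


@dataclass
class GeneratorConfig:
    """Sampling distributions, pools and sizes for corpus generation.

    Defaults (via :func:`default_config_from_tables`) are the normalized
    published counts; probability dictionaries map value tuples/values to
    probabilities and must each sum to 1 (+-1e-9).
    """

    n_units: int = 821
    seed: int = 0
    cancer_type_probs: Dict[str, float] = field(default_factory=dict)
    cge_ccs_joint: Dict[Tuple[str, str], float] = field(default_factory=dict)
    ige_given_ccs: Dict[str, Dict[str, float]] = field(default_factory=dict)
    pt_given_ccs: Dict[str, Dict[str, float]] = field(default_factory=dict)
    gene_pool: Tuple[str, ...] = _GENE_POOL
    cancer_terms: Dict[str, Tuple[str, ...]] = field(default_factory=lambda: dict(_CANCER_TERMS))
    keywords: Dict[str, Tuple[str, ...]] = field(default_factory=lambda: dict(_KEYWORDS))
    templates: Tuple[str, ...] = _TEMPLATES
    flip_rates: Dict[str, float] = field(
        default_factory=lambda: {CGE: 0.01, CCS: 0.21, IGE: 0.02, PT: 0.14}
    )

    def validate(self) -> List[str]:
        problems = []
        if self.n_units <= 0:
            problems.append("n_units must be positive")
        for name, probs in (
            ("cancer_type_probs", self.cancer_type_probs),
            ("cge_ccs_joint", self.cge_ccs_joint),
        ):
            if probs and abs(sum(probs.values()) - 1.0) > 1e-9:
                problems.append(f"{name} does not sum to 1")
        for name, conditionals in (
            ("ige_given_ccs", self.ige_given_ccs),
            ("pt_given_ccs", self.pt_given_ccs),
        ):
            for ccs_value, probs in conditionals.items():
                if abs(sum(probs.values()) - 1.0) > 1e-9:
                    problems.append(f"{name}[{ccs_value}] does not sum to 1")
        for concept, f in self.flip_rates.items():
            if not 0.0 <= f <= 1.0:
                problems.append(f"flip rate for {concept} outside [0, 1]")
        if not self.gene_pool or not self.templates:
            problems.append("gene pool and template pool must be non-empty")
        return problems


def default_config_from_tables(n_units: int = 821, seed: int = 0) -> GeneratorConfig:
    """Config whose distributions are the normalized published counts.

    E.g. P(CCS = normal->cancer) = 397/821 and
    P(PT = observation | CCS = normal->cancer) = 311/397.
    """
    total = sum(_CGE_CCS_COUNTS.values())
    joint = {k: v / total for k, v in _CGE_CCS_COUNTS.items()}
    type_total = sum(_CANCER_TYPE_COUNTS.values())
    return GeneratorConfig(
        n_units=n_units,
        seed=seed,
        cancer_type_probs={k: v / type_total for k, v in _CANCER_TYPE_COUNTS.items()},
        cge_ccs_joint=joint,
        ige_given_ccs={
            ccs_value: {k: v / sum(c.values()) for k, v in c.items()}
            for ccs_value, c in _IGE_GIVEN_CCS_COUNTS.items()
        },
        pt_given_ccs={
            ccs_value: {k: v / sum(c.values()) for k, v in c.items()}
            for ccs_value, c in _PT_GIVEN_CCS_COUNTS.items()
        },
    )


def _fill_template(template: str, gene: str, kw: str, cancer: str):
    """Realize a template; returns (sentence, span per placeholder role)."""
    spans: Dict[str, Span] = {}
    out = []
    pos = 0
    cursor = 0
    values = {"gene": gene, "kw": kw, "cancer": cancer}
    while True:
        brace = template.find("{", cursor)
        if brace == -1:
            out.append(template[cursor:])
            break
        close = template.index("}", brace)
        out.append(template[cursor:brace])
        pos += brace - cursor
        role = template[brace + 1 : close]
        text = values[role]
        spans[role] = Span(text=text, start=pos, end=pos + len(text))
        out.append(text)
        pos += len(text)
        cursor = close + 1
    sentence = "".join(out)
    # templates may start with a capitalized keyword slot
    if sentence and sentence[0].islower() and spans["kw"].start == 0:
        kw_cap = sentence[0].upper() + spans["kw"].text[1:]
        sentence = kw_cap + sentence[spans["kw"].end :]
        spans["kw"] = Span(text=kw_cap, start=0, end=len(kw_cap))
    return sentence, spans


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Sample ``config.n_units`` valid annotation units (seed-deterministic)."""
    problems = config.validate()
    if problems:
        raise ValueError(f"invalid generator config: {problems}")
    ss = np.random.SeedSequence(config.seed)
    child_values, child_templates, _ = ss.spawn(3)
    rng_values = np.random.default_rng(child_values)
    rng_templates = np.random.default_rng(child_templates)

    types = list(config.cancer_type_probs)
    type_p = np.array([config.cancer_type_probs[t] for t in types])
    joint_keys = list(config.cge_ccs_joint)
    joint_p = np.array([config.cge_ccs_joint[k] for k in joint_keys])

    n = config.n_units
    type_idx = rng_values.choice(len(types), size=n, p=type_p)
    joint_idx = rng_values.choice(len(joint_keys), size=n, p=joint_p)

    units = []
    for i in range(n):
        cancer_type = types[type_idx[i]]
        cge, ccs = joint_keys[joint_idx[i]]
        if ccs == "unidentifiable":
            ige = pt = NOT_ANNOTATED
        else:
            ige_probs = config.ige_given_ccs[ccs]
            ige_keys = list(ige_probs)
            ige = ige_keys[
                rng_values.choice(len(ige_keys), p=np.array([ige_probs[k] for k in ige_keys]))
            ]
            pt_probs = config.pt_given_ccs[ccs]
            pt_keys = list(pt_probs)
            pt = pt_keys[
                rng_values.choice(len(pt_keys), p=np.array([pt_probs[k] for k in pt_keys]))
            ]

        gene = config.gene_pool[rng_templates.integers(len(config.gene_pool))]
        kw = config.keywords[cge][rng_templates.integers(len(config.keywords[cge]))]
        term_pool = config.cancer_terms[cancer_type]
        cancer = term_pool[rng_templates.integers(len(term_pool))]
        template = config.templates[rng_templates.integers(len(config.templates))]
        sentence, spans = _fill_template(template, gene, kw, cancer)

        units.append(
            AnnotationUnit(
                unit_id=f"u{i:06d}",
                pmid="",
                cancer_type=cancer_type,
                sentence=sentence,
                gene=spans["gene"],
                expression_keywords=[spans["kw"]],
                cancer_terms=[spans["cancer"]],
                cge=cge,
                ccs=ccs,
                ige=ige,
                pt=pt,
            )
        )
    return Corpus(units=units, provenance=f"synthetic seed={config.seed} n={n}")


def perturb_annotations(
    corpus: Corpus,
    flip_rates: Dict[str, float],
    seed: int,
) -> Dict[str, AgreementPairSet]:
    """Simulate a second annotator by random label flips.

    For each concept with a flip rate, each annotated unit's value is, with
    probability ``flip_rates[concept]``, replaced by a uniformly random
    *different* admissible value.  Units with the concept skipped
    (NOT_ANNOTATED) contribute no pair, preserving the scheme's structure.
    Returns one :class:`AgreementPairSet` per concept.
    """
    for concept, f in flip_rates.items():
        if concept not in catalog.CONCEPTS:
            raise ValueError(f"unknown concept: {concept!r}")
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"flip rate for {concept} outside [0, 1]")
    ss = np.random.SeedSequence(seed)
    rngs = {c: np.random.default_rng(child) for c, child in zip(catalog.CONCEPTS, ss.spawn(4))}

    out: Dict[str, AgreementPairSet] = {}
    for concept, f in flip_rates.items():
        rng = rngs[concept]
        values = catalog.VALUES[concept]
        pairs = []
        for unit in corpus:
            original = unit.concept_value(concept)
            if original is NOT_ANNOTATED:
                continue
            if rng.random() < f:
                alternatives = [v for v in values if v != original]
                flipped = alternatives[rng.integers(len(alternatives))]
            else:
                flipped = original
            pairs.append((original, flipped))
        out[concept] = AgreementPairSet(concept=concept, pairs=pairs)
    return out
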