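"""Typed annotation units, corpus I/O, markup rendering and term tagging.

The unit of annotation is one mention of a gene expression change that
co-occurs with at least one cancer-related term in a sentence.  A unit
carries character-offset spans for the gene name, the expression-change
keywords and the cancer terms, plus the four concept values (see
:mod:`oncorel.catalog`).

Two canonical on-disk dialects are provided:

* JSONL — one object per line, spans as ``{"text","start","end"}``; IGE/PT
  encoded as ``null`` when skipped.  Offsets are 0-based, half-open, in
  Unicode code points.
* TSV — header row, spans carried inline in a bracket-marked sentence:
  ``[*…*]_g_`` (gene), ``[*…*]_e_`` (expression keyword), ``[*…*]_c_``
  (cancer term); empty IGE/PT cell means skipped.

``parse(write(c)) == c`` field-for-field in both dialects.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Sequence, TextIO

from . import catalog
from .catalog import CCS, CGE, IGE, NOT_ANNOTATED, PT

__all__ = [
    "Span",
    "AnnotationUnit",
    "Corpus",
    "CorpusFormatError",
    "validate_unit",
    "parse_corpus",
    "write_corpus",
    "render_marked_sentence",
    "parse_marked_sentence",
    "strip_markers",
    "longest_match_tag",
    "load_dictionary",
]


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files; carries line number and field."""

    def __init__(self, message: str, line: Optional[int] = None, fieldname: Optional[str] = None):
        loc = f"line {line}: " if line is not None else ""
        fld = f" (field {fieldname!r})" if fieldname else ""
        super().__init__(f"{loc}{message}{fld}")
        self.line = line
        self.fieldname = fieldname


@dataclass(frozen=True)
class Span:
    """A substring of the containing sentence: 0-based, half-open offsets."""

    text: str
    start: int
    end: int

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class AnnotationUnit:
    """One gene-expression-change mention with its four concept values."""

    unit_id: str
    sentence: str
    gene: Span
    expression_keywords: List[Span]
    cancer_terms: List[Span]
    cge: str
    ccs: str
    ige: Optional[str] = NOT_ANNOTATED
    pt: Optional[str] = NOT_ANNOTATED
    pmid: str = ""
    cancer_type: str = "other:unspecified"

    def concept_value(self, concept: str) -> Optional[str]:
        return {CGE: self.cge, CCS: self.ccs, IGE: self.ige, PT: self.pt}[concept]


@dataclass
class Corpus:
    """An ordered collection of annotation units with unique ids."""

    units: List[AnnotationUnit] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self) -> Iterator[AnnotationUnit]:
        return iter(self.units)


_CANCER_TYPES = ("prostate", "breast", "ovarian")


def _span_violations(span: Span, sentence: str, role: str) -> List[str]:
    out = []
    if not (0 <= span.start < span.end <= len(sentence)):
        out.append(
            f"{role} span [{span.start},{span.end}) outside sentence of length {len(sentence)}"
        )
    elif sentence[span.start : span.end] != span.text:
        out.append(
            f"{role} span text {span.text!r} does not match sentence substring "
            f"{sentence[span.start:span.end]!r}"
        )
    return out


def validate_unit(unit: AnnotationUnit) -> List[str]:
    """Check every structural invariant of *unit*; violations are data.

    Returns an empty list iff the unit is valid.  Each entry names the
    invariant and the offending field.
    """
    v: List[str] = []
    if not unit.unit_id:
        v.append("unit_id: empty")
    if not (unit.cancer_type in _CANCER_TYPES or unit.cancer_type.startswith("other:")):
        v.append(f"cancer_type: {unit.cancer_type!r} not a known type or 'other:<name>'")

    if not catalog.is_admissible(CGE, unit.cge):
        v.append(f"cge: inadmissible value {unit.cge!r}")
    if not catalog.is_admissible(CCS, unit.ccs):
        v.append(f"ccs: inadmissible value {unit.ccs!r}")
    if not catalog.is_admissible(IGE, unit.ige, allow_skip=True):
        v.append(f"ige: inadmissible value {unit.ige!r}")
    if not catalog.is_admissible(PT, unit.pt, allow_skip=True):
        v.append(f"pt: inadmissible value {unit.pt!r}")

    # IGE/PT are skipped iff CCS is "unidentifiable".
    if unit.ccs == "unidentifiable":
        if unit.ige is not NOT_ANNOTATED:
            v.append("ige: IGE annotated with unidentifiable CCS")
        if unit.pt is not NOT_ANNOTATED:
            v.append("pt: PT annotated with unidentifiable CCS")
    elif catalog.is_admissible(CCS, unit.ccs):
        if unit.ige is NOT_ANNOTATED:
            v.append("ige: IGE missing while CCS is identifiable")
        if unit.pt is NOT_ANNOTATED:
            v.append("pt: PT missing while CCS is identifiable")

    if not unit.expression_keywords:
        v.append("expression_keywords: at least one expression keyword span required")
    if not unit.cancer_terms:
        v.append("cancer_terms: at least one cancer-term span required")

    v.extend(_span_violations(unit.gene, unit.sentence, "gene"))
    for i, s in enumerate(unit.expression_keywords):
        v.extend(_span_violations(s, unit.sentence, f"expression_keywords[{i}]"))
    for i, s in enumerate(unit.cancer_terms):
        v.extend(_span_violations(s, unit.sentence, f"cancer_terms[{i}]"))
    return v


# ---------------------------------------------------------------------------
# JSONL dialect


def _span_to_json(s: Span) -> dict:
    return {"text": s.text, "start": s.start, "end": s.end}


def _span_from_json(obj: dict, line: int, fieldname: str) -> Span:
    try:
        return Span(text=obj["text"], start=int(obj["start"]), end=int(obj["end"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise CorpusFormatError(f"malformed span: {exc}", line, fieldname) from exc


def _unit_to_json(u: AnnotationUnit) -> dict:
    return {
        "unit_id": u.unit_id,
        "pmid": u.pmid,
        "cancer_type": u.cancer_type,
        "sentence": u.sentence,
        "gene": _span_to_json(u.gene),
        "expression_keywords": [_span_to_json(s) for s in u.expression_keywords],
        "cancer_terms": [_span_to_json(s) for s in u.cancer_terms],
        "cge": u.cge,
        "ccs": u.ccs,
        "ige": u.ige,
        "pt": u.pt,
    }


def _unit_from_json(obj: dict, line: int) -> AnnotationUnit:
    required = ("unit_id", "sentence", "gene", "expression_keywords", "cancer_terms", "cge", "ccs")
    for key in required:
        if key not in obj:
            raise CorpusFormatError("missing required key", line, key)
    return AnnotationUnit(
        unit_id=str(obj["unit_id"]),
        pmid=str(obj.get("pmid") or ""),
        cancer_type=str(obj.get("cancer_type") or "other:unspecified"),
        sentence=obj["sentence"],
        gene=_span_from_json(obj["gene"], line, "gene"),
        expression_keywords=[
            _span_from_json(s, line, "expression_keywords") for s in obj["expression_keywords"]
        ],
        cancer_terms=[_span_from_json(s, line, "cancer_terms") for s in obj["cancer_terms"]],
        cge=obj["cge"],
        ccs=obj["ccs"],
        ige=obj.get("ige", NOT_ANNOTATED),
        pt=obj.get("pt", NOT_ANNOTATED),
    )


# ---------------------------------------------------------------------------
# Bracket markup (shared by the TSV dialect and render_marked_sentence)

_ROLE_TAGS = {"gene": "g", "keyword": "e", "cancer": "c"}
_MARKER_RE = re.compile(r"\[\*(.*?)\*\]_([gec])_", re.DOTALL)


def render_marked_sentence(unit: AnnotationUnit) -> str:
    """Render the sentence with inline role markers.

    The gene span is wrapped as ``[*…*]_g_``, expression keywords as
    ``[*…*]_e_`` and cancer terms as ``[*…*]_c_``.  Markers are inserted
    right-to-left so earlier offsets stay valid; :func:`strip_markers`
    recovers the original sentence exactly.
    """
    problems = validate_unit(unit)
    if problems:
        raise ValueError(f"cannot render invalid unit {unit.unit_id}: {problems}")
    tagged = [(unit.gene, "g")]
    tagged += [(s, "e") for s in unit.expression_keywords]
    tagged += [(s, "c") for s in unit.cancer_terms]
    for (a, ra), (b, rb) in _pairs(tagged):
        if a.overlaps(b):
            raise ValueError(
                f"overlapping spans: {a.text!r}[{a.start},{a.end})/_{ra}_ and "
                f"{b.text!r}[{b.start},{b.end})/_{rb}_"
            )
    out = unit.sentence
    for span, tag in sorted(tagged, key=lambda t: t[0].start, reverse=True):
        out = out[: span.start] + f"[*{span.text}*]_{tag}_" + out[span.end :]
    return out


def _pairs(items):
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            yield items[i], items[j]


def strip_markers(marked: str) -> str:
    """Remove all ``[*…*]_x_`` role markers, recovering the plain sentence."""
    return _MARKER_RE.sub(lambda m: m.group(1), marked)


def parse_marked_sentence(marked: str):
    """Invert the bracket markup: plain sentence plus spans per role tag.

    Returns ``(sentence, {"g": [Span,…], "e": […], "c": […]})`` with spans
    in textual order.
    """
    spans = {"g": [], "e": [], "c": []}
    sentence_parts: List[str] = []
    pos = 0  # cursor in the marked string
    plain_len = 0
    for m in _MARKER_RE.finditer(marked):
        before = marked[pos : m.start()]
        sentence_parts.append(before)
        plain_len += len(before)
        text = m.group(1)
        spans[m.group(2)].append(Span(text=text, start=plain_len, end=plain_len + len(text)))
        sentence_parts.append(text)
        plain_len += len(text)
        pos = m.end()
    sentence_parts.append(marked[pos:])
    return "".join(sentence_parts), spans


# ---------------------------------------------------------------------------
# Corpus I/O

_TSV_COLUMNS = ("unit_id", "pmid", "cancer_type", "marked_sentence", "cge", "ccs", "ige", "pt")


def parse_corpus(source: TextIO | str, format: str = "jsonl") -> Corpus:
    """Parse a corpus stream in one of the canonical dialects.

    Every unit is validated; the first invalid record aborts the parse with
    an error naming the line number and field.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    if format == "jsonl":
        units = list(_parse_jsonl(source))
    elif format == "tsv":
        units = list(_parse_tsv(source))
    else:
        raise ValueError(f"unknown corpus format: {format!r} (expected 'jsonl' or 'tsv')")

    seen = set()
    for u in units:
        if u.unit_id in seen:
            raise CorpusFormatError(f"duplicate unit_id {u.unit_id!r}")
        seen.add(u.unit_id)
    return Corpus(units=units)


def _check_parsed(unit: AnnotationUnit, line: int) -> AnnotationUnit:
    problems = validate_unit(unit)
    if problems:
        raise CorpusFormatError("; ".join(problems), line)
    return unit


def _parse_jsonl(stream: TextIO) -> Iterator[AnnotationUnit]:
    for line_no, raw in enumerate(stream, start=1):
        if not raw.strip():
            continue
        try:
            obj = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise CorpusFormatError(f"invalid JSON: {exc.msg}", line_no) from exc
        yield _check_parsed(_unit_from_json(obj, line_no), line_no)


def _parse_tsv(stream: TextIO) -> Iterator[AnnotationUnit]:
    header_seen = False
    for line_no, raw in enumerate(stream, start=1):
        row = raw.rstrip("\n")
        if not row:
            continue
        cells = row.split("\t")
        if not header_seen:
            if tuple(cells) != _TSV_COLUMNS:
                raise CorpusFormatError(
                    f"bad TSV header {cells!r}, expected {list(_TSV_COLUMNS)}", line_no
                )
            header_seen = True
            continue
        if len(cells) != len(_TSV_COLUMNS):
            raise CorpusFormatError(
                f"expected {len(_TSV_COLUMNS)} columns, got {len(cells)}", line_no
            )
        rec = dict(zip(_TSV_COLUMNS, cells))
        sentence, spans = parse_marked_sentence(rec["marked_sentence"])
        if len(spans["g"]) != 1:
            raise CorpusFormatError(
                f"expected exactly one gene marker, found {len(spans['g'])}",
                line_no,
                "marked_sentence",
            )
        yield _check_parsed(
            AnnotationUnit(
                unit_id=rec["unit_id"],
                pmid=rec["pmid"],
                cancer_type=rec["cancer_type"],
                sentence=sentence,
                gene=spans["g"][0],
                expression_keywords=spans["e"],
                cancer_terms=spans["c"],
                cge=rec["cge"],
                ccs=rec["ccs"],
                ige=rec["ige"] or NOT_ANNOTATED,
                pt=rec["pt"] or NOT_ANNOTATED,
            ),
            line_no,
        )


def write_corpus(corpus: Corpus, format: str = "jsonl") -> str:
    """Serialize *corpus* to the given dialect (round-trip inverse of parse)."""
    for u in corpus:
        problems = validate_unit(u)
        if problems:
            raise ValueError(f"refusing to serialize invalid unit {u.unit_id!r}: {problems}")
    if format == "jsonl":
        return "".join(json.dumps(_unit_to_json(u), ensure_ascii=False) + "\n" for u in corpus)
    if format == "tsv":
        lines = ["\t".join(_TSV_COLUMNS)]
        for u in corpus:
            lines.append(
                "\t".join(
                    (
                        u.unit_id,
                        u.pmid,
                        u.cancer_type,
                        render_marked_sentence(u),
                        u.cge,
                        u.ccs,
                        u.ige or "",
                        u.pt or "",
                    )
                )
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown corpus format: {format!r} (expected 'jsonl' or 'tsv')")


# ---------------------------------------------------------------------------
# Dictionary-based cancer-term tagging


def load_dictionary(source: TextIO | str | Iterable[str]) -> set:
    """Load a term dictionary: one term per line, '#' comments ignored."""
    if isinstance(source, str):
        source = io.StringIO(source)
    terms = set()
    for line in source:
        term = line.split("#", 1)[0].strip()
        if term:
            terms.add(term)
    return terms


def _is_token_char(ch: str) -> bool:
    return ch.isalnum()


def _boundary_ok(text: str, start: int, end: int) -> bool:
    if start > 0 and _is_token_char(text[start - 1]) and _is_token_char(text[start]):
        return False
    if end < len(text) and _is_token_char(text[end - 1]) and _is_token_char(text[end]):
        return False
    return True


def longest_match_tag(text: str, dictionary: Sequence[str] | set) -> List[Span]:
    """Leftmost-longest, non-overlapping dictionary matching.

    Matching is case-insensitive and anchored at token boundaries, where a
    token is a maximal run of letters/digits; scanning resumes after each
    match.  This is the standard greedy tagger used to locate disease terms.
    """
    terms = [t for t in dictionary if t]
    if not terms:
        raise ValueError("dictionary must contain at least one non-empty term")
    lowered = sorted({t.lower() for t in terms}, key=len, reverse=True)
    low_text = text.lower()
    spans: List[Span] = []
    i = 0
    n = len(text)
    while i < n:
        if not _is_token_char(text[i]) or (i > 0 and _is_token_char(text[i - 1])):
            i += 1
            continue
        hit = None
        for term in lowered:  # longest first
            end = i + len(term)
            if end <= n and low_text[i:end] == term and _boundary_ok(text, i, end):
                hit = end
                break
        if hit is None:
            i += 1
        else:
            spans.append(Span(text=text[i:hit], start=i, end=hit))
            i = hit
    return spans
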