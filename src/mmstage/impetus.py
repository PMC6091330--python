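"""Parser and classifiers for IMPeTUs PET/CT descriptor strings.

IMPeTUs (Italian Myeloma criteria for PET USe) is a standardized visual
notation for FDG-PET/CT findings in multiple myeloma.  A descriptor is a
comma-separated token list such as::

    BM(3), F3.SP.ExtraSP(4), L2, PM, EM.N(2)

with the components

``BM(n)[A]``
    Diffuse bone-marrow uptake graded 1-5 on the Deauville scale; an optional
    ``A`` suffix marks appendicular-skeleton involvement (stored verbatim,
    uninterpreted).
``F<g>[.S][.SP][.ExtraSP][(n)]``
    Focal bone lesions: a 1-4 lesion-count grade, site flags (skull, spine,
    outside the spine) and an optional Deauville score of the hottest lesion.
``L<g>``
    Lytic-lesion count grade 1-4.
``Fr``
    Pathological fracture.
``PM``
    Paramedullary disease (soft-tissue extension through breached cortex).
``EM[.N[(n)]][.EN[(n)]]``
    Extramedullary disease with nodal/extranodal site flags, each carrying an
    optional Deauville score; a score may follow each site, e.g.
    ``EM.N(5)EN(4)``.

Deauville scores grade uptake against the mediastinal blood pool (2/3
boundary) and the liver (3/4 boundary): 1 no uptake, 2 <= mediastinum,
3 > mediastinum but <= liver, 4 moderately > liver, 5 markedly > liver.
Lesion-count grades: 1 = no lesions, 2 = 1-3, 3 = 4-10, 4 = >10.

Positivity cutoffs (``em_positive``, ``bone_positive``) follow the PET
reading rules used for Durie-Salmon Plus staging: Deauville >= 4, or >= 3
for small (0.5-1 cm) diffuse lytic lesions when a size is supplied.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "EmSite",
    "ImpetusDescriptor",
    "GradeSemantics",
    "DEFAULT_GRADE_SEMANTICS",
    "parse_descriptor",
    "serialize_descriptor",
    "em_positive",
    "bone_positive",
]

#: token spelling -> canonical focal-site name
FOCAL_SITE_TOKENS = {"S": "skull", "SP": "spine", "ExtraSP": "extraspine"}
#: canonical focal-site order used by the serializer
FOCAL_SITE_ORDER = ("skull", "spine", "extraspine")
#: token spelling -> canonical extramedullary-site name
EM_SITE_TOKENS = {"N": "nodal", "EN": "extranodal"}
EM_TOKEN_FOR_SITE = {v: k for k, v in EM_SITE_TOKENS.items()}
FOCAL_TOKEN_FOR_SITE = {v: k for k, v in FOCAL_SITE_TOKENS.items()}

DEAUVILLE_RANGE = range(1, 6)
GRADE_RANGE = range(1, 5)


class ParseError(ValueError):
    """Malformed IMPeTUs token; carries the offending token and its offset."""

    def __init__(self, message: str, token: str, offset: int):
        super().__init__(f"{message}: {token!r} at offset {offset}")
        self.token = token
        self.offset = offset


def _check_deauville(value: int, what: str) -> None:
    if value not in DEAUVILLE_RANGE:
        raise ValueError(f"{what} must be a Deauville score 1-5, got {value}")


def _check_grade(value: int, what: str) -> None:
    if value not in GRADE_RANGE:
        raise ValueError(f"{what} must be a lesion-count grade 1-4, got {value}")


@dataclass(frozen=True)
class EmSite:
    """One extramedullary site flag with its (optional) Deauville score."""

    site: str  # 'nodal' | 'extranodal'
    score: Optional[int] = None

    def __post_init__(self) -> None:
        if self.site not in EM_TOKEN_FOR_SITE:
            raise ValueError(f"unknown EM site {self.site!r}")
        if self.score is not None:
            _check_deauville(self.score, "EM site score")


@dataclass(frozen=True)
class ImpetusDescriptor:
    """Structured record of one IMPeTUs descriptor string.

    ``raw`` keeps the original text for provenance and is excluded from
    equality, so a parsed string and its re-parsed canonical serialization
    compare equal.
    """

    bm_score: int
    bm_appendicular: bool = False
    focal_grade: Optional[int] = None
    focal_sites: frozenset = frozenset()
    focal_score: Optional[int] = None
    lytic_grade: Optional[int] = None
    fracture: bool = False
    paramedullary: bool = False
    em_present: bool = False
    em_sites: tuple = ()
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        _check_deauville(self.bm_score, "BM score")
        if self.focal_grade is not None:
            _check_grade(self.focal_grade, "focal grade")
        if self.focal_score is not None:
            if self.focal_grade is None:
                raise ValueError("focal score requires a focal grade")
            _check_deauville(self.focal_score, "focal score")
        if self.focal_sites and self.focal_grade is None:
            raise ValueError("focal sites require a focal grade")
        unknown = set(self.focal_sites) - set(FOCAL_SITE_ORDER)
        if unknown:
            raise ValueError(f"unknown focal sites {sorted(unknown)}")
        if self.lytic_grade is not None:
            _check_grade(self.lytic_grade, "lytic grade")
        if self.em_sites and not self.em_present:
            raise ValueError("em_sites given without em_present")


@dataclass(frozen=True)
class GradeSemantics:
    """Meaning of the numeric grades; editable configuration, not hard-coded.

    Count ranges are half-open on the right only at the top grade, whose
    upper bound is ``None`` (">10 lesions").
    """

    focal_grade_to_count_range: dict = field(
        default_factory=lambda: {1: (0, 0), 2: (1, 3), 3: (4, 10), 4: (11, None)}
    )
    lytic_grade_to_count_range: dict = field(
        default_factory=lambda: {1: (0, 0), 2: (1, 3), 3: (4, 10), 4: (11, None)}
    )
    deauville_reference_text: dict = field(
        default_factory=lambda: {
            1: "no uptake",
            2: "uptake <= mediastinum",
            3: "uptake > mediastinum but <= liver",
            4: "uptake > liver + 10%",
            5: "uptake markedly > liver",
        }
    )

    def __post_init__(self) -> None:
        for name, table in (
            ("focal", self.focal_grade_to_count_range),
            ("lytic", self.lytic_grade_to_count_range),
        ):
            prev_hi = -1
            for grade in sorted(table):
                lo, hi = table[grade]
                if lo <= prev_hi:
                    raise ValueError(f"{name} grade ranges overlap at grade {grade}")
                prev_hi = float("inf") if hi is None else hi


DEFAULT_GRADE_SEMANTICS = GradeSemantics()

_BM_RE = re.compile(r"^BM\((\d+)\)(A?)$")
_F_RE = re.compile(r"^F(\d+)((?:\.(?:ExtraSP|SP|S))*)(?:\((\d+)\))?$")
_L_RE = re.compile(r"^L(\d+)$")
_EM_RE = re.compile(r"^EM(.*)$", re.DOTALL)
_EM_SITE_RE = re.compile(r"\.?(EN|N)(?:\((\d+)\))?")


def _split_tokens(text: str) -> Iterable[tuple[str, int]]:
    """Yield (token, offset-of-token-in-text) for a comma-separated list."""
    pos = 0
    for chunk in text.split(","):
        stripped = chunk.strip()
        offset = pos + chunk.index(stripped) if stripped else pos
        yield stripped, offset
        pos += len(chunk) + 1


def _parse_em_sites(body: str, token: str, offset: int) -> tuple:
    sites = []
    pos = 0
    while pos < len(body):
        m = _EM_SITE_RE.match(body, pos)
        if m is None or m.start() != pos:
            raise ParseError("malformed EM site list", token, offset)
        score = int(m.group(2)) if m.group(2) is not None else None
        if score is not None and score not in DEAUVILLE_RANGE:
            raise ParseError("EM score outside 1-5", token, offset)
        sites.append(EmSite(EM_SITE_TOKENS[m.group(1)], score))
        pos = m.end()
    return tuple(sites)


def parse_descriptor(text: str) -> ImpetusDescriptor:
    """Parse an IMPeTUs string into an :class:`ImpetusDescriptor`.

    Token names are case-sensitive; whitespace around commas is ignored;
    unknown or malformed tokens raise :class:`ParseError` naming the token
    and its character offset.  The bone-marrow component is mandatory.
    """
    if not isinstance(text, str) or not text.strip():
        raise ParseError("empty descriptor", text if isinstance(text, str) else "", 0)

    fields: dict = {}

    def set_once(key: str, value, token: str, offset: int) -> None:
        if key in fields:
            raise ParseError(f"duplicate {key} component", token, offset)
        fields[key] = value

    for token, offset in _split_tokens(text):
        if not token:
            raise ParseError("empty token", token, offset)
        if token == "PM":
            set_once("paramedullary", True, token, offset)
            continue
        if token == "Fr":
            set_once("fracture", True, token, offset)
            continue
        m = _BM_RE.match(token)
        if m:
            score = int(m.group(1))
            if score not in DEAUVILLE_RANGE:
                raise ParseError("BM score outside 1-5", token, offset)
            set_once("bm_score", score, token, offset)
            fields["bm_appendicular"] = m.group(2) == "A"
            continue
        m = _F_RE.match(token)
        if m and token.startswith("F"):
            grade = int(m.group(1))
            if grade not in GRADE_RANGE:
                raise ParseError("focal grade outside 1-4", token, offset)
            set_once("focal_grade", grade, token, offset)
            sites = frozenset(
                FOCAL_SITE_TOKENS[s] for s in m.group(2).split(".") if s
            )
            fields["focal_sites"] = sites
            if m.group(3) is not None:
                score = int(m.group(3))
                if score not in DEAUVILLE_RANGE:
                    raise ParseError("focal score outside 1-5", token, offset)
                fields["focal_score"] = score
            continue
        m = _L_RE.match(token)
        if m:
            grade = int(m.group(1))
            if grade not in GRADE_RANGE:
                raise ParseError("lytic grade outside 1-4", token, offset)
            set_once("lytic_grade", grade, token, offset)
            continue
        m = _EM_RE.match(token)
        if m:
            set_once("em_present", True, token, offset)
            fields["em_sites"] = _parse_em_sites(m.group(1), token, offset)
            continue
        raise ParseError("unknown token", token, offset)

    if "bm_score" not in fields:
        raise ParseError("missing mandatory BM component", text.strip(), 0)
    try:
        return ImpetusDescriptor(raw=text, **fields)
    except ValueError as exc:  # invariant violations surface as parse errors
        raise ParseError(str(exc), text.strip(), 0) from exc


def serialize_descriptor(d: ImpetusDescriptor) -> str:
    """Render the canonical string form; ``parse(serialize(d)) == d``."""
    tokens = [f"BM({d.bm_score}){'A' if d.bm_appendicular else ''}"]
    if d.focal_grade is not None:
        t = f"F{d.focal_grade}"
        for site in FOCAL_SITE_ORDER:
            if site in d.focal_sites:
                t += f".{FOCAL_TOKEN_FOR_SITE[site]}"
        if d.focal_score is not None:
            t += f"({d.focal_score})"
        tokens.append(t)
    if d.lytic_grade is not None:
        tokens.append(f"L{d.lytic_grade}")
    if d.fracture:
        tokens.append("Fr")
    if d.paramedullary:
        tokens.append("PM")
    if d.em_present:
        t = "EM"
        for s in d.em_sites:
            t += f".{EM_TOKEN_FOR_SITE[s.site]}"
            if s.score is not None:
                t += f"({s.score})"
        tokens.append(t)
    return ", ".join(tokens)


def em_positive(d: ImpetusDescriptor, min_score: int = 4) -> bool:
    """PET-positive extramedullary disease: any EM site with Deauville >= 4.

    Sites without a recorded score are treated as non-assessable and do not
    count toward positivity (logged at debug level).
    """
    if not d.em_present:
        return False
    scores = [s.score for s in d.em_sites if s.score is not None]
    if len(scores) < len(d.em_sites):
        logger.debug(
            "EM site(s) without Deauville score treated as non-assessable: %r",
            d.raw or serialize_descriptor(d),
        )
    return any(score >= min_score for score in scores)


def bone_positive(
    d: ImpetusDescriptor,
    lesion_size_cm: Optional[float] = None,
    min_score: int = 4,
    small_lytic_min_score: int = 3,
) -> bool:
    """PET-positive focal bone disease.

    Positive when the focal-lesion Deauville score is >= 4, or — for small
    diffuse lytic lesions, when a lesion size between 0.5 and 1 cm is
    supplied — when the score is >= 3.  The size is a side input because
    descriptor strings carry no lesion sizes.
    """
    if d.focal_score is None:
        return False
    if d.focal_score >= min_score:
        return True
    if (
        lesion_size_cm is not None
        and 0.5 <= lesion_size_cm <= 1.0
        and d.focal_score >= small_lytic_min_score
    ):
        return True
    return False
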