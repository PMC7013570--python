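"""ICD-9/ICD-10 code handling and comorbidity-category mapping.

Admission records code diagnoses with ICD-9-AM or ICD-10-AM codes.  For
network construction those codes are grouped into a small set of chronic
comorbidity categories (the Elixhauser index in the Quan et al. coding),
while two *index diseases* — type 2 diabetes mellitus (T2DM) and
cardiovascular disease (CVD, the union of five constituent categories) —
define cohort membership rather than network nodes.

The mapping is shipped as an editable delimited text file
(``data/elixhauser_quan.tsv``) so that alternative comorbidity indices can
be substituted without code changes.  Patterns use three notations:

* exact:    ``404.11``       — matches that canonical code only
* wildcard: ``428.x``        — matches every code with that prefix
* range:    ``250.0-250.3``  — inclusive clinical range (en dash accepted)

Canonical form is the uppercased code with the dot removed, e.g.
``i50.9`` → ``I509``.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

logger = logging.getLogger(__name__)

DEFAULT_MAPPING_RESOURCE = "elixhauser_quan.tsv"
DEFAULT_EXCLUSION_RESOURCE = "exclusions.tsv"


class IcdError(ValueError):
    """Raised for malformed codes, patterns, or corrupt mapping tables."""


class IcdVersion(enum.Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"

    @classmethod
    def parse(cls, text: str) -> "IcdVersion":
        t = str(text).strip().upper().replace("-", "").replace("AM", "")
        if t in ("ICD9", "9"):
            return cls.ICD9
        if t in ("ICD10", "10"):
            return cls.ICD10
        raise IcdError(f"unrecognized ICD version tag: {text!r}")


_ICD9_RE = re.compile(r"^[VE]?[0-9]+$")
_ICD10_RE = re.compile(r"^[A-Z][0-9A-Z]+$")


@dataclass(frozen=True)
class IcdCode:
    """A single diagnosis code with its coding-system version.

    ``raw`` preserves the text as recorded; ``canonical`` is the matching
    form (uppercase, no dot, no whitespace).
    """

    version: IcdVersion
    raw: str
    canonical: str


def _clean(raw: str) -> str:
    return re.sub(r"[\s.]", "", str(raw)).upper()


def canonicalize(raw: str, version: IcdVersion) -> IcdCode:
    """Canonicalize a raw code; idempotent on already-canonical codes.

    Raises :class:`IcdError` for codes that are empty after cleaning or
    syntactically impossible in the stated version, so that callers can
    skip-and-log bad rows.
    """
    canonical = _clean(raw)
    if not canonical:
        raise IcdError(f"empty ICD code after cleaning: {raw!r}")
    if version is IcdVersion.ICD9:
        if not _ICD9_RE.match(canonical):
            raise IcdError(f"malformed ICD-9 code: {raw!r}")
    else:
        if not _ICD10_RE.match(canonical):
            raise IcdError(f"malformed ICD-10 code: {raw!r}")
    return IcdCode(version=version, raw=str(raw), canonical=canonical)


def infer_version(raw: str) -> IcdVersion:
    """Heuristic version inference for inputs without a version column.

    Leading digit or 'V' → ICD-9; any leading letter including 'E' →
    ICD-10.  ICD-9 external-cause codes (E800–E999) share the shape of
    ICD-10 chapter-E metabolic codes and cannot be told apart without a
    version tag; they are resolved to ICD-10 because chapter E carries the
    endocrine and metabolic diagnoses this analysis depends on, while
    external-cause codes map to no comorbidity either way.
    """
    canonical = _clean(raw)
    if not canonical:
        raise IcdError(f"empty ICD code after cleaning: {raw!r}")
    head = canonical[0]
    if head.isdigit() or head == "V":
        return IcdVersion.ICD9
    return IcdVersion.ICD10


class PatternKind(enum.Enum):
    EXACT = "exact"
    WILDCARD = "wildcard"
    RANGE = "range"


@dataclass(frozen=True)
class CodePattern:
    version: IcdVersion
    kind: PatternKind
    payload: Union[str, tuple[str, str]]

    def representative(self) -> str:
        """A canonical code guaranteed to match this pattern."""
        if self.kind is PatternKind.RANGE:
            return self.payload[0]
        return self.payload  # exact payload / wildcard prefix


_RANGE_SEP_RE = re.compile(r"\s*[–-]\s*")
_WILDCARD_RE = re.compile(r"^(.*?)\.?[xX]$")


def _endpoint(text: str, version: IcdVersion, spec: str) -> str:
    # range endpoints may themselves carry a trailing ".x"
    m = _WILDCARD_RE.match(text.strip())
    base = m.group(1) if m else text
    canonical = _clean(base)
    if not canonical:
        raise IcdError(f"empty range endpoint in pattern {spec!r}")
    return canonical


def compile_pattern(spec: str, version: IcdVersion) -> CodePattern:
    """Compile one pattern in exact / wildcard / range notation.

    Raises :class:`IcdError` with the offending fragment for anything that
    fits none of the three notations.
    """
    text = str(spec).strip()
    if not text:
        raise IcdError("empty pattern")
    parts = _RANGE_SEP_RE.split(text)
    if len(parts) == 2:
        low, high = (_endpoint(p, version, text) for p in parts)
        if (low[: len(high)] if len(low) > len(high) else low) > (
            high[: len(low)] if len(high) > len(low) else high
        ):
            raise IcdError(f"inverted range in pattern {text!r}: {low} > {high}")
        return CodePattern(version, PatternKind.RANGE, (low, high))
    if len(parts) > 2:
        raise IcdError(f"unrecognized pattern notation (multiple dashes): {text!r}")
    m = _WILDCARD_RE.match(text)
    if m:
        prefix = _clean(m.group(1))
        if not prefix:
            raise IcdError(f"wildcard pattern with empty prefix: {text!r}")
        return CodePattern(version, PatternKind.WILDCARD, prefix)
    return CodePattern(version, PatternKind.EXACT, _clean(text))


def matches(code: IcdCode, pattern: CodePattern) -> bool:
    """Whether a canonical code falls under a compiled pattern.

    Range semantics: a code is in range if its canonical form truncated to
    each bound's length lies within that bound, which reproduces clinical
    range readings such as "250.0–250.3 covers 250.0x through 250.3x" and
    also handles unequal-length bounds (424.0–424.91).
    """
    if code.version is not pattern.version:
        raise IcdError(
            f"version mismatch: code {code.canonical} is {code.version.value}, "
            f"pattern is {pattern.version.value}"
        )
    c = code.canonical
    if pattern.kind is PatternKind.EXACT:
        return c == pattern.payload
    if pattern.kind is PatternKind.WILDCARD:
        return c.startswith(pattern.payload)
    low, high = pattern.payload
    return c[: len(low)] >= low and c[: len(high)] <= high


@dataclass
class ComorbidityMap:
    """Compiled comorbidity lookup: category name → pattern lists.

    ``map_code`` hard-errors if a code matches two categories — the bundled
    table is curated to be disjoint, and a corrupt user-supplied table
    should fail loudly rather than silently pick one.
    """

    categories: list[str]
    patterns: dict[str, list[CodePattern]] = field(default_factory=dict)

    def map_code(self, code: IcdCode) -> Optional[str]:
        hits = []
        for category in self.categories:
            for pattern in self.patterns.get(category, ()):
                if pattern.version is code.version and matches(code, pattern):
                    hits.append(category)
                    break
        if len(hits) > 1:
            raise IcdError(
                f"code {code.canonical} ({code.version.value}) matches multiple "
                f"categories: {hits}"
            )
        return hits[0] if hits else None


@dataclass
class IndexDiseaseDef:
    """An index (cohort-defining) disease: T2DM, or CVD with 5 subcategories."""

    name: str
    patterns: list[CodePattern] = field(default_factory=list)
    subcategories: dict[str, list[CodePattern]] = field(default_factory=dict)

    def matches_code(self, code: IcdCode) -> bool:
        return any(
            p.version is code.version and matches(code, p) for p in self.patterns
        )


@dataclass
class MappingTables:
    """Everything a run needs from the mapping files."""

    comorbidities: ComorbidityMap
    index_diseases: dict[str, IndexDiseaseDef]
    exclusions: list[CodePattern]


def _read_rows(source: Union[str, Path, Iterable[str]]) -> list[tuple[str, str, str, str]]:
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = list(source)
    rows = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split("\t")
        if len(parts) != 4:
            raise IcdError(f"mapping line {lineno}: expected 4 tab-separated fields")
        rows.append(tuple(p.strip() for p in parts))
    return rows


def load_mapping(
    path: Union[str, Path, None] = None,
    exclusion_path: Union[str, Path, None] = None,
) -> MappingTables:
    """Load the bundled mapping (default) or user-supplied mapping files.

    Roles: ``comorbidity`` rows feed the ComorbidityMap; ``index:<name>``
    and ``index:<name>:<subcategory>`` rows feed IndexDiseaseDefs;
    ``exclusion`` rows feed the cleaning filter.
    """
    rows: list[tuple[str, str, str, str]] = []
    if path is None:
        data = resources.files("comorbnet.data").joinpath(DEFAULT_MAPPING_RESOURCE)
        rows += _read_rows(data.read_text().splitlines())
    else:
        rows += _read_rows(path)
    if exclusion_path is None:
        data = resources.files("comorbnet.data").joinpath(DEFAULT_EXCLUSION_RESOURCE)
        rows += _read_rows(data.read_text().splitlines())
    else:
        rows += _read_rows(exclusion_path)

    categories: list[str] = []
    patterns: dict[str, list[CodePattern]] = {}
    index_diseases: dict[str, IndexDiseaseDef] = {}
    exclusions: list[CodePattern] = []

    for version_tag, pattern_spec, category, role in rows:
        version = IcdVersion.parse(version_tag)
        pattern = compile_pattern(pattern_spec, version)
        if role == "comorbidity":
            if category not in patterns:
                categories.append(category)
                patterns[category] = []
            patterns[category].append(pattern)
        elif role == "exclusion":
            exclusions.append(pattern)
        elif role.startswith("index:"):
            parts = role.split(":", 2)
            name = parts[1]
            idx = index_diseases.setdefault(name, IndexDiseaseDef(name=name))
            idx.patterns.append(pattern)
            if len(parts) == 3:
                idx.subcategories.setdefault(parts[2], []).append(pattern)
        else:
            raise IcdError(f"unrecognized role {role!r} in mapping table")

    return MappingTables(
        comorbidities=ComorbidityMap(categories=categories, patterns=patterns),
        index_diseases=index_diseases,
        exclusions=exclusions,
    )
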