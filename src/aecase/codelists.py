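"""Categorised clinical code lists.

Every rule in the case-definition engine is driven by membership of a code in
a named category: the diagnosis tiers (the five core eczema Read codes, plus
the wider "likely" and "possible" tiers), the treatment classes grouped along
British National Formulary lines (emollients, topical steroids, topical
calcineurin inhibitors, topical anti-infectives, systemic immunomodulators,
phototherapy), exclusionary conditions, dermatology consults, atopy codes and
diagnostic procedures.

The five core diagnosis codes ship built in (:func:`builtin_core_codes`); all
other categories are supplied by the user as small delimited text files
(comma or tab separated, columns ``code,description[,category]``, header row
optional, UTF-8).

Matching is exact string equality after trimming surrounding whitespace.  Two
print variants of the core codes ("M1120.0" for infantile eczema and "M11400"
for allergic/intrinsic eczema) are accepted as aliases of the canonical forms
"M112.00" and "M114.00".
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Union

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "CodeEntry",
    "CodeList",
    "CodeRegistry",
    "CodeListError",
    "CodeListFormatError",
    "DIAGNOSIS_TIERS",
    "TREATMENT_CATEGORIES",
    "SPECIFIC_TREATMENT_CATEGORIES",
    "PRECEDENCE",
    "CODE_ALIASES",
    "CORE_READ_CODES",
    "canonical",
    "builtin_core_codes",
    "load_codelist",
    "write_codelist",
    "classify_code",
]


class CodeListError(ValueError):
    """Invalid code-list content (tier nesting broken, code in both a
    diagnosis tier and the exclusion list, missing category, ...)."""


class CodeListFormatError(CodeListError):
    """Malformed code-list file; the message carries the offending line."""


class Category(str, Enum):
    """Semantic category of a clinical code."""

    CORE_DX = "CORE_DX"
    LIKELY_DX = "LIKELY_DX"
    POSSIBLE_DX = "POSSIBLE_DX"
    EMOLLIENT = "EMOLLIENT"
    TOPICAL_STEROID = "TOPICAL_STEROID"
    TCI = "TCI"
    TOPICAL_ANTIINFECTIVE = "TOPICAL_ANTIINFECTIVE"
    SYSTEMIC = "SYSTEMIC"
    PHOTOTHERAPY = "PHOTOTHERAPY"
    EXCLUSION = "EXCLUSION"
    DERM_CONSULT = "DERM_CONSULT"
    ATOPY = "ATOPY"
    PROCEDURE = "PROCEDURE"


#: Diagnosis tiers, narrowest first.  When several tiers are loaded they must
#: nest: CORE_DX is a subset of LIKELY_DX is a subset of POSSIBLE_DX.
DIAGNOSIS_TIERS: tuple[Category, ...] = (
    Category.CORE_DX,
    Category.LIKELY_DX,
    Category.POSSIBLE_DX,
)

#: Categories that count as eczema-directed therapy for the "treatment codes
#: on separate dates" criterion.
TREATMENT_CATEGORIES = frozenset(
    {
        Category.EMOLLIENT,
        Category.TOPICAL_STEROID,
        Category.TCI,
        Category.TOPICAL_ANTIINFECTIVE,
        Category.SYSTEMIC,
        Category.PHOTOTHERAPY,
    }
)

#: Treatments considered specific to atopic eczema (topical steroids and
#: topical calcineurin inhibitors).
SPECIFIC_TREATMENT_CATEGORIES = frozenset(
    {Category.TOPICAL_STEROID, Category.TCI}
)

#: Lookup precedence for :meth:`CodeRegistry.classify`: diagnosis tiers are
#: consulted before treatment classes (specific before nonspecific), then the
#: remaining categories.  A code present in several lists resolves to the
#: first matching category in this order.
PRECEDENCE: tuple[Category, ...] = (
    Category.CORE_DX,
    Category.LIKELY_DX,
    Category.POSSIBLE_DX,
    Category.TOPICAL_STEROID,
    Category.TCI,
    Category.EMOLLIENT,
    Category.TOPICAL_ANTIINFECTIVE,
    Category.SYSTEMIC,
    Category.PHOTOTHERAPY,
    Category.EXCLUSION,
    Category.DERM_CONSULT,
    Category.ATOPY,
    Category.PROCEDURE,
)

#: Print variants of two core codes mapped to their canonical Read forms.
CODE_ALIASES: Mapping[str, str] = {
    "M1120.0": "M112.00",
    "M11400": "M114.00",
}

#: The five core atopic-eczema diagnosis Read codes (canonical forms).
CORE_READ_CODES: Mapping[str, str] = {
    "M111.00": "Atopic dermatitis/eczema",
    "M112.00": "Infantile eczema",
    "M113.00": "Flexural eczema",
    "M114.00": "Allergic/intrinsic eczema",
    "M12z100": "Eczema not otherwise specified",
}


def canonical(code: str) -> str:
    """Trim surrounding whitespace and resolve known print-variant aliases."""
    code = code.strip()
    return CODE_ALIASES.get(code, code)


@dataclass(frozen=True)
class CodeEntry:
    """One clinical code with its free-text description and category."""

    code: str
    description: str = ""
    category: Category = Category.CORE_DX

    def __post_init__(self) -> None:
        object.__setattr__(self, "code", canonical(self.code))
        object.__setattr__(self, "category", Category(self.category))
        if not self.code:
            raise CodeListError("code must be non-empty")


@dataclass
class CodeList:
    """An ordered collection of :class:`CodeEntry` with a provenance tag."""

    entries: list[CodeEntry] = field(default_factory=list)
    provenance: str = "<memory>"

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CodeEntry]:
        return iter(self.entries)

    def __contains__(self, code: str) -> bool:
        code = canonical(code)
        return any(e.code == code for e in self.entries)

    @property
    def categories(self) -> set[Category]:
        return {e.category for e in self.entries}

    def codes(self, category: Optional[Category] = None) -> set[str]:
        """Set of codes, optionally restricted to one category."""
        if category is None:
            return {e.code for e in self.entries}
        category = Category(category)
        return {e.code for e in self.entries if e.category == category}


def builtin_core_codes() -> CodeList:
    """The built-in list of the five core eczema diagnosis Read codes."""
    entries = [
        CodeEntry(code, desc, Category.CORE_DX)
        for code, desc in CORE_READ_CODES.items()
    ]
    return CodeList(entries=entries, provenance="builtin:core")


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def load_codelist(
    path: Union[str, Path],
    category: Optional[Union[Category, str]] = None,
) -> CodeList:
    """Load a delimited code-list file.

    Parameters
    ----------
    path:
        Comma- or tab-separated text (auto-detected), optional header row,
        columns ``code,description[,category]``.
    category:
        Category applied to rows that do not carry their own third column.

    Duplicate codes within a category collapse to the first entry with a
    logged warning.  An empty code field raises :class:`CodeListFormatError`
    naming the line; a missing file raises :class:`FileNotFoundError`.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not any(line.strip() for line in lines):
        logger.warning("code-list file %s is empty", path)
        return CodeList(entries=[], provenance=str(path))

    delimiter = _sniff_delimiter(next(line for line in lines if line.strip()))
    reader = csv.reader(lines, delimiter=delimiter)

    entries: list[CodeEntry] = []
    seen: dict[tuple[str, Category], int] = {}
    n_dup = 0
    for lineno, row in enumerate(reader, start=1):
        if not row or not any(cell.strip() for cell in row):
            continue
        first = row[0].strip()
        if lineno == 1 and first.lower() == "code":
            continue  # header row
        if not first:
            raise CodeListFormatError(
                f"{path}: empty code field on line {lineno}"
            )
        description = row[1].strip() if len(row) > 1 else ""
        if len(row) > 2 and row[2].strip():
            try:
                cat = Category(row[2].strip().upper())
            except ValueError as exc:
                raise CodeListFormatError(
                    f"{path}: unknown category {row[2]!r} on line {lineno}"
                ) from exc
        elif category is not None:
            cat = Category(category)
        else:
            raise CodeListError(
                f"{path}: no category column and no default category given"
            )
        entry = CodeEntry(first, description, cat)
        key = (entry.code, entry.category)
        if key in seen:
            n_dup += 1
            continue
        seen[key] = lineno
        entries.append(entry)
    if n_dup:
        logger.warning(
            "code-list file %s: %d duplicate code(s) collapsed", path, n_dup
        )
    return CodeList(entries=entries, provenance=str(path))


def write_codelist(codelist: CodeList, path: Union[str, Path]) -> None:
    """Write a code list as ``code,description,category`` CSV with header."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["code", "description", "category"])
        for entry in codelist.entries:
            writer.writerow([entry.code, entry.description, entry.category.value])


class CodeRegistry:
    """A queryable collection of loaded code lists.

    Classification walks :data:`PRECEDENCE` so that a code present in several
    lists resolves deterministically (diagnosis tiers before treatments).
    """

    def __init__(self, lists: Iterable[CodeList] = ()) -> None:
        self._by_category: dict[Category, dict[str, CodeEntry]] = {}
        for codelist in lists:
            self.add(codelist)

    @classmethod
    def with_builtin_core(cls, *lists: CodeList) -> "CodeRegistry":
        """Registry seeded with the five built-in core diagnosis codes."""
        return cls([builtin_core_codes(), *lists])

    @classmethod
    def from_directory(cls, directory: Union[str, Path], include_core: bool = True) -> "CodeRegistry":
        """Load every ``<category>.csv`` / ``.tsv`` file in *directory*.

        File stems are matched case-insensitively against category names
        (e.g. ``topical_steroid.csv``).  The built-in core codes are included
        unless a ``core_dx`` file overrides them.
        """
        directory = Path(directory)
        registry = cls()
        names = {c.value.lower(): c for c in Category}
        loaded_core = False
        for child in sorted(directory.iterdir()):
            if child.suffix.lower() not in {".csv", ".tsv", ".txt"}:
                continue
            cat = names.get(child.stem.lower())
            if cat is None:
                logger.warning("ignoring %s: stem is not a category name", child)
                continue
            registry.add(load_codelist(child, cat))
            loaded_core = loaded_core or cat is Category.CORE_DX
        if include_core and not loaded_core:
            registry.add(builtin_core_codes())
        return registry

    def add(self, codelist: CodeList) -> None:
        for entry in codelist.entries:
            self._by_category.setdefault(entry.category, {}).setdefault(
                entry.code, entry
            )

    def codes(self, category: Union[Category, str]) -> set[str]:
        return set(self._by_category.get(Category(category), {}))

    def has_category(self, category: Union[Category, str]) -> bool:
        return bool(self._by_category.get(Category(category)))

    def classify(self, code: str) -> Optional[Category]:
        """Category of *code* under the documented precedence, or ``None``."""
        code = canonical(code)
        for category in PRECEDENCE:
            if code in self._by_category.get(category, {}):
                return category
        return None

    def validate(self) -> None:
        """Check cross-list invariants; raise :class:`CodeListError` if broken.

        Checks: loaded diagnosis tiers nest (core within likely within
        possible); no code sits in both a diagnosis tier and the exclusion
        list.  A core list differing from the five built-in codes is allowed
        but logged as an explicit override.
        """
        tiers = [t for t in DIAGNOSIS_TIERS if self.has_category(t)]
        for narrow, wide in zip(tiers, tiers[1:]):
            missing = self.codes(narrow) - self.codes(wide)
            if missing:
                raise CodeListError(
                    f"diagnosis tiers do not nest: {sorted(missing)} in "
                    f"{narrow.value} but not in {wide.value}"
                )
        dx_codes = set().union(*(self.codes(t) for t in DIAGNOSIS_TIERS if self.has_category(t)), set())
        overlap = dx_codes & self.codes(Category.EXCLUSION)
        if overlap:
            raise CodeListError(
                f"codes in both a diagnosis tier and EXCLUSION: {sorted(overlap)}"
            )
        core = self.codes(Category.CORE_DX)
        if core and core != set(CORE_READ_CODES):
            logger.warning(
                "CORE_DX list overrides the built-in five codes: %s",
                sorted(core),
            )


def classify_code(
    code: str, lists: Union[CodeRegistry, Iterable[CodeList]]
) -> Optional[Category]:
    """Classify one code against a registry or a collection of code lists."""
    if not isinstance(lists, CodeRegistry):
        lists = CodeRegistry(lists)
    return lists.classify(code)
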