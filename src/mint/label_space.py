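"""Label vocabulary, alias handling, and clinical-text construction.

The label space is the closed universe of class names an upstream
classifier can emit — disease names for phenotype-driven rare-disease
prediction (~520 labels), tissue types for histopathology (19 labels).
Every downstream stage (preference building, fuzzy response grading,
simulation) shares a single normal form for name lookup, defined here.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "normalize",
    "LabelEntry",
    "LabelSpace",
    "TermDictionary",
    "PatientRecord",
    "load_label_space",
    "write_label_space",
    "load_term_dictionary",
    "hpo_terms_to_text",
    "format_patient_prompt",
    "DEFAULT_DEMOGRAPHIC_TEMPLATE",
]

_WS = re.compile(r"\s+")


def normalize(text: str) -> str:
    """Canonical normal form shared by lookup and fuzzy matching.

    Case-fold, strip, collapse internal whitespace, strip trailing periods.
    """
    out = _WS.sub(" ", text.strip()).casefold()
    return out.rstrip(".").rstrip()


@dataclass(frozen=True)
class LabelEntry:
    """One vocabulary entry: canonical name, optional abbreviation, stable id."""

    canonical_name: str
    abbreviation: Optional[str] = None
    label_id: int = 0

    def __post_init__(self) -> None:
        if not self.canonical_name or not self.canonical_name.strip():
            raise ValueError("canonical_name must be non-empty")
        if self.abbreviation is not None and not self.abbreviation.strip():
            raise ValueError("abbreviation, if given, must be non-empty")


class LabelSpace:
    """Ordered, closed vocabulary of labels with O(1) normalized lookup.

    Canonical names must be unique after :func:`normalize`; each
    abbreviation maps to exactly one entry. Row order defines ``label_id``.
    """

    def __init__(self, entries: Sequence[LabelEntry]):
        if len(entries) < 2:
            raise ValueError(f"a label space needs >=2 entries, got {len(entries)}")
        self.entries: list[LabelEntry] = list(entries)
        self._by_name: dict[str, LabelEntry] = {}
        self._by_abbrev: dict[str, LabelEntry] = {}
        seen_ids: set[int] = set()
        for e in self.entries:
            if e.label_id in seen_ids:
                raise ValueError(f"duplicate label_id {e.label_id}")
            seen_ids.add(e.label_id)
            key = normalize(e.canonical_name)
            if key in self._by_name:
                raise ValueError(
                    f"duplicate canonical name after normalization: {e.canonical_name!r}"
                )
            self._by_name[key] = e
            if e.abbreviation is not None:
                akey = normalize(e.abbreviation)
                if akey in self._by_abbrev:
                    raise ValueError(f"abbreviation maps to >1 entry: {e.abbreviation!r}")
                self._by_abbrev[akey] = e

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "LabelSpace":
        return cls([LabelEntry(n, None, i) for i, n in enumerate(names)])

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return normalize(name) in self._by_name

    def lookup(self, name: str) -> LabelEntry:
        """Exact (normalized) lookup by canonical name; KeyError if absent."""
        try:
            return self._by_name[normalize(name)]
        except KeyError:
            raise KeyError(f"label not in space: {name!r}") from None

    def lookup_any(self, name: str) -> Optional[LabelEntry]:
        """Lookup by canonical name or abbreviation; None if absent."""
        key = normalize(name)
        return self._by_name.get(key) or self._by_abbrev.get(key)

    def names(self) -> list[str]:
        return [e.canonical_name for e in self.entries]

    def label_id_of(self, name: str) -> int:
        return self.lookup(name).label_id


def load_label_space(path) -> LabelSpace:
    """Read a labels TSV (header ``canonical_name<TAB>abbreviation``).

    Row order is preserved as ``label_id`` order. Duplicate canonical names
    (after normalization) and files with fewer than two data rows are hard
    errors.
    """
    entries: list[LabelEntry] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ValueError(f"empty label file: {path}")
        if not header or normalize(header[0]) != "canonical_name":
            raise ValueError(
                f"label file must start with a 'canonical_name' header, got {header!r}"
            )
        for i, row in enumerate(reader):
            if not row or not "".join(row).strip():
                continue
            name = row[0]
            abbrev = row[1] if len(row) > 1 and row[1].strip() else None
            entries.append(LabelEntry(name.strip(), abbrev, len(entries)))
    if len(entries) < 2:
        raise ValueError(f"label file {path} has {len(entries)} data rows; need >=2")
    return LabelSpace(entries)


def write_label_space(space: LabelSpace, path) -> None:
    """Write the TSV that :func:`load_label_space` reads back unchanged."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("canonical_name\tabbreviation\n")
        for e in space.entries:
            fh.write(f"{e.canonical_name}\t{e.abbreviation or ''}\n")


class TermDictionary:
    """Mapping from phenotype-term identifiers (e.g. ``HP:0000486``) to text."""

    def __init__(self, mapping: Mapping[str, str]):
        for tid, text in mapping.items():
            if not text or not text.strip():
                raise ValueError(f"empty term text for id {tid!r}")
        self.mapping: dict[str, str] = dict(mapping)

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.mapping

    def __getitem__(self, term_id: str) -> str:
        return self.mapping[term_id]


def load_term_dictionary(path) -> TermDictionary:
    """Read a term dictionary TSV (header ``term_id<TAB>term_text``)."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ValueError(f"empty term dictionary: {path}")
        for row in reader:
            if not row or not "".join(row).strip():
                continue
            if len(row) < 2:
                raise ValueError(f"malformed dictionary row: {row!r}")
            tid, text = row[0].strip(), row[1].strip()
            if tid in mapping:
                raise ValueError(f"duplicate term id: {tid!r}")
            mapping[tid] = text
    return TermDictionary(mapping)


@dataclass
class PatientRecord:
    """Structured patient fields used to build a prompt.

    ``phenotype_term_ids`` must be non-empty; the true label must belong to
    the label space the record is used with (validated downstream).
    """

    sample_id: str
    age: str
    sex: str
    ethnicity: str
    phenotype_term_ids: list[str] = field(default_factory=list)
    true_label: str = ""

    def __post_init__(self) -> None:
        if not self.phenotype_term_ids:
            raise ValueError("a patient record needs at least one phenotype term id")


def hpo_terms_to_text(ids: Sequence[str], dictionary: TermDictionary) -> str:
    """Turn phenotype-term ids into clinical text, joined with ", ".

    Term texts are looked up in input order and joined with a comma and a
    space; original casing is preserved and nothing is appended. Unknown
    ids are a hard error.
    """
    if not ids:
        raise ValueError("term id list must be non-empty")
    unknown = [t for t in ids if t not in dictionary]
    if unknown:
        raise KeyError(f"term id(s) not in dictionary: {unknown}")
    return ", ".join(dictionary[t] for t in ids)


# Demographics lead the prompt in the order sex, age, ethnicity.
DEFAULT_DEMOGRAPHIC_TEMPLATE = (
    "A {age} {sex} patient of {ethnicity} descent with the following "
    "clinical features: {phenotypes}"
)


def format_patient_prompt(
    rec: PatientRecord,
    dictionary: TermDictionary,
    template: str = DEFAULT_DEMOGRAPHIC_TEMPLATE,
) -> str:
    """Render a patient record as prompt text.

    The demographic sentence comes first, followed by the phenotype text
    from :func:`hpo_terms_to_text`. The template is a single configurable
    format string with ``{age}``, ``{sex}``, ``{ethnicity}`` and
    ``{phenotypes}`` slots. If all three demographic fields are empty the
    phenotype text is returned alone.
    """
    phenotypes = hpo_terms_to_text(rec.phenotype_term_ids, dictionary)
    if not (rec.age.strip() or rec.sex.strip() or rec.ethnicity.strip()):
        return phenotypes
    return template.format(
        age=rec.age.strip(), sex=rec.sex.strip(), ethnicity=rec.ethnicity.strip(),
        phenotypes=phenotypes,
    )
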