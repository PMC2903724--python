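"""Converting tabular database dumps into aTags.

Structured databases (drug/side-effect associations, receptor-ligand
affinity tables, ...) can be flattened into aTags row by row: a text
template turns each row into a human-readable sentence, and designated
columns supply the entity tags.  Quantitative values (e.g. a Ki affinity)
stay inside the sentence as plain text -- the convention deliberately
gives up relational structure in exchange for simplicity, so no typed
RDF literals are emitted.

The mapping is declarative (:class:`MappingConfig`) and can be loaded
from a JSON file, so a new database dump needs configuration, not code.
"""

from __future__ import annotations

import csv
import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .model import Atag, AtagCollection, OntologyEntity, guess_vocabulary, make_atag

__all__ = [
    "EntityColumn",
    "MappingConfig",
    "ConversionError",
    "ConversionReport",
    "row_to_atag",
    "convert_table",
]


class ConversionError(ValueError):
    """A row could not be converted; the message names row and column."""


@dataclass(frozen=True)
class EntityColumn:
    """How one column (or column pair) of a table becomes an entity tag.

    Exactly one of ``uri_prefix`` (URI = prefix + cell value) and
    ``uri_column`` (URI taken verbatim from another column) must be set.
    The label comes from ``label_column`` if given, else from the cell
    value of ``column`` itself.  An empty cell yields no tag.
    """

    column: str
    uri_prefix: Optional[str] = None
    uri_column: Optional[str] = None
    label_column: Optional[str] = None
    vocabulary: Optional[str] = None

    def __post_init__(self):
        if (self.uri_prefix is None) == (self.uri_column is None):
            raise ValueError(
                f"entity column {self.column!r}: exactly one of uri_prefix / "
                "uri_column must be given")


@dataclass(frozen=True)
class MappingConfig:
    """Declarative row-to-aTag mapping.

    ``text_template`` and ``provenance_template`` use ``{column}``
    placeholders referring to header names of the input table.
    """

    text_template: str
    entity_columns: tuple[EntityColumn, ...] = ()
    provenance_template: Optional[str] = None
    delimiter: str = "\t"

    def placeholders(self) -> set[str]:
        out = set()
        for template in (self.text_template, self.provenance_template or ""):
            for _, name, _, _ in string.Formatter().parse(template):
                if name:
                    out.add(name)
        return out

    def referenced_columns(self) -> set[str]:
        cols = set(self.placeholders())
        for ec in self.entity_columns:
            cols.add(ec.column)
            if ec.uri_column:
                cols.add(ec.uri_column)
            if ec.label_column:
                cols.add(ec.label_column)
        return cols

    def to_dict(self) -> dict:
        return {
            "text_template": self.text_template,
            "entity_columns": [
                {k: v for k, v in (
                    ("column", ec.column), ("uri_prefix", ec.uri_prefix),
                    ("uri_column", ec.uri_column),
                    ("label_column", ec.label_column),
                    ("vocabulary", ec.vocabulary)) if v is not None}
                for ec in self.entity_columns],
            "provenance_template": self.provenance_template,
            "delimiter": self.delimiter,
        }

    @classmethod
    def from_dict(cls, obj: Mapping) -> "MappingConfig":
        return cls(
            text_template=obj["text_template"],
            entity_columns=tuple(EntityColumn(**ec) for ec in obj.get("entity_columns", [])),
            provenance_template=obj.get("provenance_template"),
            delimiter=obj.get("delimiter", "\t"))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "MappingConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class ConversionReport:
    """Tallies of a table conversion; ``rows_read == emitted + skipped``."""

    rows_read: int = 0
    emitted: int = 0
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def skipped_count(self) -> int:
        return len(self.skipped)


def _require(row: Mapping[str, Optional[str]], column: str, row_number: int) -> str:
    value = row.get(column)
    if value is None:
        raise ConversionError(f"row {row_number}: missing column {column!r}")
    return value


def row_to_atag(row: Mapping[str, Optional[str]], cfg: MappingConfig,
                base_uri: str, *, row_number: int = 0) -> Atag:
    """Convert one table row into an aTag according to *cfg*.

    The snippet text is the template instantiated with the row's values;
    each entity column with a non-empty cell contributes one tag.

    Raises :class:`ConversionError` if a referenced column is absent,
    naming the row number and column.
    """
    values = {col: _require(row, col, row_number) for col in cfg.placeholders()}
    text = cfg.text_template.format(**values)
    entities = []
    for ec in cfg.entity_columns:
        cell = _require(row, ec.column, row_number)
        if not cell.strip():
            continue
        if ec.uri_prefix is not None:
            uri = ec.uri_prefix + cell.strip().replace(" ", "_")
        else:
            uri = _require(row, ec.uri_column, row_number).strip()
            if not uri:
                continue
        label = cell.strip()
        if ec.label_column:
            label = _require(row, ec.label_column, row_number).strip() or label
        entities.append(OntologyEntity(
            uri=uri, preferred_label=label,
            source_vocabulary=ec.vocabulary or guess_vocabulary(uri)))
    provenance = None
    if cfg.provenance_template:
        provenance = cfg.provenance_template.format(**values)
    return make_atag(text, entities, provenance_uri=provenance, base_uri=base_uri)


def convert_table(path: Union[str, Path, Iterable[str]], cfg: MappingConfig,
                  base_uri: str, *, strict: bool = True,
                  ) -> tuple[AtagCollection, ConversionReport]:
    """Convert a delimited text file (header row required) into aTags.

    Rows are processed in order with bounded memory per row.  In strict
    mode (default) the first bad row aborts the conversion; in permissive
    mode bad rows are skipped and recorded in the report with their
    reason.  Always: ``rows_read == emitted + skipped``.
    """
    if isinstance(path, (str, Path)):
        lines: Iterable[str] = Path(path).read_text(encoding="utf-8").splitlines()
    else:
        lines = path
    reader = csv.DictReader(lines, delimiter=cfg.delimiter, restval=None)
    if reader.fieldnames is None:
        raise ConversionError("table has no header row")
    missing = cfg.referenced_columns() - set(reader.fieldnames)
    if missing:
        raise ConversionError(
            "header lacks columns referenced by the mapping: "
            + ", ".join(sorted(missing)))
    collection = AtagCollection(base_uri=base_uri)
    report = ConversionReport()
    for row_number, row in enumerate(reader, 1):
        report.rows_read += 1
        try:
            atag = row_to_atag(row, cfg, base_uri, row_number=row_number)
        except (ConversionError, ValueError) as exc:
            if strict:
                raise ConversionError(f"row {row_number}: {exc}") from exc
            report.skipped.append((row_number, str(exc)))
            continue
        collection.atags.append(atag)
        report.emitted += 1
    return collection, report
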