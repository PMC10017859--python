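"""Question-record ingestion, JSON-Schema form flattening, dedup, splitting.

A questionnaire item is identified by its *field name* (the verbatim question
text) and its *field path* (the slash-terminated trail of section/subsection
titles under which it appeared on the form). Syntactically identical questions
frequently recur under different section titles across forms and form
revisions, so the distinctness count depends on whether the path participates
in the key.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Any, Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("form_id", "field_path", "field_name")
OPTIONAL_COLUMNS = ("record_id", "value_kind", "allowed_values", "date_of_conduct", "site_id")

_WS = re.compile(r"\s+")


class ValueKind(str, Enum):
    """Answer type of a form field."""

    FREE_TEXT = "free_text"
    NUMBER = "number"
    CHOICE = "choice"
    MULTI_ANSWER = "multi_answer"


@dataclass(frozen=True)
class QuestionRecord:
    """One form field: question text plus section path and provenance."""

    record_id: str
    form_id: str
    field_path: str
    field_name: str
    value_kind: ValueKind = ValueKind.FREE_TEXT
    allowed_values: tuple[str, ...] | None = None
    date_of_conduct: str | None = None
    site_id: str | None = None

    def __post_init__(self) -> None:
        if not normalize_text(self.field_name):
            raise ValueError("field_name is empty after whitespace collapse")
        if self.field_path and not self.field_path.endswith("/"):
            raise ValueError(f"field_path {self.field_path!r} must be '' or end with '/'")
        if any(not seg for seg in self.field_path.split("/")[:-1]) and self.field_path:
            raise ValueError(f"field_path {self.field_path!r} contains empty segments")
        enumerated = self.value_kind in (ValueKind.CHOICE, ValueKind.MULTI_ANSWER)
        if enumerated != (self.allowed_values is not None):
            raise ValueError(
                "allowed_values must be present iff value_kind is choice/multi_answer"
            )


@dataclass(frozen=True)
class Partition:
    """Disjoint, exhaustive train/test split of record ids."""

    train_ids: frozenset[str]
    test_ids: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.train_ids & self.test_ids:
            raise ValueError("train and test ids overlap")


def normalize_text(text: str) -> str:
    """Case-fold and collapse whitespace. No stemming, no punctuation removal —
    the minimal rule that merges title-cased/whitespace duplicates while
    staying auditable."""
    return _WS.sub(" ", text).strip().casefold()


class MissingColumnError(KeyError):
    """A mandatory column/key is absent from the input."""


class MalformedRowError(ValueError):
    """A row violates the record contract; carries its 0-based row index."""

    def __init__(self, row_index: int, message: str):
        super().__init__(f"row {row_index}: {message}")
        self.row_index = row_index


def _parse_allowed(raw: Any) -> tuple[str, ...] | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    if isinstance(raw, (list, tuple)):
        return tuple(str(v) for v in raw)
    s = str(raw).strip()
    if not s:
        return None
    if s.startswith("["):
        return tuple(str(v) for v in json.loads(s))
    return tuple(v.strip() for v in s.split(";"))


def _record_from_mapping(row: dict[str, Any], index: int) -> QuestionRecord:
    for col in MANDATORY_COLUMNS:
        val = row.get(col)
        if val is None or (isinstance(val, float) and np.isnan(val)) or str(val).strip() == "":
            if col == "field_path" and val is not None and str(val) == "":
                continue  # empty path is legal (root-level field)
            raise MalformedRowError(index, f"missing mandatory column {col!r}")
    kind = ValueKind(str(row.get("value_kind") or ValueKind.FREE_TEXT.value))
    allowed = _parse_allowed(row.get("allowed_values"))
    if kind in (ValueKind.CHOICE, ValueKind.MULTI_ANSWER) and allowed is None:
        allowed = ()
    try:
        return QuestionRecord(
            record_id=str(row.get("record_id") or f"r{index:06d}"),
            form_id=str(row["form_id"]),
            field_path=str(row.get("field_path") if row.get("field_path") is not None else ""),
            field_name=str(row["field_name"]),
            value_kind=kind,
            allowed_values=allowed,
            date_of_conduct=(str(row["date_of_conduct"]) if row.get("date_of_conduct") else None),
            site_id=(str(row["site_id"]) if row.get("site_id") else None),
        )
    except ValueError as exc:
        raise MalformedRowError(index, str(exc)) from exc


def load_question_records(source: str | Path | IO[str]) -> list[QuestionRecord]:
    """Read question records from delimited text (CSV/TSV, header required)
    or JSON lines, preserving input order.

    The format is sniffed from the first non-blank character ('{' means JSON
    lines) and, for delimited text, the delimiter from the header line.
    An empty input yields an empty list; a missing mandatory column raises
    :class:`MissingColumnError`; a row with a missing mandatory value raises
    :class:`MalformedRowError` naming the row.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    stripped = text.lstrip()
    if not stripped:
        return []
    if stripped[0] == "{":
        rows: list[dict[str, Any]] = []
        for i, line in enumerate(filter(None, (ln.strip() for ln in text.splitlines()))):
            rows.append(json.loads(line))
        if rows:
            present = set().union(*(r.keys() for r in rows))
            missing = [c for c in MANDATORY_COLUMNS if c not in present]
            if missing:
                raise MissingColumnError(f"missing mandatory column {missing[0]!r}")
        return [_record_from_mapping(r, i) for i, r in enumerate(rows)]
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    from io import StringIO

    df = pd.read_csv(StringIO(text), sep=delim, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing mandatory column {missing[0]!r}")
    records = []
    for i, row in enumerate(df.to_dict(orient="records")):
        clean = {k: (v if str(v) != "" else None) for k, v in row.items()}
        if "field_path" in row:
            clean["field_path"] = row["field_path"]  # empty path stays ""
        records.append(_record_from_mapping(clean, i))
    return records


class SchemaFormatError(ValueError):
    """The JSON-Schema document cannot be traversed as a form definition."""


def _iter_schema_leaves(
    schema: dict[str, Any], path: str, pointer: str
) -> Iterator[tuple[str, str, str, dict[str, Any]]]:
    props = schema.get("properties", {})
    for name, sub in props.items():
        sub_pointer = f"{pointer}/properties/{name}"
        if not isinstance(sub, dict):
            logger.warning("skipping malformed property at %s", sub_pointer)
            continue
        if sub.get("type") == "object" or "properties" in sub:
            yield from _iter_schema_leaves(sub, f"{path}{name}/", sub_pointer)
        else:
            yield path, name, sub_pointer, sub


def flatten_json_schema(schema: dict[str, Any], form_id: str) -> list[QuestionRecord]:
    """Depth-first flattening of a JSON-Schema form definition into records.

    Sections/subsections are nested ``object`` schemas named by their titles;
    each non-object leaf property becomes one record whose ``field_path`` is
    the slash-joined, slash-terminated trail of ancestor property names and
    whose ``field_name`` is the leaf property name. Typing: string/number →
    free_text/number; a property carrying enumerated values → choice; an
    array-typed property → multi_answer. Unsupported leaf types are skipped
    and logged with their JSON pointer.
    """
    if not isinstance(schema, dict) or (
        schema.get("type", "object") != "object" and "properties" not in schema
    ):
        raise SchemaFormatError("schema root must be an object type")
    records: list[QuestionRecord] = []
    for i, (path, name, pointer, sub) in enumerate(_iter_schema_leaves(schema, "", "#")):
        typ = sub.get("type")
        if "enum" in sub:
            kind, allowed = ValueKind.CHOICE, tuple(str(v) for v in sub["enum"])
        elif typ == "array":
            items = sub.get("items", {}) or {}
            kind = ValueKind.MULTI_ANSWER
            allowed = tuple(str(v) for v in items.get("enum", ()))
        elif typ == "string":
            kind, allowed = ValueKind.FREE_TEXT, None
        elif typ in ("number", "integer"):
            kind, allowed = ValueKind.NUMBER, None
        else:
            logger.warning("skipping unsupported leaf type %r at %s", typ, pointer)
            continue
        records.append(
            QuestionRecord(
                record_id=f"{form_id}:{len(records):04d}",
                form_id=form_id,
                field_path=path,
                field_name=name,
                value_kind=kind,
                allowed_values=allowed,
            )
        )
    return records


def distinct_questions(
    records: Iterable[QuestionRecord], key_mode: str = "path_and_text"
) -> tuple[list[str], int]:
    """Distinct-question keys (first-occurrence order) and their count.

    ``path_and_text`` keys on normalized path + "|" + normalized question
    text; ``text_only`` keys on the normalized question text alone, merging
    the same question asked under different section titles.
    """
    if key_mode not in ("path_and_text", "text_only"):
        raise ValueError(f"unknown key_mode {key_mode!r}")
    seen: dict[str, None] = {}
    for rec in records:
        if key_mode == "path_and_text":
            key = normalize_text(rec.field_path) + "|" + normalize_text(rec.field_name)
        else:
            key = normalize_text(rec.field_name)
        seen.setdefault(key, None)
    keys = list(seen)
    return keys, len(keys)


def partition_records(ids: Iterable[str], train_size: int, seed: int) -> Partition:
    """Uniform random train/test split without replacement, reproducible by seed."""
    ids = list(ids)
    n = len(ids)
    if not 0 < train_size < n:
        raise ValueError(f"train_size must be in (0, {n}); got {train_size}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = frozenset(ids[i] for i in perm[:train_size])
    test = frozenset(ids[i] for i in perm[train_size:])
    return Partition(train_ids=train, test_ids=test, seed=seed)


def write_records_jsonl(records: Iterable[QuestionRecord], path: str | Path) -> None:
    """Persist records as canonical JSON lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = {
                "record_id": rec.record_id,
                "form_id": rec.form_id,
                "field_path": rec.field_path,
                "field_name": rec.field_name,
                "value_kind": rec.value_kind.value,
            }
            if rec.allowed_values is not None:
                obj["allowed_values"] = list(rec.allowed_values)
            if rec.date_of_conduct:
                obj["date_of_conduct"] = rec.date_of_conduct
            if rec.site_id:
                obj["site_id"] = rec.site_id
            fh.write(json.dumps(obj) + "\n")
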