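"""Dataset readers/writers and rule-model persistence.

CSV (RFC-4180) is the primary interchange format; ARFF is supported
because many benchmark survival datasets circulate in it.  Attribute
kinds are inferred (a column whose non-missing values all parse as
numbers is numeric, anything else nominal) unless overridden.  Times
are parsed directly from their decimal strings to binary floats; no
rounding or unit conversion is applied.

Model files are plain text: a schema header, one premise per rule in
the ASCII syntax of :mod:`survrules.rules`, and each conclusion curve
as tab-separated (time, probability) pairs.  Floats are written with
``repr`` (shortest round-trip form), so save/load reproduces curves
bit-exactly.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    NOMINAL,
    NUMERIC,
    AttributeMeta,
    KMCurve,
    SurvivalDataset,
    SurvivalRecord,
)
from .rules import RuleSet, SurvivalRule, format_premise, parse_premise

__all__ = [
    "DatasetFormatError",
    "DatasetSchemaConfig",
    "read_dataset",
    "write_dataset",
    "save_model",
    "load_model",
]


class DatasetFormatError(ValueError):
    """Malformed dataset file (bad status, negative time, missing column...)."""


@dataclass
class DatasetSchemaConfig:
    """How to interpret the columns of a dataset file."""

    time_column: str = "time"
    status_column: str = "status"
    weight_column: str | None = None
    kind_overrides: Mapping[str, str] = field(default_factory=dict)
    missing_tokens: tuple = ("", "?", "NA")

    def __post_init__(self):
        if self.time_column == self.status_column:
            raise ValueError("time and status columns must be distinct")


def _try_float(token: str):
    try:
        return float(token)
    except ValueError:
        return None


def _build_dataset(
    columns: Sequence[str],
    rows: Sequence[Sequence[str]],
    schema: DatasetSchemaConfig,
    declared_kinds: Mapping[str, object] | None = None,
) -> SurvivalDataset:
    """Shared CSV/ARFF assembly: kind inference, validation, records."""
    for required in (schema.time_column, schema.status_column):
        if required not in columns:
            raise DatasetFormatError(f"missing mandatory column {required!r}")
    if schema.weight_column is not None and schema.weight_column not in columns:
        raise DatasetFormatError(f"missing weight column {schema.weight_column!r}")
    special = {schema.time_column, schema.status_column}
    if schema.weight_column:
        special.add(schema.weight_column)
    covariate_cols = [c for c in columns if c not in special]
    col_idx = {c: i for i, c in enumerate(columns)}
    missing = set(schema.missing_tokens)

    def cell(row, name):
        return row[col_idx[name]].strip()

    # decide attribute kinds and nominal domains
    attributes = []
    kinds = {}
    for name in covariate_cols:
        declared = (declared_kinds or {}).get(name)
        override = schema.kind_overrides.get(name)
        values = [cell(r, name) for r in rows]
        present = [v for v in values if v not in missing]
        if override is not None:
            kind = override
        elif isinstance(declared, tuple):  # ARFF nominal declaration
            kind = NOMINAL
        elif declared is not None:
            kind = declared
        else:
            kind = NUMERIC if present and all(_try_float(v) is not None for v in present) else NOMINAL
        kinds[name] = kind
        if kind == NOMINAL:
            if isinstance(declared, tuple):
                domain = declared
            else:
                domain = tuple(sorted(set(present)))
            if not domain:
                domain = ("?",)  # fully-missing nominal column; placeholder domain
            attributes.append(AttributeMeta(name, NOMINAL, domain))
        else:
            attributes.append(AttributeMeta(name, NUMERIC))

    records = []
    for rn, row in enumerate(rows, start=1):
        if len(row) != len(columns):
            raise DatasetFormatError(f"row {rn}: expected {len(columns)} fields, got {len(row)}")
        t_raw = cell(row, schema.time_column)
        if t_raw in missing:
            raise DatasetFormatError(f"row {rn}: missing time value")
        t = _try_float(t_raw)
        if t is None:
            raise DatasetFormatError(f"row {rn}: time {t_raw!r} is not a number")
        if t < 0:
            raise DatasetFormatError(f"row {rn}: negative time {t_raw}")
        s_raw = cell(row, schema.status_column)
        if s_raw in missing:
            raise DatasetFormatError(f"row {rn}: missing status value")
        s = _try_float(s_raw)
        if s is None or s not in (0.0, 1.0):
            raise DatasetFormatError(
                f"row {rn}: status {s_raw!r} in column {schema.status_column!r} must be 0 or 1"
            )
        weight = 1.0
        if schema.weight_column:
            w_raw = cell(row, schema.weight_column)
            w = _try_float(w_raw)
            if w is None or w <= 0:
                raise DatasetFormatError(f"row {rn}: weight {w_raw!r} must be positive")
            weight = w
        cov = {}
        for name in covariate_cols:
            v = cell(row, name)
            if v in missing:
                cov[name] = None
            elif kinds[name] == NUMERIC:
                f = _try_float(v)
                if f is None:
                    raise DatasetFormatError(
                        f"row {rn}: non-numeric value {v!r} in numeric column {name!r}"
                    )
                cov[name] = f
            else:
                cov[name] = v
        records.append(SurvivalRecord(covariates=cov, time=t, status=int(s), weight=weight))
    return SurvivalDataset(attributes, records)


def _read_csv(path: Path, schema: DatasetSchemaConfig) -> SurvivalDataset:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    columns = [str(c) for c in df.columns]
    rows = df.to_numpy(dtype=object).tolist()
    rows = [[str(v) for v in row] for row in rows]
    return _build_dataset(columns, rows, schema)


def _read_arff(path: Path, schema: DatasetSchemaConfig) -> SurvivalDataset:
    """Minimal ARFF reader: dense rows, numeric and nominal attributes."""
    columns: list = []
    declared: dict = {}
    data_rows: list = []
    in_data = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if in_data:
            data_rows.append(next(csv.reader([line])))
            continue
        if low.startswith("@relation"):
            continue
        if low.startswith("@attribute"):
            rest = line[len("@attribute") :].strip()
            if rest.startswith(("'", '"')):
                quote = rest[0]
                end = rest.index(quote, 1)
                name, spec = rest[1:end], rest[end + 1 :].strip()
            else:
                parts = rest.split(None, 1)
                if len(parts) != 2:
                    raise DatasetFormatError(f"malformed attribute line: {line!r}")
                name, spec = parts
            spec = spec.strip()
            if spec.startswith("{"):
                values = tuple(
                    v.strip().strip("'\"") for v in spec.strip("{}").split(",")
                )
                declared[name] = values  # nominal domain in declaration order
            elif spec.lower() in ("numeric", "real", "integer"):
                declared[name] = NUMERIC
            elif spec.lower() == "string":
                declared[name] = NOMINAL
            else:
                raise DatasetFormatError(f"unsupported attribute type {spec!r}")
            columns.append(name)
        elif low.startswith("@data"):
            in_data = True
        else:
            raise DatasetFormatError(f"unrecognised ARFF line: {line!r}")
    if not in_data:
        raise DatasetFormatError("ARFF file has no @data section")
    rows = [[v.strip() for v in row] for row in data_rows]
    return _build_dataset(columns, rows, schema, declared_kinds=declared)


def read_dataset(path, schema: DatasetSchemaConfig | None = None) -> SurvivalDataset:
    """Read a survival dataset from CSV or ARFF (detected by extension)."""
    path = Path(path)
    schema = schema or DatasetSchemaConfig()
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return _read_csv(path, schema)
    if suffix == ".arff":
        return _read_arff(path, schema)
    raise DatasetFormatError(f"unknown dataset format {suffix!r} (expected .csv or .arff)")


def write_dataset(dataset: SurvivalDataset, path, schema: DatasetSchemaConfig | None = None) -> None:
    """Write a dataset as CSV; missing covariates become empty cells."""
    schema = schema or DatasetSchemaConfig()
    path = Path(path)
    names = dataset.attribute_names
    include_weight = schema.weight_column is not None or any(
        r.weight != 1.0 for r in dataset.records
    )
    weight_col = schema.weight_column or "weight"
    header = names + [schema.time_column, schema.status_column]
    if include_weight:
        header.append(weight_col)
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(header)
    kinds = {a.name: a.kind for a in dataset.attributes}
    for rec in dataset.records:
        row = []
        for name in names:
            v = rec.covariates.get(name)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                row.append("")
            elif kinds[name] == NUMERIC:
                row.append(repr(float(v)))
            else:
                row.append(str(v))
        row.append(repr(rec.time))
        row.append(str(rec.status))
        if include_weight:
            row.append(repr(rec.weight))
        writer.writerow(row)
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Model persistence

_MODEL_MAGIC = "survrules-model 1"


def _curve_lines(curve: KMCurve) -> list:
    lines = [f"curve {repr(curve.n_effective)} {curve.times.size}"]
    for t, p in zip(curve.times, curve.probs):
        lines.append(f"{repr(float(t))}\t{repr(float(p))}")
    return lines


def save_model(ruleset: RuleSet, path) -> None:
    lines = [_MODEL_MAGIC, f"mincov {repr(float(ruleset.mincov))}", f"attributes {len(ruleset.attributes)}"]
    for a in ruleset.attributes:
        lines.append(f"{a.name}\t{a.kind}\t{','.join(a.domain)}")
    lines.append("default")
    lines.extend(_curve_lines(ruleset.default_curve))
    lines.append(f"rules {len(ruleset.rules)}")
    for rule in ruleset.rules:
        lines.append("rule")
        lines.append(f"premise {format_premise(rule.conditions)}")
        lines.append(f"quality {repr(float(rule.quality)) if rule.quality is not None else 'NA'}")
        lines.append(f"p_value {repr(float(rule.p_value)) if rule.p_value is not None else 'NA'}")
        lines.append(
            f"coverage {repr(float(rule.coverage_count)) if rule.coverage_count is not None else 'NA'}"
        )
        lines.extend(_curve_lines(rule.conclusion))
    Path(path).write_text("\n".join(lines) + "\n")


class _Reader:
    def __init__(self, lines):
        self.lines = lines
        self.pos = 0

    def next(self) -> str:
        if self.pos >= len(self.lines):
            raise DatasetFormatError("unexpected end of model file")
        line = self.lines[self.pos]
        self.pos += 1
        return line

    def expect(self, prefix: str) -> str:
        line = self.next()
        if not line.startswith(prefix):
            raise DatasetFormatError(f"expected {prefix!r}, got {line!r}")
        return line[len(prefix) :].strip()


def _read_curve(reader: _Reader) -> KMCurve:
    head = reader.expect("curve ").split()
    n_eff, count = float(head[0]), int(head[1])
    times, probs = [], []
    for _ in range(count):
        t_raw, p_raw = reader.next().split("\t")
        times.append(float(t_raw))
        probs.append(float(p_raw))
    return KMCurve(times=np.array(times), probs=np.array(probs), n_effective=n_eff)


def _opt_float(raw: str):
    return None if raw == "NA" else float(raw)


def load_model(path) -> RuleSet:
    lines = Path(path).read_text().splitlines()
    reader = _Reader(lines)
    if reader.next() != _MODEL_MAGIC:
        raise DatasetFormatError("not a survrules model file")
    mincov = float(reader.expect("mincov "))
    n_attrs = int(reader.expect("attributes "))
    attributes = []
    for _ in range(n_attrs):
        name, kind, domain_raw = reader.next().split("\t")
        domain = tuple(domain_raw.split(",")) if domain_raw else ()
        attributes.append(AttributeMeta(name, kind, domain))
    reader.expect("default")
    default_curve = _read_curve(reader)
    n_rules = int(reader.expect("rules "))
    rules = []
    for _ in range(n_rules):
        reader.expect("rule")
        premise = parse_premise(reader.expect("premise "), attributes)
        quality = _opt_float(reader.expect("quality "))
        p_value = _opt_float(reader.expect("p_value "))
        coverage = _opt_float(reader.expect("coverage "))
        conclusion = _read_curve(reader)
        rules.append(
            SurvivalRule(
                conditions=premise,
                conclusion=conclusion,
                quality=quality,
                coverage_count=coverage,
                p_value=p_value,
            )
        )
    return RuleSet(rules=rules, default_curve=default_curve, mincov=mincov, attributes=attributes)
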