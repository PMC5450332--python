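"""Conditions, survival rules and rule sets.

A survival rule is a conjunction of elementary conditions over the
covariates whose conclusion is a Kaplan-Meier curve fitted on the
training records the premise covers:

    IF c1 AND c2 AND ... AND cn THEN S(t | premise)

Coverage follows the "ignored value" strategy for missing data: a
record with a missing value on a tested attribute is not covered.
Prediction averages the conclusions of all covering rules pointwise and
falls back to the default (full-training-set) curve when no rule
covers the record.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    NOMINAL,
    NUMERIC,
    AttributeMeta,
    KMCurve,
    SurvivalDataset,
    SurvivalRecord,
    is_missing,
)

OP_EQ = "="
OP_LT = "<"
OP_GE = ">="
OP_IN = "in"

__all__ = [
    "OP_EQ",
    "OP_LT",
    "OP_GE",
    "OP_IN",
    "Condition",
    "SurvivalRule",
    "RuleSet",
    "condition_covers",
    "condition_mask",
    "rule_covers",
    "merge_numeric_conditions",
    "average_curves",
    "predict",
    "format_rule",
    "format_premise",
    "parse_premise",
    "parse_rule",
]


@dataclass(frozen=True)
class Condition:
    """One elementary attribute test.

    Operators: ``=`` (nominal equality), ``<`` / ``>=`` (numeric
    thresholds) and ``in`` (left-closed right-open numeric interval,
    value = (low, high)).
    """

    attribute: str
    operator: str
    value: object

    def __post_init__(self):
        if self.operator not in (OP_EQ, OP_LT, OP_GE, OP_IN):
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.operator == OP_IN:
            low, high = self.value
            if not low < high:
                raise ValueError(f"empty interval [{low}, {high})")
            object.__setattr__(self, "value", (float(low), float(high)))
        elif self.operator in (OP_LT, OP_GE):
            object.__setattr__(self, "value", float(self.value))

    def covers_value(self, v) -> bool:
        if is_missing(v):
            return False
        if self.operator == OP_EQ:
            return v == self.value
        v = float(v)
        if self.operator == OP_LT:
            return v < self.value
        if self.operator == OP_GE:
            return v >= self.value
        low, high = self.value
        return low <= v < high

    def __str__(self) -> str:
        if self.operator == OP_EQ:
            return f"{self.attribute} = {self.value}"
        if self.operator == OP_IN:
            low, high = self.value
            return f"{self.attribute} in [{low!r}, {high!r})"
        return f"{self.attribute} {self.operator} {self.value!r}"


def condition_covers(condition: Condition, record: SurvivalRecord) -> bool:
    """True iff the record's value is present and satisfies the test."""
    if condition.attribute not in record.covariates:
        raise KeyError(f"record has no attribute {condition.attribute!r}")
    return condition.covers_value(record.covariates[condition.attribute])


def condition_mask(condition: Condition, dataset: SurvivalDataset) -> np.ndarray:
    """Vectorised coverage of a condition over a whole dataset."""
    meta = dataset.attribute(condition.attribute)
    if condition.operator == OP_EQ:
        if meta.kind != NOMINAL:
            raise ValueError(f"equality test on numeric attribute {meta.name!r}")
        codes = dataset.nominal_codes(meta.name)
        try:
            code = meta.domain.index(condition.value)
        except ValueError:
            return np.zeros(len(dataset), bool)
        return codes == code
    if meta.kind != NUMERIC:
        raise ValueError(f"threshold test on nominal attribute {meta.name!r}")
    v = dataset.numeric_values(meta.name)
    with np.errstate(invalid="ignore"):
        if condition.operator == OP_LT:
            return v < condition.value
        if condition.operator == OP_GE:
            return v >= condition.value
        low, high = condition.value
        return (v >= low) & (v < high)


@dataclass
class SurvivalRule:
    """A conjunctive premise with a Kaplan-Meier conclusion.

    ``quality`` is the log-rank statistic of the covered/uncovered
    split of the training set, ``coverage_count`` the weighted number
    of covered training records and ``p_value`` the raw chi-square(1)
    upper tail of the statistic.
    """

    conditions: tuple
    conclusion: KMCurve | None = None
    quality: float | None = None
    coverage_count: float | None = None
    p_value: float | None = None

    def __post_init__(self):
        self.conditions = tuple(self.conditions)

    def covers(self, record: SurvivalRecord) -> bool:
        return all(condition_covers(c, record) for c in self.conditions)

    def coverage_mask(self, dataset: SurvivalDataset) -> np.ndarray:
        mask = np.ones(len(dataset), bool)
        for c in self.conditions:
            mask &= condition_mask(c, dataset)
        return mask

    def __str__(self) -> str:
        return format_premise(self.conditions)


def rule_covers(rule: SurvivalRule, record: SurvivalRecord) -> bool:
    """Conjunction over the premise; an empty premise covers everything."""
    return rule.covers(record)


def merge_numeric_conditions(rule: SurvivalRule) -> SurvivalRule:
    """Collapse same-attribute numeric conditions into one condition.

    ``A >= x AND A < y`` becomes ``A in [x, y)``; several thresholds in
    the same direction collapse to the tightest.  Coverage is unchanged.
    A contradictory premise (empty intersection) raises, as it cannot
    arise from valid growing.
    """
    merged = _merge_conditions(rule.conditions)
    return SurvivalRule(
        conditions=merged,
        conclusion=rule.conclusion,
        quality=rule.quality,
        coverage_count=rule.coverage_count,
        p_value=rule.p_value,
    )


def _merge_conditions(conditions: Sequence[Condition]) -> tuple:
    bounds: dict = {}  # attribute -> [low, high]
    order: list = []  # first-occurrence order of numeric attributes
    out: list = []
    for c in conditions:
        if c.operator == OP_EQ:
            out.append(("eq", c))
            continue
        if c.attribute not in bounds:
            bounds[c.attribute] = [-np.inf, np.inf]
            order.append(c.attribute)
            out.append(("num", c.attribute))
        lo, hi = bounds[c.attribute]
        if c.operator == OP_GE:
            lo = max(lo, c.value)
        elif c.operator == OP_LT:
            hi = min(hi, c.value)
        else:  # interval
            lo = max(lo, c.value[0])
            hi = min(hi, c.value[1])
        bounds[c.attribute] = [lo, hi]

    result = []
    seen = set()
    for kind, payload in out:
        if kind == "eq":
            result.append(payload)
            continue
        name = payload
        if name in seen:
            continue
        seen.add(name)
        lo, hi = bounds[name]
        if lo >= hi:
            raise ValueError(f"contradictory premise on {name!r}: [{lo}, {hi})")
        if np.isinf(lo) and np.isinf(hi):
            raise ValueError(f"unbounded merged condition on {name!r}")
        if np.isinf(lo):
            result.append(Condition(name, OP_LT, hi))
        elif np.isinf(hi):
            result.append(Condition(name, OP_GE, lo))
        else:
            result.append(Condition(name, OP_IN, (lo, hi)))
    return tuple(result)


# ---------------------------------------------------------------------------
# Prediction


def average_curves(curves: Sequence[KMCurve]) -> KMCurve:
    """Unweighted pointwise mean of step curves.

    The result is a step function on the union of the input jump times;
    each covering rule contributes equally.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("cannot average an empty list of curves")
    if len(curves) == 1:
        return curves[0]
    times = np.unique(np.concatenate([c.times for c in curves]))
    probs = np.mean([c.evaluate(times) for c in curves], axis=0)
    n_eff = float(np.mean([c.n_effective for c in curves]))
    return KMCurve(times=times, probs=probs, n_effective=n_eff)


@dataclass
class RuleSet:
    """An ordered rule list plus the default full-training-set curve."""

    rules: list
    default_curve: KMCurve
    mincov: float = 7.0
    attributes: list = field(default_factory=list)

    def predict(self, record: SurvivalRecord) -> KMCurve:
        matching = [r.conclusion for r in self.rules if r.covers(record)]
        if not matching:
            return self.default_curve
        return average_curves(matching)

    def predict_dataset(self, dataset: SurvivalDataset) -> list:
        """Predicted curve per record, using vectorised rule coverage."""
        masks = [r.coverage_mask(dataset) for r in self.rules]
        out = []
        for i in range(len(dataset)):
            matching = [r.conclusion for r, m in zip(self.rules, masks) if m[i]]
            out.append(average_curves(matching) if matching else self.default_curve)
        return out

    def __len__(self) -> int:
        return len(self.rules)


def predict(ruleset: RuleSet, record: SurvivalRecord) -> KMCurve:
    """Average of the conclusions of all covering rules; default when none."""
    return ruleset.predict(record)


# ---------------------------------------------------------------------------
# Text round-trip.  Grammar (one premise):
#   premise   := condition (" AND " condition)*
#   condition := name " >= " number | name " < " number
#              | name " in [" number ", " number ")" | name " = " token
# Numbers are written with repr() so parsing reproduces the premise
# bit-exactly; attribute names and nominal values must not contain tabs
# or the literal token " AND ".


def format_premise(conditions: Sequence[Condition]) -> str:
    if not conditions:
        return "TRUE"
    return " AND ".join(str(c) for c in conditions)


def format_rule(rule: SurvivalRule) -> str:
    """Serialize a rule premise in the diff-friendly ASCII syntax."""
    return format_premise(rule.conditions)


_IN_RE = re.compile(r"^(?P<attr>.+?) in \[(?P<low>[^,]+), (?P<high>[^)]+)\)$")


def _parse_condition(text: str, by_name: dict) -> Condition:
    text = text.strip()
    m = _IN_RE.match(text)
    if m:
        name = m.group("attr").strip()
        meta = _require(by_name, name, text)
        if meta.kind != NUMERIC:
            raise ValueError(f"interval test on nominal attribute {name!r}")
        return Condition(name, OP_IN, (float(m.group("low")), float(m.group("high"))))
    for op in (OP_GE, OP_LT):
        token = f" {op} "
        if token in text:
            name, _, raw = text.partition(token)
            meta = _require(by_name, name.strip(), text)
            if meta.kind != NUMERIC:
                raise ValueError(f"threshold test on nominal attribute {meta.name!r}")
            return Condition(meta.name, op, float(raw))
    if " = " in text:
        name, _, raw = text.partition(" = ")
        meta = _require(by_name, name.strip(), text)
        if meta.kind != NOMINAL:
            raise ValueError(f"equality test on numeric attribute {meta.name!r}")
        value = raw.strip()
        if value not in meta.domain:
            raise ValueError(f"value {value!r} outside the domain of {meta.name!r}")
        return Condition(meta.name, OP_EQ, value)
    raise ValueError(f"cannot parse condition {text!r}")


def _require(by_name: dict, name: str, context: str) -> AttributeMeta:
    if name not in by_name:
        raise ValueError(f"unknown attribute {name!r} in {context!r}")
    return by_name[name]


def parse_premise(text: str, attributes: Sequence[AttributeMeta]) -> tuple:
    """Parse ``format_premise`` output back into a condition tuple."""
    by_name = {a.name: a for a in attributes}
    text = text.strip()
    if text == "TRUE":
        return ()
    return tuple(_parse_condition(part, by_name) for part in text.split(" AND "))


def parse_rule(text: str, attributes: Sequence[AttributeMeta]) -> SurvivalRule:
    """Parse a premise into a rule shell (no conclusion attached)."""
    return SurvivalRule(conditions=parse_premise(text, attributes))
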