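"""Core survival-analysis primitives.

Weighted Kaplan-Meier (product-limit) estimation, at-risk/event tables
for a covered/uncovered split of a dataset, and the two-sample log-rank
chi-square statistic that serves as the rule-quality measure throughout
the package.

Observation weights enter every event count ``d`` and at-risk count
``r`` as fractional multiplicities, so a record of weight 2 is
indistinguishable from two unit-weight copies of it.  Times are compared
with exact floating-point equality: inputs are expected as recorded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2

NOMINAL = "nominal"
NUMERIC = "numeric"

__all__ = [
    "NOMINAL",
    "NUMERIC",
    "AttributeMeta",
    "SurvivalRecord",
    "SurvivalDataset",
    "KMCurve",
    "RiskTable",
    "is_missing",
    "km_fit",
    "km_eval",
    "build_risk_table",
    "logrank_statistic",
    "logrank_pvalue",
]


def is_missing(value) -> bool:
    """True for the two representations of a missing covariate (None / NaN)."""
    if value is None:
        return True
    return isinstance(value, float) and math.isnan(value)


@dataclass(frozen=True)
class AttributeMeta:
    """Schema entry for one covariate.

    ``domain`` is the ordered tuple of admissible values for nominal
    attributes (its order is the deterministic tie-break order during
    induction); it is empty for numeric attributes.
    """

    name: str
    kind: str
    domain: tuple = ()

    def __post_init__(self):
        if self.kind not in (NOMINAL, NUMERIC):
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        if self.kind == NOMINAL and not self.domain:
            raise ValueError(f"nominal attribute {self.name!r} needs a non-empty domain")
        if self.kind == NUMERIC and self.domain:
            raise ValueError(f"numeric attribute {self.name!r} must not declare a domain")
        object.__setattr__(self, "domain", tuple(self.domain))


@dataclass
class SurvivalRecord:
    """One right-censored observation.

    ``status`` is 1 when the event was observed and 0 for a censored
    observation; ``time`` is the follow-up time in study units.
    Missing covariate values are stored as ``None`` (or NaN).
    """

    covariates: dict
    time: float
    status: int
    weight: float = 1.0

    def __post_init__(self):
        self.time = float(self.time)
        self.status = int(self.status)
        self.weight = float(self.weight)
        if not self.time >= 0:
            raise ValueError(f"time must be non-negative, got {self.time}")
        if self.status not in (0, 1):
            raise ValueError(f"status must be 0 or 1, got {self.status}")
        if not self.weight > 0:
            raise ValueError(f"weight must be positive, got {self.weight}")


class SurvivalDataset:
    """An ordered attribute schema plus a list of :class:`SurvivalRecord`.

    Caches per-attribute numpy views (numeric values with NaN for
    missing, nominal integer codes with -1 for missing) that the
    induction and evaluation machinery operates on.
    """

    def __init__(self, attributes: Sequence[AttributeMeta], records: Sequence[SurvivalRecord]):
        self.attributes = list(attributes)
        self.records = list(records)
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("attribute names must be unique")
        self._by_name = {a.name: a for a in self.attributes}
        for i, rec in enumerate(self.records):
            for key, value in rec.covariates.items():
                if key not in self._by_name:
                    raise ValueError(f"record {i} has undeclared attribute {key!r}")
                meta = self._by_name[key]
                if meta.kind == NOMINAL and not is_missing(value) and value not in meta.domain:
                    raise ValueError(
                        f"record {i}: value {value!r} outside the domain of {key!r}"
                    )
        self._cache: dict = {}

    # -- basic views -------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def attribute(self, name: str) -> AttributeMeta:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown attribute {name!r}") from None

    @property
    def attribute_names(self) -> list:
        return [a.name for a in self.attributes]

    def _column(self, key, builder):
        if key not in self._cache:
            self._cache[key] = builder()
        return self._cache[key]

    @property
    def times(self) -> np.ndarray:
        return self._column("__times", lambda: np.array([r.time for r in self.records], float))

    @property
    def statuses(self) -> np.ndarray:
        return self._column("__status", lambda: np.array([r.status for r in self.records], float))

    @property
    def weights(self) -> np.ndarray:
        return self._column("__weights", lambda: np.array([r.weight for r in self.records], float))

    def numeric_values(self, name: str) -> np.ndarray:
        """Values of a numeric attribute as floats, NaN where missing."""
        meta = self.attribute(name)
        if meta.kind != NUMERIC:
            raise ValueError(f"{name!r} is not numeric")

        def build():
            out = np.empty(len(self.records))
            for i, rec in enumerate(self.records):
                v = rec.covariates.get(name)
                out[i] = np.nan if is_missing(v) else float(v)
            return out

        return self._column(("num", name), build)

    def nominal_codes(self, name: str) -> np.ndarray:
        """Domain indices of a nominal attribute, -1 where missing."""
        meta = self.attribute(name)
        if meta.kind != NOMINAL:
            raise ValueError(f"{name!r} is not nominal")

        def build():
            lookup = {v: i for i, v in enumerate(meta.domain)}
            out = np.empty(len(self.records), dtype=np.int64)
            for i, rec in enumerate(self.records):
                v = rec.covariates.get(name)
                out[i] = -1 if is_missing(v) else lookup[v]
            return out

        return self._column(("nom", name), build)

    def subset(self, indices) -> "SurvivalDataset":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return SurvivalDataset(self.attributes, [self.records[int(i)] for i in indices])


# ---------------------------------------------------------------------------
# Kaplan-Meier estimation


@dataclass(frozen=True, eq=False)
class KMCurve:
    """Right-continuous step estimate of a survival function.

    ``times`` are the strictly increasing jump (event) times and
    ``probs`` the survival probabilities immediately after each jump;
    the curve is 1 before the first jump and constant past the last.
    ``n_effective`` records the total weight the curve was fitted on.
    """

    times: np.ndarray
    probs: np.ndarray
    n_effective: float

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "probs", np.asarray(self.probs, float))
        if self.times.ndim != 1 or self.times.shape != self.probs.shape:
            raise ValueError("times and probs must be 1-d and aligned")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def _lookup(self, t, side):
        t_arr = np.asarray(t, float)
        if np.any(t_arr < 0):
            raise ValueError("evaluation time must be non-negative")
        idx = np.searchsorted(self.times, t_arr, side=side)
        padded = np.concatenate(([1.0], self.probs))
        out = padded[idx]
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def evaluate(self, t):
        """S(t): right-continuous evaluation (jump value applies at the jump)."""
        return self._lookup(t, "right")

    def evaluate_left(self, t):
        """S(t-): left limit (value just before the jump at t)."""
        return self._lookup(t, "left")


def _km_from_arrays(times: np.ndarray, status: np.ndarray, weights: np.ndarray) -> KMCurve:
    ut, g = np.unique(times, return_inverse=True)
    d = np.bincount(g, weights=weights * status, minlength=ut.size)
    wt = np.bincount(g, weights=weights, minlength=ut.size)
    at_risk = np.cumsum(wt[::-1])[::-1]  # weight with time >= t: censored ties stay at risk
    ev = d > 0
    probs = np.cumprod(1.0 - d[ev] / at_risk[ev])
    return KMCurve(times=ut[ev], probs=probs, n_effective=float(weights.sum()))


def _record_arrays(records: Iterable[SurvivalRecord]):
    recs = list(records)
    t = np.array([r.time for r in recs], float)
    s = np.array([r.status for r in recs], float)
    w = np.array([r.weight for r in recs], float)
    return t, s, w


def km_fit(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Weighted product-limit estimate over the records' event times.

    At a tied time carrying both events and censorings the censored
    records are still counted at risk (events processed first).
    """
    records = list(records)
    if not records:
        raise ValueError("no records to estimate a survival curve from")
    return _km_from_arrays(*_record_arrays(records))


def km_eval(curve: KMCurve, t) -> float:
    """Evaluate a KM curve right-continuously; 1 before the first event."""
    return curve.evaluate(t)


# ---------------------------------------------------------------------------
# Two-sample log-rank statistic


@dataclass(frozen=True, eq=False)
class RiskTable:
    """Per-event-time counts for a covered/uncovered split.

    One row per distinct event time across both groups: weighted event
    counts ``d_c``/``d_u`` and weighted at-risk counts ``r_c``/``r_u``.
    """

    times: np.ndarray
    d_c: np.ndarray
    d_u: np.ndarray
    r_c: np.ndarray
    r_u: np.ndarray


def build_risk_table(covered: Sequence[SurvivalRecord], uncovered: Sequence[SurvivalRecord]) -> RiskTable:
    covered, uncovered = list(covered), list(uncovered)
    if not covered and not uncovered:
        raise ValueError("risk table requires at least one record")
    tc, sc, wc = _record_arrays(covered)
    tu, su, wu = _record_arrays(uncovered)
    all_t = np.concatenate([tc, tu])
    ut = np.unique(all_t)
    G = ut.size

    def group_counts(t, s, w):
        if t.size == 0:
            return np.zeros(G), np.zeros(G)
        g = np.searchsorted(ut, t)
        d = np.bincount(g, weights=w * s, minlength=G)
        wt = np.bincount(g, weights=w, minlength=G)
        r = np.cumsum(wt[::-1])[::-1]
        return d, r

    d_c, r_c = group_counts(tc, sc, wc)
    d_u, r_u = group_counts(tu, su, wu)
    ev = (d_c + d_u) > 0
    return RiskTable(times=ut[ev], d_c=d_c[ev], d_u=d_u[ev], r_c=r_c[ev], r_u=r_u[ev])


def logrank_from_table(table: RiskTable) -> float:
    """x^2 / y over the table's event times; 0 whenever y = 0.

    Summation terms whose variance denominator vanishes (total at-risk
    weight <= 1) contribute nothing, so the statistic is finite for
    every split.
    """
    r = table.r_c + table.r_u
    d = table.d_c + table.d_u
    ok = r > 0
    x = float(np.sum(table.d_u[ok] - table.r_u[ok] / r[ok] * d[ok]))
    den = r > 1
    y = float(
        np.sum(
            (table.r_c * table.r_u * d * (r - d))[den] / (r**2 * (r - 1.0))[den]
        )
    )
    if y <= 0:
        return 0.0
    return x * x / y


def logrank_statistic(covered: Sequence[SurvivalRecord], uncovered: Sequence[SurvivalRecord]) -> float:
    """Two-sample log-rank chi-square between covered and uncovered records.

    Degenerate splits (either group empty, or no events at all) return 0
    by contract so that rule quality stays totally ordered.
    """
    covered, uncovered = list(covered), list(uncovered)
    if not covered or not uncovered:
        return 0.0
    return logrank_from_table(build_risk_table(covered, uncovered))


def logrank_pvalue(statistic: float) -> float:
    """Upper-tail chi-square(1) probability of a log-rank statistic."""
    if statistic < 0:
        raise ValueError("log-rank statistic must be non-negative")
    return float(chi2.sf(statistic, 1))
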