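"""Synthetic right-censored datasets with known rule-shaped structure.

The generator draws covariates i.i.d. from declared marginals, assigns
each record the exponential event-time distribution of the first
matching region (regions are condition lists over the covariates, with
first-match priority resolving overlaps) or the baseline rate, applies
an independent censoring mechanism, and optionally injects
missing-completely-at-random values.  Exponential event and censoring
times keep every distributional statement checkable in closed form.

Censoring can be specified directly (exponential rate or uniform upper
bound) or as a target censoring *fraction*: in that case the
exponential censoring rate is solved numerically so that the expected
fraction of censored records, averaged over the realised per-record
event rates, equals the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .core import (
    NOMINAL,
    NUMERIC,
    AttributeMeta,
    SurvivalDataset,
    SurvivalRecord,
)
from .rules import OP_EQ, OP_GE, OP_IN, OP_LT, Condition

__all__ = [
    "CovariateSpec",
    "RegionSpec",
    "GeneratorConfig",
    "generate",
    "make_fixture",
    "planted_structure_config",
    "layered_risk_config",
    "generator_config_from_dict",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one covariate.

    ``dist`` is ("normal", mu, sigma) or ("uniform", lo, hi) for
    numeric attributes and ("categorical", values, probs) for nominal
    ones.
    """

    name: str
    kind: str
    dist: tuple

    @staticmethod
    def normal(name: str, mu: float = 0.0, sigma: float = 1.0) -> "CovariateSpec":
        return CovariateSpec(name, NUMERIC, ("normal", float(mu), float(sigma)))

    @staticmethod
    def uniform(name: str, lo: float = 0.0, hi: float = 1.0) -> "CovariateSpec":
        return CovariateSpec(name, NUMERIC, ("uniform", float(lo), float(hi)))

    @staticmethod
    def uniform_int(name: str, lo: int, hi: int) -> "CovariateSpec":
        """Integer-valued numeric covariate on [lo, hi] (a score or count)."""
        return CovariateSpec(name, NUMERIC, ("uniform_int", int(lo), int(hi)))

    @staticmethod
    def categorical(name: str, values: Sequence[str], probs: Sequence[float] | None = None) -> "CovariateSpec":
        values = tuple(str(v) for v in values)
        if probs is None:
            probs = tuple(1.0 / len(values) for _ in values)
        probs = tuple(float(p) for p in probs)
        if len(probs) != len(values) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("probs must align with values and sum to 1")
        return CovariateSpec(name, NOMINAL, ("categorical", values, probs))

    def meta(self) -> AttributeMeta:
        if self.kind == NOMINAL:
            return AttributeMeta(self.name, NOMINAL, self.dist[1])
        return AttributeMeta(self.name, NUMERIC)


@dataclass(frozen=True)
class RegionSpec:
    """A covariate region with its own exponential event rate.

    Regions need not partition the covariate space; the first matching
    region (declaration order) wins.  Rates are events per time unit.
    """

    conditions: tuple
    rate: float

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if not self.rate > 0:
            raise ValueError("region rate must be positive")


@dataclass
class GeneratorConfig:
    n: int
    covariates: list
    regions: list = field(default_factory=list)
    baseline_rate: float = 0.1
    censoring: tuple | None = None  # ("exponential", rate) | ("uniform", hi) | ("fraction", p)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not self.baseline_rate > 0:
            raise ValueError("baseline rate must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must be in [0, 1)")
        if self.censoring is not None:
            kind, value = self.censoring
            if kind not in ("exponential", "uniform", "fraction"):
                raise ValueError(f"unknown censoring mechanism {kind!r}")
            if kind == "fraction":
                if not 0.0 <= value < 1.0:
                    raise ValueError("censoring fraction must be in [0, 1)")
            elif not value > 0:
                raise ValueError("censoring parameter must be positive")


def _validate_regions(config: GeneratorConfig) -> None:
    by_name = {c.name: c for c in config.covariates}
    for region in config.regions:
        for cond in region.conditions:
            if cond.attribute not in by_name:
                raise ValueError(
                    f"region condition on undeclared attribute {cond.attribute!r}"
                )
            spec = by_name[cond.attribute]
            if cond.operator == OP_EQ:
                if spec.kind != NOMINAL:
                    raise ValueError(f"equality region condition on numeric {spec.name!r}")
                if cond.value not in spec.dist[1]:
                    raise ValueError(
                        f"region value {cond.value!r} unattainable for {spec.name!r}"
                    )
            elif spec.kind != NUMERIC:
                raise ValueError(f"threshold region condition on nominal {spec.name!r}")


def _condition_mask_columns(cond: Condition, columns: dict) -> np.ndarray:
    col = columns[cond.attribute]
    if cond.operator == OP_EQ:
        return col == cond.value
    v = col.astype(float)
    if cond.operator == OP_LT:
        return v < cond.value
    if cond.operator == OP_GE:
        return v >= cond.value
    lo, hi = cond.value
    return (v >= lo) & (v < hi)


def _solve_censoring_rate(rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving the target expected censored fraction.

    With event rate lambda_i and censoring rate c, record i is censored
    with probability c / (lambda_i + c); the mean over records is a
    strictly increasing function of c, solved by bisection.
    """

    def f(c):
        return float(np.mean(c / (rates + c))) - target

    lo, hi = 1e-12, float(rates.max())
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e15:
            raise RuntimeError("failed to bracket the censoring rate")
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)


def generate(config: GeneratorConfig):
    """Draw a dataset; returns ``(dataset, region_labels)``.

    ``region_labels[i]`` is the index of the first region matching
    record ``i``, or -1 for baseline records.  Region membership is
    decided on the latent (pre-missingness) covariates.  Fully
    reproducible from ``config.seed``.
    """
    _validate_regions(config)
    rng = np.random.default_rng(config.seed)
    n = config.n

    columns: dict = {}
    for spec in config.covariates:
        if spec.kind == NUMERIC:
            kind, a, b = spec.dist
            if kind == "normal":
                columns[spec.name] = rng.normal(a, b, size=n)
            elif kind == "uniform":
                columns[spec.name] = rng.uniform(a, b, size=n)
            elif kind == "uniform_int":
                columns[spec.name] = rng.integers(int(a), int(b) + 1, size=n).astype(float)
            else:
                raise ValueError(f"unknown numeric marginal {kind!r}")
        else:
            _, values, probs = spec.dist
            codes = rng.choice(len(values), size=n, p=probs)
            columns[spec.name] = np.array(values, object)[codes]

    rates = np.full(n, config.baseline_rate)
    labels = np.full(n, -1, dtype=int)
    unassigned = np.ones(n, bool)
    for ri, region in enumerate(config.regions):
        mask = np.ones(n, bool)
        for cond in region.conditions:
            mask &= _condition_mask_columns(cond, columns)
        mask &= unassigned  # first-match priority
        rates[mask] = region.rate
        labels[mask] = ri
        unassigned &= ~mask

    event_time = rng.exponential(1.0 / rates)
    if config.censoring is None:
        time, status = event_time, np.ones(n, int)
    else:
        kind, value = config.censoring
        if kind == "fraction" and value == 0.0:
            time, status = event_time, np.ones(n, int)
        else:
            if kind == "exponential":
                cens = rng.exponential(1.0 / value, size=n)
            elif kind == "uniform":
                cens = rng.uniform(0.0, value, size=n)
            else:
                c_rate = _solve_censoring_rate(rates, value)
                cens = rng.exponential(1.0 / c_rate, size=n)
            status = (event_time <= cens).astype(int)
            time = np.minimum(event_time, cens)

    missing: dict = {}
    if config.missing_rate > 0:
        for spec in config.covariates:
            missing[spec.name] = rng.random(n) < config.missing_rate

    attributes = [spec.meta() for spec in config.covariates]
    records = []
    for i in range(n):
        cov = {}
        for spec in config.covariates:
            if missing and missing[spec.name][i]:
                cov[spec.name] = None
            else:
                v = columns[spec.name][i]
                cov[spec.name] = float(v) if spec.kind == NUMERIC else str(v)
        records.append(
            SurvivalRecord(covariates=cov, time=float(time[i]), status=int(status[i]))
        )
    return SurvivalDataset(attributes, records), labels


def planted_structure_config(
    n: int = 300,
    n_noise: int = 10,
    hazard_ratio: float = 25.0,
    censoring_fraction: float = 0.3,
    baseline_rate: float = 0.1,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GeneratorConfig:
    """Study configuration with one dominant binary risk factor.

    A binary covariate ``risk_group`` splits the population 50/50; the
    "high" half has ``hazard_ratio`` times the baseline event rate.
    Noise covariates (a mix of standard-normal, uniform and 3-level
    nominal attributes) carry no signal.
    """
    covariates = [CovariateSpec.categorical("risk_group", ("high", "low"))]
    for i in range(n_noise):
        if i % 3 == 0:
            covariates.append(CovariateSpec.normal(f"noise{i:02d}"))
        elif i % 3 == 1:
            covariates.append(CovariateSpec.uniform(f"noise{i:02d}", 0.0, 10.0))
        else:
            covariates.append(CovariateSpec.categorical(f"noise{i:02d}", ("a", "b", "c")))
    regions = [
        RegionSpec(
            conditions=(Condition("risk_group", OP_EQ, "high"),),
            rate=baseline_rate * hazard_ratio,
        )
    ]
    censoring = ("fraction", censoring_fraction) if censoring_fraction > 0 else None
    return GeneratorConfig(
        n=n,
        covariates=covariates,
        regions=regions,
        baseline_rate=baseline_rate,
        censoring=censoring,
        missing_rate=missing_rate,
        seed=seed,
    )


def layered_risk_config(
    n: int = 500,
    censoring_fraction: float = 0.3,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GeneratorConfig:
    """Study configuration with a layered, multi-region hazard structure.

    A nominal treatment arm and an integer severity score jointly define
    four regions whose event rates span a 40-fold range, plus two noise
    covariates.  Because the true model is a *set* of rules at several
    granularities, induced rule counts respond to the ``mincov``
    parameter — the configuration used to study model-size scaling
    (the single-factor :func:`planted_structure_config` is essentially
    a two-rule problem and cannot).
    """
    covariates = [
        CovariateSpec.categorical("arm", ("treated", "control")),
        CovariateSpec.uniform_int("severity", 0, 10),
        CovariateSpec.uniform_int("noise_score", 0, 19),
        CovariateSpec.categorical("noise_c", ("a", "b", "c")),
    ]
    regions = [
        RegionSpec(
            (Condition("arm", OP_EQ, "control"), Condition("severity", OP_GE, 7.0)),
            rate=2.0,
        ),
        RegionSpec(
            (Condition("arm", OP_EQ, "control"), Condition("severity", OP_LT, 3.0)),
            rate=0.4,
        ),
        RegionSpec((Condition("severity", OP_GE, 8.5),), rate=0.8),
        RegionSpec((Condition("arm", OP_EQ, "treated"), Condition("severity", OP_LT, 2.0)),
                   rate=0.05),
    ]
    censoring = ("fraction", censoring_fraction) if censoring_fraction > 0 else None
    return GeneratorConfig(
        n=n,
        covariates=covariates,
        regions=regions,
        baseline_rate=0.2,
        censoring=censoring,
        missing_rate=missing_rate,
        seed=seed,
    )


def generator_config_from_dict(obj: dict) -> GeneratorConfig:
    """Build a GeneratorConfig from a JSON-style document.

    Expected shape::

        {"n": 300, "seed": 1, "baseline_rate": 0.1,
         "censoring": ["fraction", 0.3], "missing_rate": 0.0,
         "covariates": [{"name": "g", "kind": "nominal",
                         "values": ["a", "b"], "probs": [0.5, 0.5]},
                        {"name": "x", "kind": "numeric",
                         "dist": ["normal", 0, 1]}],
         "regions": [{"rate": 2.5,
                      "conditions": [{"attribute": "g",
                                      "operator": "=", "value": "a"}]}]}
    """
    covariates = []
    for c in obj["covariates"]:
        if c["kind"] == NOMINAL:
            covariates.append(
                CovariateSpec.categorical(c["name"], c["values"], c.get("probs"))
            )
        else:
            dist = tuple(c.get("dist", ("normal", 0.0, 1.0)))
            if dist[0] == "normal":
                covariates.append(CovariateSpec.normal(c["name"], dist[1], dist[2]))
            elif dist[0] == "uniform":
                covariates.append(CovariateSpec.uniform(c["name"], dist[1], dist[2]))
            elif dist[0] == "uniform_int":
                covariates.append(CovariateSpec.uniform_int(c["name"], dist[1], dist[2]))
            else:
                raise ValueError(f"unknown numeric marginal {dist[0]!r}")
    regions = []
    for r in obj.get("regions", []):
        conds = tuple(
            Condition(
                d["attribute"],
                d["operator"],
                tuple(d["value"]) if d["operator"] == OP_IN else d["value"],
            )
            for d in r["conditions"]
        )
        regions.append(RegionSpec(conditions=conds, rate=float(r["rate"])))
    censoring = obj.get("censoring")
    if censoring is not None:
        censoring = (censoring[0], float(censoring[1]))
    return GeneratorConfig(
        n=int(obj["n"]),
        covariates=covariates,
        regions=regions,
        baseline_rate=float(obj.get("baseline_rate", 0.1)),
        censoring=censoring,
        missing_rate=float(obj.get("missing_rate", 0.0)),
        seed=int(obj.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# Hand-written unit-test fixtures (all <= 20 records, deterministic)


def _dataset(attrs, rows):
    attributes = attrs
    names = [a.name for a in attributes]
    records = [
        SurvivalRecord(
            covariates=dict(zip(names, row[:-2])), time=row[-2], status=row[-1]
        )
        for row in rows
    ]
    return SurvivalDataset(attributes, records)


def make_fixture(name: str) -> SurvivalDataset:
    """Small deterministic datasets used throughout the test suite.

    - ``km_basic``: five records, alternating event/censored, the
      classic product-limit hand check (S = 0.8, 0.5333..., 0).
    - ``logrank_pair``: events at 1,2 (group "c") vs 3,4 (group "u").
    - ``ibs_mixed``: ten records, four censored, two covariates,
      distinct integer times.
    - ``merge_coverage``: twenty records over two numeric and one
      nominal covariate for merging/coverage semantics.
    """
    if name == "km_basic":
        return _dataset(
            [AttributeMeta("x", NUMERIC)],
            [(float(i), float(i), st) for i, st in zip(range(1, 6), (1, 0, 1, 0, 1))],
        )
    if name == "logrank_pair":
        return _dataset(
            [AttributeMeta("group", NOMINAL, ("c", "u"))],
            [("c", 1.0, 1), ("c", 2.0, 1), ("u", 3.0, 1), ("u", 4.0, 1)],
        )
    if name == "ibs_mixed":
        rows = [
            (0.5, "a", 1.0, 1),
            (1.2, "b", 2.0, 0),
            (2.0, "a", 3.0, 1),
            (3.1, "b", 4.0, 1),
            (4.4, "a", 5.0, 0),
            (5.0, "b", 6.0, 1),
            (6.2, "a", 7.0, 0),
            (7.7, "b", 8.0, 1),
            (8.1, "a", 9.0, 0),
            (9.5, "b", 10.0, 1),
        ]
        return _dataset(
            [AttributeMeta("x", NUMERIC), AttributeMeta("g", NOMINAL, ("a", "b"))],
            rows,
        )
    if name == "merge_coverage":
        rows = []
        for i in range(1, 21):
            rows.append(
                (float(i), float(21 - i), "a" if i % 2 else "b", float(i), i % 3 != 0)
            )
        return _dataset(
            [
                AttributeMeta("a", NUMERIC),
                AttributeMeta("b", NUMERIC),
                AttributeMeta("g", NOMINAL, ("a", "b")),
            ],
            [(r[0], r[1], r[2], r[3], int(r[4])) for r in rows],
        )
    raise KeyError(f"unknown fixture {name!r}")
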