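"""Separate-and-conquer induction of survival rule sets.

The learner adds rules to an initially empty set until every training
record is covered.  A rule is grown by greedily appending the
elementary condition that maximises the two-sample log-rank statistic
between the records covered and not covered by the rule — always
computed on the entire training set — subject to the constraint that
the rule keeps covering at least ``mincov`` weight of previously
uncovered records.  Growing is followed by hill-climbing pruning that
removes conditions while the statistic strictly improves, and by
merging of same-attribute numeric conditions.

Candidate conditions are recomputed from the currently covered records
at every growing step: nominal attributes contribute one equality test
per observed value, numeric attributes contribute ``<``/``>=`` tests at
the arithmetic means of adjacent distinct observed values.  Missing
values are skipped throughout.

Implementation note: the quality sweep evaluates all candidates of an
attribute at once.  Writing the log-rank sums as x = sum_t c_t r_c^t -
sum_t d_c^t and y = sum_t a_t r_c^t - b_t (r_c^t)^2 (with c, a, b
precomputed from whole-dataset event counts) makes both linear in the
covered-group at-risk curve r_c, which is piecewise constant between
covered observation times; candidates differ only in value-rank prefix
sums, so one (segment x value-rank) weight matrix yields every
candidate's statistic.  This keeps full induction runs on datasets of a
few hundred records around a second.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    NOMINAL,
    NUMERIC,
    SurvivalDataset,
    SurvivalRecord,
    km_fit,
    logrank_pvalue,
)
from .rules import (
    OP_EQ,
    OP_GE,
    OP_LT,
    Condition,
    RuleSet,
    SurvivalRule,
    _merge_conditions,
    condition_mask,
)

logger = logging.getLogger(__name__)

_EPS = 1e-9  # slack for weighted mincov comparisons

__all__ = ["InductionConfig", "learn", "grow", "prune", "enumerate_conditions"]


@dataclass
class InductionConfig:
    """Induction parameters.

    ``mincov`` is the minimum weight of previously uncovered records a
    new rule must cover (default 7); ``max_conditions`` optionally caps
    premise length during growing (unlimited by default).
    """

    mincov: float = 7.0
    max_conditions: int | None = None

    def __post_init__(self):
        if not self.mincov > 0:
            raise ValueError("mincov must be positive")
        if self.max_conditions is not None and self.max_conditions < 1:
            raise ValueError("max_conditions must be at least 1")


class NoCandidateError(RuntimeError):
    """Raised when no admissible condition exists for an empty premise."""


# ---------------------------------------------------------------------------
# Vectorised log-rank machinery


class _Ctx:
    """Per-dataset arrays shared across growing and pruning.

    For every event time t of the full dataset (index e below) the
    whole-dataset event weight d_t and at-risk weight r_t are fixed, so
    the log-rank sums for a candidate covered group reduce to

        x = sum_e (d_e / r_e) rc_e  -  (total covered event weight)
        y = sum_e a_e rc_e - b_e rc_e^2

    with a_e = y-coefficient * r_e and b_e the y-coefficient itself.
    rc_e (covered at-risk weight) is a step function of e that only
    changes at the event-time positions of covered records, hence the
    prefix-sum arrays ``c1cum``/``aycum``/``ayrcum`` below, which turn
    the sums over all event times into sums over covered segments.
    """

    def __init__(self, dataset: SurvivalDataset):
        self.ds = dataset
        self.n = len(dataset)
        self.w = dataset.weights
        self.s = dataset.statuses
        self.ws = self.w * self.s
        t = dataset.times
        ut, g = np.unique(t, return_inverse=True)
        d_tot = np.bincount(g, weights=self.ws, minlength=ut.size)
        wt = np.bincount(g, weights=self.w, minlength=ut.size)
        r_tot = np.cumsum(wt[::-1])[::-1]
        ev = d_tot > 0
        self.ev_times = ut[ev]
        d_e = d_tot[ev]
        r_e = r_tot[ev]
        self.E = self.ev_times.size
        coef1 = d_e / r_e
        with np.errstate(divide="ignore", invalid="ignore"):
            yc = d_e * (r_e - d_e) / (r_e**2 * (r_e - 1.0))
        yc[r_e <= 1.0] = 0.0  # zero-denominator terms contribute nothing
        # pos[i]: number of event rows with time <= t_i; record i is at
        # risk exactly for event rows e < pos[i].
        self.pos = np.searchsorted(self.ev_times, t, side="right")
        self.c1cum = np.concatenate(([0.0], np.cumsum(coef1)))
        self.aycum = np.concatenate(([0.0], np.cumsum(yc)))
        self.ayrcum = np.concatenate(([0.0], np.cumsum(yc * r_e)))
        self.numeric = {
            a.name: dataset.numeric_values(a.name)
            for a in dataset.attributes
            if a.kind == NUMERIC
        }
        self.nominal = {
            a.name: dataset.nominal_codes(a.name)
            for a in dataset.attributes
            if a.kind == NOMINAL
        }
        self._full_sweep_cache: dict = {}

    def _segments(self, pos_sub: np.ndarray):
        """Unique at-risk breakpoints and per-segment coefficient sums."""
        upos, pinv = np.unique(pos_sub, return_inverse=True)
        prev = np.concatenate(([0], upos[:-1]))
        a1 = self.c1cum[upos] - self.c1cum[prev]
        ay = self.aycum[upos] - self.aycum[prev]
        ayr = self.ayrcum[upos] - self.ayrcum[prev]
        return upos, pinv, a1, ay, ayr

    @staticmethod
    def _stat(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x)
        np.divide(x * x, y, out=out, where=y > 0)
        return out

    def stat_matrix(self, pos_sub, k, m, w_sub, e_sub, prefix: bool):
        """Statistics of all rank-defined candidates of one attribute.

        ``k`` is each record's value rank (0..m-1).  With
        ``prefix=True`` candidate j covers ranks <= j (numeric
        thresholds); otherwise candidate j covers exactly rank j
        (nominal values).  Returns (stats_lo, stats_hi) for prefix mode
        — the "<" and ">=" sides — or a single stats array otherwise.
        """
        upos, pinv, a1, ay, ayr = self._segments(pos_sub)
        P = upos.size
        S = np.bincount(pinv * m + k, weights=w_sub, minlength=P * m).reshape(P, m)
        d_rank = np.bincount(k, weights=e_sub, minlength=m)
        if prefix:
            S = np.cumsum(S, axis=1)
            d_rank = np.cumsum(d_rank)
        # R[q, j]: covered at-risk weight of candidate j on segment q
        R = np.cumsum(S[::-1], axis=0)[::-1]
        x = a1 @ R - d_rank
        y = ayr @ R - ay @ (R * R)
        if not prefix:
            return self._stat(x, y)
        # complement side (">= threshold"): rc' = rc_total - rc per segment
        Rc = R[:, [m - 1]] - R
        x_hi = a1 @ Rc - (d_rank[m - 1] - d_rank)
        y_hi = ayr @ Rc - ay @ (Rc * Rc)
        return self._stat(x, y), self._stat(x_hi, y_hi)

    def stat_indices(self, idx: np.ndarray) -> float:
        """Log-rank statistic of the split (records idx) vs (the rest)."""
        if idx.size == 0 or idx.size == self.n:
            return 0.0
        pos_sub = self.pos[idx]
        upos, pinv, a1, ay, ayr = self._segments(pos_sub)
        S = np.bincount(pinv, weights=self.w[idx], minlength=upos.size)
        R = np.cumsum(S[::-1])[::-1]
        x = float(a1 @ R) - float(self.ws[idx].sum())
        y = float(ayr @ R) - float(ay @ (R * R))
        if y <= 0:
            return 0.0
        return x * x / y

    def stat_mask(self, mask: np.ndarray) -> float:
        return self.stat_indices(np.flatnonzero(mask))

    def cond_mask(self, cond: Condition) -> np.ndarray:
        return condition_mask(cond, self.ds)


_STAT_RTOL = 1e-9  # statistics closer than this are treated as tied


def _stat_gt(a: float, b: float) -> bool:
    """a strictly better than b, beyond floating-point tie tolerance."""
    return a > b + _STAT_RTOL * max(1.0, b)


def _argbest(stats, covs, admissible):
    """Index of the best candidate: max statistic, then max coverage, then first.

    Statistic ties are resolved with a small relative tolerance so that
    numerically equivalent candidates (e.g. the two sides of a binary
    split, which induce the same partition) fall through to the
    coverage tie-break.
    """
    idx = np.flatnonzero(admissible)
    if idx.size == 0:
        return None
    s = stats[idx]
    smax = s.max()
    idx = idx[s >= smax - _STAT_RTOL * max(1.0, smax)]
    c = covs[idx]
    idx = idx[c == c.max()]
    return int(idx[0])


def _numeric_candidates(ctx: _Ctx, name: str, C: np.ndarray):
    """(B indices, ranks, unique values, stats_lt, stats_ge, cov_lt, cov_ge)."""
    v = ctx.numeric[name]
    B = np.flatnonzero(C & ~np.isnan(v))
    if B.size == 0:
        return None
    vals = v[B]
    uniq = np.unique(vals)
    m = uniq.size
    if m < 2:
        return None
    k = np.searchsorted(uniq, vals)
    s_lo, s_hi = ctx.stat_matrix(ctx.pos[B], k, m, ctx.w[B], ctx.ws[B], prefix=True)
    c_cum = np.cumsum(np.bincount(k, weights=ctx.w[B], minlength=m))
    return B, k, uniq, s_lo[: m - 1], s_hi[: m - 1], c_cum[: m - 1], c_cum[m - 1] - c_cum[: m - 1]


def _nominal_candidates(ctx: _Ctx, name: str, C: np.ndarray):
    """(B indices, codes, domain, per-value stats, per-value coverage)."""
    codes = ctx.nominal[name]
    domain = ctx.ds.attribute(name).domain
    B = np.flatnonzero(C & (codes >= 0))
    if B.size == 0:
        return None
    k = codes[B]
    nv = len(domain)
    stats = ctx.stat_matrix(ctx.pos[B], k, nv, ctx.w[B], ctx.ws[B], prefix=False)
    cvec = np.bincount(k, weights=ctx.w[B], minlength=nv)
    return B, k, domain, stats, cvec


def _attribute_candidates(ctx: _Ctx, attr, C: np.ndarray, full: bool):
    """Candidate sweep for one attribute; cached when C covers everything."""
    key = attr.name
    if full and key in ctx._full_sweep_cache:
        return ctx._full_sweep_cache[key]
    if attr.kind == NUMERIC:
        res = _numeric_candidates(ctx, attr.name, C)
    else:
        res = _nominal_candidates(ctx, attr.name, C)
    if full:
        ctx._full_sweep_cache[key] = res
    return res


def _best_for_attribute(ctx, attr, C, uw, mincov_eff, current_cov, full, allow_nonshrinking):
    """Best admissible candidate on one attribute.

    Returns (stat, coverage_weight, Condition, shrinks) or None.
    Candidate order — thresholds ascending with "<" before ">=", nominal
    domain order — breaks exact statistic/coverage ties deterministically.
    """
    res = _attribute_candidates(ctx, attr, C, full)
    if res is None:
        return None
    if attr.kind == NUMERIC:
        B, k, uniq, s_lo, s_hi, c_lo, c_hi = res
        m = uniq.size
        u_cum = np.cumsum(np.bincount(k, weights=uw[B], minlength=m))
        u_lo, u_hi = u_cum[: m - 1], u_cum[m - 1] - u_cum[: m - 1]
        J = 2 * (m - 1)
        stats = np.empty(J)
        covs = np.empty(J)
        adm = np.empty(J, bool)
        stats[0::2], stats[1::2] = s_lo, s_hi
        covs[0::2], covs[1::2] = c_lo, c_hi
        adm[0::2] = u_lo >= mincov_eff - _EPS
        adm[1::2] = u_hi >= mincov_eff - _EPS
        best = _argbest(stats, covs, adm)
        if best is None:
            return None
        thr = 0.5 * (uniq[best // 2] + uniq[best // 2 + 1])
        op = OP_LT if best % 2 == 0 else OP_GE
        return float(stats[best]), float(covs[best]), Condition(attr.name, op, thr), True
    B, k, domain, stats, cvec = res
    uvec = np.bincount(k, weights=uw[B], minlength=len(domain))
    shrinks = cvec < current_cov - _EPS
    adm = (cvec > 0) & (uvec >= mincov_eff - _EPS)
    if not allow_nonshrinking:
        adm = adm & shrinks
    best = _argbest(stats, cvec, adm)
    if best is None:
        return None
    return (
        float(stats[best]),
        float(cvec[best]),
        Condition(attr.name, OP_EQ, domain[best]),
        bool(shrinks[best]),
    )


def _grow_premise(ctx: _Ctx, U: np.ndarray, mincov_eff: float, max_conditions):
    """Grow a premise from scratch; returns (conditions, covered mask)."""
    C = np.ones(ctx.n, bool)
    premise: list = []
    uw = np.where(U, ctx.w, 0.0)
    while max_conditions is None or len(premise) < max_conditions:
        full = not premise
        current_cov = float(ctx.w[C].sum())
        best = None  # (stat, cov, condition, shrinks)
        for attr in ctx.ds.attributes:
            cand = _best_for_attribute(
                ctx, attr, C, uw, mincov_eff, current_cov, full, False
            )
            if cand is not None and (
                best is None
                or _stat_gt(cand[0], best[0])
                or (not _stat_gt(best[0], cand[0]) and cand[1] > best[1])
            ):
                best = cand
        if best is None and not premise:
            # Degenerate data: fall back to a condition that keeps coverage
            # unchanged (single-valued nominal attribute) so the covering
            # loop can terminate with a whole-dataset rule.
            for attr in ctx.ds.attributes:
                if attr.kind != NOMINAL:
                    continue
                cand = _best_for_attribute(
                    ctx, attr, C, uw, mincov_eff, current_cov, full, True
                )
                if cand is not None and (
                    best is None
                    or _stat_gt(cand[0], best[0])
                    or (not _stat_gt(best[0], cand[0]) and cand[1] > best[1])
                ):
                    best = cand
            if best is None:
                raise NoCandidateError(
                    "no admissible condition for an empty premise "
                    f"(mincov_eff={mincov_eff})"
                )
        if best is None:
            break
        stat, cov, cond, shrinks = best
        premise.append(cond)
        C &= ctx.cond_mask(cond)
        logger.debug("grow: added %s (statistic=%.6g, coverage=%.6g)", cond, stat, cov)
        if not shrinks:
            break
    return premise, C


def _prune_premise(ctx: _Ctx, conditions: Sequence[Condition]):
    """Hill-climbing deletion while the log-rank statistic strictly improves."""
    conds = list(conditions)
    masks = [ctx.cond_mask(c) for c in conds]
    ones = np.ones(ctx.n, bool)
    current = ctx.stat_mask(np.logical_and.reduce(masks) if masks else ones)
    while len(conds) > 1:
        L = len(conds)
        prefix = [ones]
        for m in masks[:-1]:
            prefix.append(prefix[-1] & m)
        suffix = [ones]
        for m in reversed(masks[1:]):
            suffix.append(suffix[-1] & m)
        suffix.reverse()
        best_i, best_stat = None, current
        for i in range(L):
            s = ctx.stat_mask(prefix[i] & suffix[i])
            if _stat_gt(s, best_stat):  # strict improvement; ties keep the premise
                best_i, best_stat = i, s
        if best_i is None:
            break
        logger.debug("prune: removed %s (%.6g -> %.6g)", conds[best_i], current, best_stat)
        del conds[best_i]
        del masks[best_i]
        current = best_stat
    return conds


def _coverage_mask(ctx: _Ctx, conditions: Sequence[Condition]) -> np.ndarray:
    mask = np.ones(ctx.n, bool)
    for c in conditions:
        mask &= ctx.cond_mask(c)
    return mask


def _finalize(ctx: _Ctx, conditions: Sequence[Condition], merge: bool):
    conds = _merge_conditions(conditions) if merge else tuple(conditions)
    C = _coverage_mask(ctx, conds)
    stat = ctx.stat_mask(C)
    covered = [ctx.ds.records[i] for i in np.flatnonzero(C)]
    rule = SurvivalRule(
        conditions=conds,
        conclusion=km_fit(covered),
        quality=stat,
        coverage_count=float(ctx.w[C].sum()),
        p_value=logrank_pvalue(stat),
    )
    return rule, C


# ---------------------------------------------------------------------------
# Public operations


def enumerate_conditions(covered_records: Sequence[SurvivalRecord], attributes) -> list:
    """All candidate conditions derivable from the covered records.

    Nominal attributes yield one equality test per domain value observed
    among the covered records; numeric attributes yield ``<`` and ``>=``
    tests at the midpoints of adjacent distinct observed values.
    Missing values are skipped, so an attribute with no known value
    among the covered records contributes nothing.
    """
    from .core import is_missing

    covered_records = list(covered_records)
    if not covered_records:
        raise ValueError("no covered records to enumerate conditions from")
    out: list = []
    for attr in attributes:
        values = [
            r.covariates.get(attr.name)
            for r in covered_records
            if not is_missing(r.covariates.get(attr.name))
        ]
        if not values:
            continue
        if attr.kind == NOMINAL:
            observed = set(values)
            out.extend(Condition(attr.name, OP_EQ, v) for v in attr.domain if v in observed)
        else:
            uniq = np.unique(np.asarray(values, float))
            for lo, hi in zip(uniq[:-1], uniq[1:]):
                thr = 0.5 * (lo + hi)
                out.append(Condition(attr.name, OP_LT, thr))
                out.append(Condition(attr.name, OP_GE, thr))
    return out


def grow(dataset: SurvivalDataset, uncovered, config: InductionConfig | None = None) -> SurvivalRule:
    """Grow one rule against the given previously-uncovered records.

    ``uncovered`` is a boolean mask or an index array over the dataset.
    The returned rule is neither pruned nor merged; its conclusion and
    quality are fitted on the records it covers in the full dataset.
    """
    config = config or InductionConfig()
    ctx = _Ctx(dataset)
    U = _as_mask(uncovered, len(dataset))
    if not U.any():
        raise ValueError("uncovered set is empty")
    mincov_eff = min(config.mincov, float(ctx.w[U].sum()))
    premise, _ = _grow_premise(ctx, U, mincov_eff, config.max_conditions)
    rule, _ = _finalize(ctx, premise, merge=False)
    return rule


def prune(rule: SurvivalRule, dataset: SurvivalDataset, config: InductionConfig | None = None) -> SurvivalRule:
    """Prune a rule by hill-climbing condition deletion.

    The output quality (log-rank statistic on the full dataset) is never
    below the input's.  One-condition rules are returned refitted but
    otherwise unchanged.
    """
    if not rule.conditions:
        raise ValueError("cannot prune a rule with an empty premise")
    ctx = _Ctx(dataset)
    conds = _prune_premise(ctx, rule.conditions)
    pruned, _ = _finalize(ctx, conds, merge=False)
    return pruned


def _as_mask(indices, n: int) -> np.ndarray:
    arr = np.asarray(indices)
    if arr.dtype == bool:
        if arr.size != n:
            raise ValueError("mask length mismatch")
        return arr.copy()
    mask = np.zeros(n, bool)
    mask[arr] = True
    return mask


def learn(dataset: SurvivalDataset, config: InductionConfig | None = None) -> RuleSet:
    """Induce a survival rule set covering the whole training dataset.

    Rules are added until no record remains uncovered; every non-final
    rule covers at least ``mincov`` weight of previously uncovered
    records at creation, and the final rule's constraint is relaxed to
    the remaining uncovered weight so the loop can terminate.  Each rule
    is grown, pruned, merged, and equipped with a Kaplan-Meier
    conclusion fitted on the training records it covers.  The default
    curve is fitted on the full training set.

    Records whose covariates are all missing cannot be covered by any
    non-empty premise; they are released from the coverage obligation
    with a warning and fall back to the default curve at prediction.
    """
    config = config or InductionConfig()
    if len(dataset) == 0:
        raise ValueError("cannot learn from an empty dataset")
    if not dataset.attributes:
        raise ValueError("cannot learn from a dataset without attributes")
    ctx = _Ctx(dataset)

    coverable = np.zeros(ctx.n, bool)
    for v in ctx.numeric.values():
        coverable |= ~np.isnan(v)
    for codes in ctx.nominal.values():
        coverable |= codes >= 0
    if not coverable.all():
        logger.warning(
            "%d record(s) have no known covariate values and cannot be covered; "
            "they will receive the default curve",
            int((~coverable).sum()),
        )
    U = coverable.copy()
    if not U.any():
        raise ValueError("no coverable records: every covariate value is missing")

    rules: list = []
    while U.any():
        remaining = float(ctx.w[U].sum())
        mincov_eff = min(config.mincov, remaining)
        try:
            premise, _ = _grow_premise(ctx, U, mincov_eff, config.max_conditions)
        except NoCandidateError:
            # Relax to the lightest uncovered record; if even that fails, the
            # stragglers are not expressible and are abandoned to the default.
            floor = float(ctx.w[U].min())
            premise = None
            if floor < mincov_eff:
                try:
                    premise, _ = _grow_premise(ctx, U, floor, config.max_conditions)
                except NoCandidateError:
                    premise = None
            if premise is None:
                logger.warning(
                    "abandoning %d uncoverable record(s); they will use the default curve",
                    int(U.sum()),
                )
                break
        conds = _prune_premise(ctx, premise)
        rule, C = _finalize(ctx, conds, merge=True)
        rules.append(rule)
        logger.debug(
            "rule %d: %s (statistic=%.6g, coverage=%.6g, newly covered=%.6g)",
            len(rules),
            rule,
            rule.quality,
            rule.coverage_count,
            float(ctx.w[C & U].sum()),
        )
        U &= ~C
    return RuleSet(
        rules=rules,
        default_curve=km_fit(dataset.records),
        mincov=config.mincov,
        attributes=list(dataset.attributes),
    )
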