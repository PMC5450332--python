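"""Model evaluation: censoring-weighted Brier score, integrated Brier
score (IBS), censoring-stratified cross-validation and rule-set
characterisation.

The Brier score at horizon ``t*`` is the squared difference between the
observed event status and the predicted survival probability, weighted
by the inverse of the censoring survival function ``G`` (a Kaplan-Meier
estimate fitted on the training records with event and censoring roles
flipped).  Observations censored at or before ``t*`` receive weight 0;
they still shape the score through ``G``.

``G`` is evaluated at the left limit ``G(t-)`` so that a record scored
at its own censoring time is not divided by a post-drop value.  Records
whose required ``G`` value is exactly 0 are excluded from the mean at
that horizon (the tail of the follow-up interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core import (
    KMCurve,
    SurvivalDataset,
    SurvivalRecord,
    _km_from_arrays,
    _record_arrays,
    km_fit,
    logrank_pvalue,
)
from .induction import InductionConfig, learn
from .rules import RuleSet

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "censoring_km",
    "brier_score_at",
    "brier_curve",
    "integrated_brier_score",
    "stratified_cv_folds",
    "cross_validate",
    "characterize_ruleset",
]


@dataclass
class EvaluationReport:
    """Prediction error plus rule-set shape statistics for one model fit.

    ``fraction_significant`` is the fraction of rules whose log-rank
    p-value, Benjamini-Hochberg adjusted across the rule set, falls
    below 0.05.
    """

    ibs: float = float("nan")
    n_rules: int = 0
    mean_rule_length: float = float("nan")
    mean_coverage_fraction: float = float("nan")
    fraction_significant: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "ibs": self.ibs,
            "n_rules": self.n_rules,
            "mean_rule_length": self.mean_rule_length,
            "mean_coverage_fraction": self.mean_coverage_fraction,
            "fraction_significant": self.fraction_significant,
        }


def censoring_km(training_records: Sequence[SurvivalRecord]) -> KMCurve:
    """KM estimate of the censoring survival function G.

    Fitted on the training records with status replaced by ``1 - status``,
    so censorings become the "events" of the flipped problem.
    """
    records = list(training_records)
    if not records:
        raise ValueError("no training records for the censoring estimate")
    t, s, w = _record_arrays(records)
    return _km_from_arrays(t, 1.0 - s, w)


def brier_score_at(record: SurvivalRecord, predicted_curve: KMCurve, G: KMCurve, t_star: float) -> float:
    """Single-record censoring-weighted Brier score at horizon ``t_star``.

    Returns NaN when the required inverse-probability weight is
    undefined (G evaluates to 0); aggregate scores drop such terms.
    """
    if t_star < 0:
        raise ValueError("t_star must be non-negative")
    s_hat = predicted_curve.evaluate(t_star)
    if record.time <= t_star and record.status == 1:
        g = G.evaluate_left(record.time)
        return (0.0 - s_hat) ** 2 / g if g > 0 else float("nan")
    if record.time > t_star:
        g = G.evaluate_left(t_star)
        return (1.0 - s_hat) ** 2 / g if g > 0 else float("nan")
    return 0.0  # censored at or before the horizon


def brier_curve(
    test_records: Sequence[SurvivalRecord],
    predictions: Sequence[KMCurve],
    G: KMCurve,
    grid,
) -> np.ndarray:
    """Mean Brier score over the test records at each grid horizon."""
    records = list(test_records)
    if len(records) != len(predictions):
        raise ValueError("one predicted curve per test record required")
    grid = np.atleast_1d(np.asarray(grid, float))
    t, s, _ = _record_arrays(records)
    S = np.vstack([c.evaluate(grid) for c in predictions])  # (R, T)
    g_grid = np.atleast_1d(G.evaluate_left(grid))
    g_ti = np.atleast_1d(G.evaluate_left(t))

    event = (t[:, None] <= grid[None, :]) & (s[:, None] == 1.0)
    alive = t[:, None] > grid[None, :]
    bad = (event & (g_ti[:, None] <= 0)) | (alive & (g_grid[None, :] <= 0))

    contrib = np.zeros_like(S)
    with np.errstate(divide="ignore", invalid="ignore"):
        ev_term = S**2 / g_ti[:, None]
        al_term = (1.0 - S) ** 2 / g_grid[None, :]
    use_ev = event & ~bad
    use_al = alive & ~bad
    contrib[use_ev] = ev_term[use_ev]
    contrib[use_al] = al_term[use_al]
    counts = (~bad).sum(axis=0)
    out = np.zeros(grid.size)
    np.divide(contrib.sum(axis=0), counts, out=out, where=counts > 0)
    return out


def integrated_brier_score(
    test_records: Sequence[SurvivalRecord],
    predictions: Sequence[KMCurve],
    G: KMCurve,
) -> float:
    """Time-averaged Brier score over [0, max observed test time].

    The Brier score is a step function between observed times, so the
    integral is an exact left-rectangle sum over the sorted distinct
    test-set times augmented with 0 and the maximum time.
    """
    records = list(test_records)
    if not records:
        raise ValueError("empty test set")
    t, _, _ = _record_arrays(records)
    max_t = float(t.max())
    if max_t == 0:
        return 0.0
    pts = np.unique(np.concatenate(([0.0], t)))
    widths = np.diff(pts)
    bs = brier_curve(records, predictions, G, pts[:-1])
    return float(np.sum(bs * widths) / max_t)


# ---------------------------------------------------------------------------
# Cross-validation


def stratified_cv_folds(dataset: SurvivalDataset, k: int = 10, repeats: int = 10, seed: int = 0):
    """Censoring-stratified k-fold partition schedule.

    Event and censored records are shuffled separately and dealt
    round-robin so every fold keeps the dataset's event/censored
    proportion (remainders spread one per fold).  Returns a list of
    ``repeats`` partitions, each a list of ``k`` sorted index arrays.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    status = dataset.statuses
    events = np.flatnonzero(status == 1.0)
    censored = np.flatnonzero(status == 0.0)
    rng = np.random.default_rng(seed)
    schedule = []
    for _ in range(repeats):
        folds = [[] for _ in range(k)]
        for group in (events, censored):
            perm = rng.permutation(group)
            for pos, idx in enumerate(perm):
                folds[pos % k].append(int(idx))
        schedule.append([np.array(sorted(f), dtype=int) for f in folds])
    return schedule


def characterize_ruleset(ruleset: RuleSet, training_dataset: SurvivalDataset) -> EvaluationReport:
    """Rule-set shape statistics on its training set.

    Reports the rule count, mean premise length after merging, mean
    fraction of training weight covered per rule, and the fraction of
    rules significant at 0.05 after Benjamini-Hochberg adjustment of the
    per-rule log-rank p-values (covered vs uncovered).
    """
    n_rules = len(ruleset.rules)
    if n_rules == 0:
        return EvaluationReport(n_rules=0, fraction_significant=0.0)
    w = training_dataset.weights
    total = float(w.sum())
    lengths, coverages, pvals = [], [], []
    from .induction import _Ctx  # shared vectorised statistic

    ctx = _Ctx(training_dataset)
    for rule in ruleset.rules:
        mask = rule.coverage_mask(training_dataset)
        lengths.append(len(rule.conditions))
        coverages.append(float(w[mask].sum()) / total)
        pvals.append(logrank_pvalue(ctx.stat_mask(mask)))
    adjusted = multipletests(pvals, alpha=0.05, method="fdr_bh")[1]
    return EvaluationReport(
        n_rules=n_rules,
        mean_rule_length=float(np.mean(lengths)),
        mean_coverage_fraction=float(np.mean(coverages)),
        fraction_significant=float(np.mean(adjusted < 0.05)),
    )


def cross_validate(
    dataset: SurvivalDataset,
    config: InductionConfig | None = None,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    predictor: str = "rules",
):
    """Repeated censoring-stratified cross-validation.

    Per fold: learn on the training split (or, with
    ``predictor="km"``, use only the training-set Kaplan-Meier curve as
    a baseline), estimate ``G`` on the same training split, predict all
    test records and compute the IBS on the test split.  Folds whose
    training split carries no events are skipped with a warning.

    Returns ``(reports, aggregate)`` where ``aggregate`` is the
    unweighted mean over fold reports.
    """
    if predictor not in ("rules", "km"):
        raise ValueError("predictor must be 'rules' or 'km'")
    config = config or InductionConfig()
    schedule = stratified_cv_folds(dataset, k=k, repeats=repeats, seed=seed)
    all_idx = np.arange(len(dataset))
    reports = []
    for rep, folds in enumerate(schedule):
        for fi, test_idx in enumerate(folds):
            if test_idx.size == 0:
                continue
            train_idx = np.setdiff1d(all_idx, test_idx)
            train = dataset.subset(train_idx)
            if not np.any(train.statuses == 1.0):
                logger.warning("repeat %d fold %d: no events in training split, skipped", rep, fi)
                continue
            if predictor == "rules":
                model = learn(train, config)
            else:
                model = RuleSet(
                    rules=[],
                    default_curve=km_fit(train.records),
                    mincov=config.mincov,
                    attributes=list(train.attributes),
                )
            G = censoring_km(train.records)
            test = dataset.subset(test_idx)
            predictions = model.predict_dataset(test)
            ibs = integrated_brier_score(test.records, predictions, G)
            report = characterize_ruleset(model, train)
            report.ibs = ibs
            reports.append(report)
    if not reports:
        raise ValueError("every fold was degenerate; nothing to aggregate")
    aggregate = EvaluationReport(
        ibs=float(np.mean([r.ibs for r in reports])),
        n_rules=float(np.mean([r.n_rules for r in reports])),
        mean_rule_length=float(np.nanmean([r.mean_rule_length for r in reports]))
        if any(np.isfinite(r.mean_rule_length) for r in reports)
        else float("nan"),
        mean_coverage_fraction=float(np.nanmean([r.mean_coverage_fraction for r in reports]))
        if any(np.isfinite(r.mean_coverage_fraction) for r in reports)
        else float("nan"),
        fraction_significant=float(np.mean([r.fraction_significant for r in reports])),
    )
    return reports, aggregate
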