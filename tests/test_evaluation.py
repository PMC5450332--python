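"""Censoring-weighted Brier score, IBS, stratified CV, characterisation."""

import numpy as np
import pytest

import survrules as sr
from survrules.evaluation import brier_curve


def rec(time, status, **cov):
    return sr.SurvivalRecord(covariates=cov, time=time, status=status)


def constant_curve(p):
    if p == 1.0:
        return sr.KMCurve(times=[], probs=[], n_effective=1)
    return sr.KMCurve(times=[0.0], probs=[p], n_effective=1)


def oracle_curve(t_event):
    """Perfect predictor: survival 1 before the event, 0 from it on."""
    return sr.KMCurve(times=[t_event], probs=[0.0], n_effective=1)


class TestCensoringKM:
    def test_no_censoring_gives_identity(self):
        G = sr.censoring_km([rec(t, 1) for t in range(1, 6)])
        assert G.times.size == 0
        assert G.evaluate(100.0) == 1.0

    def test_all_censored_equals_event_km(self):
        times = [1.0, 2.0, 3.0]
        G = sr.censoring_km([rec(t, 0) for t in times])
        ref = sr.km_fit([rec(t, 1) for t in times])
        np.testing.assert_allclose(G.times, ref.times)
        np.testing.assert_allclose(G.probs, ref.probs, atol=1e-15)

    def test_mixed_matches_flipped_reference(self, ibs_mixed):
        from lifelines import KaplanMeierFitter

        G = sr.censoring_km(ibs_mixed.records)
        kmf = KaplanMeierFitter().fit(
            [r.time for r in ibs_mixed.records],
            [1 - r.status for r in ibs_mixed.records],
        )
        grid = np.linspace(0, 12, 49)
        np.testing.assert_allclose(
            G.evaluate(grid), kmf.survival_function_at_times(grid).to_numpy(), atol=1e-12
        )


class TestBrierScoreAt:
    G1 = constant_curve(1.0)

    def test_perfect_survivor_prediction_scores_zero(self):
        assert sr.brier_score_at(rec(5, 1), constant_curve(1.0), self.G1, 3.0) == 0.0

    def test_event_before_horizon_squared_difference(self):
        assert sr.brier_score_at(rec(2, 1), constant_curve(0.5), self.G1, 3.0) == pytest.approx(0.25)

    def test_censored_before_horizon_scores_zero(self):
        assert sr.brier_score_at(rec(2, 0), constant_curve(0.5), self.G1, 3.0) == 0.0

    def test_inverse_weighting_by_G(self):
        G = sr.KMCurve(times=[1.0], probs=[0.5], n_effective=4)
        # event at 3 <= horizon: weight 1/G(3-) = 2
        assert sr.brier_score_at(rec(3, 1), constant_curve(0.5), G, 4.0) == pytest.approx(0.5)

    def test_negative_horizon_rejected(self):
        with pytest.raises(ValueError):
            sr.brier_score_at(rec(1, 1), constant_curve(0.5), self.G1, -1.0)


class TestIntegratedBrierScore:
    def test_oracle_predictor_scores_zero_without_censoring(self):
        records = [rec(t, 1) for t in (1.0, 2.0, 5.0, 7.0)]
        preds = [oracle_curve(r.time) for r in records]
        G = sr.censoring_km(records)
        assert sr.integrated_brier_score(records, preds, G) == pytest.approx(0.0, abs=1e-15)

    def test_constant_half_predictor_scores_quarter(self):
        records = [rec(t, 1) for t in (1.0, 3.0, 4.0, 9.0)]
        preds = [constant_curve(0.5)] * len(records)
        G = sr.censoring_km(records)
        assert sr.integrated_brier_score(records, preds, G) == pytest.approx(0.25, abs=1e-15)

    def test_zero_censoring_reduces_to_uncensored_brier(self, rng):
        # direct implementation of the uncensored time-averaged Brier score
        records = [rec(float(t), 1) for t in rng.integers(1, 30, size=20)]
        model = sr.km_fit(records)
        preds = [model] * len(records)
        G = sr.censoring_km(records)
        got = sr.integrated_brier_score(records, preds, G)

        times = np.array([r.time for r in records])
        pts = np.unique(np.concatenate(([0.0], times)))
        max_t = times.max()
        acc = 0.0
        for lo, hi in zip(pts[:-1], pts[1:]):
            s = model.evaluate(lo)
            bs = np.mean([(s - (1.0 if t > lo else 0.0)) ** 2 for t in times])
            acc += bs * (hi - lo)
        assert got == pytest.approx(acc / max_t, abs=1e-12)

    def test_mixed_censoring_matches_independent_reference(self, ibs_mixed):
        """Naive direct-formula IBS with a lifelines censoring estimate."""
        from lifelines import KaplanMeierFitter

        records = ibs_mixed.records
        model = sr.km_fit(records)
        preds = [model] * len(records)
        G = sr.censoring_km(records)
        got = sr.integrated_brier_score(records, preds, G)

        kmf = KaplanMeierFitter().fit(
            [r.time for r in records], [1 - r.status for r in records]
        )

        def g_left(t):  # integer fixture times: half-step below is the left limit
            return float(kmf.survival_function_at_times([t - 0.5]).iloc[0])

        times = np.array([r.time for r in records])
        pts = np.unique(np.concatenate(([0.0], times)))
        acc = 0.0
        for lo, hi in zip(pts[:-1], pts[1:]):
            scores, kept = [], 0
            for r in records:
                s_hat = model.evaluate(lo)
                if r.time <= lo and r.status == 1:
                    g = g_left(r.time)
                    if g <= 0:
                        continue
                    scores.append(s_hat**2 / g)
                elif r.time > lo:
                    g = g_left(lo) if lo > 0 else 1.0
                    if g <= 0:
                        continue
                    scores.append((1 - s_hat) ** 2 / g)
                else:
                    scores.append(0.0)
            acc += np.mean(scores) * (hi - lo)
        expected = acc / times.max()
        assert got == pytest.approx(expected, abs=1e-6)

    def test_brier_curve_matches_scikit_survival(self, ibs_mixed):
        """Cross-check BS(t) against sksurv on a grid avoiding G's jumps."""
        from sksurv.metrics import brier_score as sksurv_brier

        records = ibs_mixed.records
        ruleset = sr.learn(ibs_mixed, sr.InductionConfig(mincov=3))
        preds = ruleset.predict_dataset(ibs_mixed)
        G = sr.censoring_km(records)
        grid = np.array([1.5, 3.5, 4.5, 6.5, 8.5])
        got = brier_curve(records, preds, G, grid)

        y = np.array(
            [(bool(r.status), r.time) for r in records],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        estimate = np.vstack([c.evaluate(grid) for c in preds])
        _, ref = sksurv_brier(y, y, estimate, grid)
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_order_invariance(self, ibs_mixed, rng):
        records = list(ibs_mixed.records)
        model = sr.km_fit(records)
        G = sr.censoring_km(records)
        base = sr.integrated_brier_score(records, [model] * len(records), G)
        perm = rng.permutation(len(records))
        shuffled = [records[i] for i in perm]
        assert sr.integrated_brier_score(shuffled, [model] * len(records), G) == pytest.approx(
            base, rel=1e-12
        )


class TestStratifiedFolds:
    def make_dataset(self, n_events, n_censored):
        records = [rec(float(i + 1), 1) for i in range(n_events)]
        records += [rec(float(i + 1), 0) for i in range(n_censored)]
        return sr.SurvivalDataset([sr.AttributeMeta("x", "numeric")], records)

    def test_exact_stratification(self):
        ds = self.make_dataset(60, 40)
        folds = sr.stratified_cv_folds(ds, k=10, repeats=1, seed=3)[0]
        status = ds.statuses
        for fold in folds:
            assert (status[fold] == 0).sum() == 4
            assert (status[fold] == 1).sum() == 6

    def test_partition_contract(self):
        ds = self.make_dataset(33, 14)
        schedule = sr.stratified_cv_folds(ds, k=5, repeats=3, seed=9)
        for folds in schedule:
            all_idx = np.concatenate(folds)
            assert len(all_idx) == len(ds)
            assert len(np.unique(all_idx)) == len(ds)

    def test_round_robin_remainder(self):
        ds = self.make_dataset(57, 43)
        folds = sr.stratified_cv_folds(ds, k=10, repeats=1, seed=0)[0]
        censored_counts = sorted(int((ds.statuses[f] == 0).sum()) for f in folds)
        assert sum(censored_counts) == 43
        assert set(censored_counts) <= {4, 5}

    def test_too_few_folds_rejected(self):
        ds = self.make_dataset(5, 5)
        with pytest.raises(ValueError):
            sr.stratified_cv_folds(ds, k=1)


class TestCrossValidate:
    def test_deterministic_given_seed(self):
        ds, _ = sr.generate(sr.planted_structure_config(n=80, n_noise=2, seed=3))
        _, agg1 = sr.cross_validate(ds, sr.InductionConfig(mincov=7), k=5, repeats=1, seed=11)
        _, agg2 = sr.cross_validate(ds, sr.InductionConfig(mincov=7), k=5, repeats=1, seed=11)
        assert agg1.as_dict() == agg2.as_dict()

    def test_km_baseline_nonnegative(self):
        ds, _ = sr.generate(sr.planted_structure_config(n=60, n_noise=2, seed=4))
        reports, agg = sr.cross_validate(ds, k=5, repeats=1, seed=2, predictor="km")
        assert agg.ibs >= 0
        assert all(r.n_rules == 0 for r in reports)

    def test_no_train_test_leakage(self):
        ds, _ = sr.generate(sr.planted_structure_config(n=50, n_noise=2, seed=5))
        schedule = sr.stratified_cv_folds(ds, k=5, repeats=2, seed=7)
        all_idx = np.arange(len(ds))
        for folds in schedule:
            for fold in folds:
                train = np.setdiff1d(all_idx, fold)
                assert np.intersect1d(train, fold).size == 0


class TestCharacterize:
    def test_degenerate_whole_dataset_rule(self):
        attrs = [sr.AttributeMeta("g", "nominal", ("only",))]
        records = [sr.SurvivalRecord({"g": "only"}, float(t), 1) for t in range(1, 9)]
        ds = sr.SurvivalDataset(attrs, records)
        ruleset = sr.learn(ds, sr.InductionConfig(mincov=7))
        report = sr.characterize_ruleset(ruleset, ds)
        assert report.n_rules == 1
        assert report.mean_coverage_fraction == pytest.approx(1.0)
        assert report.fraction_significant == 0.0

    def test_mean_length_is_arithmetic_mean(self):
        ds, _ = sr.generate(sr.planted_structure_config(n=100, n_noise=3, seed=8))
        ruleset = sr.learn(ds, sr.InductionConfig(mincov=7))
        report = sr.characterize_ruleset(ruleset, ds)
        assert report.mean_rule_length == pytest.approx(
            np.mean([len(r.conditions) for r in ruleset.rules])
        )

    def test_significance_fraction_matches_hand_rolled_bh(self):
        # step-up procedure implemented directly, e.g. (.01,.02,.03,.9) -> (.04,.04,.04,.9)
        def bh(pvals):
            p = np.asarray(pvals, float)
            order = np.argsort(p)
            m = p.size
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        np.testing.assert_allclose(
            bh([0.01, 0.02, 0.03, 0.9]), [0.04, 0.04, 0.04, 0.9], atol=1e-12
        )

        ds, _ = sr.generate(sr.planted_structure_config(n=150, n_noise=3, seed=9))
        ruleset = sr.learn(ds, sr.InductionConfig(mincov=7))
        report = sr.characterize_ruleset(ruleset, ds)
        pvals = []
        for rule in ruleset.rules:
            mask = rule.coverage_mask(ds)
            stat = sr.logrank_statistic(
                [r for r, m in zip(ds.records, mask) if m],
                [r for r, m in zip(ds.records, mask) if not m],
            )
            pvals.append(sr.logrank_pvalue(stat))
        expected = float(np.mean(bh(pvals) < 0.05))
        assert report.fraction_significant == pytest.approx(expected)
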