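"""Likelihood-ratio estimation, log-LR summation and set assembly."""
import math

import numpy as np
import pytest

import mitoevidence as me
from mitoevidence.io_model import ValidationError


def _features(calls, predictor_ids=None):
    calls = np.asarray(calls, dtype=float)
    if predictor_ids is None:
        predictor_ids = [f"s{j+1}" for j in range(calls.shape[1])]
    return me.FeatureMatrix(
        [f"p{i}" for i in range(calls.shape[0])], predictor_ids, calls
    )


def _catalog(n_pos, n_neg):
    return me.ProteinCatalog(
        [(f"p{i}", me.Label.POSITIVE, "") for i in range(n_pos)]
        + [(f"p{i + n_pos}", me.Label.NEGATIVE, "") for i in range(n_neg)]
    )


class TestEstimateLikelihoodRatios:
    def test_direct_frequency_counts(self):
        # 8/10 positives, 2/10 negatives call 1; alpha=0 -> L1=4, L0=0.25
        calls = np.concatenate([np.ones(8), np.zeros(2), np.ones(2), np.zeros(8)])
        lr = me.estimate_likelihood_ratios(
            _features(calls[:, None]), _catalog(10, 10), alpha=0.0
        )
        assert lr["s1"].l1 == pytest.approx(4.0)
        assert lr["s1"].l0 == pytest.approx(0.25)

    def test_laplace_pseudocount(self):
        calls = np.concatenate([np.ones(8), np.zeros(2), np.ones(2), np.zeros(8)])
        lr = me.estimate_likelihood_ratios(
            _features(calls[:, None]), _catalog(10, 10), alpha=1.0
        )
        assert lr["s1"].l1 == pytest.approx((9 / 12) / (3 / 12))

    def test_uninformative_predictor_unit_ratios(self):
        calls = np.concatenate([np.ones(5), np.zeros(5), np.ones(5), np.zeros(5)])
        lr = me.estimate_likelihood_ratios(
            _features(calls[:, None]), _catalog(10, 10), alpha=0.0
        )
        assert lr["s1"].l1 == pytest.approx(1.0)
        assert lr["s1"].l0 == pytest.approx(1.0)

    def test_zero_cell_with_alpha_zero_instructs_pseudocount(self):
        calls = np.concatenate([np.ones(10), np.zeros(10)])
        with pytest.raises(ValidationError, match="alpha > 0"):
            me.estimate_likelihood_ratios(
                _features(calls[:, None]), _catalog(10, 10), alpha=0.0
            )

    def test_missing_calls_excluded_from_tallies(self):
        calls = np.array([1.0, np.nan, 0.0, 1.0, 0.0, np.nan])[:, None]
        lr = me.estimate_likelihood_ratios(_features(calls), _catalog(3, 3), alpha=1.0)
        pl = lr["s1"]
        assert (pl.n1_pos, pl.n0_pos, pl.n1_neg, pl.n0_neg) == (1, 1, 1, 1)

    def test_estimate_converges_to_generating_odds_ratio(self):
        # L1 -> sens / (1 - spec) as n grows
        sens, spec = 0.42, 0.96
        cfg = me.SynthConfig(n_pos=100_000, n_neg=100_000, seed=19)
        cat = me.generate_gold_standard(cfg)
        fm = me.generate_predictor_calls(
            cat, (me.PredictorProfile("s", sens, spec),), seed=19
        )
        lr = me.estimate_likelihood_ratios(fm, cat, alpha=1.0)
        truth = sens / (1.0 - spec)
        assert abs(lr["s"].l1 - truth) / truth < 0.05


class TestPriorOdds:
    def test_paper_value_one_in_nineteen(self):
        odds = me.prior_odds(1500, 30480)
        assert odds == pytest.approx(1500 / 28980)
        assert round(1.0 / odds) == 19

    def test_equal_split_gives_even_odds(self):
        assert me.prior_odds(7, 14) == pytest.approx(1.0)

    def test_exact_twentieth(self):
        assert me.prior_odds(1, 21) == pytest.approx(0.05)

    @pytest.mark.parametrize("n_pos,n_total", [(0, 10), (10, 10), (11, 10)])
    def test_bounds_violation(self, n_pos, n_total):
        with pytest.raises(ValidationError):
            me.prior_odds(n_pos, n_total)


class TestIntegrate:
    def _table(self, ratios):
        return me.LikelihoodTable(
            {
                sid: me.PredictorLikelihood(sid, l1, l0, 1, 1, 1, 1)
                for sid, (l1, l0) in ratios.items()
            },
            alpha=1.0,
        )

    def test_no_predictors_gives_prior(self):
        fm = me.FeatureMatrix(["p0"], [], np.empty((1, 0)))
        odds = me.OddsModel(n_pos=1500, n_total=30480)
        res = me.integrate(fm, self._table({}), odds=odds)
        assert res.loglr[0] == 0.0
        assert res.posterior_odds()[0] == pytest.approx(odds.prior_odds)

    def test_two_predictor_arithmetic(self):
        fm = _features([[1.0, 1.0]])
        res = me.integrate(fm, self._table({"s1": (4.0, 0.5), "s2": (2.0, 0.5)}))
        assert res.loglr[0] == pytest.approx(math.log10(8.0))

    def test_unit_ratio_contributes_nothing(self):
        fm = _features([[1.0], [0.0]])
        res = me.integrate(fm, self._table({"s1": (1.0, 1.0)}))
        assert np.all(res.loglr == 0.0)

    def test_missing_policies(self):
        fm = _features([[np.nan]])
        table = self._table({"s1": (4.0, 0.5)})
        assert me.integrate(fm, table, missing_policy="skip").loglr[0] == 0.0
        assert me.integrate(fm, table, missing_policy="as_absent").loglr[
            0
        ] == pytest.approx(math.log10(0.5))

    def test_unknown_predictor_rejected(self):
        fm = _features([[1.0]], predictor_ids=["mystery"])
        with pytest.raises(ValidationError, match="mystery"):
            me.integrate(fm, self._table({"s1": (4.0, 0.5)}))

    def test_additive_over_predictor_partitions(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 2, size=(50, 6)).astype(float)
        fm = _features(calls)
        cat = _catalog(25, 25)
        lr = me.estimate_likelihood_ratios(fm, cat, alpha=1.0)
        whole = me.integrate(fm, lr).loglr
        fa = me.FeatureMatrix(fm.protein_ids, fm.predictor_ids[:3], calls[:, :3])
        fb = me.FeatureMatrix(fm.protein_ids, fm.predictor_ids[3:], calls[:, 3:])
        parts = me.integrate(fa, lr).loglr + me.integrate(fb, lr).loglr
        assert np.allclose(whole, parts)


class TestClassify:
    def test_strict_inequality_at_threshold(self):
        res = me.IntegrationResult(["a", "b", "c"], np.array([1.40, 1.37, 1.30]))
        calls = me.classify(res, 1.37)
        assert list(calls) == [True, False, False]

    def test_very_low_threshold_calls_everything(self):
        res = me.IntegrationResult(["a", "b"], np.array([-5.0, 0.0]))
        assert me.classify(res, -1e9).all()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        res = me.IntegrationResult(
            [f"p{i}" for i in range(100)], rng.standard_normal(100)
        )
        prev = me.classify(res, -3.0)
        for t in (-1.0, 0.0, 1.0, 3.0):
            cur = me.classify(res, t)
            assert not np.any(cur & ~prev)  # raising t never adds a positive
            prev = cur


class TestGroupMerging:
    def test_record_threshold_counting(self):
        calls = np.zeros((1, 9))
        calls[0, :5] = 1.0  # 5 of 9 group predictors call 1
        fm = _features(calls)
        merged = me.merge_group_indirect(fm, set(fm.predictor_ids), 4)
        assert merged.calls[0, 0] == 1.0
        merged6 = me.merge_group_indirect(fm, set(fm.predictor_ids), 6)
        assert merged6.calls[0, 0] == 0.0

    def test_threshold_one_is_or_and_full_is_and(self):
        calls = np.array([[1.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        fm = _features(calls)
        group = set(fm.predictor_ids)
        assert list(me.merge_group_indirect(fm, group, 1).calls[:, 0]) == [1, 0, 1]
        assert list(me.merge_group_indirect(fm, group, 2).calls[:, 0]) == [0, 0, 1]
        assert np.array_equal(
            me.merge_group_direct(fm, group).calls,
            me.merge_group_indirect(fm, group, 1).calls,
        )

    def test_threshold_above_group_size_rejected(self):
        fm = _features([[1.0, 1.0]])
        with pytest.raises(ValidationError):
            me.merge_group_indirect(fm, set(fm.predictor_ids), 3)


class TestCoreSet:
    @pytest.mark.parametrize(
        "integrated,experimental,negatives,expected",
        [
            ({"a", "b"}, {"b", "c"}, set(), {"a", "b", "c"}),
            ({"a", "b"}, {"c"}, {"a"}, {"b", "c"}),
            (set(), set(), {"x"}, set()),
        ],
    )
    def test_set_algebra(self, integrated, experimental, negatives, expected):
        assert me.assemble_core_set(integrated, experimental, negatives) == expected


class TestIntegrationRecovery:
    def test_single_perfect_predictor_auc_one(self):
        cat = me.generate_gold_standard(me.SynthConfig(n_pos=50, n_neg=100, seed=2))
        fm = me.generate_predictor_calls(
            cat, (me.PredictorProfile("s", 1.0, 1.0),), seed=2
        )
        lr = me.estimate_likelihood_ratios(fm, cat, alpha=1.0)
        res = me.integrate(fm, lr)
        labels = [p in cat.positives for p in res.protein_ids]
        assert me.roc_curve(res.loglr, labels).auc == 1.0

    def test_integration_dominates_single_predictors(self, paper_scale_catalog):
        # conditional independence holds by construction, so the summed
        # log-LR should rank at least as well as any one predictor
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            fm = me.generate_predictor_calls(
                paper_scale_catalog, me.DEFAULT_PREDICTOR_PROFILES, seed=seed
            )
            lr = me.estimate_likelihood_ratios(fm, paper_scale_catalog, alpha=1.0)
            res = me.integrate(fm, lr)
            labels = [p in paper_scale_catalog.positives for p in res.protein_ids]
            integrated = me.roc_curve(res.loglr, labels).auc
            best_single = max(
                me.roc_curve(fm.calls[:, j], labels).auc
                for j in range(len(fm.predictor_ids))
            )
            wins += integrated >= best_single
        assert wins >= n_seeds - 1
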