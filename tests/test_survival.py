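"""Kaplan-Meier, log-rank and concordance: hand oracles and invariants."""

import itertools

import numpy as np
import pytest

from mrsig.survival import concordance_index, km_estimate, logrank_test, survival_at

from conftest import make_outcomes, random_survival


class TestKaplanMeier:
    def test_all_censored_is_flat_one(self):
        curve = km_estimate(make_outcomes([1.0, 2.0, 3.0], [0, 0, 0]))
        assert len(curve.event_times) == 0
        assert survival_at(curve, 2.5) == (1.0, False)

    def test_hand_product_limit_with_censoring(self):
        # censor at 1, events at 2 and 3: S(2) = 1/2, S(3) = 0
        curve = km_estimate(make_outcomes([1.0, 2.0, 3.0], [0, 1, 1]))
        assert survival_at(curve, 2.0)[0] == pytest.approx(0.5, abs=1e-10)
        assert survival_at(curve, 2.5)[0] == pytest.approx(0.5, abs=1e-10)
        assert survival_at(curve, 3.0)[0] == pytest.approx(0.0, abs=1e-10)
        assert survival_at(curve, 0.0) == (1.0, False)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(1.0, 40)
        curve = km_estimate(make_outcomes(times, np.ones(40, dtype=int)))
        for t in (0.2, 0.7, 1.5):
            assert survival_at(curve, t)[0] == pytest.approx(np.mean(times > t))

    def test_censoring_at_event_time_processed_after_events(self):
        # at t=2 one event and one censoring: both in the risk set of 3
        curve = km_estimate(make_outcomes([1.0, 2.0, 2.0, 3.0], [1, 1, 0, 1]))
        assert survival_at(curve, 2.0)[0] == pytest.approx(0.75 * (1 - 1 / 3))

    def test_extrapolation_flagged(self):
        curve = km_estimate(make_outcomes([1.0, 2.0], [1, 0]))
        value, extrapolated = survival_at(curve, 10.0)
        assert extrapolated and value == pytest.approx(0.5)

    def test_lifelines_cross_check(self):
        rng = np.random.default_rng(2)
        _, outcomes = random_survival(rng, 60)
        curve = km_estimate(outcomes)
        from lifelines import KaplanMeierFitter

        times = [o.time for o in outcomes]
        events = [o.event for o in outcomes]
        kmf = KaplanMeierFitter().fit(times, events)
        for t in (0.1, 0.5, 1.0, 2.0):
            assert survival_at(curve, t)[0] == pytest.approx(
                float(kmf.predict(t)), abs=1e-10
            )


class TestLogRank:
    def test_identical_groups_give_zero(self):
        group = make_outcomes([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1])
        chi2, df, p = logrank_test([group, group])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_hand_computed_six_sample_instance(self):
        """Events at disjoint times; O-E/V arithmetic done by hand below."""
        a = make_outcomes([1.0, 3.0, 5.0], [1, 1, 1])
        b = make_outcomes([2.0, 4.0, 6.0], [1, 1, 1])
        # time 1: n=6, nA=3, d=1 -> E_A=1/2, V=(1*5/5)*(3/6)(3/6)=1/4
        # time 2: n=5, nA=2, d=1 -> E_A=2/5, V=(2/5)(3/5)=6/25
        # time 3: n=4, nA=2, d=1 -> E_A=1/2, V=1/4
        # time 4: n=3, nA=1, d=1 -> E_A=1/3, V=(1/3)(2/3)=2/9
        # time 5: n=2, nA=1, d=1 -> E_A=1/2, V=1/4
        # time 6: n=1, nA=0, d=1 -> E_A=0,   V=0
        o_minus_e = (1 - 0.5) + (0 - 0.4) + (1 - 0.5) + (0 - 1 / 3) + (1 - 0.5) - 0
        v = 0.25 + 6 / 25 + 0.25 + 2 / 9 + 0.25
        chi2, df, p = logrank_test([a, b])
        assert chi2 == pytest.approx(o_minus_e**2 / v, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([make_outcomes([1.0], [1])])

    def test_label_swap_invariance_and_lifelines_agreement(self):
        rng = np.random.default_rng(3)
        _, outcomes = random_survival(rng, 80)
        half = len(outcomes) // 2
        a, b = outcomes[:half], outcomes[half:]
        chi2_ab, _, p_ab = logrank_test([a, b])
        chi2_ba, _, p_ba = logrank_test([b, a])
        assert chi2_ab == pytest.approx(chi2_ba, abs=1e-10)
        from lifelines.statistics import logrank_test as ll_logrank

        res = ll_logrank(
            [o.time for o in a], [o.time for o in b],
            [o.event for o in a], [o.event for o in b],
        )
        assert chi2_ab == pytest.approx(res.test_statistic, abs=1e-8)
        assert p_ab == pytest.approx(res.p_value, abs=1e-8)

    def test_three_group_statistic_has_two_df(self):
        rng = np.random.default_rng(4)
        _, outcomes = random_survival(rng, 90)
        groups = [outcomes[i::3] for i in range(3)]
        chi2, df, p = logrank_test(groups)
        assert df == 2 and chi2 >= 0

    def test_null_rejection_rate_near_alpha(self):
        """Type-I error of the two-group test at alpha=0.05."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            _, outcomes = random_survival(rng, 60)
            labels = rng.permutation(60) < 30
            a = [o for o, m in zip(outcomes, labels) if m]
            b = [o for o, m in zip(outcomes, labels) if not m]
            _, _, p = logrank_test([a, b])
            rejections += p < 0.05
        rate = rejections / n_sim
        # exact binomial 99% interval around 0.05 at 400 draws
        assert 0.024 <= rate <= 0.081


def brute_force_concordance(scores, outcomes):
    """Exhaustive pair enumeration with the declared tie conventions."""
    num = den = 0.0
    for i, j in itertools.permutations(range(len(outcomes)), 2):
        oi, oj = outcomes[i], outcomes[j]
        if oi.event != 1:
            continue
        if oi.time < oj.time or (oi.time == oj.time and oj.event == 0):
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_ordering_gives_one(self):
        outcomes = make_outcomes([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        assert concordance_index([4.0, 3.0, 2.0, 1.0], outcomes) == 1.0
        assert concordance_index([1.0, 2.0, 3.0, 4.0], outcomes) == 0.0

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        times = rng.choice([1.0, 2.0, 3.0, 4.0], n)  # deliberate time ties
        events = rng.integers(0, 2, n)
        if events.sum() == 0:
            events[0] = 1
        scores = rng.choice([0.0, 0.5, 1.0, 2.0], n)  # deliberate score ties
        outcomes = make_outcomes(times, events)
        try:
            ours = concordance_index(scores, outcomes)
        except ValueError:
            return  # no permissible pairs in this draw
        assert ours == pytest.approx(brute_force_concordance(scores, outcomes), abs=1e-12)

    def test_negation_flips_concordance(self):
        rng = np.random.default_rng(7)
        x, outcomes = random_survival(rng, 50, beta=0.8)
        c = concordance_index(x, outcomes)
        assert concordance_index(-x, outcomes) == pytest.approx(1.0 - c, abs=1e-12)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(8)
        _, outcomes = random_survival(rng, 2000)
        scores = rng.standard_normal(2000)
        assert 0.47 <= concordance_index(scores, outcomes) <= 0.53

    def test_no_permissible_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_index([1.0, 2.0], make_outcomes([1.0, 1.0], [1, 1]))
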