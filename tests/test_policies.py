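"""Unit and property tests for the bandit policies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdswts.policies import (
    BetaTrace,
    DiscountedTS,
    FDSWThompsonSampling,
    HotWindow,
    OraclePolicy,
    PolicyConfig,
    RandomPolicy,
    SlidingWindowTS,
    ThompsonSampling,
    make_policy,
    policy_from_spec,
)


def beta_mean_sd(a, b):
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    return mean, np.sqrt(var)


class TestBetaTrace:
    @pytest.mark.parametrize("s,f", [(0, 0), (999, 0), (2, 2)])
    def test_sample_mean_matches_posterior(self, s, f, rng):
        """Draws come from Beta(s+1, f+1): empirical mean within 3 sigma."""
        trace = BetaTrace(s, f)
        n = 20_000
        draws = np.array([trace.sample(rng) for _ in range(n)])
        assert np.all((draws >= 0) & (draws <= 1))
        mean, sd = beta_mean_sd(s + 1, f + 1)
        assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(n)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            BetaTrace(-1, 0)

    def test_discount_then_add(self):
        trace = BetaTrace()
        trace.add(1)
        assert (trace.s, trace.f) == (1, 0)
        trace.discount(0.5)
        trace.add(0)
        assert (trace.s, trace.f) == (0.5, 1)


class TestHotWindow:
    @pytest.mark.parametrize(
        "contents,a,b",
        [((), 1, 1), ((1, 1, 1, 1), 5, 1), ((1, 0), 2, 2)],
    )
    def test_posterior_shapes(self, contents, a, b, rng):
        w = HotWindow(10, contents)
        assert (w.alpha, w.beta) == (a, b)
        n = 20_000
        draws = np.array([w.sample(rng) for _ in range(n)])
        mean, sd = beta_mean_sd(a, b)
        assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(n)

    def test_fifo_eviction(self):
        w = HotWindow(2, (1, 1, 0))
        assert w.contents == (1, 0)
        assert (w.successes, w.failures) == (1, 1)

    @given(st.lists(st.integers(0, 1), max_size=60), st.integers(1, 7))
    @settings(max_examples=60, deadline=None)
    def test_contents_are_last_n_rewards(self, rewards, cap):
        """Window always reproduces the trailing min(n, #rewards) entries."""
        w = HotWindow(cap)
        for r in rewards:
            w.append(r)
        assert w.contents == tuple(rewards[-cap:])
        assert w.successes == sum(rewards[-cap:])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            HotWindow(0)
        with pytest.raises(ValueError):
            HotWindow(3, (2,))


class TestThompsonSampling:
    def test_fresh_state_is_exchangeable(self, rng):
        """With uniform priors every arm is picked ~1/K of the time."""
        pol = ThompsonSampling(4)
        picks = np.array([pol.select(rng) for _ in range(10_000)])
        freqs = np.bincount(picks, minlength=4) / len(picks)
        band = 3 * np.sqrt(0.25 * 0.75 / len(picks))
        assert np.all(np.abs(freqs - 0.25) < band)

    def test_dominant_arm_wins(self, rng):
        pol = ThompsonSampling(4)
        pol._s[:] = [99, 0, 0, 0]
        pol._f[:] = [0, 99, 99, 99]
        picks = [pol.select(rng) for _ in range(2000)]
        assert np.mean(np.array(picks) == 0) >= 0.999

    def test_observe_updates_only_played_arm(self):
        pol = ThompsonSampling(4)
        pol.update(2, 1)
        assert pol._s.tolist() == [0, 0, 1, 0]
        assert pol._f.tolist() == [0, 0, 0, 0]

    def test_non_binary_reward_rejected(self):
        with pytest.raises(ValueError):
            ThompsonSampling(2).update(0, 0.5)


class TestDiscountedTS:
    def test_gamma_one_matches_plain_ts(self):
        """gamma=1 gives byte-identical choices to TS under a shared stream."""
        env_rewards = np.random.default_rng(0).integers(0, 2, size=200)
        choices = {}
        for name, pol in [("ts", ThompsonSampling(3)), ("dts", DiscountedTS(3, 1.0))]:
            rng = np.random.default_rng(42)
            seq = []
            for t in range(200):
                arm = pol.select(rng)
                pol.update(arm, int(env_rewards[t]))
                seq.append(arm)
            choices[name] = seq
        assert choices["ts"] == choices["dts"]

    def test_geometric_accumulation(self):
        """Ten consecutive unit rewards sum to a geometric series."""
        pol = DiscountedTS(2, 0.9)
        for _ in range(10):
            pol.update(0, 1)
        expected = (1 - 0.9**10) / (1 - 0.9)  # sum of 0.9^i, i=0..9
        assert pol._s[0] == pytest.approx(expected, abs=1e-12)

    def test_pure_decay_of_unplayed_arm(self):
        pol = DiscountedTS(2, 0.5)
        pol._s[:] = [0, 8]
        pol._f[:] = [0, 8]
        for _ in range(10):
            pol.update(0, 1)
        assert pol._s[1] == pytest.approx(8 * 2.0**-10)
        assert pol._f[1] == pytest.approx(8 * 2.0**-10)

    def test_played_arm_only_mode(self):
        pol = DiscountedTS(2, 0.5, discount_unplayed=False)
        pol._s[:] = [0, 8]
        pol.update(0, 1)
        assert pol._s[1] == 8  # untouched in this mode

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            DiscountedTS(2, 0.0)
        with pytest.raises(ValueError):
            DiscountedTS(2, 1.5)

    @given(
        st.floats(min_value=0.5, max_value=0.999),
        st.lists(st.integers(0, 1), min_size=1, max_size=200),
    )
    @settings(max_examples=50, deadline=None)
    def test_discounted_counts_bounded(self, gamma, rewards):
        """Geometric-series bound: s stays below 1/(1-gamma)."""
        pol = DiscountedTS(1, gamma)
        for r in rewards:
            pol.update(0, r)
        bound = 1.0 / (1.0 - gamma) + 1e-9
        assert pol._s[0] <= bound and pol._f[0] <= bound


class TestSlidingWindowTS:
    def test_window_larger_than_horizon_matches_ts(self):
        env_rewards = np.random.default_rng(3).integers(0, 2, size=300)
        choices = {}
        for name, pol in [("ts", ThompsonSampling(4)), ("sw", SlidingWindowTS(4, 300))]:
            rng = np.random.default_rng(7)
            seq = []
            for t in range(300):
                arm = pol.select(rng)
                pol.update(arm, int(env_rewards[t]))
                seq.append(arm)
            choices[name] = seq
        assert choices["ts"] == choices["sw"]

    def test_global_window_counts(self):
        pol = SlidingWindowTS(2, 2)
        for arm, r in [(0, 1), (1, 0), (0, 1)]:
            pol.update(arm, r)
        assert pol.window_contents == ((1, 0), (0, 1))
        # arm 0 posterior Beta(2,1); arm 1 posterior Beta(1,2)
        assert pol._s.tolist() == [1, 0]
        assert pol._f.tolist() == [0, 1]

    def test_absent_arm_uses_prior(self, rng):
        pol = SlidingWindowTS(2, 3)
        for _ in range(3):
            pol.update(0, 1)
        n = 20_000
        draws = np.array([rng.beta(pol._s[1] + 1, pol._f[1] + 1) for _ in range(n)])
        assert abs(draws.mean() - 0.5) < 3 * np.sqrt(1 / 12 / n)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            SlidingWindowTS(2, 0)


class TestFDSW:
    def test_single_arm_always_selected(self, rng):
        pol = FDSWThompsonSampling(1, gamma=0.9, window=5)
        assert all(pol.select(rng) == 0 for _ in range(50))

    def test_dominant_arm_selected(self, rng):
        pol = FDSWThompsonSampling(2, gamma=0.9, window=200, aggregation="mean")
        pol._s[:] = [100, 0]
        pol._f[:] = [0, 100]
        for _ in range(100):
            pol.windows[0].append(1)
            pol.windows[1].append(0)
        pol._hot_a[:] = [w.alpha for w in pol.windows]
        pol._hot_b[:] = [w.beta for w in pol.windows]
        picks = [pol.select(rng) for _ in range(2000)]
        assert np.mean(np.array(picks) == 0) >= 0.999

    def test_min_aggregation_is_pessimistic(self, rng):
        """A strong history with an all-failure recent window loses under f=min.

        Arm A: historic Beta(101,1) but hot Beta(1,51) (50 recent zeros);
        arm B: both traces Beta(31,31).  min pulls A's score to its hot
        sample, so B wins most selections.  Checked against an
        independent Monte-Carlo of the two min-distributions.
        """
        n = 4000
        # independent oracle on raw Beta draws
        a_score = np.minimum(rng.beta(101, 1, n), rng.beta(1, 51, n))
        b_score = np.minimum(rng.beta(31, 31, n), rng.beta(31, 31, n))
        assert (b_score > a_score).mean() > 0.5

        pol = FDSWThompsonSampling(2, gamma=1.0, window=60, aggregation="min")
        pol._s[:] = [100, 30]
        pol._f[:] = [0, 30]
        for _ in range(50):
            pol.windows[0].append(0)
        for r in [1, 0] * 30:
            pol.windows[1].append(r)
        pol._hot_a[:] = [w.alpha for w in pol.windows]
        pol._hot_b[:] = [w.beta for w in pol.windows]
        picks = np.array([pol.select(rng) for _ in range(n)])
        assert (picks == 1).mean() > 0.5

    def test_update_recurrences(self):
        # gamma=1 reduces to plain TS counts
        pol = FDSWThompsonSampling(2, gamma=1.0, window=10)
        for r in [1, 0, 1]:
            pol.update(0, r)
        assert (pol._s[0], pol._f[0]) == (2, 1)
        # discount-then-add with gamma=0.5
        pol = FDSWThompsonSampling(2, gamma=0.5, window=10)
        pol.update(0, 1)
        assert (pol._s[0], pol._f[0]) == (1, 0)
        pol.update(0, 0)
        assert (pol._s[0], pol._f[0]) == (0.5, 1)

    def test_update_discounts_all_arms_and_windows_stay_per_arm(self):
        pol = FDSWThompsonSampling(2, gamma=0.5, window=2)
        pol._s[:] = [0, 4]
        for r in [1, 1, 0]:
            pol.update(0, r)
        assert pol.windows[0].contents == (1, 0)
        assert pol.windows[1].contents == ()
        assert pol._s[1] == pytest.approx(4 * 0.5**3)

    def test_scores_recorded_for_audit(self, rng):
        pol = FDSWThompsonSampling(3, gamma=0.9, window=5, aggregation="mean")
        pol.select(rng)
        scores = pol.last_scores
        assert len(scores) == 3
        for s in scores:
            assert 0 <= s.theta <= 1 and 0 <= s.theta_hot <= 1
            assert s.score == pytest.approx(0.5 * (s.theta + s.theta_hot))

    def test_limit_equivalence_posteriors(self):
        """gamma=1 and n>=T: historic and hot posteriors coincide each step."""
        pol = FDSWThompsonSampling(3, gamma=1.0, window=500)
        rng = np.random.default_rng(5)
        for _ in range(300):
            arm = pol.select(rng)
            pol.update(arm, int(rng.random() < 0.4))
            hot_s = np.array([w.successes for w in pol.windows], dtype=float)
            hot_f = np.array([w.failures for w in pol.windows], dtype=float)
            assert np.array_equal(pol._s, hot_s)
            assert np.array_equal(pol._f, hot_f)

    def test_unknown_aggregation_rejected(self):
        with pytest.raises(ValueError):
            FDSWThompsonSampling(2, gamma=0.9, window=5, aggregation="median")

    def test_custom_callable_aggregation(self, rng):
        pol = FDSWThompsonSampling(2, gamma=0.9, window=5, aggregation=np.hypot)
        assert pol.select(rng) in (0, 1)


class TestRandomAndOracle:
    def test_random_is_uniform(self, rng):
        pol = RandomPolicy(4)
        picks = np.array([pol.select(rng) for _ in range(10_000)])
        freqs = np.bincount(picks, minlength=4) / len(picks)
        band = 3 * np.sqrt(0.25 * 0.75 / len(picks))
        assert np.all(np.abs(freqs - 0.25) < band)

    def test_oracle_plays_argmax(self, rng):
        pol = OraclePolicy(4)
        assert pol.select(rng, mu_t=[0.2, 0.3, 0.4, 0.5]) == 3
        assert pol.select(rng, mu_t=[0.0, 0.7, 0.1, 0.3]) == 1
        assert pol.select(rng, mu_t=[0.5, 0.5, 0.1, 0.3]) == 0  # tie -> lowest

    def test_oracle_requires_mu(self, rng):
        pol = OraclePolicy(2)
        with pytest.raises(ValueError):
            pol.select(rng)
        with pytest.raises(ValueError):
            pol.select(rng, mu_t=[])


class TestConfigAndSpecs:
    def test_zero_arms_rejected(self):
        with pytest.raises(ValueError):
            make_policy("ts", 0)

    @pytest.mark.parametrize(
        "spec,kind,attrs",
        [
            ("ts", "ts", {}),
            ("d-ts:gamma=0.98", "d-ts", {"gamma": 0.98}),
            ("sw-ts:n=100", "sw-ts", {"window": 100}),
            (
                "fdsw-mean:gamma=0.95,n=25",
                "f-dsw",
                {"gamma": 0.95, "window": 25, "aggregation_name": "mean"},
            ),
            ("min-dsw:gamma=0.95,n=100", "f-dsw", {"aggregation_name": "min"}),
        ],
    )
    def test_spec_round_trip(self, spec, kind, attrs):
        cfg = policy_from_spec(spec, arm_count=4)
        pol = cfg.build()
        assert pol.kind == kind
        for key, val in attrs.items():
            assert getattr(pol, key) == val

    def test_bad_specs_rejected(self):
        with pytest.raises(ValueError):
            policy_from_spec("ucb", 4)
        with pytest.raises(ValueError):
            policy_from_spec("ts:alpha=2", 4)
        with pytest.raises(ValueError):
            PolicyConfig("sw-ts", 4).build()  # missing window
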