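import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fiberlearn import discrimination as dsc
from fiberlearn import photometry as pho
from fiberlearn import synthetic as syn
from fiberlearn.config import MovementConfig, SimConfig
from fiberlearn.discrimination import (
    AUCTimecourse,
    auc,
    auc_analysis,
    auc_timecourse,
    lick_rate_trace,
    shuffle_null,
    significance_latency,
    trace_onset,
)
from fiberlearn.io import ValidationError

from conftest import make_session, make_table


def brute_force_auc(a, b):
    """Independent oracle: enumerate all cross-pairs, ties count 1/2."""
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0
               for x in a for y in b)
    return wins / (len(a) * len(b))


class TestAUC:
    def test_stated_example(self):
        a, b = [1, 2, 3], [0, 1, 2]
        assert brute_force_auc(a, b) == pytest.approx(7 / 9)
        assert auc(a, b) == pytest.approx(7 / 9)

    def test_identical_sets(self):
        assert auc([1, 2, 3], [1, 2, 3]) == 0.5
        assert auc([5.0], [5.0]) == 0.5

    def test_complete_separation(self):
        assert auc([4, 5, 6], [1, 2, 3]) == 1.0
        assert auc([1, 2, 3], [4, 5, 6]) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            auc([], [1.0])

    def test_complement_identity(self, rng):
        for _ in range(50):
            a = rng.integers(0, 5, size=rng.integers(1, 9))
            b = rng.integers(0, 5, size=rng.integers(1, 9))
            assert auc(a, b) + auc(b, a) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=7)
        base = auc(a, b)
        for f in (np.exp, np.tanh, lambda x: 3 * x + 2, np.arcsinh):
            assert auc(f(a), f(b)) == pytest.approx(base, abs=1e-12)

    def test_matches_brute_force_on_small_alphabet(self, rng):
        for _ in range(200):
            a = rng.integers(0, 5, size=rng.integers(1, 9))
            b = rng.integers(0, 5, size=rng.integers(1, 9))
            assert auc(a, b) == brute_force_auc(a.tolist(), b.tolist())

    @given(
        st.lists(st.integers(0, 4), min_size=1, max_size=8),
        st.lists(st.integers(0, 4), min_size=1, max_size=8),
    )
    def test_oracle_and_complement_properties(self, a, b):
        assert auc(a, b) == brute_force_auc(a, b)
        assert auc(a, b) + auc(b, a) == pytest.approx(1.0, abs=1e-12)


class TestAUCTimecourse:
    def _session_table(self, n=600, inject=None, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        stim = ["go"] * n
        licks = [[2.0] if i % 2 == 0 else [] for i in range(n)]
        table = make_table(stim, licks)
        traces = rng.normal(0, 0.05, size=(n, 240))
        if inject is not None:
            inject(traces, table)
        return make_session(traces), table

    def test_identical_classes_at_half(self):
        # all trials share the same trace -> every pooled value ties
        table = make_table(
            ["go"] * 40, [[2.0] if i % 2 == 0 else [] for i in range(40)]
        )
        session = make_session(np.ones((40, 240)))
        tc = auc_timecourse(session, table, "choice", "expert")
        np.testing.assert_allclose(tc.auc, 0.5)

    def test_late_ramp_on_hits_rises(self):
        t = -3.0 + np.arange(240) / 30.0

        def inject(traces, table):
            ramp = np.clip((t - 0.2) / 0.8, 0, 1)
            traces[table.outcome == "hit"] += 0.5 * ramp

        session, table = self._session_table(inject=inject)
        tc = auc_timecourse(session, table, "choice", "expert")
        pre = tc.auc[(t > -1.0) & (t <= 0.0)]
        late = tc.auc[(t >= 0.6) & (t < 1.0)]
        assert abs(pre.mean() - 0.5) < 0.05
        assert late.mean() > 0.9

    def test_per_frame_matches_scalar_auc(self):
        session, table = self._session_table(n=60)
        tc = auc_timecourse(session, table, "choice", "expert")
        hit = table.outcome == "hit"
        miss = table.outcome == "miss"
        for j in (0, 100, 239):
            expected = auc(session.traces[hit, j], session.traces[miss, j])
            assert tc.auc[j] == pytest.approx(expected, abs=1e-12)

    def test_small_class_warns_nan(self):
        table = make_table(["go"] * 40, [[2.0]] * 39 + [[]])
        session = make_session(np.zeros((40, 240)))
        with pytest.warns(UserWarning, match="< 2"):
            tc = auc_timecourse(session, table, "choice", "expert")
        assert np.isnan(tc.auc).all()

    def test_alt_choice_flat_without_nogo_response(self):
        cfg = SimConfig(
            n_trials=1000, seed=31, nogo_gain=0.0,
            movement=MovementConfig(coupling_gain=0.0),
        )
        table = syn.simulate_behavior(cfg)
        session, _ = syn.simulate_photometry(table, cfg)
        norm_s = pho.normalize_trials(session)
        tc = auc_timecourse(norm_s, table, "alt_choice", "expert")
        assert np.nanmax(np.abs(tc.auc - 0.5)) < 0.2
        assert abs(np.nanmean(tc.auc) - 0.5) < 0.05

    def test_unknown_pair_rejected(self, std_bundle):
        table, session, _ = std_bundle
        with pytest.raises(ValidationError, match="pair"):
            auc_timecourse(session, table, "everything", "expert")


class TestShuffleNull:
    def test_determinism(self, std_bundle):
        table, session, _ = std_bundle
        m1, s1 = shuffle_null(session, table, "choice", "expert", n=20, seed=7)
        m2, s2 = shuffle_null(session, table, "choice", "expert", n=20, seed=7)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(s1, s2)

    def test_seed_changes_null(self, std_bundle):
        table, session, _ = std_bundle
        m1, _ = shuffle_null(session, table, "choice", "expert", n=20, seed=7)
        m2, _ = shuffle_null(session, table, "choice", "expert", n=20, seed=8)
        assert not np.array_equal(m1, m2)

    def test_null_mean_near_half(self, std_bundle):
        table, session, _ = std_bundle
        mean, sd = shuffle_null(session, table, "choice", "expert", n=100, seed=1)
        # exchangeability: per-frame null mean within 3 SE of 0.5
        se = sd / np.sqrt(100)
        frac = np.mean(np.abs(mean - 0.5) <= 3 * np.maximum(se, 1e-9))
        assert frac > 0.95

    def test_too_few_iterations_rejected(self, std_bundle):
        table, session, _ = std_bundle
        with pytest.raises(ValidationError):
            shuffle_null(session, table, "choice", "expert", n=1)

    def test_matches_explicit_recomputation(self):
        """The rank re-summing shortcut equals literally recomputing the AUC
        with permuted labels."""
        rng = np.random.default_rng(3)
        table = make_table(
            ["go"] * 12, [[2.0] if i % 3 else [] for i in range(12)]
        )
        session = make_session(rng.normal(size=(12, 10)))
        mean, sd = shuffle_null(session, table, "choice", "expert", n=5, seed=9)
        # replay the permutations by hand
        hit = table.outcome == "hit"
        miss = table.outcome == "miss"
        rows = hit | miss
        vals = session.traces[rows]
        n_a = int(hit.sum())
        rng2 = np.random.default_rng(9)
        nulls = []
        for _ in range(5):
            perm = rng2.permutation(int(rows.sum()))
            a_rows = perm[:n_a]
            b_rows = perm[n_a:]
            nulls.append(
                [auc(vals[a_rows, j], vals[b_rows, j]) for j in range(10)]
            )
        nulls = np.array(nulls)
        np.testing.assert_allclose(mean, nulls.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(sd, nulls.std(axis=0), atol=1e-12)


class TestSignificanceLatency:
    def _tc(self, auc_vals, t=None):
        n = len(auc_vals)
        if t is None:
            t = -1.0 + np.arange(n) * 0.1
        return AUCTimecourse(
            time_s=np.asarray(t),
            auc=np.asarray(auc_vals, dtype=float),
            null_mean=np.full(n, 0.5),
            null_sd=np.full(n, 0.01),
        )

    def test_step_latency(self):
        vals = [0.5] * 15 + [1.0] * 5
        tc = self._tc(vals)
        latency = significance_latency(tc)
        assert latency == pytest.approx(0.5)  # frame 15 at t = -1 + 1.5

    def test_never_significant_undefined(self):
        tc = self._tc([0.5] * 20)
        assert significance_latency(tc) is None

    def test_pre_onset_significance_ineligible(self):
        vals = [1.0] * 5 + [0.5] * 15  # significant only before t = 0
        tc = self._tc(vals)
        assert significance_latency(tc) is None

    def test_zero_sd_floor(self):
        tc = self._tc([0.5] * 15 + [0.5001] * 5)
        tc.null_sd = np.zeros(20)
        assert significance_latency(tc) == pytest.approx(0.5)

    def test_requires_null(self):
        tc = AUCTimecourse(time_s=np.arange(5.0), auc=np.full(5, 0.5))
        with pytest.raises(ValidationError, match="null"):
            significance_latency(tc)


class TestTraceOnset:
    def test_quadratic_ramp_matches_finite_difference_oracle(self):
        t = np.linspace(-3, 5, 241)
        t0 = 0.5
        trace = np.where(t < t0, 0.0, (t - t0) ** 2)
        got = trace_onset(trace, t)
        # oracle: by-hand smoothing + second difference, first max pre-peak
        sm = np.array(
            [np.mean(trace[max(0, i - 1):min(len(t), i + 2)]) if 0 < i < len(t) - 1
             else trace[i] for i in range(len(t))]
        )
        # mode="nearest" edge handling
        sm[0] = np.mean([trace[0], trace[0], trace[1]])
        sm[-1] = np.mean([trace[-2], trace[-1], trace[-1]])
        d2 = [sm[i + 1] - 2 * sm[i] + sm[i - 1] for i in range(1, len(t) - 1)]
        peak = int(np.argmax(sm))
        seg = d2[: max(peak - 1, 1)]
        tol = 1e-8 * max(np.ptp(sm), 1.0)
        j = next(i for i, v in enumerate(seg) if v >= max(seg) - tol)
        assert got == pytest.approx(t[1:-1][j])
        # and it lands near the true corner
        assert abs(got - t0) <= 3 * (t[1] - t[0])

    @pytest.mark.parametrize("tau", [0.3, 0.5])
    def test_logistic_closed_form(self, tau):
        t = np.linspace(-3, 5, 241)
        t0 = 1.0
        trace = 1.0 / (1.0 + np.exp(-(t - t0) / tau))
        expected = t0 - 1.317 * tau  # maximizer of the logistic 2nd derivative
        assert trace_onset(trace, t) == pytest.approx(
            expected, abs=2 * (t[1] - t[0])
        )

    def test_constant_trace_undefined(self):
        t = np.arange(10.0)
        assert trace_onset(np.full(10, 3.0), t) is None

    def test_negative_going_trace(self):
        t = np.linspace(-3, 5, 241)
        trace = -1.0 / (1.0 + np.exp(-(t - 1.0) / 0.3))
        assert trace_onset(trace, t) == pytest.approx(1.0 - 1.317 * 0.3, abs=0.1)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            trace_onset(np.arange(4.0), np.arange(4.0))


class TestLickRateTrace:
    def test_delta_bump_at_common_lick_time(self):
        table = make_table(["go"] * 520, [[1.5]] * 520)
        t = -3.0 + np.arange(240) / 30.0
        rate = lick_rate_trace(table, "expert", t)
        peak_t = t[np.argmax(rate)]
        assert abs(peak_t - 1.5) < 0.1
        assert rate[t < 1.3].max() == 0.0
        assert rate.max() > 0.3

    def test_no_licks_zero_trace(self):
        table = make_table(["go"] * 520, [[]] * 520)
        t = -3.0 + np.arange(240) / 30.0
        rate = lick_rate_trace(table, "expert", t)
        np.testing.assert_array_equal(rate, 0.0)
        assert trace_onset(rate, t) is None

    def test_lick_onset_after_choice_onset(self, std_bundle):
        table, session, _ = std_bundle
        choice = pho.choice_trace(session, table, "expert")
        licks = lick_rate_trace(table, "expert", session.time_s)
        on_choice = trace_onset(choice, session.time_s)
        on_lick = trace_onset(licks, session.time_s)
        assert on_choice is not None and on_lick is not None
        assert on_choice < on_lick


class TestFullAnalysis:
    def test_expert_choice_analysis(self, std_bundle):
        table, session, _ = std_bundle
        tc = auc_analysis(session, table, "choice", "expert", seed=5)
        assert tc.latency_s is not None
        assert tc.latency_s >= 0.2  # ramp starts at 0.2 s
        assert tc.significant is not None

    def test_novice_choice_not_significant(self, std_bundle):
        table, session, _ = std_bundle
        tc = auc_analysis(session, table, "choice", "novice", seed=5)
        assert tc.latency_s is None

    def test_stim_before_choice(self, std_bundle):
        table, session, _ = std_bundle
        stim = auc_analysis(session, table, "stim", "expert", seed=5)
        choice = auc_analysis(session, table, "choice", "expert", seed=5)
        assert stim.latency_s < choice.latency_s
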