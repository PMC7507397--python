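import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadsync import task_model as tm
from dyadsync.errors import ValidationError
from dyadsync.task_model import (
    DyadSession,
    StrategyKind,
    StrategyParams,
    TrialRecord,
    compute_threshold,
    default_params,
    draw_dyad_effects,
    draw_trial_rts,
    score_trial,
    simulate_cohort,
    simulate_session,
    summarize_behavior,
)


class TestComputeThreshold:
    def test_direct_formula(self):
        assert compute_threshold(0.3, 0.3) == pytest.approx(0.075)

    def test_group_mean_rt(self):
        assert compute_threshold(0.83, 0.83) == pytest.approx(0.2075)

    def test_invalid_input(self):
        with pytest.raises(ValidationError):
            compute_threshold(0.4, 0.0)
        with pytest.raises(ValidationError):
            compute_threshold(-0.1, 0.5)

    @given(
        r1=st.floats(0.01, 4.0),
        r2=st.floats(0.01, 4.0),
        a=st.floats(0.1, 10.0),
    )
    def test_homogeneity(self, r1, r2, a):
        assert compute_threshold(a * r1, a * r2) == pytest.approx(
            a * compute_threshold(r1, r2), rel=1e-12
        )


class TestScoreTrial:
    def test_win(self):
        assert score_trial(0.05, 0.075) == 1

    def test_tie_rules(self):
        assert score_trial(0.075, 0.075, "leq") == 1
        assert score_trial(0.075, 0.075, "lt") == -1

    def test_loss(self):
        assert score_trial(0.2, 0.075) == -1

    def test_invalid(self):
        with pytest.raises(ValidationError):
            score_trial(-0.1, 0.075)
        with pytest.raises(ValidationError):
            score_trial(0.1, 0.075, tie_rule="bogus")


class TestDrawTrialRts:
    def test_degenerate_coupling(self):
        params = StrategyParams(
            dyad_mean_rt_mean=0.5,
            dyad_mean_rt_sd=0.1,
            within_dyad_coupling=1.0,
            trial_noise_sd=0.0,
            inconsistency_rate=0.0,
        )
        rng = np.random.default_rng(0)
        eff = draw_dyad_effects("immediate", params, rng)
        rt1, rt2 = draw_trial_rts("immediate", params, eff, rng)
        assert rt1 == rt2

    def test_immediate_mean_rt(self):
        params = default_params("immediate")
        rng = np.random.default_rng(1)
        rts = []
        for _ in range(250):
            eff = draw_dyad_effects("immediate", params, rng)
            for _ in range(40):
                rts.append(draw_trial_rts("immediate", params, eff, rng))
        rts = np.asarray(rts)
        assert rts.size == 2 * 10_000
        se = rts.std() / np.sqrt(250 * 2)  # dyads are the independent unit
        assert abs(rts.mean() - 0.30) < 3 * max(se, 1e-3)

    def test_delayed_between_dyad_sd(self):
        params = default_params("delayed")
        rng = np.random.default_rng(2)
        means = [draw_dyad_effects("delayed", params, rng).mean_rt for _ in range(10_000)]
        assert abs(np.std(means) - 0.44) / 0.44 < 0.10
        assert abs(np.mean(means) - 0.83) < 0.02

    def test_clipping_bounds(self):
        params = default_params("none")
        rng = np.random.default_rng(3)
        eff = draw_dyad_effects("none", params, rng)
        for _ in range(500):
            rt1, rt2 = draw_trial_rts("none", params, eff, rng)
            assert 0 < rt1 <= params.timeout
            assert 0 < rt2 <= params.timeout


class TestSimulateSession:
    def test_forty_trials(self, delayed_session):
        assert delayed_session.n_trials == 40
        assert {t.block_index for t in delayed_session.trials} == {1, 2}
        assert all(1 <= t.trial_index <= 20 for t in delayed_session.trials)

    def test_determinism(self):
        a = simulate_session("d", "immediate", seed=42)
        b = simulate_session("d", "immediate", seed=42)
        assert a.trials == b.trials
        assert a.score_trajectory == b.score_trajectory

    def test_trial_invariants(self, delayed_session):
        for t in delayed_session.trials:
            assert t.threshold == pytest.approx((t.rt1 + t.rt2) / 8, abs=1e-15)
            assert t.rtd == pytest.approx(abs(t.rt1 - t.rt2))
            assert 0.6 <= t.cue_delay <= 1.5
            assert t.outcome in (1, -1)

    def test_timeout_trial_wins_on_zero_rtd(self):
        thr = compute_threshold(4.0, 4.0)
        assert thr == pytest.approx(1.0)
        assert score_trial(0.0, thr) == 1

    def test_score_trajectory_matches_outcomes(self, delayed_session):
        score = 0
        for t, s in zip(delayed_session.trials, delayed_session.score_trajectory):
            score += t.outcome
            assert s == score


def _manual_session(outcomes, rt=0.4, rtd=0.0):
    trials = []
    score = 0
    traj = []
    for i, out in enumerate(outcomes):
        rt1, rt2 = rt, rt + (rtd if out == -1 else 0.0)
        thr = compute_threshold(rt1, rt2)
        trials.append(
            TrialRecord(
                block_index=1 + i // 20,
                trial_index=1 + i % 20,
                cue_delay=1.0,
                rt1=rt1,
                rt2=rt2,
                threshold=thr,
                rtd=abs(rt1 - rt2),
                outcome=out,
            )
        )
        score += out
        traj.append(score)
    return DyadSession("dX", StrategyKind.IMMEDIATE, trials, traj)


class TestSummarizeBehavior:
    def test_wr_fraction(self):
        sess = _manual_session([1] * 30 + [-1] * 10, rtd=0.5)
        assert summarize_behavior(sess).wr == pytest.approx(0.75)

    def test_cc_identity(self):
        sess = _manual_session([1] * 40)
        s = summarize_behavior(sess)
        assert s.cc == pytest.approx(s.mean_threshold - s.mean_rtd)

    def test_cc_value(self):
        assert 0.2075 - 0.10 == pytest.approx(0.1075)

    def test_all_wins(self):
        sess = _manual_session([1] * 40)
        s = summarize_behavior(sess)
        assert s.wr == 1.0
        assert sess.final_score == 40

    def test_empty_session_errors(self):
        with pytest.raises(ValidationError):
            summarize_behavior(DyadSession("d", StrategyKind.NONE, [], []))

    def test_wr_score_identity(self):
        for seed in range(5):
            for strat in ("delayed", "immediate", "none"):
                sess = simulate_session("d", strat, seed=seed)
                s = summarize_behavior(sess)
                n = sess.n_trials
                assert s.wr == pytest.approx((sess.final_score + n) / (2 * n))


class TestWinRuleMonotonicity:
    @given(
        rt1=st.floats(0.05, 2.0),
        rt2=st.floats(0.05, 2.0),
        c=st.floats(0.001, 1.9),
    )
    @settings(max_examples=200)
    def test_shifting_both_rts_never_turns_win_to_loss(self, rt1, rt2, c):
        rtd = abs(rt1 - rt2)
        before = score_trial(rtd, compute_threshold(rt1, rt2))
        after = score_trial(rtd, compute_threshold(rt1 + c, rt2 + c))
        if before == 1:
            assert after == 1


class TestSimulateCohort:
    def test_default_sizes(self):
        sessions = simulate_cohort(seed=0)
        assert len(sessions) == 43
        by = {}
        for s in sessions:
            by[s.strategy.value] = by.get(s.strategy.value, 0) + 1
        assert by == {"delayed": 17, "immediate": 16, "none": 10}

    def test_empty(self):
        assert simulate_cohort({"delayed": 0, "immediate": 0, "none": 0}) == []

    def test_negative_size_errors(self):
        with pytest.raises(ValidationError):
            simulate_cohort({"delayed": -1})

    def test_determinism(self):
        a = simulate_cohort(seed=9)
        b = simulate_cohort(seed=9)
        assert all(x.trials == y.trials for x, y in zip(a, b))

    def test_group_mean_rt_ordering(self):
        sessions = simulate_cohort(
            {"delayed": 200, "immediate": 200, "none": 200}, seed=5
        )
        means = {}
        for strat in ("delayed", "immediate", "none"):
            vals = [
                summarize_behavior(s).mean_rt
                for s in sessions
                if s.strategy.value == strat
            ]
            means[strat] = np.mean(vals)
        assert means["delayed"] > means["none"] > means["immediate"]

    def test_cc_wr_correlation_positive(self):
        sessions = simulate_cohort({"delayed": 40, "immediate": 40, "none": 40}, seed=6)
        summ = [summarize_behavior(s) for s in sessions]
        cc = [s.cc for s in summ]
        wr = [s.wr for s in summ]
        assert np.corrcoef(cc, wr)[0, 1] > 0


class TestFrames:
    def test_trials_frame_shape(self):
        sessions = simulate_cohort({"delayed": 2, "immediate": 1, "none": 0}, seed=1)
        df = tm.trials_to_frame(sessions)
        assert len(df) == 3 * 40
        assert set(df["dyad_id"]) == {s.dyad_id for s in sessions}

    def test_roundtrip_sessions_from_frame(self):
        sessions = simulate_cohort({"delayed": 2, "immediate": 2, "none": 1}, seed=2)
        df = tm.trials_to_frame(sessions)
        rebuilt = tm.sessions_from_frame(df)
        for a, b in zip(sessions, rebuilt):
            assert a.dyad_id == b.dyad_id
            assert a.strategy == b.strategy
            assert a.score_trajectory == b.score_trajectory
            for ta, tb in zip(a.trials, b.trials):
                assert ta.rt1 == pytest.approx(tb.rt1)
                assert ta.threshold == pytest.approx(tb.threshold)

    def test_missing_column_errors(self):
        sessions = simulate_cohort({"delayed": 1, "immediate": 0, "none": 0}, seed=3)
        df = tm.trials_to_frame(sessions).drop(columns=["rt1_s"])
        with pytest.raises(ValidationError, match="rt1_s"):
            tm.sessions_from_frame(df)


class TestMechanismRecovery:
    """Cohort-level decomposition: thresholds drive the win-rate ordering
    while RTDs stay statistically indistinguishable."""

    def test_replicate_cohorts(self):
        from scipy import stats as sps

        n_rep = 20
        ok_rtd = ok_thr = ok_wr = 0
        for seed in range(n_rep):
            sessions = simulate_cohort(seed=seed)
            by = {}
            for s in sessions:
                by.setdefault(s.strategy.value, []).append(summarize_behavior(s))
            rtd = [[x.mean_rtd for x in by[g]] for g in ("delayed", "immediate", "none")]
            thr = [[x.mean_threshold for x in by[g]] for g in ("delayed", "immediate", "none")]
            wr = [np.mean([x.wr for x in by[g]]) for g in ("delayed", "immediate", "none")]
            ok_rtd += sps.f_oneway(*rtd).pvalue > 0.05
            ok_thr += (
                sps.f_oneway(*thr).pvalue < 0.05
                and np.mean(thr[0]) > np.mean(thr[2]) > np.mean(thr[1])
            )
            ok_wr += wr[0] > wr[1] > wr[2]
        assert ok_rtd >= 0.8 * n_rep
        assert ok_thr >= 0.8 * n_rep
        assert ok_wr >= 0.8 * n_rep
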