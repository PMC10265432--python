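import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from ema_rt.preprocess import (
    REASON_LOW_ACCURACY,
    REASON_RT_RANGE,
    d_prime,
    exclusion_summary,
    filter_ema_rts,
    filter_ss_trials,
    log_rt,
    add_log_rt,
    score_gng_session,
    score_sessions,
    score_ss_session,
)

from conftest import make_frame


def ema_frame(rts):
    return make_frame([{"rt_seconds": rt, "item_id": f"i{k}"} for k, rt in enumerate(rts)])


def ss_frame(rts, correct, occasion="o0"):
    return make_frame(
        [
            {"measure": "SYMBOL_SEARCH", "item_id": f"t{k:02d}", "rt_seconds": rt,
             "correct": c, "occasion_id": occasion}
            for k, (rt, c) in enumerate(zip(rts, correct))
        ]
    )


def gng_frame(n_targets, n_hits, n_nontargets, n_fas):
    rows = []
    for k in range(n_targets):
        rows.append({"measure": "GO_NO_GO", "item_id": f"g{k:02d}", "is_target": True,
                     "correct": k < n_hits, "rt_seconds": 0.5})
    for k in range(n_nontargets):
        rows.append({"measure": "GO_NO_GO", "item_id": f"g{k + n_targets:02d}",
                     "is_target": False, "correct": k >= n_fas, "rt_seconds": 0.5})
    return make_frame(rows)


class TestFilterEma:
    def test_ultrafast_flagged(self):
        out = filter_ema_rts(ema_frame([0.1]))
        assert not out["valid"].iloc[0]
        assert out["invalid_reason"].iloc[0] == REASON_RT_RANGE

    def test_boundaries_inclusive(self):
        out = filter_ema_rts(ema_frame([0.2, 30.0]))
        assert out["valid"].all()

    def test_toy_input_exactly_one_valid(self):
        out = filter_ema_rts(ema_frame([0.1, 5.0, 31.0]))
        assert out["valid"].sum() == 1
        assert out.loc[out["valid"], "rt_seconds"].iloc[0] == 5.0

    def test_records_flagged_not_deleted(self):
        out = filter_ema_rts(ema_frame([0.1, 5.0, 31.0]))
        assert len(out) == 3

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            filter_ema_rts(ema_frame([1.0]), lo=0.0)
        with pytest.raises(ValueError):
            filter_ema_rts(ema_frame([1.0]), lo=2.0, hi=1.0)

    def test_idempotent(self):
        once = filter_ema_rts(ema_frame([0.1, 5.0, 31.0]))
        twice = filter_ema_rts(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_non_ema_rows_untouched(self):
        df = pd.concat(
            [ema_frame([0.1]), ss_frame([0.1], [True])], ignore_index=True
        )
        out = filter_ema_rts(df)
        assert out["valid"].iloc[1]  # SS row not judged by EMA filter


class TestFilterSymbolSearch:
    def test_low_accuracy_session_fully_invalid(self):
        # 20 trials, 13 correct = 65% < 70%
        correct = [True] * 13 + [False] * 7
        out = filter_ss_trials(ss_frame([1.0] * 20, correct))
        assert (~out["valid"]).all()
        assert (out["invalid_reason"] == REASON_LOW_ACCURACY).all()

    def test_single_slow_trial_flagged(self):
        rts = [1.0] * 19 + [6.0]
        out = filter_ss_trials(ss_frame(rts, [True] * 20))
        assert (~out["valid"]).sum() == 1
        assert out.loc[~out["valid"], "rt_seconds"].iloc[0] == 6.0

    def test_exactly_70_percent_retained(self):
        correct = [True] * 14 + [False] * 6
        out = filter_ss_trials(ss_frame([1.0] * 20, correct))
        assert out["valid"].all()

    def test_rt_range_precedence_over_accuracy(self):
        # low-accuracy session with one out-of-range trial: that trial gets
        # the rt_range reason, the rest low_accuracy
        correct = [True] * 10 + [False] * 10
        rts = [6.0] + [1.0] * 19
        out = filter_ss_trials(ss_frame(rts, correct))
        assert out["invalid_reason"].iloc[0] == REASON_RT_RANGE
        assert (out["invalid_reason"].iloc[1:] == REASON_LOW_ACCURACY).all()

    def test_accuracy_computed_before_rt_exclusion(self):
        # 10 trials, 7 correct (70%) -- among them one 6 s trial; session kept
        rts = [6.0] + [1.0] * 9
        correct = [True] * 7 + [False] * 3
        out = filter_ss_trials(ss_frame(rts, correct))
        assert out["valid"].sum() == 9

    def test_empty_ss_warns(self):
        with pytest.warns(UserWarning, match="no SYMBOL_SEARCH"):
            filter_ss_trials(ema_frame([1.0]))

    def test_idempotent(self):
        once = filter_ss_trials(ss_frame([6.0] + [1.0] * 19, [True] * 20))
        twice = filter_ss_trials(once)
        pd.testing.assert_frame_equal(once, twice)


class TestExclusionSummary:
    def test_published_symbol_search_totals(self):
        s = exclusion_summary(n_total=287543, n_rt_range=9557, n_low_accuracy=2956)
        assert s.n_excluded == 12513
        assert s.pct_excluded == 4.35
        assert s.pct_rt_range == 3.32
        assert s.pct_low_accuracy == 1.03

    def test_published_ema_totals(self):
        s = exclusion_summary(n_total=461896, n_rt_range=5979)
        assert s.pct_excluded == 1.29

    def test_no_exclusions(self):
        s = exclusion_summary(n_total=100, n_rt_range=0)
        assert s.n_excluded == 0
        assert s.pct_excluded == 0.0

    def test_from_frame_counts_disjoint_reasons(self):
        df = filter_ss_trials(ss_frame([6.0] + [1.0] * 19, [True] * 20))
        s = exclusion_summary(df, measure="SYMBOL_SEARCH")
        assert (s.n_total, s.n_rt_range, s.n_low_accuracy) == (20, 1, 0)

    def test_unrounded_percentages_additive(self):
        s = exclusion_summary(n_total=287543, n_rt_range=9557, n_low_accuracy=2956)
        assert s.pct_rt_range_exact + s.pct_low_accuracy_exact == pytest.approx(
            s.pct_excluded_exact, abs=1e-12
        )


class TestLogRt:
    def test_unit_rt_is_zero(self):
        assert log_rt(1.0) == 0.0

    def test_e_is_one(self):
        assert log_rt(np.e) == pytest.approx(1.0)

    def test_half_second(self):
        assert log_rt(0.5) == pytest.approx(-0.6931, abs=1e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            log_rt(0.0)

    def test_invalid_records_excluded_not_transformed(self):
        df = filter_ema_rts(ema_frame([0.1, 1.0]))
        out = add_log_rt(df)
        assert np.isnan(out["log_rt"].iloc[0])
        assert out["log_rt"].iloc[1] == 0.0


class TestDPrime:
    def test_equal_rates_give_zero(self):
        dp, _, _ = d_prime(5, 10, 5, 10)
        assert dp == pytest.approx(0.0, abs=1e-12)

    def test_textbook_rates(self):
        dp, hr, fr = d_prime(9, 10, 1, 10)
        assert (hr, fr) == (0.9, 0.1)
        assert dp == pytest.approx(2.5631, abs=1e-4)

    def test_perfect_session_rate_correction(self):
        dp, hr, fr = d_prime(50, 50, 0, 25)
        assert hr == pytest.approx(0.99)
        assert fr == pytest.approx(0.02)
        assert dp == pytest.approx(4.380, abs=1e-3)

    def test_antisymmetric_under_rate_swap(self):
        a, _, _ = d_prime(9, 10, 2, 10)
        b, _, _ = d_prime(2, 10, 9, 10)
        assert a == pytest.approx(-b, abs=1e-12)

    def test_requires_both_stimulus_types(self):
        with pytest.raises(ValueError):
            d_prime(5, 10, 0, 0)


class TestSessionScoring:
    def test_gng_session_score(self):
        score = score_gng_session(gng_frame(50, 50, 25, 0))
        assert score.d_prime == pytest.approx(4.380, abs=1e-3)
        assert score.hit_rate == pytest.approx(0.99)
        assert score.fa_rate == pytest.approx(0.02)

    def test_gng_missing_stimulus_type_flagged(self):
        df = gng_frame(10, 8, 0, 0)
        scores = score_sessions(df, measure="GO_NO_GO")
        assert not scores["d_prime_defined"].iloc[0]
        assert np.isnan(scores["d_prime"].iloc[0])

    def test_ss_constant_rts(self):
        score = score_ss_session(ss_frame([1.0, 1.0, 1.0], [True] * 3))
        assert score.mean_log_rt_accurate == pytest.approx(0.0)
        assert score.median_rt_accurate == 1.0
        assert score.accuracy == 1.0

    def test_ss_symmetric_logs(self):
        score = score_ss_session(ss_frame([0.5, 1.0, 2.0], [True] * 3))
        assert score.median_rt_accurate == 1.0
        assert score.mean_log_rt_accurate == pytest.approx(0.0, abs=1e-12)

    def test_ss_accuracy_over_all_trials(self):
        score = score_ss_session(ss_frame([1.0, 1.0, 1.0, 1.0], [True, True, False, False]))
        assert score.accuracy == 0.5
        assert score.n_valid_trials == 4

    def test_mean_log_tracks_median_on_lognormal_sessions(self):
        # person-level association between the two Symbol Search scores
        rng = np.random.default_rng(5)
        P, O, T = 40, 20, 20
        u = rng.normal(0, 0.3, P)
        mean_log, median = [], []
        for p in range(P):
            logs = u[p] + rng.normal(0, 0.15, (O, T)) + rng.normal(0, 0.2, (O, 1))
            rts = np.exp(logs)
            mean_log.append(np.log(rts).mean())
            median.append(np.median(rts, axis=1).mean())
        r = np.corrcoef(mean_log, median)[0, 1]
        assert r > 0.9
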