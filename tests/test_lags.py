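"""Lag schedules and the lagged-RR algorithm, checked against an
independent loop-and-table reference implementation."""

import numpy as np
import pytest

from relolife import (
    LagSchedule,
    alt_lag_weights,
    apply_lags,
    detect_transitions,
    epa_cessation_weights,
    epa_inception_weights,
)
from relolife.errors import ValidationError

# ---------------------------------------------------------------------------
# Independent reference: the biphasic cessation weights written out as a
# literal table, and a plain year-by-year state machine for the lagged RR.
# ---------------------------------------------------------------------------

CESSATION_TABLE = [
    0.70, 0.575, 0.45, 0.325, 0.20,                      # years 1-5
] + [0.20 - 0.20 * k / 15.0 for k in range(1, 16)]        # years 6-20


def reference_lagged_rr(rr, pm, inc_weights, ces_weights, threshold, lag_start):
    """Straightforward loop-style reference for the lagged RR path."""
    out = []
    active = None  # (direction, from_rr, years_elapsed)
    for t in range(len(rr)):
        if t < lag_start or t == 0:
            out.append(rr[t])
            continue
        change = pm[t] - pm[t - 1]
        if change >= threshold:
            active = ("up", out[t - 1], 0)
        elif -change >= threshold:
            active = ("down", out[t - 1], 0)
        if active is None:
            out.append(rr[t])
            continue
        direction, from_rr, elapsed = active
        table = inc_weights if direction == "up" else ces_weights
        w = table[elapsed] if elapsed < len(table) else table[-1]
        if direction == "up":
            value = from_rr + w * (rr[t] - from_rr)  # algebraically equal form
            value = from_rr * (1 + w * (rr[t] / from_rr - 1))
        else:
            value = rr[t] * (1 + w * (from_rr / rr[t] - 1))
        out.append(value)
        elapsed += 1
        finished = elapsed >= len(table)
        active = None if finished else (direction, from_rr, elapsed)
    return np.array(out)


class TestEpaSchedules:
    def test_cessation_weights_match_published_shape(self):
        ces = epa_cessation_weights()
        assert len(ces) == 20
        np.testing.assert_allclose(ces.weights, CESSATION_TABLE, atol=1e-12)
        assert ces.weight(1) == 0.70
        assert ces.weight(5) == pytest.approx(0.20)
        assert ces.weight(20) == 0.0
        # biphasic decrements: 0.125/yr then 0.20/15 per year
        np.testing.assert_allclose(np.diff(ces.weights[:5]), -0.125, atol=1e-12)
        np.testing.assert_allclose(np.diff(ces.weights[4:]), -0.20 / 15, atol=1e-12)

    def test_inception_is_exact_complement(self):
        inc, ces = epa_inception_weights(), epa_cessation_weights()
        np.testing.assert_array_equal(inc.weights + ces.weights, np.ones(20))
        assert inc.weight(1) == pytest.approx(0.30)
        assert inc.weight(5) == pytest.approx(0.80)
        assert inc.weight(20) == 1.0


class TestAltSchedules:
    def test_none_realizes_full_effect_immediately(self):
        assert alt_lag_weights("none", "inception").weight(1) == 1.0
        assert alt_lag_weights("none", "cessation").weight(1) == 0.0
        assert alt_lag_weights("none", "cessation").weight(7) == 0.0

    def test_short8_steep_and_terminates(self):
        s = alt_lag_weights("short8")
        assert len(s) == 8
        assert s.weight(8) == 0.0
        assert s.weight(5) <= 0.10  # ≥90% of the effect resolved by year 5
        assert np.all(np.diff(s.weights) <= 0)

    def test_triphasic38_terminates_at_38(self):
        s = alt_lag_weights("triphasic38")
        assert len(s) == 38
        assert s.weight(38) == 0.0
        assert np.all(np.diff(s.weights) <= 0)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValidationError):
            alt_lag_weights("gradual99")

    @pytest.mark.parametrize("name", ["epa", "short8", "triphasic38", "none"])
    def test_all_schedules_satisfy_invariants(self, name):
        ces = alt_lag_weights(name, "cessation")
        inc = alt_lag_weights(name, "inception")
        assert np.all((ces.weights >= 0) & (ces.weights <= 1))
        assert ces.weights[-1] == 0.0 and inc.weights[-1] == 1.0
        np.testing.assert_allclose(inc.weights, 1 - ces.weights)


class TestLagScheduleValidation:
    def test_rejects_increasing_cessation(self):
        with pytest.raises(ValidationError):
            LagSchedule("cessation", np.array([0.2, 0.5, 0.0]))

    def test_rejects_nonterminating_inception(self):
        with pytest.raises(ValidationError):
            LagSchedule("inception", np.array([0.3, 0.9]))

    def test_rejects_out_of_range_weights(self):
        with pytest.raises(ValidationError):
            LagSchedule("cessation", np.array([1.2, 0.0]))


class TestDetectTransitions:
    def test_single_step_up(self):
        trans = detect_transitions([10.0, 10.0, 50.0, 50.0])
        assert len(trans) == 1
        assert trans[0].year_index == 2
        assert trans[0].direction == "up"
        assert trans[0].delta == 40.0

    def test_sub_threshold_changes_ignored(self):
        assert detect_transitions([10.0, 14.0, 10.0]) == []

    def test_constant_series_empty(self):
        assert detect_transitions([30.0] * 10) == []

    def test_exact_threshold_counts(self):
        trans = detect_transitions([10.0, 15.0])
        assert len(trans) == 1 and trans[0].direction == "up"

    def test_every_qualifying_change_emitted(self):
        trans = detect_transitions([10, 50, 10, 50, 48, 10])
        assert [(t.year_index, t.direction) for t in trans] == [
            (1, "up"), (2, "down"), (3, "up"), (5, "down")]


class TestApplyLags:
    def test_toy_upward_first_year(self, epa_pair):
        inc, ces = epa_pair
        rr = np.array([1.0] + [1.2] * 25)
        pm = np.array([10.0] + [50.0] * 25)
        out = apply_lags(rr, pm, inc, ces)
        assert out[1] == pytest.approx(1.0 * (1 + 0.30 * 0.2))   # 1.06

    def test_toy_downward_first_year(self, epa_pair):
        inc, ces = epa_pair
        rr = np.array([1.2] + [1.0] * 25)
        pm = np.array([50.0] + [10.0] * 25)
        out = apply_lags(rr, pm, inc, ces)
        assert out[1] == pytest.approx(1.0 * (1 + 0.70 * 0.2))   # 1.14

    def test_constant_exposure_identity(self, epa_pair):
        inc, ces = epa_pair
        rr = np.linspace(1.0, 1.5, 40)  # RR may drift (age bands) without moves
        pm = np.full(40, 30.0)
        np.testing.assert_array_equal(apply_lags(rr, pm, inc, ces), rr)

    def test_none_pair_is_identity(self):
        inc = alt_lag_weights("none", "inception")
        ces = alt_lag_weights("none", "cessation")
        rng = np.random.default_rng(7)
        pm = rng.choice([10.0, 50.0], size=30)
        rr = 1.0 + pm / 100.0
        np.testing.assert_array_equal(apply_lags(rr, pm, inc, ces), rr)

    def test_convergence_after_schedule_length(self, epa_pair):
        inc, ces = epa_pair
        n = 30
        rr = np.array([1.0] + [1.2] * (n - 1))
        pm = np.array([10.0] + [50.0] * (n - 1))
        out = apply_lags(rr, pm, inc, ces)
        np.testing.assert_array_equal(out[20:], rr[20:])
        assert np.all(out[1:20] < 1.2)

    def test_no_lags_before_assignment_start(self, epa_pair):
        inc, ces = epa_pair
        rr = np.array([1.0, 1.2, 1.2, 1.2, 1.0, 1.0, 1.0])
        pm = np.array([10.0, 50.0, 50.0, 50.0, 10.0, 10.0, 10.0])
        out = apply_lags(rr, pm, inc, ces, lag_start_index=4)
        np.testing.assert_array_equal(out[:4], rr[:4])  # pre-window unlagged
        assert out[4] == pytest.approx(1.0 * (1 + 0.70 * 0.2))

    def test_bounded_by_bracketing_rrs(self, epa_pair):
        inc, ces = epa_pair
        rng = np.random.default_rng(11)
        pm = rng.choice([8.0, 55.0], size=60)
        rr = np.where(pm > 30, 1.35, 1.02)
        out = apply_lags(rr, pm, inc, ces)
        assert np.all(out >= 1.02 - 1e-12)
        assert np.all(out <= 1.35 + 1e-12)

    def test_interruption_restarts_from_current_effective_rr(self, epa_pair):
        inc, ces = epa_pair
        # up at year 1, reversed at year 3 while the inception lag evolves
        rr = np.array([1.0, 1.3, 1.3, 1.0, 1.0, 1.0])
        pm = np.array([10.0, 50.0, 50.0, 10.0, 10.0, 10.0])
        out = apply_lags(rr, pm, inc, ces)
        up1 = 1.0 * (1 + 0.30 * 0.3)
        up2 = 1.0 * (1 + (1 - 0.575) * 0.3)
        assert out[1] == pytest.approx(up1)
        assert out[2] == pytest.approx(up2)
        # new downward episode starts from the frozen effective RR out[2]
        assert out[3] == pytest.approx(1.0 * (1 + 0.70 * (up2 / 1.0 - 1)))

    def test_misaligned_lengths_rejected(self, epa_pair):
        inc, ces = epa_pair
        with pytest.raises(ValidationError):
            apply_lags(np.ones(5), np.ones(6), inc, ces)

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_reference_on_random_two_level_histories(self, seed, epa_pair):
        """100 random 30-year two-level histories vs the loop reference."""
        inc, ces = epa_pair
        rng = np.random.default_rng(seed)
        pm = rng.choice([10.0, 50.0], size=30)
        rr = np.where(pm == 50.0, 1.25, 1.04)
        lag_start = int(rng.integers(0, 10))
        got = apply_lags(rr, pm, inc, ces, lag_start_index=lag_start)
        want = reference_lagged_rr(rr, pm, list(inc.weights), list(ces.weights),
                                   5.0, lag_start)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_dataframe_input_applies_per_cause(self, epa_pair):
        import pandas as pd

        inc, ces = epa_pair
        pm = np.array([10.0] + [50.0] * 24)
        frame = pd.DataFrame({"copd": [1.0] + [1.2] * 24, "lri": [1.0] + [1.1] * 24})
        out = apply_lags(frame, pm, inc, ces)
        assert out["copd"].iloc[1] == pytest.approx(1.06)
        assert out["lri"].iloc[1] == pytest.approx(1.03)
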