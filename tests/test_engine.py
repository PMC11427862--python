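from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jitai.catalog import default_catalog
from jitai.config import ConfigurationError, EngineConfig, NormalizerConfig
from jitai.engine import (
    Baseline,
    FlowError,
    FlowState,
    SchedulingState,
    SensedSample,
    StressScore,
    ValidationError,
    compute_stress_score,
    gate_nudge,
    learn_baseline,
    schedule_emas,
    select_intervention,
    step_flow,
)

T0 = datetime(2024, 1, 8, 9, 0)  # a Monday, 9:00


def sample(emails=0.0, meetings=0.0, frac=0.0, facial=-3.0, hr=55.0):
    return SensedSample(
        timestamp=T0, emails_received_running=emails, meetings_today=meetings,
        fraction_of_day=frac, facial_score=facial, heart_rate=hr,
    )


class TestStressScore:
    def test_all_components_zero(self):
        s = compute_stress_score(sample())
        assert s.value == 0.0
        assert all(v == 0.0 for v in s.components.values())

    def test_all_components_at_maximum(self):
        nz = NormalizerConfig()
        s = compute_stress_score(
            sample(emails=nz.emails_hi, meetings=nz.meetings_hi, frac=1.0,
                   facial=nz.facial_cap, hr=nz.heart_rate_hi)
        )
        assert s.value == 1.0

    def test_known_component_mix(self):
        """Components normalizing to (0.2, 0.4, 0.6, 0.8, 1.0) average 0.6."""
        nz = NormalizerConfig()
        s = compute_stress_score(
            sample(
                emails=0.2 * nz.emails_hi,
                meetings=0.4 * nz.meetings_hi,
                frac=0.6,
                facial=0.8 * 2 * nz.facial_cap - nz.facial_cap,
                hr=nz.heart_rate_hi,
            )
        )
        assert s.value == pytest.approx(0.6, abs=1e-12)

    def test_score_is_mean_of_components(self):
        s = compute_stress_score(sample(emails=7, meetings=2, frac=0.3, facial=0.5, hr=80))
        assert s.value == pytest.approx(np.mean(list(s.components.values())), abs=1e-15)

    @settings(max_examples=50, deadline=None)
    @given(
        emails=st.floats(0, 40), meetings=st.floats(0, 20),
        frac=st.floats(0, 1), facial=st.floats(-5, 5), hr=st.floats(40, 140),
        bump=st.floats(0, 10),
    )
    def test_monotone_in_each_component(self, emails, meetings, frac, facial, hr, bump):
        base = compute_stress_score(sample(emails, meetings, frac, facial, hr)).value
        assert compute_stress_score(sample(emails + bump, meetings, frac, facial, hr)).value >= base
        assert compute_stress_score(sample(emails, meetings + bump, frac, facial, hr)).value >= base
        assert compute_stress_score(sample(emails, meetings, min(1.0, frac + bump / 10), facial, hr)).value >= base


class TestBaseline:
    def test_defaults_are_range_midpoints(self):
        b = learn_baseline([], [])
        assert (b.score_threshold, b.ema_threshold, b.source) == (0.5, 3.0, "default")

    def test_learned_means(self):
        b = learn_baseline([0.2, 0.4], [1, 2, 3])
        assert (b.score_threshold, b.ema_threshold, b.source) == (
            pytest.approx(0.3), pytest.approx(2.0), "learned")

    def test_partial_data(self):
        b = learn_baseline([0.5], [])
        assert b.score_threshold == pytest.approx(0.5)
        assert b.score_source == "learned"
        assert b.ema_threshold == 3.0
        assert b.ema_source == "default"

    def test_ema_out_of_scale_rejected(self):
        with pytest.raises(ValidationError):
            learn_baseline([], [0])
        with pytest.raises(ValidationError):
            learn_baseline([], [6])


def clear_state(now):
    return SchedulingState(
        work_start=now.replace(hour=9, minute=0),
        work_end=now.replace(hour=17, minute=0),
    )


HIGH = StressScore(0.9, {})
LOW = StressScore(0.1, {})
BASE = Baseline(0.5, 3.0)


class TestGate:
    def test_all_clear_sends(self):
        now = T0.replace(hour=11)
        assert gate_nudge(clear_state(now), now, HIGH, None, BASE).send

    def test_outside_working_hours(self):
        now = T0.replace(hour=18)
        d = gate_nudge(clear_state(now), now, HIGH, None, BASE)
        assert (d.send, d.reason) == (False, "outside_working_hours")
        # half-open interval: the end bound itself is outside
        end = T0.replace(hour=17, minute=0)
        assert gate_nudge(clear_state(end), end, HIGH, None, BASE).reason == "outside_working_hours"

    def test_daily_cap(self):
        now = T0.replace(hour=16)
        st_ = clear_state(now)
        st_.nudge_times = [now - timedelta(hours=h) for h in (7, 5, 4, 3)]
        d = gate_nudge(st_, now, HIGH, None, BASE)
        assert (d.send, d.reason) == (False, "daily_cap")

    def test_nudge_cooldown(self):
        now = T0.replace(hour=12)
        st_ = clear_state(now)
        st_.nudge_times = [now - timedelta(minutes=90)]
        assert gate_nudge(st_, now, HIGH, None, BASE).reason == "nudge_cooldown"
        st_.nudge_times = [now - timedelta(minutes=121)]
        assert gate_nudge(st_, now, HIGH, None, BASE).send

    def test_completion_cooldown(self):
        now = T0.replace(hour=12)
        st_ = clear_state(now)
        st_.completion_times = [now - timedelta(minutes=30)]
        assert gate_nudge(st_, now, HIGH, None, BASE).reason == "completion_cooldown"

    def test_pending_reschedule_blocks_jit_only(self):
        now = T0.replace(hour=12)
        st_ = clear_state(now)
        st_.pending_reschedule = now + timedelta(hours=2)
        assert gate_nudge(st_, now, HIGH, None, BASE).reason == "pending_reschedule"
        assert gate_nudge(st_, now, LOW, None, BASE, is_rescheduled=True).send

    def test_trigger_or_logic(self):
        now = T0.replace(hour=12)
        st_ = clear_state(now)
        assert gate_nudge(st_, now, LOW, None, BASE).reason == "no_trigger"
        assert gate_nudge(st_, now, LOW, 4, BASE).send  # EMA above its baseline
        assert gate_nudge(st_, now, HIGH, 1, BASE).send  # score above its baseline

    def test_block_reason_follows_rule_order(self):
        """With several rules failing, the first in rule order is reported."""
        now = T0.replace(hour=12)
        st_ = clear_state(now)
        st_.nudge_times = [now - timedelta(minutes=10)]
        st_.completion_times = [now - timedelta(minutes=10)]
        assert gate_nudge(st_, now, LOW, None, BASE).reason == "completion_cooldown"

    def test_unordered_history_rejected(self):
        now = T0.replace(hour=12)
        st_ = clear_state(now)
        st_.nudge_times = [now, now - timedelta(hours=3)]
        with pytest.raises(ValidationError):
            gate_nudge(st_, now, HIGH, None, BASE)


class TestEmaSchedule:
    def test_five_prompts_within_workday(self):
        rng = np.random.default_rng(0)
        start, end = T0, T0.replace(hour=17)
        times = schedule_emas(start, end, rng)
        assert len(times) == 5
        assert all(start <= t < end for t in times)
        assert all(b > a for a, b in zip(times, times[1:]))
        gaps = [(b - a).total_seconds() / 60 for a, b in zip(times, times[1:])]
        assert min(gaps) >= 45

    def test_deterministic_given_seed(self):
        a = schedule_emas(T0, T0.replace(hour=17), np.random.default_rng(7))
        b = schedule_emas(T0, T0.replace(hour=17), np.random.default_rng(7))
        assert a == b

    def test_infeasible_workday_rejected(self):
        with pytest.raises(ConfigurationError):
            schedule_emas(T0, T0 + timedelta(hours=1), np.random.default_rng(0),
                          n_emas=5, min_spacing_min=30)


class TestFlow:
    def start_flow(self):
        return step_flow(FlowState(), "nudge", T0)

    def test_postpone_records_time_and_source(self):
        f = self.start_flow()
        until = T0.replace(hour=15)
        f = step_flow(f, "postpone", T0 + timedelta(minutes=2), until)
        assert f.state == "postponed"
        assert f.postponed_until == until

    def test_expiry_after_30_minutes(self):
        f = self.start_flow()
        f = step_flow(f, "timeout", T0 + timedelta(minutes=30))
        assert f.state == "expired"
        assert not f.engaged

    def test_expiry_before_30_minutes_is_illegal(self):
        f = self.start_flow()
        with pytest.raises(FlowError):
            step_flow(f, "timeout", T0 + timedelta(minutes=10))

    def full_path(self):
        t = T0
        f = self.start_flow()
        f = step_flow(f, "choose_category", t, "calm")
        f = step_flow(f, "report_pre_stress", t, 3)
        f = step_flow(f, "begin", t)
        f = step_flow(f, "done", t + timedelta(minutes=4))
        return f

    def test_done_marks_engaged_without_subsequent_prompts(self):
        f = self.full_path()
        assert f.engaged
        f = step_flow(f, "abandon", T0 + timedelta(minutes=40))
        assert f.engaged  # engagement survives dropping the rating prompts

    def test_rating_requires_done_first(self):
        f = self.start_flow()
        f = step_flow(f, "choose_category", T0, "calm")
        with pytest.raises(FlowError):
            step_flow(f, "rate", T0, 4)

    def test_full_completion_path(self):
        f = self.full_path()
        f = step_flow(f, "rate", T0 + timedelta(minutes=5), 4)
        f = step_flow(f, "report_post_stress", T0 + timedelta(minutes=6), 2)
        assert f.state == "post_stress_reported"
        assert (f.rating, f.post_stress) == (4, 2)

    def test_double_postpone_rejected_by_default(self):
        f = self.start_flow()
        f = step_flow(f, "postpone", T0, T0 + timedelta(hours=2))
        with pytest.raises(FlowError):
            step_flow(f, "postpone", T0, T0 + timedelta(hours=3))

    def test_rating_scale_validated(self):
        f = self.full_path()
        with pytest.raises(FlowError):
            step_flow(f, "rate", T0, 6)


class TestSelection:
    def test_catalog_has_18_items_per_category(self):
        catalog = default_catalog()
        for cat in ("distract", "calm", "address"):
            assert sum(it.category == cat for it in catalog) == 18

    def test_without_replacement_until_exhaustion(self):
        catalog = default_catalog()
        served: set = set()
        rng = np.random.default_rng(0)
        first_cycle = [select_intervention("calm", served, rng, catalog) for _ in range(18)]
        assert len({it.intervention_id for it in first_cycle}) == 18

    def test_forced_last_item(self):
        catalog = default_catalog()
        calm_ids = [it.intervention_id for it in catalog if it.category == "calm"]
        served = set(calm_ids[:-1])
        rng = np.random.default_rng(1)
        it = select_intervention("calm", served, rng, catalog)
        assert it.intervention_id == calm_ids[-1]

    def test_exhaustion_resets_served_set(self):
        catalog = default_catalog()
        calm_ids = {it.intervention_id for it in catalog if it.category == "calm"}
        served = set(calm_ids)
        rng = np.random.default_rng(2)
        # Next 18 draws again cover the full category without repetition.
        second_cycle = {
            select_intervention("calm", served, rng, catalog).intervention_id
            for _ in range(18)
        }
        assert second_cycle == calm_ids

    def test_empty_catalog_rejected(self):
        with pytest.raises(ConfigurationError):
            select_intervention("calm", set(), np.random.default_rng(0), [])
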