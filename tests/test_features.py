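from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

from jitai.engine import FlowState, step_flow
from jitai.events import Event
from jitai.features import (
    IntegrityError,
    assign_half_hour,
    build_model_tables,
    engagement_skewness,
    label_outcomes,
    nudge_probability,
)

D = datetime(2024, 1, 8)


@pytest.mark.parametrize(
    "ts, expected_minute, expected_hour",
    [
        (D.replace(hour=10, minute=14, second=59), 0, 10),
        (D.replace(hour=10, minute=30), 30, 10),  # boundary belongs to its own slot
        (D.replace(hour=10, minute=59, second=59), 30, 10),
        (D.replace(hour=9, minute=0), 0, 9),
    ],
)
def test_assign_half_hour(ts, expected_minute, expected_hour):
    slot = assign_half_hour(ts)
    assert (slot.hour, slot.minute, slot.second) == (expected_hour, expected_minute, 0)


class TestSkewness:
    def test_symmetric_hours_give_zero(self):
        assert engagement_skewness([9, 12, 15]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_gives_zero(self):
        assert engagement_skewness([9, 9, 9]) == 0.0

    def test_short_input_gives_zero(self):
        assert engagement_skewness([9, 10]) == 0.0
        assert engagement_skewness([]) == 0.0

    def test_matches_direct_moment_oracle(self):
        hours = [9, 9, 10, 12, 16]
        x = np.asarray(hours, float)
        m2 = ((x - x.mean()) ** 2).mean()
        m3 = ((x - x.mean()) ** 3).mean()
        assert engagement_skewness(hours) == pytest.approx(m3 / m2**1.5, rel=1e-12)
        # and the biased Fisher-Pearson skewness from scipy agrees
        assert engagement_skewness(hours) == pytest.approx(
            stats.skew(x, bias=True), rel=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(
        hours=st.lists(st.floats(0, 24), min_size=3, max_size=30),
        shift=st.floats(-12, 12),
    )
    def test_location_invariant_and_sign_flips_under_reversal(self, hours, shift):
        assume(np.var(hours) > 1e-4)
        g = engagement_skewness(hours)
        assert engagement_skewness([h + shift for h in hours]) == pytest.approx(
            g, abs=1e-8
        )
        assert engagement_skewness([-h for h in hours]) == pytest.approx(-g, abs=1e-8)


class TestNudgeProbability:
    def test_uniform_over_16_slots(self):
        slots = [D.replace(hour=9 + i // 2, minute=30 * (i % 2)).time() for i in range(16)]
        assert nudge_probability(slots, slots[3]) == pytest.approx(6.25)

    def test_point_mass(self):
        s = D.replace(hour=10).time()
        assert nudge_probability([s] * 7, s) == 100.0

    def test_fraction(self):
        a, b = D.replace(hour=10).time(), D.replace(hour=14).time()
        assert nudge_probability([a] * 3 + [b] * 9, a) == pytest.approx(25.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            nudge_probability([], D.time())

    def test_sums_to_100_over_slots(self):
        rng = np.random.default_rng(0)
        slots = [
            D.replace(hour=int(h), minute=int(m)).time()
            for h, m in zip(rng.integers(9, 17, 40), rng.choice([0, 30], 40))
        ]
        total = sum(nudge_probability(slots, s) for s in set(slots))
        assert total == pytest.approx(100.0)


class TestLabels:
    def completed_flow(self, pre, post, rating):
        t = D.replace(hour=10)
        f = step_flow(FlowState(), "nudge", t)
        f = step_flow(f, "choose_category", t, "calm")
        f = step_flow(f, "report_pre_stress", t, pre)
        f = step_flow(f, "begin", t)
        f = step_flow(f, "done", t + timedelta(minutes=4))
        if rating is not None:
            f = step_flow(f, "rate", t + timedelta(minutes=5), rating)
            f = step_flow(f, "report_post_stress", t + timedelta(minutes=6), post)
        return f

    def test_improvement_and_liking(self):
        labels = label_outcomes(self.completed_flow(3, 2, 4))
        assert labels == {
            "engaged": True, "liked": True, "improved": True, "stress_reduction": 1,
        }

    def test_no_change_is_not_improved(self):
        labels = label_outcomes(self.completed_flow(2, 2, 3))
        assert labels["improved"] is False
        assert labels["stress_reduction"] == 0
        assert labels["liked"] is False

    def test_missing_downstream_fields_are_absent_not_false(self):
        labels = label_outcomes(self.completed_flow(3, None, None))
        assert labels["engaged"] is True
        assert labels["liked"] is None
        assert labels["improved"] is None

    def test_expired_flow_not_engaged(self):
        f = step_flow(FlowState(), "nudge", D.replace(hour=10))
        f = step_flow(f, "timeout", D.replace(hour=10, minute=30))
        assert label_outcomes(f)["engaged"] is False


def _enroll(pid="p000"):
    from jitai.profiles import generate_participants

    profile = generate_participants(1, seed=4)[0]
    return Event(D.replace(hour=9), pid, "participant_enrolled", profile.to_dict())


def _window(pid, hour, minute=0, attention=0, meetings=0):
    slot = D.replace(hour=hour, minute=minute)
    return Event(
        slot, pid, "context_window",
        {
            "slot_start": slot.strftime("%Y-%m-%dT%H:%M:%S"),
            "meeting_counts": meetings, "no_meeting_minutes": 0.0,
            "self_event_counts": 0, "email_messages_sent": 1,
            "email_messages_read": 2, "chat_messages_count": 0,
            "ad_hoc_call_count": 0, "number_of_attention_signals": attention,
        },
    )


def _nudge(pid, nid, hour, minute=5, source="JIT"):
    t = D.replace(hour=hour, minute=minute)
    return Event(
        t, pid, "nudge_sent",
        {
            "nudge_id": nid, "source": source, "score": 0.6,
            "score_threshold": 0.5, "ema_threshold": 3.0, "latest_ema": 2,
            "slot_start": assign_half_hour(t).strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )


class TestBuilder:
    def toy_events(self):
        """Three nudges: one fully completed, one chosen-then-abandoned,
        one ignored."""
        pid = "p000"
        ev = [
            _enroll(pid),
            _window(pid, 10, 0, attention=2800, meetings=1),
            _window(pid, 13, 0),
            _window(pid, 15, 30),
            _nudge(pid, "n1", 10),
            Event(D.replace(hour=10, minute=10), pid, "category_chosen",
                  {"nudge_id": "n1", "category": "calm"}),
            Event(D.replace(hour=10, minute=10), pid, "intervention_assigned",
                  {"nudge_id": "n1", "intervention_id": "calm_01",
                   "category": "calm", "modality": "prompt", "location": "at_desk"}),
            Event(D.replace(hour=10, minute=11), pid, "pre_stress_reported",
                  {"nudge_id": "n1", "value": 3}),
            Event(D.replace(hour=10, minute=15), pid, "intervention_done",
                  {"nudge_id": "n1"}),
            Event(D.replace(hour=10, minute=16), pid, "intervention_rated",
                  {"nudge_id": "n1", "value": 4}),
            Event(D.replace(hour=10, minute=17), pid, "post_stress_reported",
                  {"nudge_id": "n1", "value": 2}),
            _nudge(pid, "n2", 13),
            Event(D.replace(hour=13, minute=10), pid, "category_chosen",
                  {"nudge_id": "n2", "category": "address"}),
            Event(D.replace(hour=13, minute=10), pid, "intervention_assigned",
                  {"nudge_id": "n2", "intervention_id": "address_02",
                   "category": "address", "modality": "video", "location": "inside"}),
            Event(D.replace(hour=13, minute=12), pid, "flow_abandoned",
                  {"nudge_id": "n2"}),
            _nudge(pid, "n3", 15, 35),
            Event(D.replace(hour=16, minute=5), pid, "nudge_expired",
                  {"nudge_id": "n3"}),
        ]
        return ev

    def test_toy_log_exact_join(self):
        per, chosen, completed = build_model_tables(self.toy_events())
        assert [len(per), len(chosen), len(completed)] == [3, 2, 1]
        r1 = per.set_index("nudge_id").loc["n1"]
        assert r1["engaged"] and r1["liked"] and r1["improved"]
        assert r1["stress_reduction"] == 1
        assert r1["meeting_counts"] == 1
        # raw attention 2800 enters the model scaled by 1/2000
        assert r1["attention_signals"] == pytest.approx(1.4)
        r2 = per.set_index("nudge_id").loc["n2"]
        assert not r2["engaged"] and r2["category"] == "address"
        r3 = per.set_index("nudge_id").loc["n3"]
        assert not r3["engaged"] and r3["category"] is None
        # nudge probability: three nudges in three distinct slots
        assert r1["nudge_probability"] == pytest.approx(100 / 3)

    def test_orphan_flow_event_raises_integrity_error(self):
        ev = self.toy_events()
        ev.append(
            Event(D.replace(hour=16), "p000", "intervention_done",
                  {"nudge_id": "ghost"})
        )
        with pytest.raises(IntegrityError, match="ghost"):
            build_model_tables(ev)

    def test_missing_context_window_raises(self):
        ev = [self.toy_events()[0], _nudge("p000", "n9", 11)]
        with pytest.raises(IntegrityError, match="n9"):
            build_model_tables(ev)

    def test_subset_chain_and_idempotence(self, small_events, small_tables):
        per, chosen, completed = small_tables
        assert len(completed) <= len(chosen) <= len(per)
        assert set(chosen["nudge_id"]) <= set(per["nudge_id"])
        assert set(completed["nudge_id"]) <= set(chosen["nudge_id"])
        per2, chosen2, completed2 = build_model_tables(small_events)
        assert per.to_csv() == per2.to_csv()
        assert completed.to_csv() == completed2.to_csv()

    def test_completed_labels_consistent(self, small_tables):
        _, _, completed = small_tables
        assert (completed["improved"] == (completed["stress_after"] < completed["stress_before"])).all()
        assert completed["stress_reduction"].between(-4, 4).all()
        assert (completed["liked"] == (completed["rating"] >= 4)).all()
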