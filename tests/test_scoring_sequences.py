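"""Dyad attribute scoring, dominance ordering, audience classification,
sequence grouping and pant-hoot recipient assignment."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gestnet import (
    Individual,
    assign_panthoot_recipient,
    audience_counts,
    dominance_order,
    group_sequences,
    score_dyad_attributes,
)

from conftest import make_event, make_scan


def ind(id, sex="male", birth_year=1990, status="not_applicable", indeg=0.0, outdeg=0.0):
    return Individual(
        id=id, sex=sex, birth_year=birth_year, reproductive_status=status,
        pantgrunt_indegree=indeg, pantgrunt_outdegree=outdeg,
    )


class TestDyadAttributes:
    @pytest.mark.parametrize(
        "year_a,year_b,expected",
        [(1991, 1993, True), (1987, 1993, False), (1980, 1985, True), (1980, 1986, False)],
    )
    def test_age_class_window_is_five_years(self, year_a, year_b, expected):
        a, b = ind("A", birth_year=year_a), ind("B", birth_year=year_b)
        assert score_dyad_attributes(a, b, set()).same_age_class is expected

    def test_male_with_cycling_female_is_not_reproductively_active(self):
        a = ind("A", sex="male")
        b = ind("B", sex="female", status="cycling")
        assert score_dyad_attributes(a, b, set()).reproductively_active is False

    def test_male_with_oestrous_female_is_reproductively_active(self):
        a = ind("A", sex="male")
        b = ind("B", sex="female", status="oestrous")
        assert score_dyad_attributes(a, b, set()).reproductively_active is True

    def test_missing_birth_year_gives_missing_age_flag(self):
        a, b = ind("A", birth_year=None), ind("B")
        assert score_dyad_attributes(a, b, set()).same_age_class is None

    @given(
        ya=st.integers(1960, 2000),
        yb=st.integers(1960, 2000),
        sexes=st.tuples(st.sampled_from(["male", "female"]), st.sampled_from(["male", "female"])),
        kin=st.booleans(),
    )
    @settings(max_examples=50, deadline=None)
    def test_all_flags_symmetric(self, ya, yb, sexes, kin):
        """Unordered attributes are invariant to the dyad's ordering."""
        a = ind("A", sex=sexes[0], birth_year=ya,
                status="oestrous" if sexes[0] == "female" else "not_applicable")
        b = ind("B", sex=sexes[1], birth_year=yb,
                status="cycling" if sexes[1] == "female" else "not_applicable")
        kin_pairs = {frozenset(("A", "B"))} if kin else set()
        assert score_dyad_attributes(a, b, kin_pairs) == score_dyad_attributes(
            b, a, kin_pairs
        )


def test_dominance_order_by_pantgrunt_indegree_then_outdegree_then_id():
    inds = [
        ind("NK", indeg=2.224, outdeg=0.0),
        ind("BB", indeg=0.937, outdeg=0.134),
        ind("KT", indeg=0.0, outdeg=0.237),
        ind("KU", sex="female", indeg=0.0, outdeg=0.231),
    ]
    assert dominance_order(inds) == ["NK", "BB", "KT", "KU"]


class TestAudienceCounts:
    def make_pop(self):
        return {
            "A": ind("A", sex="male", birth_year=1990),
            "B": ind("B", sex="female", birth_year=1990),
            "C": ind("C", sex="male", birth_year=1991),
            "D": ind("D", sex="female", birth_year=1980),
            "E": ind("E", sex="male", birth_year=1989),
        }

    def test_signaller_and_recipient_excluded(self):
        event = make_event(audience_10m_ids=frozenset({"B"}))  # recipient only
        counts = audience_counts(event, self.make_pop())
        assert counts == {"same_age": 0, "diff_age": 0, "same_sex": 0, "opp_sex": 0}

    def test_classification_relative_to_signaller(self):
        event = make_event(audience_10m_ids=frozenset({"C", "D"}))
        counts = audience_counts(event, self.make_pop())
        assert counts["same_sex"] == 1 and counts["opp_sex"] == 1
        assert counts["same_age"] == 1 and counts["diff_age"] == 1

    def test_same_age_adults_counted_together(self):
        event = make_event(audience_10m_ids=frozenset({"C", "E", "B"}))
        counts = audience_counts(event, self.make_pop())
        # B is the recipient; C and E are within the 5-year window of A
        assert counts["same_age"] == 2 and counts["diff_age"] == 0

    def test_member_missing_attributes_dropped_from_affected_count(self):
        pop = self.make_pop()
        pop["X"] = ind("X", sex="male", birth_year=None)
        event = make_event(audience_10m_ids=frozenset({"X"}))
        counts = audience_counts(event, pop)
        assert counts["same_age"] == 0 and counts["diff_age"] == 0
        assert counts["same_sex"] == 1  # sex is known


class TestGroupSequences:
    def test_close_events_same_dyad_share_sequence(self):
        events = [
            make_event(event_id="e1", time_s=0.0),
            make_event(event_id="e2", time_s=10.0),
        ]
        grouped = group_sequences(events)
        assert grouped[0].sequence_id == grouped[1].sequence_id

    def test_gap_over_30s_splits(self):
        events = [
            make_event(event_id="e1", time_s=0.0),
            make_event(event_id="e2", time_s=40.0),
        ]
        grouped = group_sequences(events)
        assert grouped[0].sequence_id != grouped[1].sequence_id

    def test_different_recipients_split(self):
        events = [
            make_event(event_id="e1", time_s=0.0, recipient_id="B"),
            make_event(event_id="e2", time_s=10.0, recipient_id="C"),
        ]
        grouped = group_sequences(events)
        assert grouped[0].sequence_id != grouped[1].sequence_id

    def test_different_context_splits_when_present(self):
        events = [
            make_event(event_id="e1", time_s=0.0, context="feed"),
            make_event(event_id="e2", time_s=10.0, context="travel"),
        ]
        assert len({e.sequence_id for e in group_sequences(events)}) == 2
        assert len({e.sequence_id for e in group_sequences(events, use_context=False)}) == 1

    def test_empty_input(self):
        assert group_sequences([]) == []

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=20, deadline=None)
    def test_idempotent_and_order_invariant(self, rnd):
        events = [
            make_event(event_id=f"e{k}", time_s=float(t), recipient_id=r)
            for k, (t, r) in enumerate(
                [(0, "B"), (12, "B"), (50, "B"), (55, "C"), (70, "C"), (200, "B")]
            )
        ]
        shuffled = list(events)
        rnd.shuffle(shuffled)
        once = group_sequences(shuffled)
        assert once == group_sequences(events)
        assert group_sequences(once) == once


class TestPanthootRecipient:
    dominance = ["B", "C", "A", "D"]

    def test_visual_only_panthoot_goes_to_most_dominant_party_member(self):
        seq = [make_event(signaller_id="A", recipient_id="D", panthoot=True)]
        scan = make_scan(
            focal_id="A",
            party_ids=frozenset({"A", "B", "C"}),
            within_10m_ids=frozenset({"B"}),
        )
        assert assign_panthoot_recipient(seq, scan, self.dominance) == "B"

    def test_auditory_panthoot_goes_to_nearest_neighbour(self):
        seq = [
            make_event(
                signaller_id="A", recipient_id="D",
                gesture_type="drum", modality="auditory_long", panthoot=True,
            )
        ]
        scan = make_scan(focal_id="A", nn_id="C",
                         party_ids=frozenset({"A", "B", "C"}),
                         within_10m_ids=frozenset({"C"}))
        assert assign_panthoot_recipient(seq, scan, self.dominance) == "C"

    def test_no_panthoot_keeps_recipient(self):
        seq = [make_event(signaller_id="A", recipient_id="D")]
        scan = make_scan(focal_id="A", party_ids=frozenset({"A", "B", "D"}),
                         within_10m_ids=frozenset())
        assert assign_panthoot_recipient(seq, scan, self.dominance) == "D"

    def test_missing_nearest_neighbour_flags_sequence_unusable(self):
        seq = [
            make_event(
                signaller_id="A", recipient_id="D",
                gesture_type="drum", modality="auditory_long", panthoot=True,
            )
        ]
        scan = make_scan(focal_id="A", nn_id=None, nn_distance_m=None,
                         attention_present=None,
                         party_ids=frozenset({"A", "D"}),
                         within_10m_ids=frozenset())
        assert assign_panthoot_recipient(seq, scan, self.dominance) is None
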