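"""Cohen's kappa, dyadic repertoire summaries, the intentionality filter
and sequence-level homogeneity classification."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gestnet import (
    Repertoire,
    ValidationError,
    build_repertoires,
    classify_sequence,
    cohens_kappa,
    dyad_repertoire_summary,
    intentionality_filter,
)

from conftest import make_event


def kappa_oracle(a, b):
    """Brute-force contingency-table kappa in exact rational arithmetic."""
    n = len(a)
    both = only_a = only_b = neither = 0
    for x, y in zip(a, b):
        if x and y:
            both += 1
        elif x:
            only_a += 1
        elif y:
            only_b += 1
        else:
            neither += 1
    p_o = Fraction(both + neither, n)
    p_e = (
        Fraction(both + only_a, n) * Fraction(both + only_b, n)
        + Fraction(neither + only_a, n) * Fraction(neither + only_b, n)
    )
    if p_e == 1:
        return None
    return float((p_o - p_e) / (1 - p_e))


class TestCohensKappa:
    def test_identical_nonconstant_vectors_give_one(self):
        vec = [True] * 5 + [False] * 5
        assert cohens_kappa(vec, vec) == pytest.approx(1.0)

    def test_complementary_half_present_vectors_give_minus_one(self):
        a = [True] * 5 + [False] * 5
        b = [not x for x in a]
        assert cohens_kappa(a, b) == pytest.approx(-1.0)

    def test_worked_contingency_example(self):
        # 4 shared, 1 unique each, 4 jointly absent over a 10-type catalog
        a = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        b = [1, 1, 1, 1, 0, 1, 0, 0, 0, 0]
        assert cohens_kappa(a, b) == pytest.approx(0.6)

    def test_undefined_when_chance_agreement_is_total(self):
        assert math.isnan(cohens_kappa([False] * 4, [False] * 4))
        assert math.isnan(cohens_kappa([True] * 4, [True] * 4))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cohens_kappa([True], [True, False])

    def test_exhaustive_oracle_equivalence_length_six(self):
        """All 4096 pairs of length-6 presence vectors match the exact
        rational-arithmetic oracle."""
        vectors = list(itertools.product([False, True], repeat=6))
        for a in vectors:
            for b in vectors:
                expected = kappa_oracle(a, b)
                got = cohens_kappa(a, b)
                if expected is None:
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn_on_random_vectors(self):
        """Independent cross-check against sklearn's kappa."""
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.uniform(size=12) < 0.5
            b = rng.uniform(size=12) < 0.5
            got = cohens_kappa(a, b)
            if math.isnan(got):
                continue
            assert got == pytest.approx(
                cohen_kappa_score(a.astype(int), b.astype(int)), abs=1e-12
            )

    @given(
        a=st.lists(st.booleans(), min_size=1, max_size=20),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_symmetric_and_reflexive(self, a, data):
        b = data.draw(st.lists(st.booleans(), min_size=len(a), max_size=len(a)))
        k_ab = cohens_kappa(a, b)
        k_ba = cohens_kappa(b, a)
        if math.isnan(k_ab):
            assert math.isnan(k_ba)
        else:
            assert -1.0 - 1e-12 <= k_ab <= 1.0 + 1e-12
            assert k_ab == pytest.approx(k_ba)
        if any(a) and not all(a):
            assert cohens_kappa(a, a) == pytest.approx(1.0)


CATALOG = {"visual": tuple(f"v{k}" for k in range(12)),
           "tactile": tuple(f"t{k}" for k in range(6)),
           "auditory_short": (), "auditory_long": ()}


def rep(ind_id, types):
    return Repertoire.build(ind_id, CATALOG, types)


class TestDyadSummary:
    def test_asymmetric_nonoverlap_gives_symmetric_heterogeneous_size(self):
        # first individual has 5 types the partner lacks, partner has 2
        shared = {"v0", "v1", "v2"}
        a = rep("BB", shared | {"v3", "v4", "v5", "v6", "v7"})
        b = rep("HW", shared | {"v8", "v9"})
        s_ab = dyad_repertoire_summary(a, b)
        s_ba = dyad_repertoire_summary(b, a)
        assert s_ab.heterog_size == s_ba.heterog_size == 7
        assert s_ab.homog_size == s_ba.homog_size == 3

    def test_disjoint_repertoires_share_nothing(self):
        s = dyad_repertoire_summary(rep("A", {"v0"}), rep("B", {"v1"}))
        assert s.homog_size == 0 and s.heterog_size == 2

    def test_equal_repertoires_have_no_heterogeneous_types(self):
        types = {"v0", "v1", "v2", "t0", "t1", "t2"}
        s = dyad_repertoire_summary(rep("A", types), rep("B", types))
        assert s.homog_size == 6 and s.heterog_size == 0
        assert s.kappa == pytest.approx(1.0)

    def test_per_modality_universe(self):
        a = rep("A", {"v0", "t0"})
        b = rep("B", {"v0", "t1"})
        vis = dyad_repertoire_summary(a, b, "visual")
        assert vis.homog_size == 1 and vis.heterog_size == 0
        tac = dyad_repertoire_summary(a, b, "tactile")
        assert tac.homog_size == 0 and tac.heterog_size == 2

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_size_identities(self, data):
        universe = [f"v{k}" for k in range(12)]
        sa = set(data.draw(st.lists(st.sampled_from(universe), unique=True)))
        sb = set(data.draw(st.lists(st.sampled_from(universe), unique=True)))
        s = dyad_repertoire_summary(rep("A", sa), rep("B", sb))
        assert s.homog_size == len(sa & sb)
        assert s.homog_size + s.heterog_size == len(sa | sb)
        assert s.homog_size <= min(len(sa), len(sb))


class TestIntentionalityFilter:
    def test_threshold_strictly_above_60_percent(self):
        counts = {"g_above": (61, 100), "g_at": (60, 100), "g_low": (10, 100)}
        assert intentionality_filter(counts) == {"g_above"}

    def test_at_threshold_retained_when_not_strict(self):
        counts = {"g_at": (60, 100)}
        assert intentionality_filter(counts, strict=False) == {"g_at"}

    def test_zero_observations_excluded(self):
        assert intentionality_filter({"g_none": (0, 0)}) == set()


class TestBuildRepertoires:
    ADULTS = {"A", "B", "C"}

    def test_no_events_gives_empty_repertoire(self):
        reps = build_repertoires([], self.ADULTS)
        assert reps["A"].size == 0

    def test_single_event_gives_singleton_repertoire(self):
        reps = build_repertoires([make_event()], self.ADULTS)
        assert reps["A"].present == {"arm beckon"}

    def test_events_toward_non_adults_excluded(self):
        juvenile_event = make_event(recipient_id="juv1")
        reps = build_repertoires([juvenile_event], self.ADULTS)
        assert reps["A"].size == 0

    def test_retained_types_restrict_catalog(self):
        events = [
            make_event(event_id="e1", gesture_type="arm beckon"),
            make_event(event_id="e2", gesture_type="wave"),
        ]
        reps = build_repertoires(events, self.ADULTS, retained_types={"wave"})
        assert reps["A"].present == {"wave"}


class TestClassifySequence:
    def test_three_of_five_shared_types(self):
        signaller = rep("A", {"v0", "v1", "v2", "v3", "v4"})
        recipient = rep("B", {"v0", "v1", "v2"})
        seq = [
            make_event(event_id=f"e{k}", sequence_id="s1", gesture_type=f"v{k}",
                       time_s=float(k))
            for k in range(5)
        ]
        cls = classify_sequence(seq, {"A": signaller, "B": recipient})
        assert cls.homog_repertoire_size == 3
        assert cls.heterog_repertoire_size == 2

    def test_all_shared_types(self):
        both = rep("A", {"v0", "v1"}), rep("B", {"v0", "v1"})
        seq = [make_event(sequence_id="s1", gesture_type="v0")]
        cls = classify_sequence(seq, {"A": both[0], "B": both[1]})
        assert cls.heterog_repertoire_size == 0

    def test_single_unshared_type(self):
        reps = {"A": rep("A", {"v5"}), "B": rep("B", {"v0"})}
        seq = [make_event(sequence_id="s1", gesture_type="v5")]
        cls = classify_sequence(seq, reps)
        assert (cls.homog_repertoire_size, cls.heterog_repertoire_size) == (0, 1)

    def test_counts_distinct_types_not_events(self):
        reps = {"A": rep("A", {"v0", "v5"}), "B": rep("B", {"v0"})}
        seq = [
            make_event(event_id=f"e{k}", sequence_id="s1", gesture_type="v0",
                       time_s=float(k))
            for k in range(3)
        ]
        cls = classify_sequence(seq, reps)
        assert cls.homog_repertoire_size == 1

    def test_recipient_without_repertoire_flagged(self):
        reps = {"A": rep("A", {"v0"})}
        seq = [make_event(sequence_id="s1", gesture_type="v0")]
        assert classify_sequence(seq, reps) is None
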