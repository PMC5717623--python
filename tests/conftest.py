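import numpy as np
import pytest

from gestnet import (
    GestureEvent,
    Individual,
    ScanRecord,
    SyntheticConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic study: 8 adults, 24 follows, fixed seed."""
    config = SyntheticConfig(
        seed=11, n_individuals=8, n_follows=24, gesture_rate_per_follow=6.0
    )
    individuals, kin_pairs, repertoires, scans, events = generate_dataset(config)
    return {
        "config": config,
        "individuals": individuals,
        "kin_pairs": kin_pairs,
        "repertoires": repertoires,
        "scans": scans,
        "events": events,
    }


@pytest.fixture
def two_individuals():
    a = Individual(id="BB", sex="male", birth_year=1987, pantgrunt_indegree=0.937)
    b = Individual(
        id="HW", sex="male", birth_year=1993, pantgrunt_indegree=0.295,
        pantgrunt_outdegree=0.58,
    )
    return a, b


def make_scan(**kwargs):
    defaults = dict(
        follow_id="F0",
        focal_id="A",
        scan_index=1,
        within_10m_ids=frozenset({"B"}),
        party_ids=frozenset({"A", "B", "C"}),
        nn_id="B",
        nn_distance_m=1.0,
        attention_present=True,
        focal_activity="feed",
        nn_activity="feed",
    )
    defaults.update(kwargs)
    return ScanRecord(**defaults)


def make_event(**kwargs):
    defaults = dict(
        event_id="e1",
        follow_id="F0",
        time_s=10.0,
        signaller_id="A",
        recipient_id="B",
        gesture_type="arm beckon",
        modality="visual",
    )
    defaults.update(kwargs)
    return GestureEvent(**defaults)
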