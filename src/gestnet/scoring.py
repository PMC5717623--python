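"""Dyad attribute scoring, dominance ordering and audience classification.

Dyads are scored on four demographic axes used as controls throughout the
analysis: sex similarity, age-class similarity (birth years within five
years of each other), reproductive activity (male with oestrous female)
and maternal kinship. Dominance is ordered by pant-grunt in-degree
(pant-grunts are given up the hierarchy), with out-degree and id as
tie-breaks.
"""

from __future__ import annotations

import logging
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set

from .types import DyadAttributes, GestureEvent, Individual, ValidationError

logger = logging.getLogger(__name__)


def score_dyad_attributes(
    a: Individual,
    b: Individual,
    kin_pairs: Set[FrozenSet[str]],
    age_class_window: float = 5.0,
) -> DyadAttributes:
    """Score demographic similarity flags for the dyad (a, b).

    ``same_age_class`` is True iff the birth years differ by at most
    ``age_class_window`` years; it is None (missing, logged) when either
    birth year is unknown. ``reproductively_active`` is True only for a
    male paired with an oestrous female — all other combinations, including
    male with a cycling (non-oestrous) female, are inactive.
    """
    if a.id == b.id:
        raise ValidationError("cannot score a self-dyad")
    same_sex = a.sex == b.sex
    if a.birth_year is None or b.birth_year is None:
        logger.warning(
            "dyad (%s, %s): missing birth year, age-class flag undefined",
            a.id,
            b.id,
        )
        same_age: Optional[bool] = None
    else:
        same_age = abs(a.birth_year - b.birth_year) <= age_class_window
    active = (
        a.sex == "male" and b.sex == "female" and b.reproductive_status == "oestrous"
    ) or (
        b.sex == "male" and a.sex == "female" and a.reproductive_status == "oestrous"
    )
    return DyadAttributes(
        same_sex=same_sex,
        same_age_class=same_age,
        reproductively_active=active,
        maternal_kin=frozenset((a.id, b.id)) in kin_pairs,
    )


def dominance_order(individuals: Iterable[Individual]) -> List[str]:
    """Ids from most to least dominant.

    Ranked by pant-grunt in-degree (descending), breaking ties by
    pant-grunt out-degree (descending) then lexicographic id, so the
    ordering is total and deterministic.
    """
    return [
        ind.id
        for ind in sorted(
            individuals,
            key=lambda x: (-x.pantgrunt_indegree, -x.pantgrunt_outdegree, x.id),
        )
    ]


def audience_counts(
    event: GestureEvent,
    individuals: Mapping[str, Individual],
    age_class_window: float = 5.0,
) -> Dict[str, int]:
    """Count audience members by similarity to the signaller.

    The audience is everyone within 10 m, excluding the signaller and the
    recipient of the gesture. Each member is classified relative to the
    signaller as same/different age class and same/opposite sex; members
    with the relevant attribute missing are dropped from that count only.
    """
    signaller = individuals.get(event.signaller_id)
    if signaller is None:
        raise ValidationError(f"unknown signaller {event.signaller_id}")
    counts = {"same_age": 0, "diff_age": 0, "same_sex": 0, "opp_sex": 0}
    members = event.audience_10m_ids - {event.signaller_id, event.recipient_id}
    for member_id in members:
        member = individuals.get(member_id)
        if member is None:
            logger.warning(
                "event %s: audience member %s has no attribute record; "
                "excluded from all counts",
                event.event_id,
                member_id,
            )
            continue
        if signaller.birth_year is None or member.birth_year is None:
            logger.warning(
                "event %s: audience member %s lacks birth year; excluded "
                "from age counts",
                event.event_id,
                member_id,
            )
        elif abs(signaller.birth_year - member.birth_year) <= age_class_window:
            counts["same_age"] += 1
        else:
            counts["diff_age"] += 1
        if member.sex == signaller.sex:
            counts["same_sex"] += 1
        else:
            counts["opp_sex"] += 1
    return counts
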