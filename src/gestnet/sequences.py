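"""Gesture-sequence assembly and pant-hoot recipient assignment.

A gesture sequence is one or more gestures made consecutively by the same
signaller towards the same recipient, within the same context, with at most
30 s between consecutive gestures. Sequences accompanied by pant-hoots (a
broadcast vocalization) get their recipient reassigned for observation-level
analyses: a visual-only pant-hoot sequence is treated as directed at the
most dominant party member, while a sequence containing auditory gestures
is treated as directed at the focal's nearest neighbour.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Dict, List, Optional, Sequence

from .types import AUDITORY_MODALITIES, GestureEvent, ScanRecord, ValidationError

logger = logging.getLogger(__name__)

#: maximum gap between consecutive gestures of one sequence, seconds
MAX_SEQUENCE_GAP_S = 30.0


def group_sequences(
    events: Sequence[GestureEvent],
    max_gap_s: float = MAX_SEQUENCE_GAP_S,
    use_context: bool = True,
) -> List[GestureEvent]:
    """Assign deterministic sequence ids to gesture events.

    Events are sorted by (signaller, follow, time, event id); consecutive
    events join the same sequence iff they share signaller, recipient and
    context (when ``use_context``) and the inter-event gap is at most
    ``max_gap_s`` seconds. Ids are stable: re-grouping already grouped
    events, or a stably re-sorted copy, yields the same assignment.
    """
    ordered = sorted(
        events, key=lambda e: (e.signaller_id, e.follow_id, e.time_s, e.event_id)
    )
    out: List[GestureEvent] = []
    seq_counter = 0
    prev: Optional[GestureEvent] = None
    current_id = None
    for event in ordered:
        new_sequence = (
            prev is None
            or event.signaller_id != prev.signaller_id
            or event.follow_id != prev.follow_id
            or event.recipient_id != prev.recipient_id
            or (use_context and event.context != prev.context)
            or event.time_s - prev.time_s > max_gap_s
        )
        if new_sequence:
            seq_counter += 1
            current_id = f"seq{seq_counter:05d}"
        out.append(replace(event, sequence_id=current_id))
        prev = event
    return out


def sequences_by_id(events: Sequence[GestureEvent]) -> Dict[str, List[GestureEvent]]:
    """Group already-assigned events into sequences, preserving time order."""
    groups: Dict[str, List[GestureEvent]] = {}
    for event in sorted(events, key=lambda e: (e.time_s, e.event_id)):
        if event.sequence_id is None:
            raise ValidationError(f"event {event.event_id} has no sequence_id")
        groups.setdefault(event.sequence_id, []).append(event)
    return groups


def assign_panthoot_recipient(
    sequence: Sequence[GestureEvent],
    scan: ScanRecord,
    dominance: Sequence[str],
) -> Optional[str]:
    """Recipient of a pant-hoot-accompanied sequence for observation-level use.

    Rules: a sequence of solely visual gestures with a pant-hoot is counted
    as directed at the most dominant individual in the party (excluding the
    signaller); a sequence containing any auditory gesture with a pant-hoot
    is assumed directed at the focal's nearest neighbour. A sequence without
    pant-hoots keeps its recorded recipient. Returns None (logged) when the
    nearest neighbour is required but absent — the sequence is unusable.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    if not any(e.panthoot for e in sequence):
        return sequence[0].recipient_id
    modalities = {e.modality for e in sequence}
    signaller = sequence[0].signaller_id
    if any(m in AUDITORY_MODALITIES for m in modalities):
        if scan.nn_id is None:
            logger.warning(
                "sequence %s: pant-hoot with auditory gestures but no nearest "
                "neighbour recorded; flagged unusable",
                sequence[0].sequence_id,
            )
            return None
        return scan.nn_id
    if modalities == {"visual"}:
        rank = {ind_id: k for k, ind_id in enumerate(dominance)}
        candidates = [i for i in scan.party_ids if i != signaller and i in rank]
        if not candidates:
            logger.warning(
                "sequence %s: no ranked party member other than the signaller; "
                "flagged unusable",
                sequence[0].sequence_id,
            )
            return None
        return min(candidates, key=lambda i: rank[i])
    # tactile + pant-hoot has no reassignment rule; keep recorded recipient
    return sequence[0].recipient_id
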