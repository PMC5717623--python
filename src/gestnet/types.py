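"""Domain types for focal-follow gesture and association data.

The study system is a fission--fusion chimpanzee community observed with
focal-animal sampling: 18-minute follows of one focal adult, instantaneous
scans of party composition and proximity every 2 minutes, and continuous
recording of intentional gestures (signaller, recipient, gesture type,
sensory modality, recipient response).

All tabular files use the numeric code 999 as the missing-value sentinel;
parsed records represent missing as ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)
from typing import FrozenSet, Optional

#: numeric missing-value sentinel used in every tabular file
MISSING_CODE = 999

MODALITIES = ("visual", "tactile", "auditory_short", "auditory_long")
AUDITORY_MODALITIES = ("auditory_short", "auditory_long")

SEXES = ("male", "female")
REPRODUCTIVE_STATUSES = ("cycling", "pregnant", "nursing", "oestrous", "not_applicable")

ACTIVITIES = (
    "feed",
    "rest",
    "travel",
    "groom_give",
    "groom_receive",
    "groom_mutual",
    "other",
)

RESPONSE_TYPES = ("goal_directed", "emotional", "none")


class ValidationError(ValueError):
    """A record or file violates a structural invariant."""


@dataclass(frozen=True)
class Individual:
    """One adult subject with demographic and dominance attributes.

    ``pantgrunt_indegree``/``pantgrunt_outdegree`` are rates of the submissive
    pant-grunt vocalization received/given, used to order individuals by
    dominance (pant-grunts are directed up the hierarchy).
    """

    id: str
    sex: str
    birth_year: Optional[float] = None
    reproductive_status: str = "not_applicable"
    pantgrunt_indegree: float = 0.0
    pantgrunt_outdegree: float = 0.0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("Individual id must be non-empty")
        if self.sex not in SEXES:
            raise ValidationError(f"Individual {self.id}: unknown sex {self.sex!r}")
        if self.reproductive_status not in REPRODUCTIVE_STATUSES:
            raise ValidationError(
                f"Individual {self.id}: unknown reproductive_status "
                f"{self.reproductive_status!r}"
            )
        if self.pantgrunt_indegree < 0 or self.pantgrunt_outdegree < 0:
            raise ValidationError(
                f"Individual {self.id}: pantgrunt degrees must be >= 0"
            )


@dataclass(frozen=True)
class ScanRecord:
    """One instantaneous 2-minute scan within a focal follow.

    ``party_ids`` is everyone within the ~35 m party spread (focal included);
    ``within_10m_ids`` is the subset within 10 m of the focal; the nearest
    neighbour is the closest adult, with distance in metres and a flag for
    mutual bodily orientation (visual attention).
    """

    follow_id: str
    focal_id: str
    scan_index: int
    within_10m_ids: FrozenSet[str] = frozenset()
    party_ids: FrozenSet[str] = frozenset()
    nn_id: Optional[str] = None
    nn_distance_m: Optional[float] = None
    attention_present: Optional[bool] = None
    focal_activity: Optional[str] = None
    nn_activity: Optional[str] = None

    def __post_init__(self) -> None:
        if self.scan_index < 1:
            raise ValidationError(
                f"follow {self.follow_id}: scan_index must be >= 1, "
                f"got {self.scan_index}"
            )
        if self.focal_id not in self.party_ids:
            raise ValidationError(
                f"follow {self.follow_id} scan {self.scan_index}: focal "
                f"{self.focal_id} missing from party_ids"
            )
        if not self.within_10m_ids <= self.party_ids:
            raise ValidationError(
                f"follow {self.follow_id} scan {self.scan_index}: "
                "within_10m_ids must be a subset of party_ids"
            )
        if self.nn_id is not None and self.nn_id == self.focal_id:
            raise ValidationError(
                f"follow {self.follow_id} scan {self.scan_index}: nearest "
                "neighbour cannot be the focal individual"
            )
        if self.nn_distance_m is not None and self.nn_distance_m < 0:
            raise ValidationError(
                f"follow {self.follow_id} scan {self.scan_index}: negative "
                "nn_distance_m"
            )
        for name in ("focal_activity", "nn_activity"):
            val = getattr(self, name)
            if val is not None and val not in ACTIVITIES:
                raise ValidationError(
                    f"follow {self.follow_id} scan {self.scan_index}: "
                    f"unknown {name} {val!r}"
                )


@dataclass(frozen=True)
class GestureEvent:
    """One intentional gesture directed by a signaller at a recipient."""

    event_id: str
    follow_id: str
    time_s: float
    signaller_id: str
    recipient_id: str
    gesture_type: str
    modality: str
    sequence_id: Optional[str] = None
    context: Optional[str] = None
    panthoot: bool = False
    response_present: bool = False
    response_type: str = "none"
    vocal_response: bool = False
    audience_10m_ids: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if self.signaller_id == self.recipient_id:
            raise ValidationError(
                f"event {self.event_id}: signaller and recipient are the same "
                f"individual ({self.signaller_id})"
            )
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"event {self.event_id}: unknown modality {self.modality!r}"
            )
        if self.response_type not in RESPONSE_TYPES:
            raise ValidationError(
                f"event {self.event_id}: unknown response_type "
                f"{self.response_type!r}"
            )
        if (self.response_type == "none") == self.response_present:
            raise ValidationError(
                f"event {self.event_id}: response_type {self.response_type!r} "
                f"inconsistent with response_present={self.response_present}"
            )
        if self.time_s < 0:
            raise ValidationError(f"event {self.event_id}: negative time_s")


@dataclass(frozen=True)
class DyadAttributes:
    """Demographic similarity flags for an (unordered) pair of adults.

    ``same_age_class`` is True when birth years differ by at most five years
    (None when either birth year is unknown); ``reproductively_active`` is
    True only for a male paired with an oestrous female.
    """

    same_sex: bool
    same_age_class: Optional[bool]
    reproductively_active: bool
    maternal_kin: bool
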