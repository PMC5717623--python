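"""Gestural repertoires, the intentionality filter, Cohen's kappa overlap
and homogeneous/heterogeneous repertoire sizes.

An individual's repertoire is the set of gesture types it was observed to
produce towards other adults, partitioned by sensory modality. Dyadic
overlap is quantified three ways:

* Cohen's kappa — chance-corrected agreement between the two
  presence/absence vectors over the catalog: ``kappa = (p_o - p_e)/(1 - p_e)``
  from the 2x2 contingency table (both present / only A / only B / both
  absent). kappa = 1 for identical non-constant repertoires, -1 for exact
  complements; it is undefined (missing) when the expected agreement p_e
  equals 1.
* homogeneous repertoire size — the number of shared types ``|A ∩ B|``.
* heterogeneous repertoire size — the symmetric count of unshared types
  ``|A \\ B| + |B \\ A|``, identical for both orderings of the dyad.

At the sequence level each distinct gesture type used is homogeneous iff
it is present in both the signaller's and the recipient's repertoire.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .types import MODALITIES, GestureEvent, ValidationError

logger = logging.getLogger(__name__)

#: intentionality threshold: retain gesture types whose criterion fraction
#: exceeds this value (strictly, by default)
INTENTIONALITY_THRESHOLD = 0.60

Catalog = Dict[str, Tuple[str, ...]]  # modality -> gesture types


def catalog_from_events(events: Iterable[GestureEvent]) -> Catalog:
    """Infer the gesture-type catalog (per modality) from observed events."""
    by_modality: Dict[str, Set[str]] = {m: set() for m in MODALITIES}
    for e in events:
        by_modality[e.modality].add(e.gesture_type)
    return {m: tuple(sorted(types)) for m, types in by_modality.items()}


@dataclass(frozen=True)
class Repertoire:
    """Presence/absence of catalog gesture types for one individual."""

    individual_id: str
    catalog: Tuple[Tuple[str, Tuple[str, ...]], ...]  # ordered (modality, types)
    present: FrozenSet[str]

    @staticmethod
    def build(
        individual_id: str, catalog: Catalog, present: Iterable[str]
    ) -> "Repertoire":
        cat = tuple((m, tuple(catalog.get(m, ()))) for m in MODALITIES)
        all_types = [t for _, types in cat for t in types]
        if len(all_types) != len(set(all_types)):
            raise ValidationError("catalog modality partition is not disjoint")
        present = frozenset(present)
        unknown = present - set(all_types)
        if unknown:
            raise ValidationError(
                f"repertoire of {individual_id} has types outside the catalog: "
                f"{sorted(unknown)}"
            )
        return Repertoire(individual_id, cat, present)

    def types(self, modality: Optional[str] = None) -> Tuple[str, ...]:
        """The catalog universe, overall or for one modality."""
        if modality is None:
            return tuple(t for _, types in self.catalog for t in types)
        for m, types in self.catalog:
            if m == modality:
                return types
        raise ValidationError(f"unknown modality {modality!r}")

    def vector(self, modality: Optional[str] = None) -> np.ndarray:
        """Presence/absence over the (per-modality or full) catalog."""
        return np.array([t in self.present for t in self.types(modality)], dtype=bool)

    def present_types(self, modality: Optional[str] = None) -> FrozenSet[str]:
        return frozenset(t for t in self.types(modality) if t in self.present)

    @property
    def size(self) -> int:
        return len(self.present)


def build_repertoires(
    events: Sequence[GestureEvent],
    adults: Set[str],
    catalog: Optional[Catalog] = None,
    retained_types: Optional[Set[str]] = None,
) -> Dict[str, Repertoire]:
    """Build per-individual repertoires from gestures directed at adults.

    A type is present for individual *i* iff *i* produced it as signaller
    towards an adult recipient at least once. ``retained_types`` (e.g. the
    output of :func:`intentionality_filter`) restricts the catalog. Every
    adult gets a repertoire, possibly empty.
    """
    if catalog is None:
        catalog = catalog_from_events(events)
    if retained_types is not None:
        catalog = {
            m: tuple(t for t in types if t in retained_types)
            for m, types in catalog.items()
        }
    produced: Dict[str, Set[str]] = {i: set() for i in adults}
    all_catalog_types = {t for types in catalog.values() for t in types}
    for e in events:
        if e.recipient_id not in adults or e.signaller_id not in adults:
            continue
        if e.gesture_type not in all_catalog_types:
            continue
        produced[e.signaller_id].add(e.gesture_type)
    return {
        i: Repertoire.build(i, catalog, types) for i, types in produced.items()
    }


def intentionality_filter(
    criterion_counts: Mapping[str, Tuple[int, int]],
    threshold: float = INTENTIONALITY_THRESHOLD,
    strict: bool = True,
) -> Set[str]:
    """Retain gesture types whose intentionality-criterion fraction passes.

    ``criterion_counts`` maps each gesture type to ``(n_meeting, n_total)``
    pooled across subjects: occurrences satisfying the intentionality
    criteria (audience present, response waiting, sensitivity to attention,
    persistence) out of all occurrences. Types *above* the threshold are
    classified intentional and retained (strictly above by default; set
    ``strict=False`` for at-or-above). Types with zero observations are
    excluded and logged.
    """
    retained: Set[str] = set()
    for gesture_type, (n_meeting, n_total) in criterion_counts.items():
        if n_total <= 0:
            logger.warning(
                "gesture type %r has no observations; excluded from the "
                "intentional catalog",
                gesture_type,
            )
            continue
        fraction = n_meeting / n_total
        if fraction > threshold or (not strict and fraction == threshold):
            retained.add(gesture_type)
    return retained


def cohens_kappa(a: Sequence[bool], b: Sequence[bool]) -> float:
    """Chance-corrected agreement between two presence/absence vectors.

    Returns NaN (missing) when the chance agreement p_e equals 1, i.e. when
    either vector is constant in a way that forces agreement by chance alone
    (e.g. both repertoires empty over the universe).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(
            f"presence vectors must be 1-D and equal length, got {a.shape} "
            f"and {b.shape}"
        )
    n = a.size
    if n == 0:
        raise ValidationError("presence vectors must have length >= 1")
    both = int(np.sum(a & b))
    only_a = int(np.sum(a & ~b))
    only_b = int(np.sum(~a & b))
    neither = int(np.sum(~a & ~b))
    p_o = (both + neither) / n
    p_e = ((both + only_a) * (both + only_b) + (neither + only_a) * (neither + only_b)) / (
        n * n
    )
    if math.isclose(p_e, 1.0):
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class DyadRepertoireSummary:
    """Symmetric dyadic overlap summary for one catalog universe."""

    id_a: str
    id_b: str
    modality: Optional[str]
    kappa: float  # NaN when undefined
    homog_size: int
    heterog_size: int


def dyad_repertoire_summary(
    rep_a: Repertoire,
    rep_b: Repertoire,
    modality: Optional[str] = None,
) -> DyadRepertoireSummary:
    """Kappa and shared/unshared type counts for a dyad.

    The kappa universe is the per-modality catalog when ``modality`` is
    given, and the full catalog for the all-gestures summary, so each
    modality's kappa is unaffected by the other modalities' catalog sizes.
    """
    if rep_a.catalog != rep_b.catalog:
        raise ValidationError(
            f"repertoires of {rep_a.individual_id} and {rep_b.individual_id} "
            "use different catalogs"
        )
    set_a = rep_a.present_types(modality)
    set_b = rep_b.present_types(modality)
    kappa = cohens_kappa(rep_a.vector(modality), rep_b.vector(modality))
    if math.isnan(kappa):
        logger.warning(
            "kappa undefined for dyad (%s, %s), modality=%s; recorded missing",
            rep_a.individual_id,
            rep_b.individual_id,
            modality,
        )
    return DyadRepertoireSummary(
        id_a=rep_a.individual_id,
        id_b=rep_b.individual_id,
        modality=modality,
        kappa=kappa,
        homog_size=len(set_a & set_b),
        heterog_size=len(set_a - set_b) + len(set_b - set_a),
    )


@dataclass(frozen=True)
class SequenceHomogeneity:
    """Per-sequence homogeneous/heterogeneous gesture-type classification."""

    sequence_id: str
    signaller_id: str
    recipient_id: str
    labels: Tuple[Tuple[str, str], ...]  # (gesture_type, homogeneous|heterogeneous)
    homog_repertoire_size: int
    heterog_repertoire_size: int


def classify_sequence(
    sequence: Sequence[GestureEvent],
    repertoires: Mapping[str, Repertoire],
) -> Optional[SequenceHomogeneity]:
    """Label each distinct gesture type in a sequence.

    A type is homogeneous iff present in both the signaller's and the
    recipient's repertoire, heterogeneous otherwise (used by the signaller
    but absent from the recipient's repertoire). Returns None (logged) when
    the recipient has no observed repertoire, since homogeneity is then
    undefined.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    first = sequence[0]
    if any(
        e.signaller_id != first.signaller_id or e.recipient_id != first.recipient_id
        for e in sequence
    ):
        raise ValidationError(
            f"sequence {first.sequence_id}: events mix signallers or recipients"
        )
    recipient_rep = repertoires.get(first.recipient_id)
    if recipient_rep is None:
        logger.warning(
            "sequence %s: recipient %s has no observed repertoire; "
            "classification skipped",
            first.sequence_id,
            first.recipient_id,
        )
        return None
    recipient_types = recipient_rep.present
    distinct = sorted({e.gesture_type for e in sequence})
    labels = tuple(
        (t, "homogeneous" if t in recipient_types else "heterogeneous")
        for t in distinct
    )
    homog = sum(1 for _, lab in labels if lab == "homogeneous")
    return SequenceHomogeneity(
        sequence_id=first.sequence_id or "",
        signaller_id=first.signaller_id,
        recipient_id=first.recipient_id,
        labels=labels,
        homog_repertoire_size=homog,
        heterog_repertoire_size=len(labels) - homog,
    )
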