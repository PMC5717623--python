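"""Synthetic focal-follow data with the statistical structure the analysis
assumes.

The generator emulates a habituated fission--fusion community observed with
focal-animal sampling: a fixed population of adults (default six males and
six females), per-modality gesture catalogs, 18-minute follows of nine
scans at 2-minute intervals, and gesture sequences sampled from the focal's
repertoire.

Planted structure, so every downstream stage is testable:

* repertoires share a group-wide core (fraction ``overlap_core`` of the
  per-modality repertoire size) plus individual-specific types, making the
  expected pairwise Cohen's kappa increase monotonically with
  ``overlap_core``;
* the per-scan probability that a partner is the focal's nearest neighbour
  within 2 m increases linearly with the dyad's (standardized) kappa,
  scaled by ``bonding_effect`` — set it to zero for an exact null;
* a recipient's response type depends on whether the gesture is
  homogeneous (present in the recipient's repertoire): homogeneous
  gestures elicit emotional displays with probability
  ``emotional_response_prob_homog``, heterogeneous ones goal-directed
  responses with probability ``goal_response_prob_heterog``.

Randomness uses one root seed; the population and each follow draw from
sub-streams derived deterministically from it, so outputs are
byte-identical across runs with the same config.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .repertoire import Catalog, Repertoire, cohens_kappa
from .types import (
    MODALITIES,
    GestureEvent,
    Individual,
    ScanRecord,
    ValidationError,
)

DEFAULT_CATALOG_SIZES = {
    "visual": 30,
    "tactile": 12,
    "auditory_short": 8,
    "auditory_long": 10,
}

_MODALITY_PREFIX = {
    "visual": "vis",
    "tactile": "tac",
    "auditory_short": "aus",
    "auditory_long": "aul",
}

_ACTIVITY_PROBS = {
    "feed": 0.34,
    "rest": 0.28,
    "travel": 0.15,
    "groom_give": 0.07,
    "groom_receive": 0.07,
    "groom_mutual": 0.05,
    "other": 0.04,
}

_RECIPROCAL_ACTIVITY = {
    "feed": "feed",
    "rest": "rest",
    "travel": "travel",
    "groom_give": "groom_receive",
    "groom_receive": "groom_give",
    "groom_mutual": "groom_mutual",
    "other": "other",
}

#: sequence lengths (number of gestures) and their probabilities
_SEQ_LEN_PROBS = ((1, 0.65), (2, 0.25), (3, 0.10))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror the observational design: 12 adults (six per sex), nine
    2-minute scans per follow, four gesture modalities with catalog sizes
    30/12/8/10, and enough follows (120) for roughly 540 gesture sequences
    at the default sequence rate.
    """

    seed: int = 0
    n_individuals: int = 12
    catalog_sizes: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATALOG_SIZES)
    )
    repertoire_fraction: float = 0.55
    overlap_core: float = 0.4
    dyad_overlap_sd: float = 2.0
    n_follows: int = 120
    scans_per_follow: int = 9
    scan_interval_min: float = 2.0
    bonding_effect: float = 0.10
    emotional_response_prob_homog: float = 0.60
    goal_response_prob_heterog: float = 0.75
    gesture_rate_per_follow: float = 4.5
    # background association structure
    party_prob: float = 0.55
    within_10m_prob: float = 0.75
    close_base_prob: float = 0.25

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValidationError("need at least 2 individuals")
        if not 0 <= self.overlap_core <= 1:
            raise ValidationError("overlap_core must be in [0, 1]")
        if not 0 < self.repertoire_fraction <= 1:
            raise ValidationError("repertoire_fraction must be in (0, 1]")
        for p in (
            self.emotional_response_prob_homog,
            self.goal_response_prob_heterog,
            self.party_prob,
            self.within_10m_prob,
            self.close_base_prob,
        ):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must be in [0, 1]")
        if self.dyad_overlap_sd < 0:
            raise ValidationError("dyad_overlap_sd must be >= 0")
        if self.scans_per_follow < 2:
            raise ValidationError("scans_per_follow must be >= 2")
        if self.n_follows < 1 or self.gesture_rate_per_follow < 0:
            raise ValidationError("invalid follow configuration")
        for m, s in self.catalog_sizes.items():
            if m not in MODALITIES:
                raise ValidationError(f"unknown modality {m!r} in catalog_sizes")
            if s < 1:
                raise ValidationError(f"catalog size for {m} must be >= 1")


def _rng(config: SyntheticConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed % (2**31), *stream])
    )


def _make_ids(n: int) -> List[str]:
    codes = ("".join(p) for p in itertools.product(string.ascii_uppercase, repeat=2))
    return list(itertools.islice(codes, n))


def make_catalog(config: SyntheticConfig) -> Catalog:
    return {
        m: tuple(
            f"{_MODALITY_PREFIX[m]}_{k:02d}" for k in range(config.catalog_sizes[m])
        )
        for m in MODALITIES
        if m in config.catalog_sizes
    }


def generate_population(
    config: SyntheticConfig,
) -> Tuple[List[Individual], Set[FrozenSet[str]], Dict[str, Repertoire]]:
    """Individuals, maternal-kin pairs and planted per-modality repertoires.

    Each repertoire is the modality core (shared group-wide) plus
    individual-specific types; individual repertoire sizes are jittered with
    s.d. ``dyad_overlap_sd``. When the non-core pool is large enough the
    individual-specific types are partitioned disjointly across individuals,
    so ``overlap_core = 0`` yields disjoint repertoires.
    """
    rng = _rng(config, 0)
    ids = _make_ids(config.n_individuals)
    n_males = config.n_individuals // 2
    individuals: List[Individual] = []
    for k, ind_id in enumerate(ids):
        male = k < n_males
        birth_year = int(rng.integers(1962, 1994))
        if male:
            status = "not_applicable"
            indeg = float(np.round(rng.exponential(0.5), 3))
        else:
            status = rng.choice(
                ["cycling", "pregnant", "nursing", "oestrous"],
                p=[0.4, 0.15, 0.3, 0.15],
            )
            indeg = 0.0
        individuals.append(
            Individual(
                id=ind_id,
                sex="male" if male else "female",
                birth_year=birth_year,
                reproductive_status=str(status),
                pantgrunt_indegree=indeg,
                pantgrunt_outdegree=float(np.round(rng.uniform(0, 0.7), 3)),
            )
        )
    n_kin = config.n_individuals // 6
    kin_pool = list(ids)
    rng.shuffle(kin_pool)
    kin_pairs = {
        frozenset((kin_pool[2 * k], kin_pool[2 * k + 1])) for k in range(n_kin)
    }

    catalog = make_catalog(config)
    present: Dict[str, Set[str]] = {i: set() for i in ids}
    for modality, types in catalog.items():
        size = len(types)
        rep_size = max(1, round(config.repertoire_fraction * size))
        core_size = round(config.overlap_core * rep_size)
        if core_size > size:
            raise ValidationError(
                f"catalog for {modality} too small for requested core "
                f"({core_size} > {size})"
            )
        pool = list(types)
        rng.shuffle(pool)
        core = pool[:core_size]
        remainder = pool[core_size:]
        mean_extra = rep_size - core_size
        # the size jitter perturbs the individual-specific component; a full
        # core (overlap_core = 1) leaves nothing individual to jitter
        extras_n = [
            0
            if mean_extra == 0
            else int(np.clip(
                round(rng.normal(mean_extra, config.dyad_overlap_sd)),
                0,
                len(remainder),
            ))
            for _ in ids
        ]
        for i in ids:
            present[i].update(core)
        if sum(extras_n) <= len(remainder):
            # pool large enough: disjoint individual-specific types
            cursor = 0
            for ind_id, k in zip(ids, extras_n):
                present[ind_id].update(remainder[cursor : cursor + k])
                cursor += k
        else:
            for ind_id, k in zip(ids, extras_n):
                chosen = rng.choice(len(remainder), size=k, replace=False)
                present[ind_id].update(remainder[c] for c in chosen)
    repertoires = {
        i: Repertoire.build(i, catalog, types) for i, types in present.items()
    }
    return individuals, kin_pairs, repertoires


def kappa_matrix(repertoires: Dict[str, Repertoire]) -> Tuple[List[str], np.ndarray]:
    """Pairwise Cohen's kappa over the full catalog, NaN diagonal."""
    ids = sorted(repertoires)
    n = len(ids)
    mat = np.full((n, n), np.nan)
    for a in range(n):
        for b in range(a + 1, n):
            k = cohens_kappa(
                repertoires[ids[a]].vector(), repertoires[ids[b]].vector()
            )
            mat[a, b] = mat[b, a] = k
    return ids, mat


def _standardized(mat: np.ndarray) -> np.ndarray:
    off = ~np.eye(mat.shape[0], dtype=bool)
    vals = mat[off]
    vals = vals[~np.isnan(vals)]
    sd = vals.std()
    if sd == 0 or vals.size == 0:
        return np.zeros_like(mat)
    out = (mat - vals.mean()) / sd
    return np.where(np.isnan(out), 0.0, out)


def _pick(rng: np.random.Generator, items: Sequence, probs: Sequence[float]):
    return items[int(rng.choice(len(items), p=np.asarray(probs) / np.sum(probs)))]


def generate_follows(
    config: SyntheticConfig,
    individuals: Sequence[Individual],
    repertoires: Dict[str, Repertoire],
) -> Tuple[List[ScanRecord], List[GestureEvent]]:
    """Scans and gesture events for ``n_follows`` focal follows.

    Fission--fusion is modelled as per-follow party draws with dyad-specific
    inclusion probabilities; the focal rotates through the population. The
    kappa -> proximity coupling and the homogeneity -> response-type rule
    are applied per scan / per gesture as described in the module docstring.
    """
    ids = [ind.id for ind in individuals]
    idx = {v: k for k, v in enumerate(ids)}
    _, kappa = kappa_matrix(repertoires)
    kz = _standardized(kappa)
    rng_dyads = _rng(config, 1)
    n = len(ids)
    # symmetric dyad-specific party affinity around the base rate
    noise = rng_dyads.normal(0, 0.05, size=(n, n))
    noise = (noise + noise.T) / 2
    p_party = np.clip(config.party_prob + noise, 0.15, 0.95)
    p_close = np.clip(
        config.close_base_prob + config.bonding_effect * kz, 0.02, 0.95
    )
    activities = list(_ACTIVITY_PROBS)
    act_probs = list(_ACTIVITY_PROBS.values())
    seq_lens = [l for l, _ in _SEQ_LEN_PROBS]
    seq_probs = [p for _, p in _SEQ_LEN_PROBS]

    scans: List[ScanRecord] = []
    events: List[GestureEvent] = []
    interval_s = config.scan_interval_min * 60.0
    for f in range(config.n_follows):
        rng = _rng(config, 2, f)
        focal = ids[f % n]
        fi = idx[focal]
        follow_id = f"F{f:04d}"
        party = frozenset(
            [focal]
            + [j for j in ids if j != focal and rng.uniform() < p_party[fi, idx[j]]]
        )
        others = sorted(party - {focal})
        follow_scans: List[ScanRecord] = []
        for s in range(1, config.scans_per_follow + 1):
            within10 = frozenset(
                j for j in others if rng.uniform() < config.within_10m_prob
            )
            nn_id: Optional[str] = None
            nn_dist: Optional[float] = None
            attention: Optional[bool] = None
            nn_activity: Optional[str] = None
            focal_activity = _pick(rng, activities, act_probs)
            if within10:
                cand = sorted(within10)
                weights = np.exp(
                    0.5 * config.bonding_effect * kz[fi, [idx[j] for j in cand]]
                )
                nn_id = _pick(rng, cand, weights)
                close = rng.uniform() < p_close[fi, idx[nn_id]]
                nn_dist = float(
                    np.round(rng.uniform(0.3, 2.0) if close else rng.uniform(2.1, 10.0), 1)
                )
                attention = bool(rng.uniform() < (0.65 if close else 0.30))
                if close and rng.uniform() < 0.7:
                    nn_activity = _RECIPROCAL_ACTIVITY[focal_activity]
                else:
                    nn_activity = _pick(rng, activities, act_probs)
            follow_scans.append(
                ScanRecord(
                    follow_id=follow_id,
                    focal_id=focal,
                    scan_index=s,
                    within_10m_ids=within10,
                    party_ids=party,
                    nn_id=nn_id,
                    nn_distance_m=nn_dist,
                    attention_present=attention,
                    focal_activity=focal_activity,
                    nn_activity=nn_activity,
                )
            )
        scans.extend(follow_scans)

        if not others or config.gesture_rate_per_follow == 0:
            continue
        focal_rep = repertoires[focal]
        rep_types = sorted(focal_rep.present)
        if not rep_types:
            continue
        modality_of = {
            t: m for m, types in focal_rep.catalog for t in types
        }
        n_seq = rng.poisson(config.gesture_rate_per_follow)
        ev_counter = 0
        for _ in range(n_seq):
            scan = follow_scans[int(rng.integers(0, len(follow_scans)))]
            if scan.nn_id is not None:
                recipient = scan.nn_id
            else:
                recipient = others[int(rng.integers(0, len(others)))]
            recipient_rep = repertoires.get(recipient)
            seq_len = _pick(rng, seq_lens, seq_probs)
            t0 = (scan.scan_index - 1) * interval_s + rng.uniform(0, interval_s)
            context = scan.focal_activity
            for g in range(seq_len):
                gesture_type = rep_types[int(rng.integers(0, len(rep_types)))]
                modality = modality_of[gesture_type]
                homogeneous = (
                    recipient_rep is not None
                    and gesture_type in recipient_rep.present
                )
                responded = rng.uniform() < (0.60 if homogeneous else 0.45)
                if responded:
                    if homogeneous:
                        emotional = (
                            rng.uniform() < config.emotional_response_prob_homog
                        )
                    else:
                        emotional = not (
                            rng.uniform() < config.goal_response_prob_heterog
                        )
                    response_type = "emotional" if emotional else "goal_directed"
                    vocal = bool(rng.uniform() < (0.30 if emotional else 0.05))
                else:
                    response_type = "none"
                    vocal = False
                panthoot = bool(
                    rng.uniform() < (0.40 if modality == "auditory_long" else 0.03)
                )
                events.append(
                    GestureEvent(
                        event_id=f"{follow_id}e{ev_counter:03d}",
                        follow_id=follow_id,
                        time_s=float(np.round(t0 + 5.0 * g, 1)),
                        signaller_id=focal,
                        recipient_id=recipient,
                        gesture_type=gesture_type,
                        modality=modality,
                        context=context,
                        panthoot=panthoot,
                        response_present=responded,
                        response_type=response_type,
                        vocal_response=vocal,
                        audience_10m_ids=scan.within_10m_ids,
                    )
                )
                ev_counter += 1
    events.sort(key=lambda e: (e.follow_id, e.time_s, e.event_id))
    return scans, events


def generate_dataset(config: SyntheticConfig):
    """Convenience wrapper: population plus follows in one call."""
    individuals, kin_pairs, repertoires = generate_population(config)
    scans, events = generate_follows(config, individuals, repertoires)
    return individuals, kin_pairs, repertoires, scans, events
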