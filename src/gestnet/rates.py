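"""Dyadic bonding rates from focal-follow scans, plus the scan-independence
quality check.

Each instantaneous scan represents one 2-minute interval, so a dyad's
rate of a bonding behaviour in minutes per hour spent in the same party is

    rate = 60 * n_behaviour_scans / n_co_party_scans

which is bounded by [0, 60] and missing when the pair was never co-present
in a party. Rates are directed: the i->j rate is computed from follows in
which i was the focal subject.

Behaviour conditions (per scan, partner j):

* ``proximity`` — j is the focal's nearest neighbour within 2 m.
* ``joint_feed`` / ``joint_rest`` / ``joint_travel`` — the proximity
  condition plus both focal and neighbour in the matching activity.
* ``attention_present`` / ``attention_absent`` — the proximity condition
  plus mutual bodily orientation present / absent.
* ``groom_given`` / ``groom_received`` / ``groom_mutual`` — j is the
  nearest neighbour and the focal activity is the matching grooming code
  (grooming implies contact, so no distance condition applies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .network import DyadMatrix, build_matrix
from .types import ScanRecord, ValidationError

logger = logging.getLogger(__name__)

#: distance (metres) defining "close proximity" to the nearest neighbour
PROXIMITY_THRESHOLD_M = 2.0

BEHAVIOURS = (
    "joint_feed",
    "joint_rest",
    "joint_travel",
    "groom_given",
    "groom_received",
    "groom_mutual",
    "attention_present",
    "attention_absent",
    "proximity",
)

_JOINT_ACTIVITY = {
    "joint_feed": "feed",
    "joint_rest": "rest",
    "joint_travel": "travel",
}
_GROOM_ACTIVITY = {
    "groom_given": "groom_give",
    "groom_received": "groom_receive",
    "groom_mutual": "groom_mutual",
}


@dataclass(frozen=True)
class BondingRate:
    dyad: Tuple[str, str]
    behaviour: str
    minutes_per_hour: float  # NaN when the dyad was never co-present
    n_behaviour: int
    n_party: int


def _is_close(scan: ScanRecord, j: str) -> bool:
    return (
        scan.nn_id == j
        and scan.nn_distance_m is not None
        and scan.nn_distance_m <= PROXIMITY_THRESHOLD_M
    )


def _behaviour_condition(scan: ScanRecord, j: str, behaviour: str) -> bool:
    if behaviour == "proximity":
        return _is_close(scan, j)
    if behaviour in _JOINT_ACTIVITY:
        act = _JOINT_ACTIVITY[behaviour]
        return (
            _is_close(scan, j)
            and scan.focal_activity == act
            and scan.nn_activity == act
        )
    if behaviour == "attention_present":
        return _is_close(scan, j) and scan.attention_present is True
    if behaviour == "attention_absent":
        return _is_close(scan, j) and scan.attention_present is False
    if behaviour in _GROOM_ACTIVITY:
        return scan.nn_id == j and scan.focal_activity == _GROOM_ACTIVITY[behaviour]
    raise ValidationError(f"unknown behaviour label {behaviour!r}")


def co_party_scans(scans: Sequence[ScanRecord], i: str, j: str) -> int:
    """Number of scans with i focal and j in i's party."""
    return sum(1 for s in scans if s.focal_id == i and j in s.party_ids)


def bonding_rate(
    scans: Sequence[ScanRecord], i: str, j: str, behaviour: str
) -> BondingRate:
    """Directed i->j bonding rate in minutes per hour co-present in a party."""
    if behaviour not in BEHAVIOURS:
        raise ValidationError(f"unknown behaviour label {behaviour!r}")
    focal_scans = [s for s in scans if s.focal_id == i and j in s.party_ids]
    n_party = len(focal_scans)
    n_beh = sum(1 for s in focal_scans if _behaviour_condition(s, j, behaviour))
    if n_party == 0:
        rate = float("nan")
    else:
        rate = 60.0 * n_beh / n_party
    return BondingRate((i, j), behaviour, rate, n_beh, n_party)


def rates_table(
    scans: Sequence[ScanRecord],
    ids: Sequence[str],
    behaviours: Sequence[str] = BEHAVIOURS,
) -> pd.DataFrame:
    """Long-format table of directed rates for every ordered dyad.

    One pass over the scans; output has columns dyad ids, behaviour,
    minutes_per_hour, n_behaviour, n_party. Invariant to follow ordering.
    """
    ids = list(ids)
    idx = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    n_party = np.zeros((n, n), dtype=int)
    n_beh = {b: np.zeros((n, n), dtype=int) for b in behaviours}
    for scan in scans:
        if scan.focal_id not in idx:
            continue
        fi = idx[scan.focal_id]
        for j in scan.party_ids:
            if j == scan.focal_id or j not in idx:
                continue
            ji = idx[j]
            n_party[fi, ji] += 1
            for b in behaviours:
                if _behaviour_condition(scan, j, b):
                    n_beh[b][fi, ji] += 1
    rows = []
    for b in behaviours:
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                np_ij = n_party[i, j]
                rate = 60.0 * n_beh[b][i, j] / np_ij if np_ij else float("nan")
                rows.append(
                    {
                        "id_a": ids[i],
                        "id_b": ids[j],
                        "behaviour": b,
                        "minutes_per_hour": rate,
                        "n_behaviour": int(n_beh[b][i, j]),
                        "n_party": int(np_ij),
                    }
                )
    return pd.DataFrame(rows)


def rate_matrix(
    scans: Sequence[ScanRecord], ids: Sequence[str], behaviour: str
) -> DyadMatrix:
    """Directed dyadic matrix of one behaviour's rates."""
    table = rates_table(scans, ids, [behaviour])
    values = {
        (r.id_a, r.id_b): r.minutes_per_hour
        for r in table.itertuples()
        if not np.isnan(r.minutes_per_hour)
    }
    return build_matrix(values, directed=True, node_ids=ids)


@dataclass(frozen=True)
class WilcoxonCheck:
    """Paired signed-rank comparison of per-dyad counts at two scan positions."""

    measure: str  # within_10m | party
    scan_a: int
    scan_b: int
    statistic: float  # min of the positive/negative rank sums; NaN if N == 0
    n_nonzero: int
    p_value: float  # NaN (not applicable) if N == 0


def _dyad_counts(
    scans: Sequence[ScanRecord], scan_index: int, measure: str
) -> Dict[Tuple[str, str], int]:
    counts: Dict[Tuple[str, str], int] = {}
    for s in scans:
        if s.scan_index != scan_index:
            continue
        members = s.within_10m_ids if measure == "within_10m" else s.party_ids
        for j in members:
            if j == s.focal_id:
                continue
            key = (s.focal_id, j)
            counts[key] = counts.get(key, 0) + 1
    return counts


def scan_independence_check(
    scans: Sequence[ScanRecord],
    positions: Sequence[Tuple[int, int]] = ((1, 2), (1, 9)),
) -> List[WilcoxonCheck]:
    """Wilcoxon signed-rank tests for similarity of association patterns
    between scan positions within the follow.

    For each focal/partner dyad, the number of follows in which the partner
    was within 10 m (or in the party) at the first position is paired with
    the count at the second position; zero differences are discarded (the
    classic convention) and the two-tailed p-value is exact for small N,
    normal-approximate otherwise. A degenerate comparison (all differences
    zero) is reported with N = 0 and missing statistic/p.
    """
    if not scans:
        raise ValidationError("no scans supplied")
    max_index = max(s.scan_index for s in scans)
    results: List[WilcoxonCheck] = []
    for measure in ("within_10m", "party"):
        for a, b in positions:
            if b > max_index or a > max_index:
                raise ValidationError(
                    f"scan position pair ({a}, {b}) exceeds max scan index "
                    f"{max_index}"
                )
            ca = _dyad_counts(scans, a, measure)
            cb = _dyad_counts(scans, b, measure)
            dyads = sorted(set(ca) | set(cb))
            diffs = np.array(
                [ca.get(d, 0) - cb.get(d, 0) for d in dyads], dtype=float
            )
            nonzero = diffs[diffs != 0]
            n_nonzero = int(nonzero.size)
            if n_nonzero == 0:
                results.append(
                    WilcoxonCheck(measure, a, b, float("nan"), 0, float("nan"))
                )
                continue
            ranks = stats.rankdata(np.abs(nonzero))
            t_plus = float(ranks[nonzero > 0].sum())
            t_minus = float(ranks[nonzero < 0].sum())
            if n_nonzero <= _EXACT_ENUMERATION_LIMIT:
                p = _exact_signed_rank_p(ranks, t_plus)
            else:
                res = stats.wilcoxon(
                    nonzero, zero_method="wilcox", alternative="two-sided"
                )
                p = float(res.pvalue)
            results.append(
                WilcoxonCheck(measure, a, b, min(t_plus, t_minus), n_nonzero, p)
            )
    return results


#: below this N the signed-rank null is enumerated exactly (mid-ranks kept,
#: so ties are handled without falling back to the normal approximation)
_EXACT_ENUMERATION_LIMIT = 14


def _exact_signed_rank_p(ranks: np.ndarray, t_plus: float) -> float:
    """Two-sided exact p over all 2^N sign assignments of the ranks."""
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    total = float(ranks.sum())
    lo, hi = min(t_plus, total - t_plus), max(t_plus, total - t_plus)
    count = np.sum(sums <= lo + 1e-9) + np.sum(sums >= hi - 1e-9)
    return float(min(1.0, count / sums.size))
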