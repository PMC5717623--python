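"""Dyadic matrices and normalized degree centrality.

A social network over N focal subjects is an N x N labelled matrix of
dyadic values (bonding rate, repertoire overlap, ...) with an undefined
diagonal. Undirected networks (e.g. Cohen's kappa overlap) are symmetric;
directed networks (e.g. proximity given by the focal) are not.

Normalized degree centrality is the mean tie value of a node's row
(outdegree) or column (indegree); for undirected networks the single value
is called the n-degree. Missing ties are excluded from the mean by default.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import ValidationError

logger = logging.getLogger(__name__)


def ordered_dyads(ids: Sequence[str]) -> List[Tuple[str, str]]:
    """All ordered pairs of distinct ids (N ids -> N*(N-1) dyads)."""
    return [(i, j) for i, j in itertools.product(ids, repeat=2) if i != j]


def unordered_dyads(ids: Sequence[str]) -> List[Tuple[str, str]]:
    """All unordered pairs of distinct ids (N ids -> N*(N-1)/2 dyads)."""
    return list(itertools.combinations(ids, 2))


@dataclass
class DyadMatrix:
    """Square labelled dyadic matrix; NaN marks missing ties, diagonal unused."""

    node_ids: Tuple[str, ...]
    values: np.ndarray
    directed: bool = True

    def __post_init__(self) -> None:
        self.node_ids = tuple(self.node_ids)
        self.values = np.asarray(self.values, dtype=float).copy()
        n = len(self.node_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} node ids"
            )
        if len(set(self.node_ids)) != n:
            raise ValidationError("duplicate node ids")
        np.fill_diagonal(self.values, np.nan)
        if not self.directed:
            a, b = self.values, self.values.T
            mism = ~np.isclose(a, b, equal_nan=True)
            if mism.any():
                i, j = np.argwhere(mism)[0]
                raise ValidationError(
                    "undirected matrix is asymmetric at "
                    f"({self.node_ids[i]}, {self.node_ids[j]})"
                )

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def index(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    def __getitem__(self, dyad: Tuple[str, str]) -> float:
        i, j = dyad
        return float(self.values[self.index(i), self.index(j)])

    def offdiag_mask(self) -> np.ndarray:
        return ~np.eye(self.n, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_ids, columns=self.node_ids)


def build_matrix(
    values: Mapping[Tuple[str, str], float],
    directed: bool = True,
    node_ids: Sequence[str] | None = None,
) -> DyadMatrix:
    """Assemble a DyadMatrix from per-dyad values.

    Undirected input may be keyed by either ordering of a pair and is
    mirrored; supplying both orderings with different values for an
    undirected matrix is an error. Dyads absent from ``values`` stay missing.
    """
    if node_ids is None:
        seen: Dict[str, None] = {}
        for i, j in values:
            seen.setdefault(i)
            seen.setdefault(j)
        node_ids = sorted(seen)
    node_ids = list(node_ids)
    idx = {v: k for k, v in enumerate(node_ids)}
    n = len(node_ids)
    mat = np.full((n, n), np.nan)
    for (i, j), v in values.items():
        if i == j:
            raise ValidationError(f"self-dyad ({i}, {i}) not allowed")
        if i not in idx or j not in idx:
            raise ValidationError(f"dyad ({i}, {j}) names an unknown id")
        a, b = idx[i], idx[j]
        if not directed:
            prev = mat[b, a]
            if not np.isnan(prev) and not np.isclose(prev, v):
                raise ValidationError(
                    f"asymmetric values for undirected dyad ({i}, {j}): "
                    f"{v} vs {prev}"
                )
            mat[b, a] = v
        mat[a, b] = v
    return DyadMatrix(tuple(node_ids), mat, directed=directed)


def normalized_degree(
    matrix: DyadMatrix,
    mode: str = "n_degree",
    zero_fill: bool = False,
) -> pd.Series:
    """Mean tie value per node: row mean (outdegree), column mean (indegree).

    For undirected matrices all three modes coincide (``n_degree``). Missing
    ties are excluded from the mean unless ``zero_fill`` is set, in which
    case they count as zeros (mimicking tools that store networks densely).
    Nodes with every tie missing get a missing centrality.
    """
    if mode not in ("n_degree", "indegree", "outdegree"):
        raise ValidationError(f"unknown centrality mode {mode!r}")
    if mode == "n_degree" and matrix.directed:
        raise ValidationError("n_degree is defined for undirected matrices only")
    vals = matrix.values.copy()
    if zero_fill:
        off = matrix.offdiag_mask()
        vals[off & np.isnan(vals)] = 0.0
    axis = 0 if mode == "indegree" else 1
    counts = np.sum(~np.isnan(vals), axis=axis)
    sums = np.nansum(vals, axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    n_missing = int(np.isnan(means).sum())
    if n_missing:
        logger.warning(
            "%d node(s) have all ties missing; centrality undefined", n_missing
        )
    return pd.Series(means, index=list(matrix.node_ids), name=mode)
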