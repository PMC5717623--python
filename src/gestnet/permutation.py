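"""Permutation inference for dyadic and node-level network data.

Standard regression p-values are invalid for network data because dyadic
observations sharing a node are not independent. The quadratic assignment
procedure (QAP) respects this dependence by permuting node labels — rows
and columns of a matrix jointly — so the permuted data keep the network's
row/column structure.

Two procedures are provided:

* ``mrqap_dsp`` — multiple regression QAP with double semi-partialling.
  Point estimates are ordinary least squares on the vectorized off-diagonal
  dyads of z-scored variables (so coefficients are standardized betas). For
  each predictor X_k, X_k is residualized on the remaining predictors; the
  residual *matrix* is QAP-permuted, the model refitted, and the two-tailed
  p-value is the add-one-corrected fraction of permutations whose |beta*|
  reaches the observed |beta|. Permuting residuals rather than raw
  predictors makes the test robust to network autocorrelation and skew.
* ``node_level_regression`` — OLS on node attributes with p-values from
  permuting the outcome vector across nodes.

Both report r-squared, per-predictor standardized coefficients and
permutation p-values, and are bit-reproducible given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import DyadMatrix
from .types import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MRQAP_PERMUTATIONS = 2000
DEFAULT_NODE_PERMUTATIONS = 10000

_COLLINEARITY_R = 0.9999


@dataclass(frozen=True)
class PermRegressionResult:
    """Standardized OLS fit with permutation p-values."""

    coefficients: Dict[str, float]
    p_values: Dict[str, float]
    r_squared: float
    n_permutations: int
    seed: Optional[int]
    n_obs: int  # dyads (MRQAP) or nodes (node-level) used after deletion

    def to_dict(self) -> Dict[str, object]:
        return {
            "coefficients": dict(self.coefficients),
            "p_values": dict(self.p_values),
            "r_squared": self.r_squared,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "n_obs": self.n_obs,
        }


def qap_permute(matrix: DyadMatrix, permutation: Sequence[str]) -> DyadMatrix:
    """Apply a node permutation to rows and columns jointly.

    ``permutation`` lists, for each position, the node id whose row/column
    moves there; it must be a bijection on the matrix's node set. The
    multiset of off-diagonal values is preserved.
    """
    if sorted(permutation) != sorted(matrix.node_ids):
        raise ValidationError("permutation is not a bijection on the node set")
    order = [matrix.index(v) for v in permutation]
    permuted = matrix.values[np.ix_(order, order)]
    return DyadMatrix(matrix.node_ids, permuted, directed=matrix.directed)


def _offdiag_vector(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return values[mask]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValidationError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


def _ols(y: np.ndarray, X: np.ndarray) -> Tuple[np.ndarray, float]:
    """Least-squares fit with intercept; returns slopes and r-squared."""
    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return coef[1:], r2


def _check_collinearity(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[1] < 2:
        return
    corr = np.corrcoef(X, rowvar=False)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            if abs(corr[a, b]) > _COLLINEARITY_R:
                raise ValidationError(
                    f"predictors {names[a]!r} and {names[b]!r} are collinear "
                    f"(|r| = {abs(corr[a, b]):.6f})"
                )


def mrqap_dsp(
    y: DyadMatrix,
    xs: Mapping[str, DyadMatrix],
    n_perm: int = DEFAULT_MRQAP_PERMUTATIONS,
    seed: Optional[int] = None,
) -> PermRegressionResult:
    """MRQAP regression with Dekker double semi-partialling.

    All matrices must share the node set; dyads with a missing value in the
    outcome or any predictor are dropped listwise (and excluded again after
    each permutation maps residuals onto missing cells).
    """
    names = list(xs)
    if not names:
        raise ValidationError("at least one predictor matrix is required")
    node_ids = y.node_ids
    for name, x in xs.items():
        if x.node_ids != node_ids:
            raise ValidationError(
                f"predictor {name!r} node set differs from the outcome's"
            )
    n = y.n
    offmask = ~np.eye(n, dtype=bool)
    yv_full = _offdiag_vector(y.values)
    xv_full = np.column_stack([_offdiag_vector(xs[k].values) for k in names])
    valid = ~np.isnan(yv_full) & ~np.isnan(xv_full).any(axis=1)
    n_used = int(valid.sum())
    if n_used < len(names) + 2:
        raise ValidationError(
            f"only {n_used} complete dyads for {len(names)} predictors"
        )
    yv = _zscore(yv_full[valid])
    Xv = np.column_stack([_zscore(xv_full[valid, k]) for k in range(len(names))])
    _check_collinearity(Xv, names)
    beta_obs, r2 = _ols(yv, Xv)

    # z-scored dyadic variables embedded back into matrix form, NaN at
    # missing/diagonal cells, so residual matrices can be node-permuted
    def _embed(vec_valid: np.ndarray) -> np.ndarray:
        full = np.full(n * n - n, np.nan)
        full[valid] = vec_valid
        mat = np.full((n, n), np.nan)
        mat[offmask] = full
        return mat

    y_mat = _embed(yv)
    x_mats = [_embed(Xv[:, k]) for k in range(len(names))]

    rng = np.random.default_rng(seed)
    p_values: Dict[str, float] = {}
    for k, name in enumerate(names):
        others = [m for idx, m in enumerate(x_mats) if idx != k]
        if others:
            others_v = np.column_stack([m[offmask] for m in others])
            ok = valid
            design = np.column_stack([np.ones(ok.sum()), others_v[ok]])
            coef, *_ = np.linalg.lstsq(design, x_mats[k][offmask][ok], rcond=None)
            resid_v = x_mats[k][offmask][ok] - design @ coef
        else:
            resid_v = x_mats[k][offmask][valid]
            resid_v = resid_v - resid_v.mean()
        resid_mat = _embed(resid_v)
        count = 0
        for _ in range(n_perm):
            order = rng.permutation(n)
            perm_resid = resid_mat[np.ix_(order, order)]
            pr_v = perm_resid[offmask]
            ok = valid & ~np.isnan(pr_v)
            if ok.sum() < len(names) + 2:
                continue
            cols = [pr_v[ok]] + [x_mats[j][offmask][ok] for j in range(len(names)) if j != k]
            design = np.column_stack([np.ones(ok.sum())] + cols)
            coef, *_ = np.linalg.lstsq(design, y_mat[offmask][ok], rcond=None)
            if abs(coef[1]) >= abs(beta_obs[k]):
                count += 1
        p_values[name] = (count + 1) / (n_perm + 1)
    return PermRegressionResult(
        coefficients=dict(zip(names, map(float, beta_obs))),
        p_values=p_values,
        r_squared=float(r2),
        n_permutations=n_perm,
        seed=seed,
        n_obs=n_used,
    )


def node_level_regression(
    y: pd.Series,
    xs: pd.DataFrame,
    n_perm: int = DEFAULT_NODE_PERMUTATIONS,
    seed: Optional[int] = None,
) -> PermRegressionResult:
    """Node-level OLS with outcome-permutation p-values.

    ``y`` holds one value per node and ``xs`` one column per predictor over
    the same index. Complete cases only; variables are z-scored so the
    coefficients are standardized betas; the permutation null shuffles the
    outcome across nodes, breaking any attribute/outcome link while keeping
    both marginal distributions.
    """
    xs = xs.loc[y.index]
    names = list(xs.columns)
    data = pd.concat([y.rename("__y__"), xs], axis=1).dropna()
    n_used = len(data)
    if n_used < len(names) + 2:
        raise ValidationError(
            f"only {n_used} complete cases for {len(names)} predictors"
        )
    if data["__y__"].nunique() == 1:
        raise ValidationError("outcome is constant across nodes")
    yv = _zscore(data["__y__"].to_numpy(dtype=float))
    Xv = np.column_stack(
        [_zscore(data[c].to_numpy(dtype=float)) for c in names]
    )
    _check_collinearity(Xv, names)
    beta_obs, r2 = _ols(yv, Xv)
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(names), dtype=int)
    for _ in range(n_perm):
        y_perm = yv[rng.permutation(n_used)]
        beta_perm, _ = _ols(y_perm, Xv)
        counts += np.abs(beta_perm) >= np.abs(beta_obs)
    p_values = {
        name: (int(c) + 1) / (n_perm + 1) for name, c in zip(names, counts)
    }
    return PermRegressionResult(
        coefficients=dict(zip(names, map(float, beta_obs))),
        p_values=p_values,
        r_squared=float(r2),
        n_permutations=n_perm,
        seed=seed,
        n_obs=n_used,
    )
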