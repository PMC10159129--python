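"""Pearson co-expression and the PCIT edge-significance filter.

PCIT (partial correlation with information theory) decides, for every pair
of features, whether their Pearson correlation survives comparison with the
indirect paths through each third feature. For a trio (x, y, z) the three
first-order partial correlations are formed, e.g.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2)),

and the trio's tolerance is the mean absolute ratio of partial to raw
correlation over the trio's edges:

    eps = (1/3) (|r_xy.z / r_xy| + |r_xz.y / r_xz| + |r_yz.x / r_yz|).

The edge (x, y) is knocked out by the trio when |r_xy| < |eps * r_xz| and
|r_xy| < |eps * r_yz| — its direct association is dominated by both legs of
the indirect path. An edge is significant iff no trio knocks it out. All
trios are always swept (no early exit), so the result is independent of
node order.

Degenerate trios: a ratio whose raw correlation is exactly zero, or whose
partial-correlation denominator is <= 1e-12, is excluded from the tolerance
average; a trio with no valid ratio is skipped entirely (conservative:
keeps edges). The knockout comparison is strict, so a perfectly symmetric
trio (all partials scaled equally) keeps all of its edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = ["PcitEdgeSet", "expression_for_correlation", "pearson_matrix", "pcit_significant"]

logger = logging.getLogger(__name__)

#: partial-correlation denominators at or below this are treated as degenerate
DENOM_EPS = 1e-12


@dataclass
class PcitEdgeSet:
    """A correlation matrix together with its PCIT-significant adjacency."""

    r: pd.DataFrame
    significant: pd.DataFrame

    @property
    def node_ids(self) -> list[str]:
        return self.r.index.tolist()

    def __post_init__(self) -> None:
        if not self.r.index.equals(self.r.columns) or not self.significant.index.equals(
            self.significant.columns
        ):
            raise ValueError("r and significant must be square with matching labels")


def expression_for_correlation(counts: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), the expression scale used for correlation."""
    factors = factors.loc[counts.sample_ids].to_numpy(dtype=float)
    mat = counts.counts.to_numpy(dtype=float) / factors
    return pd.DataFrame(np.log2(mat + 1.0), index=counts.feature_ids, columns=counts.sample_ids)


def pearson_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation over features (rows); diagonal exactly 1.

    Requires at least 3 samples. Features with zero variance carry no
    correlation signal and are dropped with a logged warning.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples to correlate, got {expr.shape[1]}")
    variances = expr.to_numpy().var(axis=1)
    constant = variances == 0
    if constant.any():
        dropped = expr.index[constant].tolist()
        logger.warning("dropping %d constant feature(s) before correlation: %s", len(dropped), dropped)
        expr = expr.loc[~constant]
    r = np.corrcoef(expr.to_numpy())
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def _validate_correlation(r: np.ndarray) -> None:
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if np.nanmax(np.abs(r)) > 1 + 1e-10:
        raise ValueError("correlations must lie in [-1, 1]")
    if not np.allclose(np.diag(r), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")


def pcit_significant(r: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Boolean adjacency of PCIT-significant edges for a correlation matrix.

    The full O(n^3) trio sweep is performed with one vectorized pass per
    conditioning node; for fewer than 3 nodes no trio exists, so every
    off-diagonal edge is significant (logged as a warning).
    """
    labels = None
    if isinstance(r, pd.DataFrame):
        labels = r.index
        rmat = r.to_numpy(dtype=float)
    else:
        rmat = np.asarray(r, dtype=float)
    _validate_correlation(rmat)
    n = rmat.shape[0]
    if n < 3:
        logger.warning("PCIT on %d node(s): no trio exists, all edges kept", n)
        adj = ~np.eye(n, dtype=bool)
    else:
        adj = _pcit_sweep(rmat)
    if labels is not None:
        return pd.DataFrame(adj, index=labels, columns=labels)
    return adj


def _pcit_sweep(R: np.ndarray) -> np.ndarray:
    n = R.shape[0]
    absR = np.abs(R)
    one_minus_sq = 1.0 - R * R
    knocked = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)

    with np.errstate(divide="ignore", invalid="ignore"):
        for z in range(n):
            rz = R[:, z]  # r_xz for each x
            omz = one_minus_sq[:, z]  # 1 - r_xz^2

            # ratio for edge (x,y) conditioned on z: |r_xy.z / r_xy|
            denA = np.sqrt(np.outer(omz, omz))
            partA = (R - np.outer(rz, rz)) / denA
            ratioA = np.abs(partA / R)
            validA = (R != 0) & (denA > DENOM_EPS)

            # ratio for edge (x,z) conditioned on y: |r_xz.y / r_xz|
            denB = np.sqrt(one_minus_sq * omz[np.newaxis, :])  # sqrt((1-r_xy^2)(1-r_yz^2))
            partB = (rz[:, np.newaxis] - R * rz[np.newaxis, :]) / denB
            ratioB = np.abs(partB / rz[:, np.newaxis])
            validB = (rz[:, np.newaxis] != 0) & (denB > DENOM_EPS)

            # ratio for edge (y,z) conditioned on x is ratioB transposed
            ratioC, validC = ratioB.T, validB.T

            total = np.where(validA, ratioA, 0.0) + np.where(validB, ratioB, 0.0) + np.where(validC, ratioC, 0.0)
            count = validA.astype(int) + validB.astype(int) + validC.astype(int)
            with np.errstate(invalid="ignore"):
                eps_bar = np.where(count > 0, total / np.maximum(count, 1), np.nan)

            # knockout of edge (x,y) by trio {x,y,z}; strict comparisons
            ko = (
                (count > 0)
                & (absR < eps_bar * absR[:, [z]])
                & (absR < eps_bar * absR[[z], :])
            )
            ko[z, :] = False
            ko[:, z] = False
            ko[idx, idx] = False
            knocked |= ko

    significant = ~knocked
    significant[idx, idx] = False
    return significant
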