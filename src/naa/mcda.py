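"""Entropy weight method and TOPSIS ranking over a node decision matrix.

The entropy weight method assigns each indicator column an objective
weight: columns whose values are more dispersed across nodes (lower
information entropy) carry more weight.  TOPSIS then scores each node by
its relative closeness to the column-wise ideal point of the weighted,
vector-normalized matrix.  Nodes whose final index exceeds 0.6 are
reported as key proteins.

Entropy of indicator j over n rows, with column shares
p_ij = x_ij / sum_i x_ij:

    e_j = -(1 / ln n) * sum_i p_ij ln p_ij        (0·ln 0 := 0)
    w_j = (1 - e_j) / sum_k (1 - e_k)

TOPSIS, with z the column-Euclidean-normalized matrix and v = w ⊙ z:

    Z+ = colmax(v),  Z- = colmin(v)
    D±_i = ||v_i - Z±||_2
    c_i = D-_i / (D+_i + D-_i)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EntropyWeights", "TopsisResult", "entropy_weights", "topsis", "select_key_nodes"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EntropyWeights:
    """Per-indicator entropy values and the resulting simplex weights."""

    entropy: pd.Series
    weights: pd.Series

    def __post_init__(self) -> None:
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ValueError("entropy weights must sum to 1")
        if (self.weights < 0).any():
            raise ValueError("entropy weights must be nonnegative")


@dataclass(frozen=True)
class TopsisResult:
    """Standardized matrix, ideal-point distances, and final indices per node."""

    z: pd.DataFrame
    v: pd.DataFrame
    z_plus: pd.Series
    z_minus: pd.Series
    d_plus: pd.Series
    d_minus: pd.Series
    scores: pd.Series


def entropy_weights(m: pd.DataFrame) -> EntropyWeights:
    """Entropy-based objective weights for each indicator column.

    Requires at least two rows (entropy over a single object is undefined
    since ln 1 = 0) and nonnegative entries.  A constant column — including
    an all-zero one — has entropy exactly 1 and hence zero discriminating
    power; if every column is constant the method degenerates and uniform
    weights are returned with a warning.
    """
    if len(m) < 2:
        raise ValueError("entropy weights need at least two rows")
    x = m.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("entropy weights require nonnegative indicator values")
    n, k = x.shape
    entropy = np.empty(k)
    for j in range(k):
        col = x[:, j]
        if np.all(col == col[0]):  # constant (or all-zero) column
            entropy[j] = 1.0
            continue
        p = col / col.sum()
        nz = p > 0
        entropy[j] = -np.sum(p[nz] * np.log(p[nz])) / np.log(n)
    entropy = np.clip(entropy, 0.0, 1.0)
    dispersion = 1.0 - entropy
    total = dispersion.sum()
    if total <= 0:
        log.warning("all indicator columns constant; falling back to uniform weights")
        weights = np.full(k, 1.0 / k)
    else:
        weights = dispersion / total
    idx = m.columns
    return EntropyWeights(
        entropy=pd.Series(entropy, index=idx, name="entropy"),
        weights=pd.Series(weights, index=idx, name="weight"),
    )


def topsis(m: pd.DataFrame, w: EntropyWeights) -> TopsisResult:
    """Rank rows of the decision matrix by closeness to the ideal point.

    Standardization is vector normalization: z_ij = x_ij / ||x_.j||_2
    (an all-zero column stays zero).  All indicators are positively
    oriented by construction, so no direction flipping is applied.
    Weights enter through the weighted normalized matrix v = w ⊙ z.
    If every row of v is identical, all scores are 0.5 by convention.
    """
    if len(m) < 2:
        raise ValueError("TOPSIS needs at least two rows")
    if list(m.columns) != list(w.weights.index):
        raise ValueError(
            f"indicator mismatch: matrix has {list(m.columns)}, "
            f"weights cover {list(w.weights.index)}"
        )
    x = m.to_numpy(dtype=float)
    norms = np.sqrt((x ** 2).sum(axis=0))
    safe = np.where(norms > 0, norms, 1.0)
    z = x / safe
    v = z * w.weights.to_numpy()
    z_plus = v.max(axis=0)
    z_minus = v.min(axis=0)
    d_plus = np.sqrt(((v - z_plus) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - z_minus) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    scores = np.where(denom > 0, d_minus / np.where(denom > 0, denom, 1.0), 0.5)
    idx = m.index
    cols = m.columns
    return TopsisResult(
        z=pd.DataFrame(z, index=idx, columns=cols),
        v=pd.DataFrame(v, index=idx, columns=cols),
        z_plus=pd.Series(z_plus, index=cols, name="z_plus"),
        z_minus=pd.Series(z_minus, index=cols, name="z_minus"),
        d_plus=pd.Series(d_plus, index=idx, name="d_plus"),
        d_minus=pd.Series(d_minus, index=idx, name="d_minus"),
        scores=pd.Series(scores, index=idx, name="c_score"),
    )


def select_key_nodes(r: TopsisResult, threshold: float = 0.6) -> list:
    """Nodes with final index strictly above ``threshold``.

    Sorted by descending score; ties broken lexicographically by node id.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    hits = r.scores[r.scores > threshold]
    return sorted(hits.index, key=lambda n: (-hits[n], n))
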