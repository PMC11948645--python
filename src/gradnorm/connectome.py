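"""Functional connectivity construction and sparsification.

Builds subject-level connectivity from parcellated BOLD time series
(Pearson correlation, Fisher r-to-z) and produces the two graph
representations the downstream stages consume:

* a row-thresholded sparse graph (strongest fraction of connections per
  row) feeding the normalized-angle affinity for gradient estimation;
* a globally-thresholded binarized positive graph for topology measures.

Tie-breaking is deterministic everywhere: values rank descending with ties
broken by ascending column index, so results are bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

_CLAMP_EPS = 1e-7  # |r| = 1 is clamped to 1 - _CLAMP_EPS before atanh


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric P x P Fisher-z connectivity with zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite connectivity entries")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("connectivity diagonal must be zero")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SparseRowGraph:
    """Row-thresholded (possibly asymmetric) graph; rows keep their top entries."""

    values: np.ndarray
    density: float


@dataclass(frozen=True)
class BinaryAdjacency:
    """Symmetric 0/1 adjacency from globally-ranked positive connections."""

    values: np.ndarray
    density: float


def compute_fc(timeseries: np.ndarray, on_degenerate: str = "clamp") -> ConnectivityMatrix:
    """Fisher-z functional connectivity from a T x P time-series matrix.

    Off-diagonal entries are ``atanh(Pearson r)`` between parcel time
    series; the diagonal is zero. Perfectly correlated parcel pairs
    (|r| = 1) are clamped to ``+/-(1 - 1e-7)`` with a warning by default,
    or raise when ``on_degenerate="error"``. Constant parcels always raise,
    naming the offending parcels.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a T x P matrix")
    T, P = ts.shape
    if T < 3:
        raise ValueError(f"need at least 3 timepoints, got {T}")
    sd = ts.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant time series for parcels {constant.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 0.0)
    hit = np.abs(r) >= 1.0 - 1e-15
    if np.any(hit):
        if on_degenerate == "error":
            i, j = np.nonzero(np.triu(hit, 1))
            raise ValueError(f"perfectly correlated parcel pairs: "
                             f"{list(zip(i.tolist(), j.tolist()))}")
        warnings.warn(
            f"{int(np.sum(np.triu(hit, 1)))} parcel pair(s) with |r| = 1 "
            f"clamped to +/-(1 - {_CLAMP_EPS})", stacklevel=2)
        r = np.clip(r, -(1.0 - _CLAMP_EPS), 1.0 - _CLAMP_EPS)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # exact symmetry against fp round-off
    return ConnectivityMatrix(values=z)


def row_threshold(fc: ConnectivityMatrix | np.ndarray, density: float = 0.10,
                  use_abs: bool = False) -> SparseRowGraph:
    """Keep the strongest ``ceil(density * (P - 1))`` entries of each row.

    Ranking is by signed value (the default reading of "strongest
    connections" in the gradient literature) or by absolute value when
    ``use_abs``; ties break deterministically by ascending column index.
    The diagonal is never retained. The input is untouched.
    """
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must be in (0, 1), got {density}")
    v = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, float)
    P = v.shape[0]
    keep = int(np.ceil(density * (P - 1)))
    rank_key = np.abs(v) if use_abs else v.copy()
    # exclude diagonal from the ranking
    np.fill_diagonal(rank_key, -np.inf)
    out = np.zeros_like(v)
    cols = np.arange(P)
    for i in range(P):
        order = np.lexsort((cols, -rank_key[i]))  # value desc, column asc
        top = order[:keep]
        out[i, top] = v[i, top]
    return SparseRowGraph(values=out, density=density)


def normalized_angle_affinity(graph: SparseRowGraph | np.ndarray) -> np.ndarray:
    """Normalized-angle similarity between connectivity profiles (rows).

    ``affinity(i, j) = 1 - arccos(cosine(row_i, row_j)) / pi`` in [0, 1];
    1 for identical profiles, 0.5 for orthogonal, 0 for anti-parallel.
    The diagonal is 1 by construction.
    """
    v = graph.values if isinstance(graph, SparseRowGraph) else np.asarray(graph, float)
    norms = np.linalg.norm(v, axis=1)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        raise ValueError(f"all-zero connectivity rows for parcels {dead.tolist()}")
    cos = (v @ v.T) / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    np.fill_diagonal(aff, 1.0)
    return (aff + aff.T) / 2.0


def binarize_positive_top(fc: ConnectivityMatrix | np.ndarray,
                          density: float = 0.10) -> BinaryAdjacency:
    """Binary graph of the globally top ``density`` fraction of positive edges.

    All P(P-1)/2 possible undirected edges are ranked by connectivity value
    (descending, ties by edge index); the strongest ``ceil(density *
    P(P-1)/2)`` positive edges become 1. If fewer positive edges exist than
    the quota, all positives are kept and a warning is logged; a matrix
    with no positive off-diagonal entries is an error.
    """
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must be in (0, 1), got {density}")
    v = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, float)
    P = v.shape[0]
    iu, ju = np.triu_indices(P, k=1)
    w = v[iu, ju]
    quota = int(np.ceil(density * len(w)))
    pos = np.flatnonzero(w > 0)
    if pos.size == 0:
        raise ValueError("no positive connections to threshold")
    if pos.size < quota:
        warnings.warn(
            f"only {pos.size} positive edges available for a quota of "
            f"{quota}; keeping all positives", stacklevel=2)
        chosen = pos
    else:
        order = np.lexsort((np.arange(len(w)), -w))  # value desc, edge index asc
        chosen = order[:quota]
    adj = np.zeros((P, P))
    adj[iu[chosen], ju[chosen]] = 1.0
    adj = adj + adj.T
    return BinaryAdjacency(values=adj, density=density)
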