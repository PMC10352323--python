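"""Weighted functional-network construction from ROI time series.

The stage turns one subject's region x time matrix into, successively:

* a Fisher-z connectivity matrix (Pearson r, atanh-transformed, zero
  diagonal),
* its nonnegative rectification (negative couplings discarded, the
  standard convention for weighted functional connectomes),
* and a sweep of thresholded weighted networks, one per sparsity level
  from 5% to 40% in 1% steps (36 networks at defaults), where sparsity is
  the retained-edge count over the N(N-1)/2 possible undirected edges and
  the strongest edges survive with their z weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synthetic import SubjectTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "ThresholdedNetworkSet",
    "default_sparsities",
    "pearson_fisher",
    "rectify_negative",
    "threshold_sweep",
]

logger = logging.getLogger(__name__)

_ATANH_EPS = 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity matrix with zero diagonal."""

    z: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.shape != (n, n):
            raise ValueError("z must be square")
        if len(self.region_labels) != n:
            raise ValueError("label count must match matrix size")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z contains non-finite entries")
        if not np.allclose(self.z, self.z.T):
            raise ValueError("z must be symmetric")
        if np.any(np.diag(self.z) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


@dataclass
class ThresholdedNetworkSet:
    """Weighted adjacency matrices of one subject across the sparsity sweep."""

    sparsities: list[float]
    networks: list[np.ndarray] = field(repr=False)
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sparsities) != len(self.networks):
            raise ValueError("sparsities and networks must align")


def default_sparsities(
    s_min: float = 0.05, s_max: float = 0.40, step: float = 0.01
) -> list[float]:
    """The sparsity grid 0.05, 0.06, ..., 0.40 (36 levels at defaults)."""
    n = int(round((s_max - s_min) / step)) + 1
    return [round(s_min + i * step, 10) for i in range(n)]


def pearson_fisher(ts: SubjectTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation of region time courses, Fisher r-to-z transformed.

    Correlations are clipped to +/-(1 - 1e-7) before atanh so numerically
    perfect correlations stay finite; the diagonal is forced to zero.
    Raises if any region has zero variance, naming the region.
    """
    X = ts.data
    if X.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = [ts.region_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance region(s): {bad}")
    r = np.corrcoef(X)
    z = np.arctanh(np.clip(r, -1.0 + _ATANH_EPS, 1.0 - _ATANH_EPS))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z, region_labels=list(ts.region_labels))


def rectify_negative(C: ConnectivityMatrix) -> ConnectivityMatrix:
    """Set every negative element to zero (idempotent)."""
    return ConnectivityMatrix(
        z=np.maximum(C.z, 0.0), region_labels=list(C.region_labels)
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def threshold_sweep(
    C: ConnectivityMatrix,
    s_min: float = 0.05,
    s_max: float = 0.40,
    step: float = 0.01,
) -> ThresholdedNetworkSet:
    """Keep the k = round(s * N(N-1)/2) strongest edges at each sparsity s.

    The input must be rectified (no negative entries). Ties at the cut are
    broken by smallest (row, col) index so the sweep is deterministic; if
    fewer than k strictly positive edges exist, all positive edges are kept
    and a warning is logged. Edge sets are nested across the sweep and
    surviving edges keep their z weights.
    """
    if not (0.0 < s_min <= s_max < 1.0):
        raise ValueError("require 0 < s_min <= s_max < 1")
    if np.any(C.z < 0):
        raise ValueError("threshold_sweep requires a rectified (nonnegative) matrix")

    n = C.n_regions
    iu, ju = np.triu_indices(n, k=1)
    w = C.z[iu, ju]
    n_pairs = w.size
    # Sort by weight descending, ties by (row, col) ascending.
    order = np.lexsort((ju, iu, -w))
    n_positive = int(np.count_nonzero(w > 0))

    sparsities = default_sparsities(s_min, s_max, step)
    networks = []
    for s in sparsities:
        k = _round_half_away(s * n_pairs)
        if k > n_positive:
            logger.warning(
                "sparsity %.2f requests %d edges but only %d positive edges "
                "exist; keeping all positive edges", s, k, n_positive,
            )
            k = n_positive
        keep = order[:k]
        A = np.zeros_like(C.z)
        A[iu[keep], ju[keep]] = w[keep]
        A = A + A.T
        networks.append(A)
    return ThresholdedNetworkSet(
        sparsities=sparsities, networks=networks,
        region_labels=list(C.region_labels),
    )
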