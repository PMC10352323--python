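"""Ten weighted network measures and their sparsity-sweep AUC summaries.

All measures use the weighted-connectome conventions: an edge of weight
``w > 0`` has length ``1/w``; distances ``d_ij`` are weighted shortest-path
lengths over those edge lengths; unreachable pairs contribute zero to
efficiencies and are excluded from the characteristic path length.

Global measures (network scalars)
    global efficiency, local efficiency, clustering coefficient,
    characteristic path length.
Nodal measures (one value per region)
    nodal efficiency, nodal local efficiency, nodal clustering
    coefficient (Onnela geometric-mean form, weights normalised by the
    network maximum), degree centrality (node strength), betweenness
    centrality (weighted shortest paths, normalised by (N-1)(N-2)/2),
    eigenvector centrality (leading eigenvector of W on the largest
    connected component, unit Euclidean norm).

Each measure is integrated over the sparsity sweep with the trapezoidal
rule, giving one threshold-free AUC scalar per subject x measure x scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd
from scipy.sparse import csgraph

from .network import ThresholdedNetworkSet

__all__ = [
    "WeightedGraph",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
    "distance_matrix",
    "nodal_efficiency",
    "global_efficiency",
    "characteristic_path_length",
    "nodal_clustering",
    "clustering_coefficient",
    "nodal_local_efficiency",
    "local_efficiency",
    "degree_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "network_metrics",
    "auc_over_sparsity",
    "cohort_auc_table",
]

GLOBAL_METRICS = (
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "characteristic_path_length",
)
NODAL_METRICS = (
    "nodal_efficiency",
    "nodal_local_efficiency",
    "nodal_clustering",
    "degree_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
)


@dataclass
class WeightedGraph:
    """Nonnegative symmetric weight matrix with zero diagonal."""

    W: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ValueError("W must be square")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W must be finite")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("W must have a zero diagonal")
        if np.any(self.W < 0):
            raise ValueError("W must be nonnegative")
        if self.node_labels is None:
            self.node_labels = [str(i) for i in range(n)]
        elif len(self.node_labels) != n:
            raise ValueError("label count must match matrix size")

    @property
    def n(self) -> int:
        return self.W.shape[0]


def _as_weights(G: WeightedGraph | np.ndarray) -> np.ndarray:
    return G.W if isinstance(G, WeightedGraph) else np.asarray(G, dtype=float)


def distance_matrix(G: WeightedGraph | np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest-path distances over lengths 1/w.

    Entries are np.inf for unreachable pairs and 0 on the diagonal.
    """
    W = _as_weights(G)
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, 0.0)
    return csgraph.shortest_path(L, method="D", directed=False)


def _nodal_efficiency_all(W: np.ndarray, D: np.ndarray | None = None) -> np.ndarray:
    n = W.shape[0]
    if n < 2:
        return np.zeros(n)
    if D is None:
        D = distance_matrix(W)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_efficiency(G: WeightedGraph, i: int) -> float:
    """Average inverse distance from node i to every other node."""
    if G.n < 2:
        raise ValueError("need at least 2 nodes")
    return float(_nodal_efficiency_all(G.W)[i])


def global_efficiency(G: WeightedGraph | np.ndarray) -> float:
    """Mean nodal efficiency over all nodes (0 for an empty graph)."""
    W = _as_weights(G)
    if W.shape[0] == 0:
        return 0.0
    return float(_nodal_efficiency_all(W).mean())


def characteristic_path_length(G: WeightedGraph | np.ndarray) -> float:
    """Mean shortest-path distance over reachable ordered pairs i != j."""
    D = distance_matrix(G)
    n = D.shape[0]
    mask = np.isfinite(D) & ~np.eye(n, dtype=bool)
    if not mask.any():
        raise ValueError("no reachable node pair")
    return float(D[mask].mean())


def _nodal_clustering_all(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    wmax = W.max(initial=0.0)
    if wmax == 0:
        return np.zeros(n)
    Wh = np.cbrt(W / wmax)
    k = (W > 0).sum(axis=1)
    num = np.diag(Wh @ Wh @ Wh)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom > 0, num / denom, 0.0)
    return C


def nodal_clustering(G: WeightedGraph, i: int) -> float:
    """Onnela weighted clustering of node i (0 when degree < 2)."""
    return float(_nodal_clustering_all(G.W)[i])


def clustering_coefficient(G: WeightedGraph | np.ndarray) -> float:
    """Mean nodal clustering over all nodes."""
    W = _as_weights(G)
    return float(_nodal_clustering_all(W).mean()) if W.shape[0] else 0.0


def _nodal_local_efficiency_all(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    deg = (W > 0).sum(axis=1)
    for i in range(n):
        if deg[i] < 2:
            continue
        nbrs = np.flatnonzero(W[i] > 0)
        sub = W[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency(sub)
    return out


def nodal_local_efficiency(G: WeightedGraph, i: int) -> float:
    """Global efficiency of the subgraph induced by i's neighbours.

    Original weights are retained and i itself is removed; 0 when i has
    fewer than two neighbours.
    """
    return float(_nodal_local_efficiency_all(G.W)[i])


def local_efficiency(G: WeightedGraph | np.ndarray) -> float:
    """Mean nodal local efficiency over all nodes."""
    W = _as_weights(G)
    return float(_nodal_local_efficiency_all(W).mean()) if W.shape[0] else 0.0


def degree_centrality(G: WeightedGraph, i: int | None = None):
    """Node strength: the sum of incident edge weights."""
    s = G.W.sum(axis=1)
    return s if i is None else float(s[i])


def _betweenness_all(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    if n < 3:
        return np.zeros(n)
    iu, ju = np.triu_indices(n, k=1)
    pos = W[iu, ju] > 0
    edges = list(zip(iu[pos].tolist(), ju[pos].tolist()))
    if not edges:
        return np.zeros(n)
    g = ig.Graph(n=n, edges=edges, directed=False)
    lengths = (1.0 / W[iu[pos], ju[pos]]).tolist()
    bc = np.asarray(g.betweenness(weights=lengths), dtype=float)
    return bc / ((n - 1) * (n - 2) / 2.0)


def betweenness_centrality(G: WeightedGraph, i: int | None = None):
    """Fraction of weighted shortest paths through a node.

    Path multiplicity is counted; values are normalised by the
    (N-1)(N-2)/2 pairs a node could possibly mediate.
    """
    bc = _betweenness_all(G.W)
    return bc if i is None else float(bc[i])


def _eigenvector_all(
    W: np.ndarray, tol: float = 1e-13, max_iter: int = 200_000
) -> np.ndarray:
    n = W.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    n_comp, labels = csgraph.connected_components(
        (W > 0).astype(np.int8), directed=False
    )
    sizes = np.bincount(labels, minlength=n_comp)
    comp = int(sizes.argmax())
    idx = np.flatnonzero(labels == comp)
    out = np.zeros(n)
    if idx.size == 1:
        out[idx[0]] = 1.0
        return out
    Wc = W[np.ix_(idx, idx)]
    # Diagonal shift keeps the dominant eigenvalue simple and positive so
    # power iteration converges even on bipartite-like components; the
    # eigenvector is unchanged.
    shift = Wc.sum(axis=1).max()
    v = np.full(idx.size, 1.0 / np.sqrt(idx.size))
    for _ in range(max_iter):
        v_new = Wc @ v + shift * v
        norm = np.linalg.norm(v_new)
        if norm == 0:  # pragma: no cover - shift > 0 on connected comps
            break
        v_new /= norm
        if np.linalg.norm(v_new - v) <= tol * np.linalg.norm(v_new):
            v = v_new
            break
        v = v_new
    else:
        raise RuntimeError("eigenvector centrality power iteration did not converge")
    v = np.abs(v)
    out[idx] = v / np.linalg.norm(v)
    return out


def eigenvector_centrality(G: WeightedGraph, i: int | None = None):
    """Leading-eigenvector importance on the largest connected component.

    The eigenvector of W restricted to the largest component is taken
    nonnegative with unit Euclidean norm; nodes outside that component
    score 0.
    """
    ec = _eigenvector_all(G.W)
    return ec if i is None else float(ec[i])


def network_metrics(W: np.ndarray) -> dict[str, float | np.ndarray]:
    """All ten measures of one weighted network in a single pass.

    Returns the four global scalars plus one array per nodal measure;
    shares the distance matrix between the measures that need it.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    D = distance_matrix(W)
    ne = _nodal_efficiency_all(W, D)
    nle = _nodal_local_efficiency_all(W)
    nc = _nodal_clustering_all(W)
    mask = np.isfinite(D) & ~np.eye(n, dtype=bool)
    cpl = float(D[mask].mean()) if mask.any() else float("nan")
    return {
        "global_efficiency": float(ne.mean()),
        "local_efficiency": float(nle.mean()),
        "clustering_coefficient": float(nc.mean()),
        "characteristic_path_length": cpl,
        "nodal_efficiency": ne,
        "nodal_local_efficiency": nle,
        "nodal_clustering": nc,
        "degree_centrality": W.sum(axis=1),
        "betweenness_centrality": _betweenness_all(W),
        "eigenvector_centrality": _eigenvector_all(W),
    }


def auc_over_sparsity(
    values: Sequence[float], sparsities: Sequence[float]
) -> float:
    """Trapezoidal integral of a measure over the sparsity grid.

    A single point has zero area; the grid must be strictly increasing.
    """
    values = np.asarray(values, dtype=float)
    sparsities = np.asarray(sparsities, dtype=float)
    if values.shape != sparsities.shape:
        raise ValueError("values and sparsities must have equal length")
    if sparsities.size and np.any(np.diff(sparsities) <= 0):
        raise ValueError("sparsities must be strictly increasing")
    if sparsities.size < 2:
        return 0.0
    return float(np.trapezoid(values, sparsities))


def subject_metric_profiles(nets: ThresholdedNetworkSet) -> pd.DataFrame:
    """Long-format per-sparsity measure table for one subject's sweep.

    Columns: metric, scope ('global' or a region label), sparsity, value.
    """
    labels = nets.region_labels or [str(i) for i in range(nets.networks[0].shape[0])]
    rows = []
    for s, W in zip(nets.sparsities, nets.networks):
        m = network_metrics(W)
        for name in GLOBAL_METRICS:
            rows.append((name, "global", s, m[name]))
        for name in NODAL_METRICS:
            vals = m[name]
            for lab, v in zip(labels, vals):
                rows.append((name, lab, s, float(v)))
    return pd.DataFrame(rows, columns=["metric", "scope", "sparsity", "value"])


def profiles_to_auc(profiles: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-sparsity profile table to one AUC per metric x scope."""
    recs = []
    for (metric, scope), grp in profiles.groupby(["metric", "scope"], sort=False):
        grp = grp.sort_values("sparsity")
        recs.append(
            (metric, scope,
             auc_over_sparsity(grp["value"].to_numpy(), grp["sparsity"].to_numpy()))
        )
    return pd.DataFrame(recs, columns=["metric", "scope", "auc"])


def cohort_auc_table(
    cohort_nets: Mapping[str, ThresholdedNetworkSet],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """AUC summary table for a cohort.

    Parameters
    ----------
    cohort_nets
        subject_id -> thresholded network sweep.
    groups
        subject_id -> group label.

    Returns a long-format frame: subject_id, group, metric, scope, auc.
    """
    frames = []
    for sid, nets in cohort_nets.items():
        auc = profiles_to_auc(subject_metric_profiles(nets))
        auc.insert(0, "group", groups[sid])
        auc.insert(0, "subject_id", sid)
        frames.append(auc)
    return pd.concat(frames, ignore_index=True)
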