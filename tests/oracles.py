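"""Independent brute-force oracles for the weighted network measures.

Everything here is deliberately naive — Floyd–Warshall over dense length
matrices, exhaustive simple-path enumeration for betweenness, explicit
triple loops for clustering, dense eigendecomposition for eigenvector
centrality — and shares no code with the package implementations it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np

TIE_TOL = 1e-12


def floyd_warshall(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def nodal_efficiency(W: np.ndarray) -> np.ndarray:
    D = floyd_warshall(W)
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j != i and np.isfinite(D[i, j]) and D[i, j] > 0:
                acc += 1.0 / D[i, j]
        out[i] = acc / (n - 1)
    return out


def global_efficiency(W: np.ndarray) -> float:
    return float(nodal_efficiency(W).mean())


def characteristic_path_length(W: np.ndarray) -> float:
    D = floyd_warshall(W)
    vals = [
        D[i, j]
        for i in range(W.shape[0])
        for j in range(W.shape[0])
        if i != j and np.isfinite(D[i, j])
    ]
    return float(np.mean(vals)) if vals else float("nan")


def nodal_clustering(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    wmax = W.max() if W.size else 0.0
    out = np.zeros(n)
    if wmax == 0:
        return out
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        acc = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h:
                    acc += ((W[i, j] / wmax) * (W[i, h] / wmax)
                            * (W[j, h] / wmax)) ** (1.0 / 3.0)
        out[i] = acc / (k * (k - 1))
    return out


def nodal_local_efficiency(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        out[i] = global_efficiency(sub)
    return out


def degree_centrality(W: np.ndarray) -> np.ndarray:
    return W.sum(axis=1)


def betweenness_centrality(W: np.ndarray) -> np.ndarray:
    """Exhaustive simple-path enumeration; counts shortest-path multiplicity."""
    n = W.shape[0]
    out = np.zeros(n)
    if n < 3:
        return out
    nodes = list(range(n))
    for s, t in itertools.combinations(nodes, 2):
        # All simple paths s -> t with their lengths.
        best = np.inf
        paths: list[tuple[float, tuple[int, ...]]] = []
        others = [v for v in nodes if v not in (s, t)]
        for r in range(len(others) + 1):
            for mid in itertools.permutations(others, r):
                path = (s, *mid, t)
                length = 0.0
                ok = True
                for a, b in zip(path, path[1:]):
                    if W[a, b] <= 0:
                        ok = False
                        break
                    length += 1.0 / W[a, b]
                if ok:
                    paths.append((length, path))
                    best = min(best, length)
        if not np.isfinite(best):
            continue
        shortest = [p for (ln, p) in paths if ln <= best + TIE_TOL]
        sigma = len(shortest)
        for p in shortest:
            for v in p[1:-1]:
                out[v] += 1.0 / sigma
    return out / ((n - 1) * (n - 2) / 2.0)


def eigenvector_centrality(W: np.ndarray) -> np.ndarray:
    """Dense eigendecomposition on the largest connected component."""
    n = W.shape[0]
    # Components by label propagation (naive).
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if W[i, j] > 0 and labels[j] < labels[i]:
                    labels[i] = labels[j]
                    changed = True
    counts: dict[int, int] = {}
    for lb in labels:
        counts[lb] = counts.get(lb, 0) + 1
    biggest = max(counts, key=lambda lb: (counts[lb], -lb))
    idx = [i for i in range(n) if labels[i] == biggest]
    out = np.zeros(n)
    if len(idx) == 1:
        out[idx[0]] = 1.0
        return out
    sub = W[np.ix_(idx, idx)]
    w, V = np.linalg.eigh(sub)
    v = V[:, np.argmax(w)]
    v = np.abs(v)
    out[idx] = v / np.linalg.norm(v)
    return out


def random_weighted_graph(
    rng: np.random.Generator, n_max: int = 8
) -> np.ndarray:
    """One random symmetric weighted graph with 4..n_max nodes."""
    n = int(rng.integers(4, n_max + 1))
    density = rng.uniform(0.3, 0.9)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(0.05, 1.0)
    return W
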