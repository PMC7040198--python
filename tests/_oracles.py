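"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as a literal transcription of the defining
formulas (naive loops, networkx for graph quantities) and must stay
independent of the mxbrain code paths it checks.
"""

from __future__ import annotations

import numpy as np


def brute_weighted_clustering(weights: np.ndarray, binary: np.ndarray) -> np.ndarray:
    """Single-layer C_i by explicit triad enumeration (ordered pairs)."""
    n = weights.shape[0]
    c = np.zeros(n)
    k = binary.sum(axis=1)
    for i in range(n):
        if k[i] < 2:
            continue
        s = 0.0
        for j in range(n):
            for m in range(n):
                s += (weights[i, j] * weights[j, m] * weights[m, i]) ** (1 / 3)
        c[i] = s / (k[i] * (k[i] - 1))
    return c


def brute_mcc1(layer_weights: list[np.ndarray], layer_binary: list[np.ndarray]) -> np.ndarray:
    """C_i1 by exhaustive enumeration over layer pairs and node pairs."""
    M = len(layer_weights)
    n = layer_weights[0].shape[0]
    num = np.zeros(n)
    for a in range(M):
        for kk in range(M):
            if kk == a:
                continue
            wa, wk = layer_weights[a], layer_weights[kk]
            for i in range(n):
                for j in range(n):
                    for m in range(n):
                        if j == m or j == i or m == i:
                            continue
                        num[i] += (wa[i, j] * wk[j, m] * wa[m, i]) ** (1 / 3)
    den = np.zeros(n)
    for a in range(M):
        ka = layer_binary[a].sum(axis=1)
        den += ka * (ka - 1)
    den *= M - 1
    out = np.zeros(n)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def brute_mcc2(layer_weights: list[np.ndarray]) -> np.ndarray:
    """C_i2 by exhaustive enumeration over ordered distinct layer triples."""
    M = len(layer_weights)
    n = layer_weights[0].shape[0]
    num = np.zeros(n)
    for a in range(M):
        for kk in range(M):
            if kk == a:
                continue
            for u in range(M):
                if u == a or u == kk:
                    continue
                wa, wk, wu = layer_weights[a], layer_weights[kk], layer_weights[u]
                for i in range(n):
                    for j in range(n):
                        for m in range(n):
                            if j == m or j == i or m == i:
                                continue
                            num[i] += (wa[i, j] * wu[j, m] * wk[m, i]) ** (1 / 3)
    den = np.zeros(n)
    for a in range(M):
        for kk in range(M):
            if kk == a:
                continue
            wa, wk = layer_weights[a], layer_weights[kk]
            for i in range(n):
                for j in range(n):
                    for m in range(n):
                        if j == m or j == i or m == i:
                            continue
                        den[i] += (wa[i, j] * wk[m, i]) ** (1 / 3)
    den *= M - 2
    out = np.zeros(n)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def brute_participation(layer_binary: list[np.ndarray]) -> np.ndarray:
    """P_i directly from the degree-proportion definition."""
    M = len(layer_binary)
    degs = np.array([b.sum(axis=1) for b in layer_binary], dtype=float)
    n = degs.shape[1]
    p = np.zeros(n)
    for i in range(n):
        o = degs[:, i].sum()
        if o == 0:
            continue
        p[i] = M / (M - 1) * (1.0 - ((degs[:, i] / o) ** 2).sum())
    return p


def exhaustive_threshold(weights: np.ndarray) -> np.ndarray:
    """Best binary graph over all distinct-weight thresholds by brute force,
    scoring J = networkx global efficiency - density; ties -> sparser."""
    import networkx as nx

    n = weights.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = np.unique(weights[iu][weights[iu] > 0])
    best = None
    for tau in vals:
        binary = (weights >= tau).astype(int)
        np.fill_diagonal(binary, 0)
        g = nx.from_numpy_array(binary)
        eff = nx.global_efficiency(g)
        cost = binary[iu].sum() / iu[0].size
        j = eff - cost
        if best is None or j > best[0] + 1e-15 or (abs(j - best[0]) <= 1e-15 and cost < best[1]):
            best = (j, cost, binary)
    return best[2]


def random_multiplex(rng: np.random.Generator, n: int, m: int, density: float = 0.4):
    """Random weighted multiplex: symmetric weights in (0, 1], zero diagonal."""
    layer_weights, layer_binary = [], []
    for _ in range(m):
        mask = np.triu(rng.random((n, n)) < density, k=1)
        w = np.where(mask, rng.uniform(0.05, 1.0, (n, n)), 0.0)
        w = w + w.T
        layer_weights.append(w)
        layer_binary.append((w > 0).astype(int))
    return layer_weights, layer_binary
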