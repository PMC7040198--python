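"""Single-layer and multiplex segregation / integration metrics.

Notation: per layer alpha, ``w_ij^a`` are the retained (thresholded)
weights, ``k_i^a`` the binary degrees; M layers, N nodes.

* Weighted clustering (single layer):
      C_i = sum_{j,m} (w_ij w_jm w_mi)^(1/3) / (k_i (k_i - 1))
* Multiplex clustering coefficient (two-layer triangles):
      C_i1 = sum_{a} sum_{k != a} sum_{j != m}
             (w_ij^a w_jm^k w_mi^a)^(1/3)
             / [ (M - 1) sum_a k_i^a (k_i^a - 1) ]
  C_i1 = 1 when every triad centred at i closes through a second layer,
  0 when triangles exist only within a single layer (or none exist).
* Three-layer variant (needs M >= 3):
      C_i2 = sum over ordered distinct layer triples (a, k, u) of
             (w_ij^a w_jm^u w_mi^k)^(1/3)
             / [ (M - 2) * sum over ordered (a, k), a != k, j != m of
                 (w_ij^a w_mi^k)^(1/3) ]
* Multiplex participation:
      o_i = sum_L k_i^L,   NLP_i^L = k_i^L / o_i,
      P_i = M/(M-1) * (1 - sum_L (NLP_i^L)^2)
  P_i = 1 for equal degrees in all layers, 0 for a single-layer
  concentration; zero overlapping degree gives P_i = 0 by convention.

Sums over node pairs (j, m) are ordered, matching the k(k-1) ordered-pair
denominators; with zero diagonals all j = m, j = i, m = i terms vanish, so
the triple products reduce to diagonals of cube-rooted-weight matrix
products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .errors import InsufficientDataError, LayerCountError, StructureError
from .netbuild import Layer, MultiplexNetwork, build_time_varying, cost_efficiency_threshold


@dataclass
class NodeMetricTable:
    """Per-node values of one named metric for one network."""

    metric_name: str
    values: np.ndarray
    channel_labels: tuple[str, ...] = ()
    network_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.channel_labels) or [f"ch{i}" for i in range(len(self.values))]
        if self.values.ndim == 1:
            return pd.DataFrame(
                {"node": labels, "metric": self.metric_name, "value": self.values,
                 "network": self.network_id}
            )
        # per-node-per-layer table (NLP)
        rows = []
        for layer_idx in range(self.values.shape[0]):
            for node, v in zip(labels, self.values[layer_idx]):
                rows.append((node, layer_idx, self.metric_name, v, self.network_id))
        return pd.DataFrame(rows, columns=["node", "layer", "metric", "value", "network"])

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def _cbrt(w: np.ndarray) -> np.ndarray:
    return np.cbrt(w)


def weighted_clustering(layer: Layer, network_id: str = "") -> NodeMetricTable:
    """Single-layer weighted clustering coefficient C_i."""
    if layer.n_nodes < 3:
        raise StructureError("need at least 3 nodes")
    v = _cbrt(layer.weighted)
    num = np.einsum("ij,jm,mi->i", v, v, v)
    k = layer.degrees.astype(float)
    den = k * (k - 1)
    c = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return NodeMetricTable("C_i", c, network_id=network_id)


def mcc_node(network: MultiplexNetwork, network_id: str = "") -> NodeMetricTable:
    """Multiplex clustering coefficient C_i1 (triangles spanning two layers)."""
    if network.M < 2:
        raise LayerCountError("C_i1 needs at least two layers")
    v = [_cbrt(l.weighted) for l in network.layers]
    n = network.N
    num = np.zeros(n)
    for a in range(network.M):
        for k in range(network.M):
            if k == a:
                continue
            num += np.einsum("ij,jm,mi->i", v[a], v[k], v[a])
    deg = np.array([l.degrees for l in network.layers], dtype=float)  # M x N
    den = (network.M - 1) * (deg * (deg - 1)).sum(axis=0)
    c = np.divide(num, den, out=np.zeros(n), where=den > 0)
    return NodeMetricTable("C_i1", c, channel_labels=network.channel_labels, network_id=network_id)


def mcc_two_layer_triads(network: MultiplexNetwork, network_id: str = "") -> NodeMetricTable:
    """C_i2: triangles whose three edges lie in three distinct layers."""
    if network.M < 3:
        raise LayerCountError("C_i2 needs at least three layers")
    v = [_cbrt(l.weighted) for l in network.layers]
    m, n = network.M, network.N
    num = np.zeros(n)
    for a in range(m):
        for k in range(m):
            if k == a:
                continue
            for u in range(m):
                if u == a or u == k:
                    continue
                num += np.einsum("ij,jm,mi->i", v[a], v[u], v[k])
    den = np.zeros(n)
    row = [vi.sum(axis=1) for vi in v]
    for a in range(m):
        for k in range(m):
            if k == a:
                continue
            den += row[a] * row[k] - np.einsum("ij,ji->i", v[a], v[k])
    den *= m - 2
    c = np.divide(num, den, out=np.zeros(n), where=den > 0)
    return NodeMetricTable("C_i2", c, channel_labels=network.channel_labels, network_id=network_id)


def mcc_network(table: NodeMetricTable) -> float:
    """Network-level MCC: the mean of C_i1 over all nodes."""
    if table.values.size == 0:
        raise StructureError("empty node table")
    return float(table.values.mean())


def participation(
    network: MultiplexNetwork, network_id: str = ""
) -> tuple[NodeMetricTable, NodeMetricTable, NodeMetricTable]:
    """Multiplex participation P_i, node-degree layer proportion NLP and
    overlapping degree o_i."""
    if network.M < 2:
        raise LayerCountError("participation needs at least two layers")
    deg = np.array([l.degrees for l in network.layers], dtype=float)  # M x N
    o = deg.sum(axis=0)
    nlp = np.divide(deg, o, out=np.zeros_like(deg), where=o > 0)
    m = network.M
    p = m / (m - 1) * (1.0 - (nlp**2).sum(axis=0))
    p = np.where(o > 0, p, 0.0)
    p = np.clip(p, 0.0, 1.0)
    labels = network.channel_labels
    return (
        NodeMetricTable("P_i", p, channel_labels=labels, network_id=network_id),
        NodeMetricTable("NLP", nlp, channel_labels=labels, network_id=network_id),
        NodeMetricTable("o_i", o, channel_labels=labels, network_id=network_id),
    )


def mpc_network(table: NodeMetricTable) -> float:
    """Network-level MPC: the mean of P_i over all nodes."""
    if table.values.size == 0:
        raise StructureError("empty node table")
    return float(table.values.mean())


# ---------------------------------------------------------------------------
# sensitivity sweeps


def _network_metric(net: MultiplexNetwork, metric: str) -> float:
    if metric == "mcc":
        return mcc_network(mcc_node(net))
    if metric == "mpc":
        return mpc_network(participation(net)[0])
    raise StructureError(f"unknown metric {metric!r} (use 'mcc' or 'mpc')")


def layer_count_sweep(
    subject_window_matrices: list[list[ConnectivityMatrix]],
    nl_grid: list[int],
    metric: str = "mpc",
) -> pd.DataFrame:
    """Network-level metric vs number of temporal layers, summarised over
    subjects (mean and SD per NL)."""
    max_nl = max(nl_grid)
    for mats in subject_window_matrices:
        if len(mats) < max_nl:
            raise InsufficientDataError(
                f"a subject has {len(mats)} windows; the grid needs {max_nl}"
            )
    rows = []
    for nl in nl_grid:
        vals = [
            _network_metric(build_time_varying(mats, n_layers=nl), metric)
            for mats in subject_window_matrices
        ]
        rows.append((nl, float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0))
    return pd.DataFrame(rows, columns=["n_layers", "mean", "sd"])


def window_length_sweep(
    filtered_epoch: np.ndarray,
    fs: float,
    lengths: list[float],
    metric: str = "mcc",
    n_layers: int = 5,
) -> dict[float, NodeMetricTable]:
    """Full rebuild (segment -> connectivity -> threshold -> metric) of the
    time-varying multiplex at each window length; the input must already be
    band-filtered."""
    from .connectivity import connectivity_matrix, instantaneous_phase
    from .preprocess import segment_windows

    out: dict[float, NodeMetricTable] = {}
    for length in lengths:
        windows = segment_windows(filtered_epoch, fs, width=length)
        if len(windows) < n_layers:
            raise InsufficientDataError(
                f"window length {length} s yields {len(windows)} windows; need {n_layers}"
            )
        mats = [
            connectivity_matrix(instantaneous_phase(w, fs), window_index=i)
            for i, w in enumerate(windows)
        ]
        net = build_time_varying(mats, n_layers=n_layers)
        if metric == "mcc":
            out[length] = mcc_node(net, network_id=f"win{length}")
        elif metric == "mpc":
            out[length] = participation(net, network_id=f"win{length}")[0]
        else:
            raise StructureError(f"unknown metric {metric!r}")
    return out
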