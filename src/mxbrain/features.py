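"""From epochs to multiplex networks to cohort feature tables.

This is the glue the statistics and classification stages consume: for each
epoch it builds the requested multiplex network (cross-frequency over bands,
or time-varying within one band) and extracts node-level MCC (C_i1) and
participation (P_i) features named ``{axis}_{metric}_{channel}``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import connectivity_matrix, instantaneous_phase
from .montage import Band, DEFAULT_BANDS
from .mxmetrics import mcc_node, participation
from .netbuild import MultiplexNetwork, build_cross_frequency, build_time_varying
from .preprocess import bandpass, segment_windows
from .recording import Cohort, EegRecording


def cross_frequency_network(
    epoch_data: np.ndarray,
    fs: float,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
) -> MultiplexNetwork:
    """Band-filter the whole epoch, estimate niPLV per band, threshold each
    band independently and stack into a frequency-axis multiplex."""
    mats = {}
    for band in bands:
        filtered = bandpass(epoch_data, fs, band)
        phases = instantaneous_phase(filtered, fs)
        mats[band.name] = connectivity_matrix(phases, band=band.name)
    return build_cross_frequency(mats, bands=tuple(b.name for b in bands))


def window_matrices(
    epoch_data: np.ndarray,
    fs: float,
    band: Band,
    window_s: float = 4.0,
) -> list:
    """niPLV matrices for every non-overlapping window of one band."""
    filtered = bandpass(epoch_data, fs, band)
    windows = segment_windows(filtered, fs, width=window_s)
    return [
        connectivity_matrix(instantaneous_phase(w, fs), band=band.name, window_index=i)
        for i, w in enumerate(windows)
    ]


def time_varying_network(
    epoch_data: np.ndarray,
    fs: float,
    band: Band,
    n_layers: int = 5,
    window_s: float = 4.0,
) -> MultiplexNetwork:
    """Time-axis multiplex: first ``n_layers`` thresholded window networks."""
    return build_time_varying(window_matrices(epoch_data, fs, band, window_s), n_layers=n_layers)


def node_features(net: MultiplexNetwork, prefix: str) -> dict[str, float]:
    """Node-level MCC and participation features of one multiplex network."""
    labels = list(net.channel_labels) or [f"ch{i}" for i in range(net.N)]
    mcc = mcc_node(net)
    p = participation(net)[0]
    feats = {}
    for ch, v in zip(labels, mcc.values):
        feats[f"{prefix}_mcc_{ch}"] = float(v)
    for ch, v in zip(labels, p.values):
        feats[f"{prefix}_mpc_{ch}"] = float(v)
    return feats


def epoch_features(
    epoch_data: np.ndarray,
    fs: float,
    axis: str,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    band: Band | None = None,
    n_layers: int = 5,
    window_s: float = 4.0,
) -> dict[str, float]:
    if axis == "frequency":
        net = cross_frequency_network(epoch_data, fs, bands)
        return node_features(net, "freq")
    if axis == "time":
        if band is None:
            band = bands[-1]
        net = time_varying_network(epoch_data, fs, band, n_layers, window_s)
        return node_features(net, f"time_{band.name}")
    raise ValueError("axis must be 'frequency' or 'time'")


def cohort_feature_table(
    cohort: Cohort,
    axis: str,
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    band: Band | None = None,
    n_layers: int = 5,
    window_s: float = 4.0,
    epoch_length: float | None = None,
) -> pd.DataFrame:
    """One feature row per epoch; recordings are cut into contiguous epochs
    of ``epoch_length`` seconds (whole recording = one epoch if omitted)."""
    rows = []
    for rec in cohort:
        epochs = _contiguous_epochs(rec, epoch_length)
        for ei, ep in enumerate(epochs):
            feats = epoch_features(
                ep, rec.fs, axis, bands=bands, band=band, n_layers=n_layers, window_s=window_s
            )
            rows.append({"subject": rec.subject_id, "group": rec.group, "epoch": ei, **feats})
    return pd.DataFrame(rows)


def _contiguous_epochs(rec: EegRecording, epoch_length: float | None) -> list[np.ndarray]:
    if epoch_length is None:
        return [rec.data]
    n = int(round(epoch_length * rec.fs))
    total = rec.n_samples // n
    return [rec.data[:, i * n : (i + 1) * n] for i in range(total)]
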