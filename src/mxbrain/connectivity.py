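"""Phase-locking connectivity estimators: PLV, iPLV and niPLV.

With instantaneous phases phi_k(t), phi_m(t) and the mean phasor

    z = (1/T) * sum_t exp(-i (phi_k(t) - phi_m(t)))

the estimators are

    PLV   = |z|
    iPLV  = |Im z|
    niPLV = |Im z| / sqrt(1 - |Re z|^2)

PLV saturates at 1 for any stable phase difference but is inflated by
zero-lag (volume-conducted) coupling; iPLV suppresses zero-lag coupling but
is bounded by |sin(phi)| for a stable lag phi; niPLV renormalises so that
any stable non-zero lag reaches 1.  When |Re z| -> 1 (pure zero-lag
locking) the niPLV denominator vanishes and the estimator returns 0 by
convention — the measure is designed to discard zero-lag coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .errors import DegenerateSignalError, LengthError, StructureError
from .montage import CHANNELS

#: |Re z| within this distance of 1 counts as a degenerate denominator.
DEGENERATE_TOL = 1e-12

#: Fraction of samples trimmed from each end after the Hilbert transform.
EDGE_TRIM_FRAC = 0.05


@dataclass
class PhaseSeries:
    """Instantaneous phases, channels x samples, already edge-trimmed."""

    phase: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.phase = np.atleast_2d(np.asarray(self.phase, dtype=float))
        if not np.isfinite(self.phase).all():
            raise StructureError("phases must be finite")
        if self.phase.shape[1] < 2:
            raise LengthError("need at least two phase samples")

    @property
    def T(self) -> int:
        return self.phase.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node niPLV weights in [0, 1], zero diagonal."""

    weights: np.ndarray
    channel_labels: tuple[str, ...] = CHANNELS
    band: str | None = None
    window_index: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise StructureError("weights must be square")
        if not np.allclose(w, w.T):
            raise StructureError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise StructureError("diagonal must be zero")
        if w.min() < 0 or w.max() > 1:
            raise StructureError("weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def instantaneous_phase(
    data: np.ndarray, fs: float, trim_frac: float = EDGE_TRIM_FRAC
) -> PhaseSeries:
    """Analytic-signal phase per channel, with ``trim_frac`` of the samples
    cut from each end to limit Hilbert edge (Gibbs) effects.

    The input should already be band-limited."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    sd = data.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise DegenerateSignalError(f"channel {bad} has zero variance")
    phase = np.angle(hilbert(data, axis=-1))
    trim = int(round(trim_frac * phase.shape[1]))
    if trim > 0:
        phase = phase[:, trim:-trim]
    return PhaseSeries(phase=phase, fs=fs)


def _mean_phasor(phi_k: np.ndarray, phi_m: np.ndarray) -> complex:
    phi_k = np.asarray(phi_k, dtype=float).ravel()
    phi_m = np.asarray(phi_m, dtype=float).ravel()
    if phi_k.size != phi_m.size:
        raise LengthError(f"phase series lengths differ: {phi_k.size} vs {phi_m.size}")
    if phi_k.size < 2:
        raise LengthError("need at least two samples")
    return complex(np.mean(np.exp(-1j * (phi_k - phi_m))))


def plv(phi_k: np.ndarray, phi_m: np.ndarray) -> float:
    """Phase locking value: modulus of the mean phasor of the phase difference."""
    return abs(_mean_phasor(phi_k, phi_m))


def iplv(phi_k: np.ndarray, phi_m: np.ndarray) -> float:
    """Imaginary PLV: |Im| of the mean phasor; blind to zero-lag coupling."""
    return abs(_mean_phasor(phi_k, phi_m).imag)


def niplv(phi_k: np.ndarray, phi_m: np.ndarray) -> float:
    """Normalized iPLV; reaches 1 for any stable non-zero lag, 0 for zero lag."""
    z = _mean_phasor(phi_k, phi_m)
    return _niplv_from_phasor(np.array(z))


def _niplv_from_phasor(z: np.ndarray) -> np.ndarray | float:
    re = np.abs(np.real(z))
    denom_sq = 1.0 - re * re
    out = np.zeros_like(re)
    ok = denom_sq > DEGENERATE_TOL
    out = np.where(ok, np.abs(np.imag(z)) / np.sqrt(np.where(ok, denom_sq, 1.0)), 0.0)
    out = np.clip(out, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def connectivity_matrix(
    phases: PhaseSeries,
    channel_labels: tuple[str, ...] | None = None,
    band: str | None = None,
    window_index: int | None = None,
) -> ConnectivityMatrix:
    """niPLV between all channel pairs, computed from one Gram matrix:

    the mean phasor of every pair (k, m) is row k of exp(-i phi) times the
    conjugate of row m, so the full matrix is E @ E^H / T."""
    if phases.phase.shape[0] < 2:
        raise StructureError("need at least two channels")
    e = np.exp(-1j * phases.phase)
    z = (e @ e.conj().T) / phases.T
    w = np.asarray(_niplv_from_phasor(z), dtype=float)
    np.fill_diagonal(w, 0.0)
    w = 0.5 * (w + w.T)  # exact symmetry against fp round-off
    labels = channel_labels
    if labels is None:
        labels = CHANNELS if w.shape[0] == len(CHANNELS) else tuple(
            f"ch{i}" for i in range(w.shape[0])
        )
    return ConnectivityMatrix(weights=w, channel_labels=labels, band=band, window_index=window_index)
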