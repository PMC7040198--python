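"""Epoch selection, amplitude artifact rejection, FIR band decomposition
and sliding-window segmentation.

The artifact rule is purely amplitude-based (any sample exceeding 80 uV on
any channel rejects the whole epoch); epochs are then chosen spread evenly
over the clean epochs that start after an initial skip (default 2 min).
Band decomposition uses a zero-phase windowed-sinc FIR filter.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import filtfilt, firwin

from .errors import InsufficientDataError, LengthError, ParameterError
from .montage import Band
from .recording import Epoch, EegRecording

ARTIFACT_THRESHOLD_UV = 80.0


def reject_artifact_epochs(
    recording: EegRecording,
    epoch_length: float,
    threshold: float = ARTIFACT_THRESHOLD_UV,
) -> list[Epoch]:
    """Cut the recording into consecutive non-overlapping epochs and keep
    those whose peak absolute amplitude stays within ``threshold`` on every
    channel.  Order is preserved; a trailing partial epoch is discarded."""
    n_ep_samples = int(round(epoch_length * recording.fs))
    if n_ep_samples > recording.n_samples:
        raise LengthError(
            f"recording ({recording.duration:.1f} s) shorter than one epoch ({epoch_length} s)"
        )
    n_epochs = recording.n_samples // n_ep_samples
    clean = []
    for i in range(n_epochs):
        seg = recording.data[:, i * n_ep_samples : (i + 1) * n_ep_samples]
        if np.abs(seg).max() <= threshold:
            clean.append(
                Epoch(
                    data=seg,
                    fs=recording.fs,
                    start=i * epoch_length,
                    index=i,
                    subject_id=recording.subject_id,
                )
            )
    return clean


def select_epochs(
    clean: list[Epoch],
    n: int = 4,
    skip_initial: float = 120.0,
) -> list[Epoch]:
    """Pick ``n`` epochs spread evenly over the clean epochs starting after
    ``skip_initial`` seconds: always the first and last eligible epoch plus
    evenly spaced interior ones (positions rounded half-up)."""
    eligible = [e for e in clean if e.start >= skip_initial]
    if len(eligible) < n:
        sid = eligible[0].subject_id if eligible else (clean[0].subject_id if clean else "?")
        raise InsufficientDataError(
            f"subject {sid!r}: {len(eligible)} eligible epochs, need {n}"
        )
    positions = np.floor(np.linspace(0, len(eligible) - 1, n) + 0.5).astype(int)
    return [eligible[p] for p in positions]


def fir_taps(band: Band, fs: float) -> int:
    """Filter length: three sampling cycles of the band's low edge, odd."""
    taps = int(round(3.0 * fs / band.low))
    return taps + 1 if taps % 2 == 0 else taps


def bandpass(data: np.ndarray, fs: float, band: Band) -> np.ndarray:
    """Zero-phase FIR band-pass (windowed sinc, Hamming, forward-backward).

    Output length equals input length.  The input must be comfortably
    longer than the filter (filtfilt pads with 3x the tap count)."""
    band.validate_for(fs)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    taps = fir_taps(band, fs)
    if data.shape[1] <= 3 * taps:
        raise LengthError(
            f"signal of {data.shape[1]} samples too short for the {band.name} "
            f"filter ({taps} taps; need > {3 * taps} samples)"
        )
    h = firwin(taps, [band.low, band.high], pass_zero=False, window="hamming", fs=fs)
    return filtfilt(h, [1.0], data, axis=-1)


def segment_windows(
    data: np.ndarray,
    fs: float,
    width: float = 4.0,
    n_windows: int | None = None,
) -> list[np.ndarray]:
    """Left-aligned consecutive non-overlapping windows of ``width`` seconds.

    A trailing partial window is dropped.  If ``n_windows`` is given, only
    the first that many are returned (error if fewer are available)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    w = int(round(width * fs))
    if w <= 0:
        raise ParameterError("window width must be positive")
    if w > data.shape[1]:
        raise LengthError(f"window ({width} s) longer than the segment")
    total = data.shape[1] // w
    if n_windows is not None:
        if n_windows > total:
            raise InsufficientDataError(f"requested {n_windows} windows, only {total} fit")
        total = n_windows
    return [data[:, i * w : (i + 1) * w] for i in range(total)]


def average_reference(data: np.ndarray) -> np.ndarray:
    """Optional common-average re-reference (off by default in the pipeline)."""
    data = np.asarray(data, dtype=float)
    return data - data.mean(axis=0, keepdims=True)
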