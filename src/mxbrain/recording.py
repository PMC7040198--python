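"""In-memory containers for multichannel EEG."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import StructureError
from .montage import CHANNELS


@dataclass
class EegRecording:
    """A channels x samples voltage array (microvolts) with metadata.

    Channel order follows :data:`mxbrain.montage.CHANNELS` unless custom
    labels are supplied.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = CHANNELS
    subject_id: str = ""
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise StructureError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise StructureError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} channel labels"
            )
        if not np.isfinite(self.data).all():
            raise StructureError("recording contains NaN or Inf samples")
        if self.fs <= 0:
            raise StructureError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """A contiguous analysis segment cut from a recording."""

    data: np.ndarray
    fs: float
    start: float = 0.0  # seconds from recording onset
    index: int = 0      # position in the original epoch grid
    subject_id: str = ""

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class Cohort:
    """An ordered set of labelled recordings (controls first, then patients)."""

    recordings: list[EegRecording] = field(default_factory=list)

    @property
    def groups(self) -> list[str]:
        return [r.group or "" for r in self.recordings]

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.recordings]

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)
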