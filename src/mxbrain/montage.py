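"""The 16-channel 10-20 scalp montage and canonical frequency bands.

Channel order is canonical throughout the package: every connectivity
matrix, layer and node-metric table indexes nodes in this order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

#: Canonical 10-20 labels of the 16-channel montage, in storage order.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4",
    "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
)

#: Anatomical groupings used by the synthetic generator's default topology.
FRONTAL = ("Fp1", "Fp2", "F3", "F4", "F7", "F8")
CENTRAL = ("C3", "C4", "T3", "T4")
POSTERIOR = ("P3", "P4", "O1", "O2", "T5", "T6")


def channel_index(label: str) -> int:
    """Position of ``label`` in the canonical montage order."""
    from .errors import UnknownNameError

    try:
        return CHANNELS.index(label)
    except ValueError:
        raise UnknownNameError(f"unknown channel label {label!r}") from None


@dataclass(frozen=True)
class Band:
    """A frequency band with inclusive pass edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ParameterError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )

    def validate_for(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ParameterError(
                f"band {self.name!r} high edge {self.high} Hz >= Nyquist ({fs / 2} Hz)"
            )

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


#: The four classical EEG rhythms, in canonical layer order.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 12.0),
    Band("beta", 12.0, 30.0),
)

BAND_ORDER: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def band_by_name(name: str) -> Band:
    from .errors import UnknownNameError

    for b in DEFAULT_BANDS:
        if b.name == name:
            return b
    raise UnknownNameError(f"unknown band {name!r}")
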