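"""Shared demo-cohort settings for the numbered analysis scripts.

A deliberately desk-scale design (8 + 8 subjects, two 20 s epochs at
256 Hz) so every script runs in seconds; the planted patient effect is the
default left-occipital beta-coupling loss.
"""

from __future__ import annotations

from pathlib import Path

from mxbrain.montage import DEFAULT_BANDS, band_by_name
from mxbrain.synthdata import (
    CohortSpec,
    default_group_effects,
    default_oscillator_specs,
    generate_cohort,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

SEED = 2020
N_PER_GROUP = 8
EPOCH_S = 20.0
EPOCHS = 2
FS = 256.0
BETA = band_by_name("beta")


def demo_cohort(bands=DEFAULT_BANDS, seed: int = SEED):
    spec = CohortSpec(
        n_per_group=N_PER_GROUP,
        group_effects=default_group_effects(),
        epoch_length=EPOCH_S,
        epochs_per_subject=EPOCHS,
        fs=FS,
        seed=seed,
    )
    base = default_oscillator_specs(bands=bands)
    return generate_cohort(spec, base)
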