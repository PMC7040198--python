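from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mxbrain.montage import band_by_name
from mxbrain.netbuild import Layer, MultiplexNetwork

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

BETA = band_by_name("beta")
ALPHA = band_by_name("alpha")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200218)


def layers_from_weights(layer_weights) -> MultiplexNetwork:
    layers = [
        Layer(weighted=w, binary=(w > 0).astype(int), label=str(i), cost=0.0)
        for i, w in enumerate(layer_weights)
    ]
    return MultiplexNetwork(layers=layers, axis="time")


@pytest.fixture(scope="session")
def beta_subject():
    """One 50 s beta-band subject with the default cluster topology."""
    from mxbrain.synthdata import default_oscillator_specs, generate_subject

    specs = default_oscillator_specs(bands=(BETA,))
    return generate_subject(specs, duration=50.0, fs=256.0, seed=11, subject_id="s-fix")


@pytest.fixture(scope="session")
def small_cohort():
    """2+2 subjects, two 10 s epochs, beta band only — pipeline-scale."""
    from mxbrain.synthdata import (
        CohortSpec,
        default_group_effects,
        default_oscillator_specs,
        generate_cohort,
    )

    spec = CohortSpec(
        n_per_group=2,
        group_effects=default_group_effects(0.3),
        epoch_length=10.0,
        epochs_per_subject=2,
        fs=256.0,
        seed=5,
    )
    return generate_cohort(spec, default_oscillator_specs(bands=(BETA,)))
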