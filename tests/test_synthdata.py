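"""The synthetic-cohort generator: determinism, locked pairs, coupling recovery."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import spearmanr

from mxbrain.connectivity import instantaneous_phase, niplv
from mxbrain.errors import ParameterError, StructureError, UnknownNameError
from mxbrain.montage import CHANNELS, band_by_name
from mxbrain.synthdata import (
    CohortSpec,
    OscillatorSpec,
    default_group_effects,
    default_oscillator_specs,
    generate_cohort,
    generate_locked_pair,
    generate_subject,
)

BETA = band_by_name("beta")
ALPHA = band_by_name("alpha")


def pair_niplv(x, y, fs):
    ps = instantaneous_phase(np.vstack([x, y]), fs)
    return niplv(ps.phase[0], ps.phase[1])


class TestLockedPair:
    def test_infinite_concentration_saturates_niplv(self):
        x, y = generate_locked_pair(np.pi / 2, np.inf, T=2560, fs=256, carrier=10, seed=1)
        assert pair_niplv(x, y, 256) == pytest.approx(1.0, abs=1e-6)

    def test_zero_lag_is_suppressed(self):
        x, y = generate_locked_pair(0.0, np.inf, T=2560, fs=256, carrier=10, seed=1)
        assert pair_niplv(x, y, 256) == pytest.approx(0.0, abs=1e-6)

    def test_independent_phases_give_near_zero_niplv(self):
        # concentration 0 = two unrelated phase walks; long series so the
        # phasor mean concentrates near its null value
        x, y = generate_locked_pair(np.pi / 4, 0.0, T=200 * 256, fs=256, carrier=10, seed=3)
        assert pair_niplv(x, y, 256) < 0.05

    def test_dispersion_shrinks_with_concentration(self):
        # niPLV should rank with concentration across seeds (pooled Spearman)
        kappas = [0.5, 1.0, 2.0, 4.0]
        ks, vals = [], []
        for kappa in kappas:
            for seed in range(50):
                x, y = generate_locked_pair(np.pi / 2, kappa, T=2560, fs=256, carrier=10, seed=seed)
                ks.append(kappa)
                vals.append(pair_niplv(x, y, 256))
        rho = spearmanr(ks, vals).statistic
        assert rho > 0.95
        means = [np.mean([v for k, v in zip(ks, vals) if k == kk]) for kk in kappas]
        assert np.all(np.diff(means) > 0)

    def test_invalid_carrier_rejected(self):
        with pytest.raises(ParameterError):
            generate_locked_pair(0.1, 1.0, T=100, fs=100, carrier=60, seed=0)
        with pytest.raises(ParameterError):
            generate_locked_pair(0.1, 1.0, T=1, fs=100, carrier=10, seed=0)


class TestGenerateSubject:
    def test_same_seed_is_bit_identical(self):
        specs = default_oscillator_specs(bands=(BETA,))
        a = generate_subject(specs, 5.0, 256.0, seed=9)
        b = generate_subject(specs, 5.0, 256.0, seed=9)
        assert np.array_equal(a.data, b.data)
        c = generate_subject(specs, 5.0, 256.0, seed=10)
        assert not np.array_equal(a.data, c.data)

    def test_uncoupled_channels_have_low_niplv(self):
        # null level is band-limited: a 50 s alpha epoch carries roughly
        # duration x bandwidth ~ 200 effective samples per pair, so the max
        # over the 120 pairs sits near 0.2.  Bounds frozen from a 40-seed
        # Monte-Carlo null (mean-of-max 0.19, never above 0.27).
        n = len(CHANNELS)
        spec = OscillatorSpec(band=ALPHA, coupling=np.zeros((n, n)))
        for seed in (0, 1, 2):
            rec = generate_subject([spec], 50.0, 256.0, seed=seed)
            from mxbrain.connectivity import connectivity_matrix
            from mxbrain.preprocess import bandpass

            filt = bandpass(rec.data, 256.0, ALPHA)
            w = connectivity_matrix(instantaneous_phase(filt, 256.0)).weights
            iu = np.triu_indices(n, k=1)
            assert w[iu].mean() <= 0.1
            assert w[iu].max() <= 0.3

    def test_coupled_pair_outranks_all_uncoupled_pairs(self):
        n = len(CHANNELS)
        labels = list(CHANNELS)
        i, j = labels.index("O1"), labels.index("T5")
        coupling = np.zeros((n, n))
        coupling[i, j] = coupling[j, i] = 40.0
        lag = np.zeros((n, n))
        lag[i, j], lag[j, i] = np.pi / 3, -np.pi / 3
        spec = OscillatorSpec(band=ALPHA, coupling=coupling, phase_lag=lag)
        rec = generate_subject([spec], 30.0, 256.0, seed=4)
        from mxbrain.connectivity import connectivity_matrix
        from mxbrain.preprocess import bandpass

        filt = bandpass(rec.data, 256.0, ALPHA)
        w = connectivity_matrix(instantaneous_phase(filt, 256.0)).weights
        coupled = w[i, j]
        others = [w[a, b] for a in range(n) for b in range(a + 1, n) if {a, b} != {i, j}]
        assert coupled > max(others)

    def test_niplv_monotone_in_coupling_strength(self):
        n = len(CHANNELS)
        labels = list(CHANNELS)
        i, j = labels.index("O1"), labels.index("T5")
        grid = [0.0, 5.0, 10.0, 20.0, 40.0]
        ks, vals = [], []
        from mxbrain.connectivity import connectivity_matrix
        from mxbrain.preprocess import bandpass

        for strength in grid:
            coupling = np.zeros((n, n))
            coupling[i, j] = coupling[j, i] = strength
            lag = np.zeros((n, n))
            lag[i, j], lag[j, i] = np.pi / 3, -np.pi / 3
            spec = OscillatorSpec(band=ALPHA, coupling=coupling, phase_lag=lag)
            for seed in range(50):
                rec = generate_subject([spec], 10.0, 256.0, seed=seed)
                filt = bandpass(rec.data, 256.0, ALPHA)
                w = connectivity_matrix(instantaneous_phase(filt, 256.0)).weights
                ks.append(strength)
                vals.append(w[i, j])
        assert spearmanr(ks, vals).statistic > 0.9

    def test_mismatched_node_counts_rejected(self):
        good = OscillatorSpec(band=BETA, coupling=np.zeros((16, 16)))
        bad = OscillatorSpec(band=ALPHA, coupling=np.zeros((4, 4)))
        with pytest.raises(StructureError):
            generate_subject([good, bad], 2.0, 256.0, seed=0)


class TestGenerateCohort:
    def test_bookkeeping_labels_and_order(self):
        spec = CohortSpec(n_per_group=2, epoch_length=2.0, epochs_per_subject=1,
                          fs=256.0, seed=0)
        cohort = generate_cohort(spec, default_oscillator_specs(bands=(BETA,)))
        assert len(cohort) == 4
        assert cohort.groups == ["control", "control", "patient", "patient"]
        assert len(set(cohort.subject_ids)) == 4

    def test_effect_modifies_patients_only(self):
        effects = default_group_effects(0.0)
        spec = CohortSpec(n_per_group=1, group_effects=effects, epoch_length=5.0,
                          epochs_per_subject=1, fs=256.0, seed=1)
        base = default_oscillator_specs(bands=(BETA,))
        cohort = generate_cohort(spec, base)
        spec_null = CohortSpec(n_per_group=1, epoch_length=5.0, epochs_per_subject=1,
                               fs=256.0, seed=1)
        cohort_null = generate_cohort(spec_null, base)
        # controls identical, patients differ once the effect is applied
        assert np.array_equal(cohort.recordings[0].data, cohort_null.recordings[0].data)
        assert not np.array_equal(cohort.recordings[1].data, cohort_null.recordings[1].data)

    def test_unknown_band_or_node_rejected(self):
        base = default_oscillator_specs(bands=(BETA,))
        spec = CohortSpec(n_per_group=1, group_effects=[("gamma", [("O1", "O2")], 0.5)],
                          epoch_length=2.0, epochs_per_subject=1, fs=256.0)
        with pytest.raises(UnknownNameError):
            generate_cohort(spec, base)
        spec = CohortSpec(n_per_group=1, group_effects=[("beta", [("O1", "Oz")], 0.5)],
                          epoch_length=2.0, epochs_per_subject=1, fs=256.0)
        with pytest.raises(UnknownNameError):
            generate_cohort(spec, base)

    def test_nyquist_guard(self):
        spec = CohortSpec(n_per_group=1, epoch_length=2.0, epochs_per_subject=1, fs=50.0)
        with pytest.raises(ParameterError):
            generate_cohort(spec, default_oscillator_specs(bands=(BETA,)))
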