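"""Synthetic EEG cohorts with controllable band-limited phase locking.

Real resting-state recordings of the kind this pipeline targets are not
publicly distributable, so every downstream stage is exercised on synthetic
cohorts whose ground truth is known.  Signals are produced by a stochastic
Kuramoto model with pairwise target phase lags: within each frequency band
the channel phases evolve by a discrete Euler update

    theta_k[t+1] = theta_k[t] + dt * omega_k
                   + dt * sum_m K_km * sin(theta_m - theta_k + lag_km)
                   + sqrt(dt) * sigma * xi_k[t]

where ``K`` is the symmetric coupling matrix (rad/s), ``lag_km`` the
antisymmetric target of ``theta_k - theta_m`` and ``sigma`` a phase-noise
scale (rad/sqrt(s)).  The observed channel signal is the sum over bands of
``amplitude * cos(theta)`` plus additive white measurement noise.

All randomness flows from one root seed through ``numpy.random.SeedSequence``
spawning: cohort seed -> one child per subject -> one child per band plus one
for measurement noise.  Identical spec + seed therefore reproduces bit-
identical arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, StructureError, UnknownNameError
from .montage import CENTRAL, CHANNELS, DEFAULT_BANDS, FRONTAL, POSTERIOR, Band
from .recording import Cohort, EegRecording

#: Seconds of simulation discarded before recording starts, so that coupled
#: oscillators reach their phase-locked regime (lock time ~ 1/K << 2 s).
BURN_IN_S = 2.0

#: Default phase-noise scale (rad/sqrt(s)).  Uncoupled pairs decorrelate in
#: well under a second; the residual spurious niPLV over an epoch is then
#: limited by the band-pass filter bandwidth (roughly duration x bandwidth
#: effective samples), not by this constant.  Pairs coupled at the default
#: strength keep a lag dispersion of ~0.15 rad and hence niPLV near 1.
PHASE_NOISE_SD = 1.5


@dataclass
class OscillatorSpec:
    """One frequency band's coupled-oscillator parameters.

    coupling[k, m] is the pull strength (rad/s) between channels k and m;
    phase_lag[k, m] is the target of theta_k - theta_m (radians) and must be
    antisymmetric.  amplitude is the per-channel cosine amplitude in
    microvolts; noise_sd the additive white measurement-noise SD in
    microvolts.
    """

    band: Band
    coupling: np.ndarray
    phase_lag: np.ndarray | None = None
    amplitude: np.ndarray | float = 10.0
    noise_sd: float = 2.0
    phase_noise_sd: float = PHASE_NOISE_SD
    freq_jitter: float | None = None  # Hz half-width of per-channel detuning

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        n = self.coupling.shape[0]
        if self.coupling.shape != (n, n):
            raise StructureError("coupling must be square")
        if not np.allclose(self.coupling, self.coupling.T):
            raise StructureError("coupling matrix must be symmetric")
        if np.any(np.diag(self.coupling) != 0):
            raise StructureError("coupling diagonal must be zero")
        if np.any(self.coupling < 0):
            raise StructureError("coupling strengths must be nonnegative")
        if self.phase_lag is None:
            self.phase_lag = np.zeros((n, n))
        self.phase_lag = np.asarray(self.phase_lag, dtype=float)
        if self.phase_lag.shape != (n, n):
            raise StructureError("phase_lag must match coupling shape")
        if not np.allclose(self.phase_lag, -self.phase_lag.T):
            raise StructureError("phase_lag must be antisymmetric")
        if self.noise_sd < 0:
            raise StructureError("noise_sd must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.coupling.shape[0]


@dataclass
class CohortSpec:
    """Study-design parameters of a two-group synthetic cohort.

    Defaults mirror the emulated study design: 20 subjects per group, four
    50 s epochs per subject, 16 channels sampled at 1024 Hz.  group_effects
    lists (band_name, node-pair set, coupling multiplier) triples applied to
    the patient group only.
    """

    n_per_group: int = 20
    group_effects: list[tuple[str, list[tuple[str, str]], float]] = field(default_factory=list)
    epoch_length: float = 50.0
    epochs_per_subject: int = 4
    fs: float = 1024.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ParameterError("n_per_group must be >= 1")
        for _, _, mult in self.group_effects:
            if mult < 0:
                raise ParameterError("coupling multipliers must be >= 0")

    def validate_against(self, specs: list[OscillatorSpec]) -> None:
        top = max(s.band.high for s in specs)
        if self.fs <= 2 * top:
            raise ParameterError(
                f"fs={self.fs} Hz must exceed twice the highest band edge ({top} Hz)"
            )
        names = {s.band.name for s in specs}
        labels = set(CHANNELS)
        for band_name, pairs, _ in self.group_effects:
            if band_name not in names:
                raise UnknownNameError(f"group effect references unknown band {band_name!r}")
            for a, b in pairs:
                if a not in labels or b not in labels:
                    raise UnknownNameError(f"group effect references unknown channel in ({a}, {b})")


# ---------------------------------------------------------------------------
# low-level simulators


def _simulate_phases(
    omega: np.ndarray,
    coupling: np.ndarray,
    lag: np.ndarray,
    sigma: float,
    fs: float,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Euler-integrate the lagged Kuramoto system; returns (N, n_samples) phases.

    The pairwise drive is evaluated with one complex matvec per step via
    sum_m K_km sin(theta_m - theta_k + lag_km)
        = Im( (K * exp(i lag) @ exp(i theta)) * exp(-i theta) ).
    """
    dt = 1.0 / fs
    n = omega.size
    burn = int(round(BURN_IN_S * fs))
    total = burn + n_samples
    b_mat = coupling * np.exp(1j * lag)
    noise = rng.standard_normal((total, n)) * (sigma * math.sqrt(dt))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    out = np.empty((n, n_samples))
    drift = omega * dt
    for t in range(total):
        e = np.exp(1j * theta)
        drive = np.imag((b_mat @ e) * np.conj(e))
        theta = theta + drift + dt * drive + noise[t]
        if t >= burn:
            out[:, t - burn] = theta
    return out


def generate_locked_pair(
    lag: float,
    concentration: float,
    T: int,
    fs: float,
    carrier: float,
    seed: int,
    amplitude: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two narrowband signals with a controlled phase-difference distribution.

    The instantaneous phase difference is dispersed around ``lag`` like a
    wrapped normal with variance 1/``concentration``: infinite concentration
    gives an exactly constant lag, zero concentration gives two independent
    phase processes.  Used to validate the phase-locking estimators against
    known ground truth.
    """
    if not 0 < carrier < fs / 2:
        raise ParameterError(f"carrier {carrier} Hz must lie in (0, Nyquist={fs / 2})")
    if T < 2:
        raise ParameterError("need at least two samples")
    if concentration < 0:
        raise ParameterError("concentration must be nonnegative")
    rng = np.random.default_rng(seed)
    t = np.arange(T) / fs
    base = 2.0 * np.pi * carrier * t + rng.uniform(0.0, 2.0 * np.pi)
    dt = 1.0 / fs
    if concentration == 0:
        # independent phases: separate Brownian phase walks on the carrier
        walk_sd = 2.0  # rad/sqrt(s)
        w1 = np.cumsum(rng.standard_normal(T)) * (walk_sd * math.sqrt(dt))
        w2 = np.cumsum(rng.standard_normal(T)) * (walk_sd * math.sqrt(dt))
        phi1, phi2 = base + w1, base - lag + w2
    elif math.isinf(concentration):
        phi1, phi2 = base, base - lag
    else:
        # Ornstein-Uhlenbeck jitter with stationary SD 1/sqrt(concentration)
        sd = 1.0 / math.sqrt(concentration)
        tau = 0.1  # s correlation time; slow relative to the carrier
        a = math.exp(-dt / tau)
        innov = rng.standard_normal(T) * (sd * math.sqrt(1.0 - a * a))
        jitter = np.empty(T)
        prev = rng.standard_normal() * sd
        for i in range(T):
            prev = a * prev + innov[i]
            jitter[i] = prev
        phi1, phi2 = base, base - lag - jitter
    return amplitude * np.cos(phi1), amplitude * np.cos(phi2)


def generate_subject(
    specs: list[OscillatorSpec],
    duration: float,
    fs: float,
    seed: int | np.random.SeedSequence,
    subject_id: str = "",
    group: str | None = None,
) -> EegRecording:
    """Simulate one subject: per-band lagged-Kuramoto phases summed into channels.

    Per band, each channel's natural frequency is the band centre plus a
    uniform detuning of half-width ``freq_jitter`` (default: the smaller of
    1 Hz and a quarter of the band width), so natural frequencies always lie
    inside the band.  Deterministic given spec + seed.
    """
    n_nodes = {s.n_nodes for s in specs}
    if len(n_nodes) != 1:
        raise StructureError(f"oscillator specs disagree on node count: {sorted(n_nodes)}")
    n = n_nodes.pop()
    if n != len(CHANNELS):
        raise StructureError(f"expected {len(CHANNELS)} channels, got {n}")
    for s in specs:
        s.band.validate_for(fs)
    n_samples = int(round(duration * fs))
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = seq.spawn(len(specs) + 1)
    data = np.zeros((n, n_samples))
    for spec, child in zip(specs, children[:-1]):
        rng = np.random.default_rng(child)
        jitter = spec.freq_jitter
        if jitter is None:
            jitter = min(1.0, spec.band.width / 4.0)
        freqs = spec.band.center + rng.uniform(-jitter, jitter, size=n)
        omega = 2.0 * np.pi * freqs
        phases = _simulate_phases(
            omega, spec.coupling, spec.phase_lag, spec.phase_noise_sd, fs, n_samples, rng
        )
        amp = np.broadcast_to(np.atleast_1d(np.asarray(spec.amplitude, float)), (n,))
        data += amp[:, None] * np.cos(phases)
    noise_rng = np.random.default_rng(children[-1])
    noise_sd = max(s.noise_sd for s in specs) if specs else 0.0
    if noise_sd > 0:
        data += noise_rng.normal(0.0, noise_sd, size=data.shape)
    return EegRecording(data, fs, CHANNELS, subject_id=subject_id, group=group)


def apply_group_effects(
    specs: list[OscillatorSpec],
    effects: list[tuple[str, list[tuple[str, str]], float]],
) -> list[OscillatorSpec]:
    """Return patient-group specs: coupling multipliers applied pairwise."""
    labels = list(CHANNELS)
    out = []
    for spec in specs:
        coupling = spec.coupling.copy()
        for band_name, pairs, mult in effects:
            if band_name != spec.band.name:
                continue
            for a, b in pairs:
                if a not in labels or b not in labels:
                    raise UnknownNameError(f"unknown channel in effect pair ({a}, {b})")
                i, j = labels.index(a), labels.index(b)
                coupling[i, j] *= mult
                coupling[j, i] *= mult
        out.append(replace(spec, coupling=coupling, phase_lag=spec.phase_lag.copy()))
    return out


def generate_cohort(cohort: CohortSpec, base: list[OscillatorSpec]) -> Cohort:
    """Simulate a two-group cohort: controls use ``base``, patients the
    effect-modified specs.  Epochs are contiguous within each recording."""
    cohort.validate_against(base)
    patient_specs = apply_group_effects(base, cohort.group_effects)
    duration = cohort.epoch_length * cohort.epochs_per_subject
    root = np.random.SeedSequence(cohort.seed)
    children = root.spawn(2 * cohort.n_per_group)
    recs = []
    for g, (group, specs) in enumerate([("control", base), ("patient", patient_specs)]):
        for i in range(cohort.n_per_group):
            child = children[g * cohort.n_per_group + i]
            sid = f"{'ctl' if group == 'control' else 'pat'}-{i + 1:02d}"
            recs.append(
                generate_subject(specs, duration, cohort.fs, child, subject_id=sid, group=group)
            )
    return Cohort(recs)


# ---------------------------------------------------------------------------
# default study topology


def coupling_from_clusters(
    clusters: list[tuple[tuple[str, ...], float]],
    offset_span: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (coupling, phase_lag) from within-cluster all-to-all coupling.

    Each cluster's channels receive evenly spaced phase offsets over
    ``offset_span`` radians; pairwise target lags are offset differences,
    which is globally consistent (every locked pair holds a constant,
    non-zero lag, so niPLV can detect it)."""
    n = len(CHANNELS)
    coupling = np.zeros((n, n))
    lag = np.zeros((n, n))
    labels = list(CHANNELS)
    for members, strength in clusters:
        idx = [labels.index(m) for m in members]
        offsets = np.linspace(0.0, offset_span, len(idx))
        for a, oa in zip(idx, offsets):
            for b, ob in zip(idx, offsets):
                if a == b:
                    continue
                coupling[a, b] = strength
                lag[a, b] = oa - ob
    return coupling, lag


def default_oscillator_specs(
    bands: tuple[Band, ...] = DEFAULT_BANDS,
    strength: float = 30.0,
) -> list[OscillatorSpec]:
    """The default cohort topology: three anatomical clusters per band.

    Frontal and posterior clusters are strongly coupled internally
    (``strength`` rad/s), the central/temporal cluster at two thirds of
    that; clusters are mutually uncoupled.  The same topology is used in
    every band so cross-frequency multiplexes have non-trivial structure.
    """
    clusters = [
        (FRONTAL, strength),
        (POSTERIOR, strength),
        (CENTRAL, 2.0 * strength / 3.0),
    ]
    coupling, lag = coupling_from_clusters(clusters)
    return [OscillatorSpec(band=b, coupling=coupling.copy(), phase_lag=lag.copy()) for b in bands]


def o1_posterior_pairs() -> list[tuple[str, str]]:
    """All posterior-cluster pairs involving O1 (the planted-effect site)."""
    return [("O1", ch) for ch in POSTERIOR if ch != "O1"]


def default_group_effects(multiplier: float = 0.0) -> list[tuple[str, list[tuple[str, str]], float]]:
    """Default patient-group effect: loss of beta-band coupling at the left
    occiput (O1's posterior-cluster edges).

    The default multiplier is 0 because coupled-oscillator locking has a
    sharp synchronization threshold: reducing the coupling while staying
    above ~half the detuning spread leaves the pair locked and produces no
    observable connectivity change.  Only coupling below that threshold -
    in the limit, removal - emulates a detectable loss of functional
    connectivity.
    """
    return [("beta", o1_posterior_pairs(), multiplier)]
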