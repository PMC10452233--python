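"""Synthetic task-EEG cohorts with known envelope-coupling ground truth.

The generator emulates the structure the downstream analysis assumes:
band-limited oscillatory ROI sources whose slow log-amplitude envelopes
carry planted pairwise correlations, independent carrier phases across
ROIs (so no genuine zero-lag coupling exists), instantaneous lead-field
mixing to sensors, additive white sensor noise, and a stimulus-locked
epoch structure.  Three subject groups can differ by scaling the planted
envelope couplings.

Latent log-envelopes are smooth Gaussian processes (low-pass filtered
white noise).  To make the *realized* sample correlation of the latent
envelopes equal the requested rho exactly — smooth processes otherwise
carry large sample-correlation noise — the independent processes are
empirically whitened and recombined through the Cholesky factor of the
target correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .preprocess import SensorEpochs, epoch_and_baseline

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupEffect:
    """Per-group perturbation: multiply planted rho on `edges` by rho_scale.

    edges=None applies the scale to every planted coupling.
    """

    rho_scale: float = 1.0
    edges: tuple[tuple[int, int], ...] | None = None


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_subjects_per_group: int = 5
    groups: tuple[str, ...] = ("HC", "CS", "SS")
    n_sensors: int = 32
    n_rois: int = 68
    dipoles_per_roi: int = 3
    fs: float = 256.0
    n_epochs: int = 30
    epoch_window: tuple[float, float] = (-100.0, 500.0)
    band: tuple[float, float] = (13.0, 30.0)
    coupling_spec: tuple[tuple[int, int, float], ...] = ()
    group_effects: dict[str, GroupEffect] = field(default_factory=dict)
    snr: float = 3.0
    #: log-std of the amplitude envelope exp(s*e): modulation depth.
    env_log_std: float = 2.0
    #: cutoff of the latent envelope process; None -> band centre / 10.
    latent_cutoff: float | None = None
    #: relative amplitude of per-dipole private noise within an ROI.
    dipole_noise: float = 0.1
    isi_ms: tuple[float, float] = (800.0, 1200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be >= 1")
        lo, hi = self.band
        if self.fs <= 2 * hi:
            raise ValueError(f"fs={self.fs} Hz aliases band up to {hi} Hz")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        for i, j, rho in self.coupling_spec:
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"rho={rho} outside [0, 1]")
            if i == j or not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError(f"bad ROI pair ({i}, {j})")
        for g in self.group_effects:
            if g not in self.groups:
                raise ValueError(f"group effect for unknown group {g!r}")

    @property
    def n_dipoles(self) -> int:
        return self.n_rois * self.dipoles_per_roi

    @property
    def latent_cutoff_hz(self) -> float:
        if self.latent_cutoff is not None:
            return self.latent_cutoff
        return (self.band[0] + self.band[1]) / 2.0 / 10.0


@dataclass
class GroundTruth:
    """What was planted: per-pair requested and realized latent correlation."""

    coupled_pairs: list[tuple[int, int, float, float]]
    group_effects: dict[str, GroupEffect] = field(default_factory=dict)
    subject_seeds: dict[str, int] = field(default_factory=dict)


@dataclass
class LeadField:
    """Forward operator: gain (sensors x dipoles*3), 3 columns per dipole."""

    gain: np.ndarray
    dipole_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2 or self.gain.shape[1] % 3:
            raise ValueError("gain must be (sensors, 3*dipoles)")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("non-finite lead field")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_dipoles(self) -> int:
        return self.gain.shape[1] // 3


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    seed: int
    continuous: np.ndarray          # sensors x samples
    onsets: np.ndarray              # stimulus onsets, sample indices
    epochs: SensorEpochs
    ground_truth: GroundTruth
    fs: float


@dataclass
class Cohort:
    config: SimulationConfig
    leadfield: LeadField
    subjects: list[SubjectRecord]

    @property
    def labels(self) -> list[str]:
        return [s.group for s in self.subjects]


def _smooth_standard_normal(n_series: int, n_samples: int, fs: float,
                            cutoff: float, rng: np.random.Generator) -> np.ndarray:
    """Low-pass filtered white noise, standardized per row.

    Generated with generous padding (trimmed afterwards) so that the long
    filter transient at a low cutoff never leaks into the series.
    """
    pad = int(10 * fs / cutoff)
    z = rng.standard_normal((n_series, n_samples + 2 * pad))
    sos = signal.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    z = signal.sosfiltfilt(sos, z, axis=-1)[:, pad:pad + n_samples]
    z = z - z.mean(axis=-1, keepdims=True)
    sd = z.std(axis=-1, keepdims=True)
    return z / np.maximum(sd, np.finfo(float).tiny)


def _exact_correlated(target_corr: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Recombine rows of z so their sample correlation matrix equals target_corr.

    Rows are centred, empirically whitened (Cholesky of the sample
    covariance), then mixed by the Cholesky factor of the target matrix.
    Requires more samples than rows.
    """
    n, t = z.shape
    if t <= n:
        raise ValueError("need more samples than processes for exact whitening")
    zc = z - z.mean(axis=-1, keepdims=True)
    cov = zc @ zc.T / t
    lw = np.linalg.cholesky(cov)
    white = np.linalg.solve(lw, zc)          # rows: unit variance, uncorrelated
    eig_floor = np.linalg.eigvalsh(target_corr).min()
    if eig_floor < -1e-10:
        raise ValueError("coupling specification is not positive semidefinite")
    lt = np.linalg.cholesky(target_corr + 1e-12 * np.eye(n))
    return lt @ white


def _coupling_matrix(config: SimulationConfig,
                     coupling: tuple[tuple[int, int, float], ...]) -> np.ndarray:
    c = np.eye(config.n_rois)
    seen = set()
    for i, j, rho in coupling:
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"pair {key} planted more than once")
        seen.add(key)
        c[i, j] = c[j, i] = rho
    return c


def effective_coupling(config: SimulationConfig,
                       group: str | None) -> tuple[tuple[int, int, float], ...]:
    """Apply the group's effect to the cohort coupling specification."""
    eff = config.group_effects.get(group) if group else None
    if eff is None:
        return tuple(config.coupling_spec)
    sel = None if eff.edges is None else {(min(i, j), max(i, j)) for i, j in eff.edges}
    out = []
    for i, j, rho in config.coupling_spec:
        if sel is None or (min(i, j), max(i, j)) in sel:
            rho = float(np.clip(rho * eff.rho_scale, 0.0, 1.0))
        out.append((i, j, rho))
    return tuple(out)


def make_onsets(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Stimulus onsets (sample indices) with jittered inter-stimulus intervals."""
    lo, hi = config.isi_ms
    gaps_s = rng.uniform(lo, hi, size=config.n_epochs) / 1000.0
    pad = max(0.2, abs(config.epoch_window[0]) / 1000.0 + 0.1)
    times = pad + np.cumsum(gaps_s) - gaps_s[0]
    return np.round(times * config.fs).astype(int)


def generate_source_signals(
    config: SimulationConfig,
    subject_seed: int,
    duration: float | None = None,
    coupling: tuple[tuple[int, int, float], ...] | None = None,
) -> tuple[np.ndarray, GroundTruth, np.ndarray]:
    """Generate dipole x time source series plus its ground truth.

    Each ROI carries one band-limited noise carrier, amplitude-modulated by
    exp(s*e_roi) with e_roi a smooth standard-normal log-envelope; planted
    pairs share latent variance so that corr(e_i, e_j) = rho exactly.
    Dipoles within an ROI replicate the ROI signal plus small private
    band-limited noise.  Returns (sources, ground_truth, onsets); onsets are
    empty when an explicit duration is given.
    """
    rng = np.random.default_rng(subject_seed)
    coupling = tuple(config.coupling_spec) if coupling is None else tuple(coupling)
    cfg_check = replace(config, coupling_spec=coupling)  # re-validate rho/indices

    if duration is None:
        onsets = make_onsets(config, rng)
        t_end = onsets[-1] / config.fs + config.epoch_window[1] / 1000.0 + 0.2
        n_samples = int(np.ceil(t_end * config.fs))
    else:
        onsets = np.array([], dtype=int)
        n_samples = int(round(duration * config.fs))
    if n_samples <= cfg_check.n_rois:
        raise ValueError("recording too short for the requested ROI count")

    # latent log-envelopes with exact pairwise correlations
    z = _smooth_standard_normal(config.n_rois, n_samples, config.fs,
                                config.latent_cutoff_hz, rng)
    env = _exact_correlated(_coupling_matrix(cfg_check, coupling), z)

    # band-limited noise carriers, independent across ROIs
    lo, hi = config.band
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=config.fs, output="sos")
    cpad = int(10 * config.fs / lo)
    carriers = signal.sosfiltfilt(
        sos, rng.standard_normal((config.n_rois, n_samples + 2 * cpad)),
        axis=-1)[:, cpad:cpad + n_samples]
    carriers /= np.maximum(carriers.std(axis=-1, keepdims=True),
                           np.finfo(float).tiny)

    roi_signals = np.exp(config.env_log_std * env) * carriers

    # dipole expansion: ROI signal + small private band-limited noise
    k = config.dipoles_per_roi
    sources = np.repeat(roi_signals, k, axis=0)
    if config.dipole_noise > 0:
        priv = signal.sosfiltfilt(
            sos, rng.standard_normal((sources.shape[0],
                                      n_samples + 2 * cpad)),
            axis=-1)[:, cpad:cpad + n_samples]
        priv /= np.maximum(priv.std(axis=-1, keepdims=True), np.finfo(float).tiny)
        sources = sources + (config.dipole_noise
                             * roi_signals.std(axis=-1).repeat(k)[:, None] * priv)

    realized = [(i, j, rho, float(np.corrcoef(env[i], env[j])[0, 1]))
                for i, j, rho in coupling]
    gt = GroundTruth(coupled_pairs=realized,
                     group_effects=dict(config.group_effects))
    return sources, gt, onsets


def roi_labels(config: SimulationConfig) -> np.ndarray:
    """Dipole -> ROI index map for the generated source grid."""
    return np.repeat(np.arange(config.n_rois), config.dipoles_per_roi)


def make_random_leadfield(n_sensors: int, n_dipoles: int, seed: int = 0,
                          smooth: float = 0.5) -> LeadField:
    """Random smooth lead field with a random orthogonal 3-triad per dipole.

    Sensor topographies are mildly smoothed Gaussian vectors; the three
    orientation columns of each dipole are orthonormalized (QR) and given a
    log-normal dipole gain.  Smoothing is kept mild because strongly
    smoothed random topographies become nearly collinear across dipoles,
    which genuinely degrades minimum-norm localization.
    """
    rng = np.random.default_rng(seed)
    gain = np.empty((n_sensors, 3 * n_dipoles))
    for d in range(n_dipoles):
        b = rng.standard_normal((n_sensors, 3))
        if smooth > 0 and n_sensors > 4:
            # cheap spatial smoothing across the sensor index
            kernel = np.exp(-0.5 * (np.arange(-3, 4) / smooth) ** 2)
            kernel /= kernel.sum()
            b = np.apply_along_axis(
                lambda c: np.convolve(np.pad(c, 3, mode="edge"), kernel,
                                      mode="valid"), 0, b)
        q, _ = np.linalg.qr(b)
        gain[:, 3 * d:3 * d + 3] = q * np.exp(rng.normal(0.0, 0.3))
    return LeadField(gain=gain)


def random_orientations(n_dipoles: int, rng: np.random.Generator) -> np.ndarray:
    """Fixed unit orientation vector per dipole."""
    v = rng.standard_normal((n_dipoles, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def mix_to_sensors(sources: np.ndarray, leadfield: LeadField, snr: float,
                   seed: int,
                   orientations: np.ndarray | None = None,
                   config: SimulationConfig | None = None,
                   onsets: np.ndarray | None = None):
    """Instantaneous lead-field mixing plus white sensor noise at the given SNR.

    Returns the continuous sensor array, or (continuous, SensorEpochs) when a
    config and onsets are supplied.  snr is the ratio of the mean sensor
    signal power to the noise power.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    sources = np.asarray(sources, dtype=float)
    rng = np.random.default_rng(seed)

    if leadfield.gain.shape[1] == sources.shape[0]:
        # already one column per (collapsed) source: direct mixing
        eff = leadfield.gain
    else:
        if leadfield.n_dipoles != sources.shape[0]:
            raise ValueError("lead field / source dimension mismatch")
        if orientations is None:
            orientations = random_orientations(leadfield.n_dipoles, rng)
        g3 = leadfield.gain.reshape(leadfield.n_sensors, leadfield.n_dipoles, 3)
        eff = np.einsum("sdk,dk->sd", g3, orientations)

    clean = eff @ sources
    sig_power = float(np.mean(clean ** 2))
    noise = rng.standard_normal(clean.shape) * np.sqrt(sig_power / snr)
    sensors = clean + noise
    if config is None or onsets is None:
        return sensors
    epochs = epoch_and_baseline(sensors, config.fs, onsets,
                                window=config.epoch_window)
    return sensors, epochs


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full multi-group cohort deterministically from the master seed."""
    if not config.groups:
        raise ValueError("empty group list")
    master = np.random.SeedSequence(config.seed)
    lf_seed, orient_seed, *subject_seeds = [
        int(s.generate_state(1)[0] % (2 ** 31))
        for s in master.spawn(2 + len(config.groups) * config.n_subjects_per_group)]
    leadfield = make_random_leadfield(config.n_sensors, config.n_dipoles,
                                      seed=lf_seed)
    orientations = random_orientations(config.n_dipoles,
                                       np.random.default_rng(orient_seed))

    subjects = []
    idx = 0
    for group in config.groups:
        coupling = effective_coupling(config, group)
        for k in range(config.n_subjects_per_group):
            seed = subject_seeds[idx]
            sources, gt, onsets = generate_source_signals(
                config, seed, coupling=coupling)
            _, epochs = mix_to_sensors(sources, leadfield, config.snr, seed + 1,
                                       orientations=orientations, config=config,
                                       onsets=onsets)
            continuous = mix_to_sensors(sources, leadfield, config.snr, seed + 1,
                                        orientations=orientations)
            sid = f"{group}{k:03d}"
            gt.subject_seeds[sid] = seed
            subjects.append(SubjectRecord(
                subject_id=sid, group=group, seed=seed, continuous=continuous,
                onsets=onsets, epochs=epochs, ground_truth=gt, fs=config.fs))
            idx += 1
    return Cohort(config=config, leadfield=leadfield, subjects=subjects)
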