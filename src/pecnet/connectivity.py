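"""Orthogonalized power-envelope connectivity (PEC).

For a node pair with analytic signals X(t), Y(t), the component of Y
orthogonal to X at each sample is

    Y_perp(t) = imag( Y(t) * conj(X(t)) / |X(t)| ),

which removes the zero-phase-lag (volume-conduction) share of Y.  Power
envelopes are the squared magnitudes, low-pass smoothed to the slow
timescale envelope coupling lives on, then log-transformed; the PEC of a
pair is the mean of the two directed Pearson correlations
corr(env(Y_perp_X), env(X)) and corr(env(X_perp_Y), env(Y)), with
envelope samples pooled across epochs before each correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .bands import BandSpec

logger = logging.getLogger(__name__)

#: Default low-pass cutoff (Hz) applied to power envelopes before the log.
DEFAULT_ENV_LOWPASS = 2.0
#: Relative floor added to power before the log transform.
LOG_FLOOR_REL = 1e-12
#: Relative magnitude below which |X| is treated as zero in orthogonalization.
ZERO_MAG_REL = 1e-12


@dataclass
class PecMatrix:
    """Symmetric ROI x ROI envelope-correlation matrix for one subject/band."""

    matrix: np.ndarray
    band: str = "broadband"
    subject_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        self.matrix = m

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]

    @property
    def upper_tri(self) -> np.ndarray:
        """Row-major upper triangle, diagonal excluded: N(N-1)/2 features."""
        iu = np.triu_indices(self.n_rois, k=1)
        return self.matrix[iu]


def analytic_signal(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Analytic signal with mirror padding to suppress Hilbert edge effects."""
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if n < 32:
        raise ValueError(f"epoch too short for analytic signal ({n} < 32 samples)")
    pad = n - 1
    width = [(0, 0)] * x.ndim
    width[axis if axis >= 0 else x.ndim + axis] = (pad, pad)
    xp = np.pad(x, width, mode="reflect")
    z = signal.hilbert(xp, axis=axis)
    sl = [slice(None)] * x.ndim
    sl[axis if axis >= 0 else x.ndim + axis] = slice(pad, pad + n)
    return z[tuple(sl)]


def orthogonalize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Component of the analytic signal y orthogonal to x, per sample.

    Samples where |x| vanishes (relative to its maximum) contribute 0.
    """
    y = np.asarray(y)
    x = np.asarray(x)
    mag = np.abs(x)
    thresh = ZERO_MAG_REL * mag.max() if mag.size else 0.0
    safe = np.where(mag > thresh, mag, 1.0)
    out = np.imag(y * np.conj(x) / safe)
    n_zero = int(np.sum(mag <= thresh))
    if n_zero:
        logger.warning("orthogonalize: %d zero-magnitude samples set to 0", n_zero)
        out = np.where(mag > thresh, out, 0.0)
    return out


def log_power_envelope(z: np.ndarray, fs: float | None = None,
                       env_lowpass: float | None = None,
                       axis: int = -1) -> np.ndarray:
    """log power envelope: log(|z|^2 + floor), optionally low-pass smoothed.

    The smoothing (zero-phase Butterworth applied to the log-power time
    course) suppresses the fast carrier-envelope and orthogonalization-
    residual fluctuations while leaving the slow envelope dynamics, on
    which power-envelope coupling lives, untouched; correlations between
    series filtered by the same low-pass are unchanged for jointly
    stationary signals.  Smoothing is skipped when env_lowpass is None,
    not below Nyquist, or the series is too short for a stable zero-phase
    pass.
    """
    z = np.asarray(z)
    p = np.abs(z) ** 2 if np.iscomplexobj(z) else z.astype(float) ** 2
    mean_p = float(p.mean())
    if mean_p == 0.0:
        raise ValueError("all-zero series has no defined log envelope")
    e = np.log(p + LOG_FLOOR_REL * mean_p)
    if env_lowpass is not None and fs is not None and env_lowpass < fs / 2:
        n = e.shape[axis]
        sos = signal.butter(2, env_lowpass, btype="lowpass", fs=fs, output="sos")
        padlen = 3 * 6  # sosfiltfilt default for a 2nd-order section pair
        if n > padlen:
            e = signal.sosfiltfilt(sos, e, axis=axis)
    return e


def _pooled_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def pec_pair(za: np.ndarray, zb: np.ndarray, fs: float,
             env_lowpass: float | None = DEFAULT_ENV_LOWPASS) -> float:
    """Symmetrized PEC of two analytic series, shape (samples[, epochs]).

    A direction whose orthogonalized component vanishes identically (the
    pure zero-lag duplicate: y is a real multiple of x) carries no envelope
    covariation beyond leakage and contributes 0.  A zero-variance *input*
    envelope leaves the correlation undefined and yields NaN.
    """
    za = np.atleast_2d(np.asarray(za).T).T  # (samples, epochs)
    zb = np.atleast_2d(np.asarray(zb).T).T
    if za.shape != zb.shape:
        raise ValueError("series must share samples and epochs")
    ea = log_power_envelope(za, fs, env_lowpass, axis=0)
    eb = log_power_envelope(zb, fs, env_lowpass, axis=0)

    def directed(y, x, ex):
        if ex.std() == 0.0:
            return np.nan
        perp = orthogonalize(y, x)
        # a residual that is pure floating-point noise (y is a real multiple
        # of x) would otherwise inherit the reference envelope spuriously
        if np.mean(perp ** 2) <= 1e-20 * np.mean(np.abs(y) ** 2):
            return 0.0
        e_perp = log_power_envelope(perp, fs, env_lowpass, axis=0)
        if e_perp.std() == 0.0:
            return 0.0
        return _pooled_corr(e_perp, ex)

    return float(np.mean([directed(zb, za, ea), directed(za, zb, eb)]))


def raw_envelope_correlation(za: np.ndarray, zb: np.ndarray, fs: float,
                             env_lowpass: float | None = DEFAULT_ENV_LOWPASS
                             ) -> float:
    """Un-orthogonalized envelope correlation (the leakage-prone quantity)."""
    za = np.atleast_2d(np.asarray(za).T).T
    zb = np.atleast_2d(np.asarray(zb).T).T
    ea = log_power_envelope(za, fs, env_lowpass, axis=0)
    eb = log_power_envelope(zb, fs, env_lowpass, axis=0)
    return _pooled_corr(ea, eb)


def pec_matrix(z: np.ndarray, fs: float,
               env_lowpass: float | None = DEFAULT_ENV_LOWPASS) -> np.ndarray:
    """All-pairs symmetrized PEC for analytic data (nodes, samples, epochs).

    Implemented as one pass per seed node: every other node is
    orthogonalized against the seed in a single vectorized step, then the
    directed envelope correlations are computed against the seed envelope
    and averaged with their transpose.
    """
    z = np.asarray(z)
    if z.ndim == 2:
        z = z[:, :, None]
    n_nodes = z.shape[0]
    directed = np.full((n_nodes, n_nodes), np.nan)
    envs = np.stack([log_power_envelope(z[a], fs, env_lowpass, axis=0)
                     for a in range(n_nodes)])
    for a in range(n_nodes):
        x = z[a]
        mag = np.abs(x)
        safe = np.where(mag > ZERO_MAG_REL * mag.max(), mag, 1.0)
        perp = np.imag(z * np.conj(x)[None] / safe[None])  # (nodes, s, e)
        e_perp = log_power_envelope(perp, fs, env_lowpass, axis=1)
        ea = envs[a].reshape(-1)
        ea = ea - ea.mean()
        sa = ea.std()
        ep = e_perp.reshape(n_nodes, -1)
        ep = ep - ep.mean(axis=1, keepdims=True)
        sp = ep.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            directed[a] = (ep @ ea) / (ea.size * np.where(sp > 0, sp, np.nan) * sa)
    pec = 0.5 * (directed + directed.T)
    np.fill_diagonal(pec, 0.0)
    return pec


def roi_aggregate(vertex_pec: np.ndarray, labels: np.ndarray,
                  band: str = "broadband", subject_id: str = "",
                  n_rois: int | None = None) -> PecMatrix:
    """Average dipole-level PEC over all dipole pairs of each ROI pair.

    Entry (A, B), A != B is the mean of vertex_pec over a in A, b in B; the
    diagonal is excluded (set to 0).  An ROI with no dipoles is rejected by
    name when n_rois declares the full node set.
    """
    vertex_pec = np.asarray(vertex_pec, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_rois = int(n_rois) if n_rois is not None else labels.max() + 1
    counts = np.bincount(labels, minlength=n_rois)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"ROI(s) without dipoles: {empty.tolist()}")
    ind = np.zeros((n_rois, labels.size))
    ind[labels, np.arange(labels.size)] = 1.0
    sums = ind @ np.nan_to_num(vertex_pec, nan=0.0) @ ind.T
    nan_counts = ind @ np.isnan(vertex_pec) @ ind.T
    denom = np.outer(counts, counts) - nan_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = sums / denom
    np.fill_diagonal(mat, 0.0)
    mat = 0.5 * (mat + mat.T)
    return PecMatrix(matrix=mat, band=band, subject_id=subject_id)


def subject_pec(source_data: np.ndarray, roi_labels: np.ndarray, fs: float,
                band: BandSpec | None = None,
                env_lowpass: float | None = DEFAULT_ENV_LOWPASS,
                subject_id: str = "") -> PecMatrix:
    """PEC matrix from dipole source series (dipoles, samples, epochs)."""
    x = np.asarray(source_data, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    if band is not None:
        from .preprocess import bandpass
        x = bandpass(np.moveaxis(x, 1, -1), fs, band.lo, band.hi)
        x = np.moveaxis(x, -1, 1)
    z = analytic_signal(np.moveaxis(x, 1, -1), axis=-1)
    z = np.moveaxis(z, -1, 1)
    vertex = pec_matrix(z, fs, env_lowpass)
    return roi_aggregate(vertex, roi_labels,
                         band=band.name if band else "broadband",
                         subject_id=subject_id)


def features_table(matrices: list[PecMatrix]) -> np.ndarray:
    """Stack upper-triangle vectors: (subjects, N(N-1)/2) feature matrix."""
    return np.vstack([m.upper_tri for m in matrices])
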