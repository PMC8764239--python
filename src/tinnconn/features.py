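"""Connectivity measures (PLV, PLI, PCC, TE) and time-frequency features.

PLV and PLI operate on the analytic signal of the (optionally band-limited)
epoch; PCC and TE operate on the raw amplitude series.  TE uses a plug-in
estimator on an equal-width joint histogram with a one-sample lag,
log base 2 (bits).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .types import (
    DEFAULT_BANDS,
    BandDefinition,
    ConnectivityMatrix,
    Epoch,
    EstimationError,
    FeatureVector,
    InputError,
    MEASURES,
)

__all__ = [
    "AnalyticPhase",
    "analytic_signal",
    "analytic_phase",
    "plv",
    "pli",
    "pcc",
    "DiscretizedJointDistribution",
    "joint_histogram",
    "transfer_entropy",
    "connectivity_matrix",
    "rhythm_stats",
    "psd_features",
    "flatten_connectivity",
    "unflatten_connectivity",
]


@dataclass
class AnalyticPhase:
    """Instantaneous phase (radians, in (−π, π]) per channel."""

    phase: np.ndarray
    band: Optional[BandDefinition] = None  # None = broadband


def _band_filter(data: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    if band.high_hz >= fs / 2:
        raise InputError(
            f"band {band.name} ({band.low_hz}-{band.high_hz} Hz) exceeds the "
            f"Nyquist limit at rate {fs}"
        )
    sos = signal.butter(4, [band.low_hz, band.high_hz], btype="bandpass",
                        fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def analytic_signal(epoch: Epoch, band: Optional[BandDefinition] = None) -> np.ndarray:
    """Complex analytic signal per channel, band-filtered first if requested."""
    data = epoch.data
    if band is not None:
        data = _band_filter(data, band, epoch.sampling_rate)
    return signal.hilbert(data, axis=-1)


def analytic_phase(epoch: Epoch, band: Optional[BandDefinition] = None) -> AnalyticPhase:
    """Instantaneous phase of the band-limited analytic signal."""
    return AnalyticPhase(phase=np.angle(analytic_signal(epoch, band)), band=band)


def _check_pair(a: np.ndarray, b: np.ndarray, min_len: int = 2) -> None:
    if a.shape != b.shape:
        raise InputError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.shape[-1] < min_len:
        raise InputError(f"need at least {min_len} samples")


def plv(phase_i: np.ndarray, phase_k: np.ndarray) -> float:
    """Phase-locking value: |mean of exp(j(φi − φk))|, in [0, 1]."""
    phase_i = np.asarray(phase_i, dtype=float)
    phase_k = np.asarray(phase_k, dtype=float)
    _check_pair(phase_i, phase_k)
    return float(np.abs(np.mean(np.exp(1j * (phase_i - phase_k)))))


def pli(z_i: np.ndarray, z_k: np.ndarray) -> float:
    """Phase lag index: |mean of sgn(Im(Zi · Zk*))|, in [0, 1].

    sgn(0) = 0, so exactly zero-lag samples contribute nothing.
    """
    z_i = np.asarray(z_i, dtype=complex)
    z_k = np.asarray(z_k, dtype=complex)
    _check_pair(z_i, z_k)
    cross = z_i * np.conj(z_k)
    im = cross.imag.copy()
    # exact zero-lag leaves ~1-ulp imaginary residue; clamp it so sgn(0)=0
    im[np.abs(im) <= 1e-12 * np.abs(cross)] = 0.0
    return float(np.abs(np.mean(np.sign(im))))


def pcc(x_i: np.ndarray, x_k: np.ndarray) -> float:
    """Pearson correlation: mean[(xi−μi)(xk−μk)] / (σi σk), in [−1, 1]."""
    x_i = np.asarray(x_i, dtype=float)
    x_k = np.asarray(x_k, dtype=float)
    _check_pair(x_i, x_k)
    si, sk = x_i.std(), x_k.std()
    if si == 0 or sk == 0:
        raise EstimationError("pcc undefined for a zero-variance signal")
    val = np.mean((x_i - x_i.mean()) * (x_k - x_k.mean())) / (si * sk)
    return float(np.clip(val, -1.0, 1.0))


@dataclass
class DiscretizedJointDistribution:
    """Joint histogram probabilities p(xi^t, xk^t, xk^{t+1}) on equal-width bins."""

    probabilities: np.ndarray  # shape (bins, bins, bins), axes (i_t, k_t, k_next)
    bins: int
    edges_i: np.ndarray
    edges_k: np.ndarray

    def __post_init__(self) -> None:
        p = self.probabilities
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise EstimationError("probabilities must be non-negative and sum to 1")


def _discretize(x: np.ndarray, bins: int):
    """Equal-width bin index per sample, in [0, bins)."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.shape, dtype=np.intp), np.linspace(lo - 0.5, hi + 0.5, bins + 1)
    edges = np.linspace(lo, hi, bins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, bins - 1)
    return idx, edges


def joint_histogram(
    x_i: np.ndarray, x_k: np.ndarray, bins: int = 4, lag: int = 1
) -> DiscretizedJointDistribution:
    """Empirical joint distribution of (xi^t, xk^t, xk^{t+lag})."""
    if bins < 2:
        raise InputError("bins must be >= 2")
    if lag < 1:
        raise InputError("lag must be >= 1")
    x_i = np.asarray(x_i, dtype=float)
    x_k = np.asarray(x_k, dtype=float)
    _check_pair(x_i, x_k, min_len=lag + 1)
    bi, edges_i = _discretize(x_i, bins)
    bk, edges_k = _discretize(x_k, bins)
    a, b, c = bi[:-lag], bk[:-lag], bk[lag:]
    flat = (a * bins + b) * bins + c
    counts = np.bincount(flat, minlength=bins ** 3).reshape(bins, bins, bins)
    return DiscretizedJointDistribution(
        probabilities=counts / counts.sum(),
        bins=bins,
        edges_i=edges_i,
        edges_k=edges_k,
    )


def transfer_entropy(
    x_i: np.ndarray, x_k: np.ndarray, bins: int = 4, lag: int = 1
) -> float:
    """Plug-in transfer entropy TE(i→k) in bits, ≥ 0.

    TE = Σ p(a,b,c) · log2[ p(c|a,b) / p(c|b) ] over the joint histogram of
    (a, b, c) = (xi^t, xk^t, xk^{t+lag}); empty cells follow the 0·log
    convention.
    """
    dist = joint_histogram(x_i, x_k, bins=bins, lag=lag)
    p_abc = dist.probabilities
    p_ab = p_abc.sum(axis=2, keepdims=True)   # p(a, b)
    p_bc = p_abc.sum(axis=0, keepdims=True)   # p(b, c)
    p_b = p_abc.sum(axis=(0, 2), keepdims=True)  # p(b)
    mask = p_abc > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (p_abc * p_b) / (p_ab * p_bc)
    te = float(np.sum(p_abc[mask] * np.log2(ratio[mask])))
    return max(te, 0.0)


def connectivity_matrix(
    epoch: Epoch,
    measure: str,
    band: Optional[BandDefinition] = None,
    bins: int = 4,
    lag: int = 1,
) -> ConnectivityMatrix:
    """All-pairs connectivity for one epoch (broadband unless a band is given)."""
    measure = measure.lower()
    if measure not in MEASURES:
        raise InputError(
            f"unknown measure {measure!r}; choose from {sorted(MEASURES)}"
        )
    n = epoch.n_channels
    vals = np.zeros((n, n))
    if measure == "plv":
        phi = analytic_phase(epoch, band).phase
        phasor = np.exp(1j * phi)
        vals = np.abs(phasor @ phasor.conj().T) / phi.shape[1]
        np.fill_diagonal(vals, 1.0)
        vals = np.clip((vals + vals.T) / 2.0, 0.0, 1.0)
    elif measure == "pli":
        z = analytic_signal(epoch, band)
        for i in range(n):
            for k in range(i + 1, n):
                vals[i, k] = vals[k, i] = pli(z[i], z[k])
    elif measure == "pcc":
        data = epoch.data if band is None else _band_filter(
            epoch.data, band, epoch.sampling_rate)
        for i in range(n):
            for k in range(i + 1, n):
                vals[i, k] = vals[k, i] = pcc(data[i], data[k])
        np.fill_diagonal(vals, 1.0)
    elif measure == "te":
        data = epoch.data if band is None else _band_filter(
            epoch.data, band, epoch.sampling_rate)
        for i in range(n):
            for k in range(n):
                if i != k:
                    vals[i, k] = transfer_entropy(data[i], data[k], bins=bins, lag=lag)
    return ConnectivityMatrix(
        values=vals,
        measure=measure,
        directed=MEASURES[measure],
        channel_labels=list(epoch.channel_labels),
    )


def rhythm_stats(epoch: Epoch, bands: Optional[Sequence[BandDefinition]] = None) -> FeatureVector:
    """Per-channel, per-band mean and standard deviation of the band-filtered
    signal.  Layout: channel-major, band-minor, (mean, std) innermost."""
    bands = list(bands) if bands is not None else list(DEFAULT_BANDS)
    n = epoch.n_channels
    values = np.empty(n * len(bands) * 2)
    names = []
    filtered = [
        _band_filter(epoch.data, b, epoch.sampling_rate) for b in bands
    ]
    pos = 0
    for ci, ch in enumerate(epoch.channel_labels):
        for bi, b in enumerate(bands):
            x = filtered[bi][ci]
            values[pos] = x.mean()
            values[pos + 1] = x.std()
            names += [f"{ch}:{b.name}:mean", f"{ch}:{b.name}:std"]
            pos += 2
    return FeatureVector(
        values=values,
        layout=f"rhythm:ch-major:{len(bands)}bands:v1",
        label=epoch.label,
        epoch_id=epoch.epoch_id,
        names=names,
    )


def psd_features(
    epoch: Epoch,
    bands: Optional[Sequence[BandDefinition]] = None,
    nperseg: Optional[int] = None,
) -> FeatureVector:
    """Per-channel band powers from an averaged periodogram (Welch).

    Band power is the PSD integrated over the band, so summing across bands
    approximately conserves the in-band signal variance (Parseval).
    """
    bands = list(bands) if bands is not None else list(DEFAULT_BANDS)
    fs = epoch.sampling_rate
    if nperseg is None:
        nperseg = min(epoch.n_samples, int(2 * fs))
    if nperseg < 2 or nperseg > epoch.n_samples:
        raise InputError(
            f"nperseg {nperseg} incompatible with epoch length {epoch.n_samples}"
        )
    freqs, pxx = signal.welch(epoch.data, fs=fs, nperseg=nperseg, axis=-1,
                              detrend="constant")
    df = freqs[1] - freqs[0]
    values = []
    names = []
    for ci, ch in enumerate(epoch.channel_labels):
        for b in bands:
            sel = (freqs >= b.low_hz) & (freqs <= b.high_hz)
            values.append(pxx[ci, sel].sum() * df)
            names.append(f"{ch}:{b.name}:power")
    return FeatureVector(
        values=np.array(values),
        layout=f"psd:ch-major:{len(bands)}bands:v1",
        label=epoch.label,
        epoch_id=epoch.epoch_id,
        names=names,
    )


def flatten_connectivity(matrix: ConnectivityMatrix) -> FeatureVector:
    """Row-major flattening: upper triangle (undirected, n(n−1)/2 values) or
    all off-diagonal entries (directed, n(n−1) values)."""
    matrix.validate()
    n = matrix.n_channels
    labels = matrix.channel_labels
    if matrix.directed:
        mask = ~np.eye(n, dtype=bool)
        layout = f"conn:{matrix.measure}:offdiag:v1"
        names = [f"{labels[i]}->{labels[k]}"
                 for i in range(n) for k in range(n) if i != k]
    else:
        mask = np.triu(np.ones((n, n), dtype=bool), k=1)
        layout = f"conn:{matrix.measure}:uppertri:v1"
        names = [f"{labels[i]}-{labels[k]}"
                 for i in range(n) for k in range(i + 1, n)]
    return FeatureVector(
        values=matrix.values[mask],
        layout=layout,
        names=names,
    )


def unflatten_connectivity(
    fv: FeatureVector, channel_labels: Sequence[str], measure: str
) -> ConnectivityMatrix:
    """Inverse of :func:`flatten_connectivity` (diagonal restored per measure)."""
    n = len(channel_labels)
    directed = MEASURES.get(measure, ":offdiag:" in fv.layout)
    vals = np.zeros((n, n))
    if directed:
        mask = ~np.eye(n, dtype=bool)
        if fv.values.size != n * (n - 1):
            raise InputError("length does not match a directed layout")
        vals[mask] = fv.values
    else:
        iu = np.triu_indices(n, k=1)
        if fv.values.size != len(iu[0]):
            raise InputError("length does not match an undirected layout")
        vals[iu] = fv.values
        vals = vals + vals.T
    if measure in ("plv", "pcc"):
        np.fill_diagonal(vals, 1.0)
    return ConnectivityMatrix(
        values=vals, measure=measure, directed=directed,
        channel_labels=list(channel_labels),
    )
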