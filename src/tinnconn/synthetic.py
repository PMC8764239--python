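"""Synthetic multichannel recordings with controlled connectivity structure.

Each class template controls three independent knobs, one per estimator
family:

* ``phase_coupling`` (κ): pairwise phase synchrony.  Channel phases are
  Brownian around a common carrier frequency with *correlated* increments,
  the correlation matrix being κ (projected to the nearest PSD matrix).
  κ=1 ⇒ identical increments ⇒ constant phase offset ⇒ PLV = 1;
  κ=0 ⇒ independent diffusion ⇒ PLV → 0 over long windows.
* ``linear_mixing``: instantaneous correlation, realized by adding a
  correlated broadband Gaussian component.
* ``directed_gain`` (g): lagged influence, realized by adding
  ``g[i, k] · x_i(t−1)`` to channel ``k`` — a one-sample-lag autoregressive
  term that drives transfer entropy.

Band structure (``band_profile``) shapes per-band oscillator amplitudes so
rhythm/PSD features can discriminate variants that differ only spectrally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal

from .types import (
    AUDITORY_CHANNELS_12,
    DEFAULT_BANDS,
    BandDefinition,
    ConfigurationError,
    Epoch,
    InputError,
    MultichannelRecording,
)

__all__ = [
    "ClassTemplate",
    "SimulationConfig",
    "GroundTruth",
    "simulate_recording",
    "build_class_templates",
    "make_labeled_dataset",
    "DEFAULT_BAND_PROFILE",
]

#: relative oscillator amplitude per band; alpha-dominant resting profile
DEFAULT_BAND_PROFILE = {
    "delta": 0.40,
    "theta": 0.30,
    "alpha": 1.00,
    "beta": 0.25,
    "low_gamma": 0.12,
    "high_gamma": 0.08,
}


def _nearest_psd(mat: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping)."""
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def _psd_factor(mat: np.ndarray) -> np.ndarray:
    """L with L Lᵀ ≈ nearest-PSD(mat); robust replacement for Cholesky."""
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


@dataclass
class ClassTemplate:
    """Generating parameters for one class of recordings."""

    label: str
    phase_coupling: np.ndarray
    linear_mixing: np.ndarray
    directed_gain: np.ndarray
    noise_sd: Union[float, np.ndarray] = 0.3
    band_profile: dict = field(default_factory=lambda: dict(DEFAULT_BAND_PROFILE))
    carrier_freq: float = 10.0
    phase_diffusion: float = 1.0  # rad^2 / s
    mixing_scale: float = 0.8
    amplitude_uv: float = 20.0

    def __post_init__(self) -> None:
        self.phase_coupling = np.asarray(self.phase_coupling, dtype=float)
        self.linear_mixing = np.asarray(self.linear_mixing, dtype=float)
        self.directed_gain = np.asarray(self.directed_gain, dtype=float)
        n = self.phase_coupling.shape[0]
        for name, m in (
            ("phase_coupling", self.phase_coupling),
            ("linear_mixing", self.linear_mixing),
            ("directed_gain", self.directed_gain),
        ):
            if m.shape != (n, n):
                raise ConfigurationError(f"{name} must be {n}×{n}, got {m.shape}")
        for name, m in (
            ("phase_coupling", self.phase_coupling),
            ("linear_mixing", self.linear_mixing),
        ):
            if not np.allclose(m, m.T):
                raise ConfigurationError(f"{name} must be symmetric")
        np.fill_diagonal(self.phase_coupling, 1.0)
        np.fill_diagonal(self.linear_mixing, 1.0)
        np.fill_diagonal(self.directed_gain, 0.0)
        if self.phase_coupling.min() < 0 or self.phase_coupling.max() > 1:
            raise ConfigurationError("phase_coupling entries must lie in [0, 1]")
        if self.linear_mixing.min() < -1 or self.linear_mixing.max() > 1:
            raise ConfigurationError("linear_mixing entries must lie in [-1, 1]")
        if self.directed_gain.min() < 0:
            raise ConfigurationError("directed_gain entries must be non-negative")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ConfigurationError("noise_sd must be non-negative")
        if any(v < 0 for v in self.band_profile.values()):
            raise ConfigurationError("band_profile amplitudes must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.phase_coupling.shape[0]


@dataclass
class SimulationConfig:
    """Knobs for a full labeled dataset: rate, duration, classes, seeding."""

    sampling_rate: float = 1000.0
    duration: float = 600.0
    epoch_s: float = 10.0
    n_epochs_target: Optional[int] = None
    channel_labels: list = field(default_factory=lambda: list(AUDITORY_CHANNELS_12))
    seed: int = 0
    classes: list = field(default_factory=list)
    recordings_per_class: Union[int, Sequence[int]] = 1
    bands: list = field(default_factory=lambda: list(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        high_edge = max(b.high_hz for b in self.bands)
        if self.sampling_rate <= 2 * high_edge:
            raise ConfigurationError(
                f"sampling_rate {self.sampling_rate} must exceed twice the "
                f"highest band edge ({high_edge} Hz)"
            )
        if self.duration < self.epoch_s:
            raise InputError(
                f"duration {self.duration}s shorter than one epoch ({self.epoch_s}s)"
            )

    def per_class_recordings(self) -> list:
        if isinstance(self.recordings_per_class, int):
            return [self.recordings_per_class] * len(self.classes)
        counts = list(self.recordings_per_class)
        if len(counts) != len(self.classes):
            raise ConfigurationError(
                "recordings_per_class list length must match number of classes"
            )
        return counts


@dataclass
class GroundTruth:
    """One entry per generated recording: label, template, realized seed."""

    entries: list = field(default_factory=list)

    def add(self, recording_id: str, label: str, template: ClassTemplate, seed) -> None:
        self.entries.append(
            {"recording_id": recording_id, "label": label,
             "template_label": template.label, "seed": int(seed)}
        )

    def labels(self) -> list:
        return [e["label"] for e in self.entries]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.entries, fh, indent=1)


def _narrowband_noise(rng, band: BandDefinition, n: int, t: int, fs: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise, one row per channel."""
    if band.high_hz >= fs / 2:
        raise ConfigurationError(
            f"band {band.name} exceeds the Nyquist frequency at rate {fs}"
        )
    sos = signal.butter(4, [band.low_hz, band.high_hz], btype="bandpass",
                        fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal((n, t)), axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _band_of(freq: float, bands) -> Optional[BandDefinition]:
    for b in bands:
        if b.low_hz <= freq <= b.high_hz:
            return b
    return None


def simulate_recording(
    template: ClassTemplate,
    config: SimulationConfig,
    seed,
) -> MultichannelRecording:
    """Generate one recording from a class template.

    Raises :class:`ConfigurationError` on a channel-count mismatch and
    :class:`InputError` when the duration cannot hold a single epoch.
    """
    n = len(config.channel_labels)
    if template.n_channels != n:
        raise ConfigurationError(
            f"template has {template.n_channels} channels, "
            f"config lists {n} labels"
        )
    if config.duration < config.epoch_s:
        raise InputError("duration too short for one epoch")

    fs = config.sampling_rate
    t_len = int(round(config.duration * fs))
    rng = np.random.default_rng(seed)
    time = np.arange(t_len) / fs

    # --- phase-coupled carrier oscillators -------------------------------
    l_phase = _psd_factor(template.phase_coupling)
    inc = l_phase @ rng.standard_normal((n, t_len))
    inc *= np.sqrt(template.phase_diffusion / fs)
    theta = np.cumsum(inc, axis=1)
    theta += rng.uniform(-np.pi, np.pi, size=(n, 1))
    carrier_band = _band_of(template.carrier_freq, config.bands)
    carrier_amp = (
        template.band_profile.get(carrier_band.name, 1.0)
        if carrier_band is not None else 1.0
    )
    x = carrier_amp * np.cos(2 * np.pi * template.carrier_freq * time + theta)

    # --- independent per-band oscillators (spectral shaping) -------------
    for band in config.bands:
        if carrier_band is not None and band.name == carrier_band.name:
            continue  # this band is carried by the coupled oscillator
        amp = template.band_profile.get(band.name, 0.0)
        if amp > 0:
            x += amp * _narrowband_noise(rng, band, n, t_len, fs)

    # --- correlated broadband Gaussian component (drives PCC) ------------
    if template.mixing_scale > 0:
        l_mix = _psd_factor(template.linear_mixing)
        x += template.mixing_scale * (l_mix @ rng.standard_normal((n, t_len)))

    # --- sensor noise ----------------------------------------------------
    noise_sd = np.broadcast_to(
        np.atleast_1d(np.asarray(template.noise_sd, dtype=float)), (n,)
    )
    x += noise_sd[:, None] * rng.standard_normal((n, t_len))

    # --- one-sample-lag directed influence (drives TE) -------------------
    g = template.directed_gain
    if np.any(g > 0):
        base = x.copy()
        src, dst = np.nonzero(g)
        for i, k in zip(src, dst):
            x[k, 1:] += g[i, k] * base[i, :-1]

    x *= template.amplitude_uv
    return MultichannelRecording(
        data=x,
        sampling_rate=fs,
        channel_labels=list(config.channel_labels),
        subject_id=f"sim-{template.label}-{seed}",
        group_label=template.label,
    )


def _template_from_sets(
    label: str,
    channels: Sequence[str],
    coupled_sets: Sequence[Sequence[str]],
    gains: Optional[dict] = None,
    kappa: float = 0.95,
    mixing: float = 0.85,
    band_profile: Optional[dict] = None,
) -> ClassTemplate:
    """Build a template whose κ/mixing matrices are block-structured over
    the given channel sets (the "similar connectivity activation" pattern)."""
    channels = list(channels)
    n = len(channels)
    idx = {c: i for i, c in enumerate(channels)}
    pc = np.zeros((n, n))
    lm = np.zeros((n, n))
    for group in coupled_sets:
        ii = [idx[c] for c in group]
        for a in ii:
            for b in ii:
                if a != b:
                    pc[a, b] = kappa
                    lm[a, b] = mixing
    dg = np.zeros((n, n))
    for (src, dst), g in (gains or {}).items():
        dg[idx[src], idx[dst]] = g
    # contrast settings tuned so connectivity features separate the four
    # classes cleanly at a few hundred epochs (slow phase drift, strong
    # shared broadband component on the coupled sets)
    return ClassTemplate(
        label=label,
        phase_coupling=pc,
        linear_mixing=lm,
        directed_gain=dg,
        band_profile=dict(band_profile or DEFAULT_BAND_PROFILE),
        phase_diffusion=1.5,
        mixing_scale=1.5,
    )


#: qualitative cluster patterns per class: channel sets with elevated
#: within-set coupling (cross-hemisphere pairs for controls, lateralized
#: sets for the tinnitus classes)
_CLASS_SETS = {
    "healthy": [["FT7", "FT8"], ["T7", "T8"], ["TP7", "TP8"]],
    "bilateral": [["T7", "T8"], ["FC6", "C6", "CP6"]],
    "left": [["FT8", "T8"], ["FC6", "CP6"], ["C5", "CP5"]],
    "right": [["FC5", "C5", "T7"], ["TP7", "CP5", "C6"]],
}

_CLASS_GAINS = {
    "healthy": {},
    "bilateral": {("T7", "T8"): 0.35},
    "left": {("T8", "FT8"): 0.35},
    "right": {("T7", "FC5"): 0.35},
}

_LFT_PROFILE = dict(DEFAULT_BAND_PROFILE, delta=0.70, theta=0.55, high_gamma=0.04)
_HFT_PROFILE = dict(DEFAULT_BAND_PROFILE, delta=0.25, theta=0.20, high_gamma=0.35)


def build_class_templates(
    scenario: str = "default",
    channel_labels: Optional[Sequence[str]] = None,
) -> list:
    """Class templates for a named scenario.

    ``default``  – four classes with pairwise-distinct connectivity structure.
    ``lft_hft``  – the left-sided class split into low/high-frequency
                   variants that differ *only* in band_profile.
    ``null``     – four templates with identical matrices (type-I testing).
    """
    channels = list(channel_labels or AUDITORY_CHANNELS_12)
    if scenario == "default":
        return [
            _template_from_sets(lbl, channels, _CLASS_SETS[lbl],
                                gains=_CLASS_GAINS[lbl])
            for lbl in ("healthy", "bilateral", "left", "right")
        ]
    if scenario == "lft_hft":
        out = []
        for lbl in ("healthy", "bilateral", "left", "right"):
            if lbl == "left":
                for sub, prof in (("left_lft", _LFT_PROFILE),
                                  ("left_hft", _HFT_PROFILE)):
                    out.append(
                        _template_from_sets(sub, channels, _CLASS_SETS["left"],
                                            gains=_CLASS_GAINS["left"],
                                            band_profile=prof)
                    )
            else:
                out.append(
                    _template_from_sets(lbl, channels, _CLASS_SETS[lbl],
                                        gains=_CLASS_GAINS[lbl])
                )
        return out
    if scenario == "null":
        return [
            _template_from_sets(lbl, channels, _CLASS_SETS["healthy"])
            for lbl in ("healthy", "bilateral", "left", "right")
        ]
    raise InputError(
        f"unknown scenario {scenario!r}; choose from default, lft_hft, null"
    )


def _segment(rec: MultichannelRecording, epoch_s: float, label, prefix: str) -> list:
    n_per = int(round(epoch_s * rec.sampling_rate))
    n_epochs = rec.n_samples // n_per
    return [
        Epoch(
            data=rec.data[:, j * n_per:(j + 1) * n_per].copy(),
            sampling_rate=rec.sampling_rate,
            channel_labels=list(rec.channel_labels),
            label=label,
            epoch_id=f"{prefix}-e{j:03d}",
        )
        for j in range(n_epochs)
    ]


def make_labeled_dataset(config: SimulationConfig):
    """Simulate all configured recordings and segment them into labeled epochs.

    Returns ``(epochs, ground_truth)``.  Deterministic for a fixed
    ``config.seed`` (child seeds are spawned from a SeedSequence).  When
    ``n_epochs_target`` is set, epochs beyond the target are dropped from
    the end of a class-interleaved ordering so classes stay balanced.
    """
    if not config.classes:
        raise ConfigurationError("config.classes is empty")
    counts = config.per_class_recordings()
    ss = np.random.SeedSequence(config.seed)
    n_recs = sum(counts)
    children = ss.spawn(n_recs)

    truth = GroundTruth()
    per_class_epochs = []
    child_iter = iter(children)
    for template, n_rec in zip(config.classes, counts):
        cls_epochs = []
        for r in range(n_rec):
            child = next(child_iter)
            rec_id = f"{template.label}-r{r:02d}"
            rec = simulate_recording(template, config, child)
            # realized seed = deterministic 63-bit digest of the child sequence
            realized = int(child.generate_state(1, dtype=np.uint64)[0] >> 1)
            truth.add(rec_id, template.label, template, realized)
            cls_epochs.extend(_segment(rec, config.epoch_s, template.label, rec_id))
        per_class_epochs.append(cls_epochs)

    # interleave classes so truncation stays balanced
    epochs = []
    longest = max(len(c) for c in per_class_epochs)
    for j in range(longest):
        for cls in per_class_epochs:
            if j < len(cls):
                epochs.append(cls[j])
    if config.n_epochs_target is not None:
        epochs = epochs[: config.n_epochs_target]
    return epochs, truth
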