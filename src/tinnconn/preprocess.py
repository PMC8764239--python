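"""Raw recordings → clean, re-referenced, channel-selected 10-s epochs.

Fixed stage order (logged): artifact hook → notch → bandpass → baseline →
re-reference → channel selection → segmentation.  All filters are
zero-phase (forward-backward IIR).
"""

from __future__ import annotations

import logging
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import signal

from .types import (
    AUDITORY_CHANNELS_12,
    Epoch,
    InputError,
    MultichannelRecording,
)

__all__ = [
    "bandpass_filter",
    "notch_filter",
    "baseline_correct",
    "rereference",
    "select_auditory_channels",
    "segment_epochs",
    "amplitude_reject",
    "preprocess_recording",
]

log = logging.getLogger(__name__)


def _check_band(low_hz: float, high_hz: float, rate: float) -> None:
    if not (0 < low_hz < high_hz):
        raise InputError(f"need 0 < low < high, got ({low_hz}, {high_hz})")
    if high_hz >= rate / 2:
        raise InputError(
            f"band edge {high_hz} Hz violates the Nyquist limit ({rate / 2} Hz)"
        )


def _padlen(rec: MultichannelRecording) -> int:
    # generous padding keeps filtfilt edge transients out of the signal body
    return int(min(rec.n_samples - 1, 3 * rec.sampling_rate))


def bandpass_filter(
    rec: MultichannelRecording, low_hz: float = 0.5, high_hz: float = 90.0
) -> MultichannelRecording:
    """Zero-phase 4th-order Butterworth band-pass."""
    _check_band(low_hz, high_hz, rec.sampling_rate)
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass",
                        fs=rec.sampling_rate, output="sos")
    return rec.with_data(
        signal.sosfiltfilt(sos, rec.data, axis=1, padlen=_padlen(rec))
    )


def notch_filter(
    rec: MultichannelRecording, line_hz: float = 50.0, width_hz: float = 2.0
) -> MultichannelRecording:
    """Zero-phase 2nd-order band-stop of ±``width_hz`` around the line frequency."""
    _check_band(line_hz - width_hz, line_hz + width_hz, rec.sampling_rate)
    sos = signal.butter(2, [line_hz - width_hz, line_hz + width_hz],
                        btype="bandstop", fs=rec.sampling_rate, output="sos")
    return rec.with_data(
        signal.sosfiltfilt(sos, rec.data, axis=1, padlen=_padlen(rec))
    )


def baseline_correct(rec: MultichannelRecording) -> MultichannelRecording:
    """Subtract the per-channel mean."""
    return rec.with_data(rec.data - rec.data.mean(axis=1, keepdims=True))


def rereference(rec: MultichannelRecording, method: str = "average") -> MultichannelRecording:
    """Re-reference after baseline correction.

    ``average`` subtracts the instantaneous channel mean so the column means
    are exactly zero.  ``rest`` is a named extension point (it needs a head
    model) and deliberately not implemented.
    """
    if rec.n_channels < 2:
        raise InputError("re-referencing requires at least 2 channels")
    if method == "average":
        data = rec.data - rec.data.mean(axis=1, keepdims=True)
        return rec.with_data(data - data.mean(axis=0, keepdims=True))
    if method == "rest":
        raise NotImplementedError(
            "REST re-referencing requires a leadfield; use method='average'"
        )
    raise InputError(f"unknown re-reference method {method!r}")


def select_auditory_channels(
    rec: MultichannelRecording, names: Optional[Sequence[str]] = None
) -> MultichannelRecording:
    """Keep exactly the requested channels, in the requested order."""
    names = list(names) if names is not None else list(AUDITORY_CHANNELS_12)
    missing = [n for n in names if n not in rec.channel_labels]
    if missing:
        raise InputError(f"requested channels not present: {missing}")
    idx = [rec.channel_labels.index(n) for n in names]
    return MultichannelRecording(
        data=rec.data[idx].copy(),
        sampling_rate=rec.sampling_rate,
        channel_labels=names,
        subject_id=rec.subject_id,
        group_label=rec.group_label,
    )


def segment_epochs(rec: MultichannelRecording, epoch_s: float = 10.0) -> list:
    """Non-overlapping epochs; the trailing remainder is discarded."""
    if epoch_s <= 0:
        raise InputError("epoch_s must be positive")
    if rec.duration < epoch_s:
        raise InputError(
            f"recording ({rec.duration:.3g}s) shorter than one epoch ({epoch_s}s)"
        )
    n_per = int(round(epoch_s * rec.sampling_rate))
    n_epochs = rec.n_samples // n_per
    return [
        Epoch(
            data=rec.data[:, j * n_per:(j + 1) * n_per].copy(),
            sampling_rate=rec.sampling_rate,
            channel_labels=list(rec.channel_labels),
            label=rec.group_label,
            epoch_id=f"{rec.subject_id or 'rec'}-e{j:03d}",
        )
        for j in range(n_epochs)
    ]


def amplitude_reject(epochs: Sequence[Epoch], threshold_uv: float = 100.0) -> list:
    """Drop epochs containing any sample beyond ``threshold_uv`` (absolute)."""
    kept = [e for e in epochs if np.abs(e.data).max() <= threshold_uv]
    if len(kept) < len(epochs):
        log.info("amplitude_reject: dropped %d/%d epochs",
                 len(epochs) - len(kept), len(epochs))
    return kept


def preprocess_recording(
    rec: MultichannelRecording,
    low_hz: float = 0.5,
    high_hz: float = 90.0,
    line_hz: Optional[float] = 50.0,
    reference: str = "average",
    channels: Optional[Sequence[str]] = None,
    epoch_s: float = 10.0,
    reject_threshold_uv: Optional[float] = None,
    artifact_hook: Optional[Callable[[MultichannelRecording], MultichannelRecording]] = None,
) -> list:
    """Run the full fixed-order preprocessing pipeline and return epochs.

    ``artifact_hook`` is the interpolation/rejection extension point; the
    default is a no-op.  ``reject_threshold_uv`` applies the amplitude
    criterion after segmentation (None disables it).
    """
    log.info("preprocess: hook -> notch -> bandpass -> baseline -> "
             "reref(%s) -> select -> segment(%gs)", reference, epoch_s)
    if artifact_hook is not None:
        rec = artifact_hook(rec)
    if line_hz is not None:
        rec = notch_filter(rec, line_hz)
    rec = bandpass_filter(rec, low_hz, high_hz)
    rec = baseline_correct(rec)
    rec = rereference(rec, reference)
    if channels is not None:
        rec = select_auditory_channels(rec, channels)
    elif all(c in rec.channel_labels for c in AUDITORY_CHANNELS_12) and rec.n_channels > 12:
        rec = select_auditory_channels(rec)
    epochs = segment_epochs(rec, epoch_s)
    if reject_threshold_uv is not None:
        epochs = amplitude_reject(epochs, reject_threshold_uv)
    return epochs
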