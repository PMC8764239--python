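"""Core data containers and error types shared across the pipeline.

Everything downstream consumes :class:`MultichannelRecording` and
:class:`Epoch`; connectivity estimators return :class:`ConnectivityMatrix`
objects whose invariants are checked eagerly, and classifiers consume
:class:`FeatureVector` stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "InputError",
    "ConfigurationError",
    "EstimationError",
    "BandDefinition",
    "DEFAULT_BANDS",
    "AUDITORY_CHANNELS_12",
    "LEFT_AUDITORY_CHANNELS",
    "RIGHT_AUDITORY_CHANNELS",
    "MONTAGE_64_LABELS",
    "MultichannelRecording",
    "Epoch",
    "ConnectivityMatrix",
    "FeatureVector",
    "MEASURES",
]


class InputError(ValueError):
    """Invalid user-supplied data or arguments (CLI exit code 2)."""

    exit_code = 2


class ConfigurationError(ValueError):
    """Invalid configuration (CLI exit code 3)."""

    exit_code = 3


class EstimationError(RuntimeError):
    """An estimator could not produce a meaningful value (e.g. zero variance)."""


# The 12 channels over the left / right auditory cortex used throughout.
LEFT_AUDITORY_CHANNELS = ["FT7", "FC5", "C5", "T7", "TP7", "CP5"]
RIGHT_AUDITORY_CHANNELS = ["FC6", "FT8", "C6", "T8", "CP6", "TP8"]
AUDITORY_CHANNELS_12 = LEFT_AUDITORY_CHANNELS + RIGHT_AUDITORY_CHANNELS

# A standard 64-channel 10-20/10-10 montage (Neuroscan-style cap) that
# contains the 12 auditory-cortex channels above.
MONTAGE_64_LABELS = [
    "Fp1", "Fpz", "Fp2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "CB1", "O1", "Oz", "O2", "CB2", "M1", "M2",
]
assert len(MONTAGE_64_LABELS) == 64


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, ``low_hz < high_hz``, both positive."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise InputError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )


DEFAULT_BANDS = [
    BandDefinition("delta", 1.0, 3.5),
    BandDefinition("theta", 4.0, 7.5),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.5, 30.0),
    BandDefinition("low_gamma", 30.5, 48.0),
    BandDefinition("high_gamma", 52.0, 90.0),
]


def _check_labels(labels: Sequence[str], n_rows: int) -> list:
    labels = list(labels)
    if len(labels) != n_rows:
        raise InputError(
            f"{len(labels)} channel labels for {n_rows} data rows"
        )
    if len(set(labels)) != len(labels):
        raise InputError("channel labels must be unique")
    return labels


@dataclass
class MultichannelRecording:
    """A channels × samples array in microvolts at a fixed sampling rate."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: list
    subject_id: str = ""
    group_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InputError("data must be 2-D (channels × samples)")
        if self.data.shape[1] < 1:
            raise InputError("recording has no samples")
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")
        self.channel_labels = _check_labels(self.channel_labels, self.data.shape[0])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sampling_rate

    def with_data(self, data: np.ndarray) -> "MultichannelRecording":
        return replace(self, data=data)


@dataclass
class Epoch:
    """One fixed-duration segment of a recording; the unit of feature extraction."""

    data: np.ndarray
    sampling_rate: float
    channel_labels: list
    label: Optional[str] = None
    epoch_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InputError("epoch data must be 2-D (channels × samples)")
        self.channel_labels = _check_labels(self.channel_labels, self.data.shape[0])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


#: measure name -> directed flag
MEASURES = {"plv": False, "pli": False, "pcc": False, "te": True}


@dataclass
class ConnectivityMatrix:
    """n×n connectivity values for one measure on one epoch (or a group mean)."""

    values: np.ndarray
    measure: str
    directed: bool
    channel_labels: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.channel_labels)
        if self.values.shape != (n, n):
            raise InputError(
                f"values shape {self.values.shape} != ({n}, {n})"
            )
        self.validate()

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def validate(self, atol: float = 1e-9) -> None:
        """Assert the per-measure range/symmetry/diagonal invariants."""
        v = self.values
        if not np.all(np.isfinite(v)):
            raise EstimationError(f"{self.measure}: non-finite entries")
        m = self.measure
        if m in ("plv", "pli", "pcc"):
            if self.directed:
                raise InputError(f"{m} is undirected")
            if not np.allclose(v, v.T, atol=atol):
                raise EstimationError(f"{m}: matrix not symmetric")
        if m == "plv":
            if v.min() < -atol or v.max() > 1 + atol:
                raise EstimationError("plv outside [0, 1]")
            if not np.allclose(np.diag(v), 1.0, atol=atol):
                raise EstimationError("plv diagonal must be 1")
        elif m == "pli":
            if v.min() < -atol or v.max() > 1 + atol:
                raise EstimationError("pli outside [0, 1]")
            if not np.allclose(np.diag(v), 0.0, atol=atol):
                raise EstimationError("pli diagonal must be 0")
        elif m == "pcc":
            if v.min() < -1 - atol or v.max() > 1 + atol:
                raise EstimationError("pcc outside [-1, 1]")
            if not np.allclose(np.diag(v), 1.0, atol=atol):
                raise EstimationError("pcc diagonal must be 1")
        elif m == "te":
            if not self.directed:
                # symmetrized TE (average of both directions) is allowed
                if not np.allclose(v, v.T, atol=atol):
                    raise EstimationError("symmetrized te must be symmetric")
            if v.min() < -atol:
                raise EstimationError("te must be non-negative")
            if not np.allclose(np.diag(v), 0.0, atol=atol):
                raise EstimationError("te diagonal must be 0")
        # unknown measures only get the finiteness check


@dataclass
class FeatureVector:
    """Ordered per-epoch features under a named layout scheme."""

    values: np.ndarray
    layout: str
    label: Optional[str] = None
    epoch_id: Optional[str] = None
    names: Optional[list] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.names is not None and len(self.names) != self.values.size:
            raise InputError("feature names do not match value count")

    def __len__(self) -> int:
        return self.values.size
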