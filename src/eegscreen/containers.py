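"""Shared in-memory containers for recordings and segments."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical eight-channel wearable montage, left/right homologous pairs
#: over prefrontal, frontal, central and parietal sites.
MONTAGE: tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4")

CLASS_LABELS: tuple[str, str] = ("H", "MDD")  # H=0, MDD=1 (positive class)

CONDITIONS: tuple[str, str] = ("EO", "EC")


@dataclass
class RawRecording:
    """Multichannel time series in microvolts at a known sampling rate."""

    samples: np.ndarray          # (n_channels, n_samples), µV
    sampling_rate: float         # Hz
    channels: tuple[str, ...]
    subject_key: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.samples.shape[0]} rows for {len(self.channels)} channels"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


@dataclass
class Segment:
    """Fixed-length artefact-screened epoch tagged with its subject key."""

    subject_key: str
    condition: str
    samples: np.ndarray          # (n_channels, epoch_samples), µV
    sampling_rate: float
    index: int = 0               # position within the source recording
    channels: tuple[str, ...] = field(default=MONTAGE)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")

    @property
    def class_label(self) -> str:
        from .cohort import parse_subject_key

        return parse_subject_key(self.subject_key)[0]
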