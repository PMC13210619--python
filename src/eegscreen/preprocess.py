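"""Segment-level preprocessing: montage reduction, bandpass, epoching and
amplitude-based artefact rejection.

Every operation here is stateless per segment and independent of subject
identity, class label and split assignment, so nothing in this module can
transfer information between train and test partitions. Any *fitted*
statistic (imputation medians, standardisation, per-channel z-scores) lives
with the models and is estimated on training subjects only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .containers import MONTAGE, RawRecording, Segment


@dataclass(frozen=True)
class PreprocessConfig:
    band_low: float = 0.5        # Hz
    band_high: float = 45.0      # Hz
    epoch_len_s: float = 4.0
    epoch_overlap: float = 0.0   # fraction of epoch length
    amp_reject_uv: float = 100.0
    montage: tuple[str, ...] = field(default=MONTAGE)
    filter_order: int = 4        # Butterworth, applied forward-backward

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if not 0 <= self.epoch_overlap < 1:
            raise ValueError("epoch_overlap must lie in [0, 1)")


def select_channels(recording: RawRecording,
                    montage: tuple[str, ...] = MONTAGE) -> RawRecording:
    """Restrict and reorder channels to the canonical montage order."""
    missing = [ch for ch in montage if ch not in recording.channels]
    if missing:
        raise ValueError(f"montage channels missing from recording: {missing}")
    idx = [recording.channels.index(ch) for ch in montage]
    return RawRecording(
        samples=recording.samples[idx],
        sampling_rate=recording.sampling_rate,
        channels=tuple(montage),
        subject_key=recording.subject_key,
        condition=recording.condition,
    )


def bandpass(recording: RawRecording, config: PreprocessConfig) -> RawRecording:
    """Zero-phase Butterworth bandpass (removes slow drift and HF noise)."""
    nyquist = recording.sampling_rate / 2.0
    if config.band_high >= nyquist:
        raise ValueError(
            f"band_high {config.band_high} Hz must be below Nyquist {nyquist} Hz"
        )
    sos = sp_signal.butter(
        config.filter_order, [config.band_low, config.band_high],
        btype="bandpass", fs=recording.sampling_rate, output="sos",
    )
    filtered = sp_signal.sosfiltfilt(sos, recording.samples, axis=-1)
    return RawRecording(
        samples=filtered,
        sampling_rate=recording.sampling_rate,
        channels=recording.channels,
        subject_key=recording.subject_key,
        condition=recording.condition,
    )


def segment(recording: RawRecording, config: PreprocessConfig) -> list[Segment]:
    """Cut a recording into fixed-length epochs; trailing partial window is
    discarded. Window count = floor((T - L) / (L (1 - overlap))) + 1."""
    fs = recording.sampling_rate
    epoch_len = int(round(config.epoch_len_s * fs))
    n = recording.samples.shape[1]
    if n < epoch_len:
        raise ValueError(
            f"recording of {n} samples shorter than one epoch ({epoch_len})"
        )
    step = int(round(epoch_len * (1.0 - config.epoch_overlap)))
    step = max(step, 1)
    count = (n - epoch_len) // step + 1
    return [
        Segment(
            subject_key=recording.subject_key,
            condition=recording.condition,
            samples=recording.samples[:, k * step:k * step + epoch_len],
            sampling_rate=fs,
            index=k,
            channels=recording.channels,
        )
        for k in range(count)
    ]


def reject_artifacts(candidates: list[Segment], config: PreprocessConfig
                     ) -> tuple[list[Segment], pd.DataFrame]:
    """Keep a segment iff max |sample| over channels and time is within the
    amplitude threshold. Returns (accepted, per-subject rejection log)."""
    accepted: list[Segment] = []
    counts: dict[str, dict[str, int]] = {}
    for seg in candidates:
        entry = counts.setdefault(seg.subject_key,
                                  {"accepted": 0, "rejected": 0})
        if np.max(np.abs(seg.samples)) <= config.amp_reject_uv:
            accepted.append(seg)
            entry["accepted"] += 1
        else:
            entry["rejected"] += 1
    log = pd.DataFrame(
        [
            {"subject_key": k, "accepted": v["accepted"],
             "rejected": v["rejected"]}
            for k, v in sorted(counts.items())
        ]
    )
    return accepted, log


def preprocess_recording(recording: RawRecording,
                         config: PreprocessConfig = PreprocessConfig()
                         ) -> tuple[list[Segment], pd.DataFrame]:
    """Montage-reduce, bandpass, epoch and artefact-screen one recording."""
    rec = select_channels(recording, config.montage)
    rec = bandpass(rec, config)
    candidates = segment(rec, config)
    return reject_artifacts(candidates, config)


def segment_index(segments: list[Segment]) -> pd.DataFrame:
    """TSV-ready index of accepted segments."""
    return pd.DataFrame(
        [
            {"subject_key": s.subject_key, "condition": s.condition,
             "segment_index": s.index}
            for s in segments
        ]
    )
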