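"""Spectral and coherence feature extraction for eight-channel EEG segments.

Three feature families with a fixed, ordered, named vocabulary:

* 40 relative band powers  ``{band}_rel_{ch}``  (5 bands x 8 channels),
* 40 log-absolute band powers ``{band}_logabs_{ch}``,
* 10 inter-hemispheric asymmetries ``{band}_asym_{frontal|centroparietal}``,

forming the 90-dimensional spectral vector; 56 magnitude-squared coherence
means ``{alpha|beta}_coh_{chA}_{chB}`` over the 28 unordered channel pairs;
and their 146-dimensional early fusion (spectral first, coherence second).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import MONTAGE, Segment


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float   # Hz, inclusive
    high: float  # Hz, exclusive


#: Canonical EEG bands. Intervals are half-open [low, high) so that adjacent
#: bands never share a frequency bin.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 40.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)

#: Homologous left/right pairs grouped into the two asymmetry sites.
ASYMMETRY_SITES: dict[str, tuple[tuple[str, str], ...]] = {
    # (left, right) electrode pairs
    "frontal": (("Fp1", "Fp2"), ("F3", "F4")),
    "centroparietal": (("C3", "C4"), ("P3", "P4")),
}

#: 28 unordered channel pairs in montage order (chA before chB).
CHANNEL_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations(MONTAGE, 2)
)

COHERENCE_BANDS: tuple[str, ...] = ("alpha", "beta")

LOG_EPS = 1e-12  # floor before the natural logarithm of absolute band power


@dataclass(frozen=True)
class EstimatorConfig:
    """Welch estimator settings.

    PSD uses 2 s windows (0.5 Hz resolution at 256 Hz, so delta spans six
    bins). Coherence uses 1 s windows: with 50% overlap a 4 s epoch yields
    seven windows, putting the magnitude-squared-coherence noise floor near
    1/7 instead of the ~1/3 that three windows would give.
    """

    psd_window_s: float = 2.0
    coherence_window_s: float = 1.0
    overlap: float = 0.5
    window: str = "hann"


def _welch_args(window_s: float, overlap: float, fs: float) -> dict:
    nperseg = int(round(window_s * fs))
    return {"nperseg": nperseg, "noverlap": int(nperseg * overlap)}


# ---------------------------------------------------------------------------
# scalar building blocks


def psd(channel_signal: np.ndarray, sampling_rate: float,
        config: EstimatorConfig = EstimatorConfig()) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectral density of a single channel."""
    x = np.asarray(channel_signal, dtype=float)
    args = _welch_args(config.psd_window_s, config.overlap, sampling_rate)
    if x.shape[-1] < args["nperseg"]:
        raise ValueError(
            f"signal length {x.shape[-1]} shorter than Welch window "
            f"{args['nperseg']}"
        )
    return signal.welch(x, fs=sampling_rate, window=config.window, **args)


def band_power(freqs: np.ndarray, density: np.ndarray, band: BandDefinition) -> float:
    """Integrated PSD over the half-open interval [band.low, band.high)."""
    freqs = np.asarray(freqs)
    if band.low < freqs[0] or band.high > freqs[-1] + (freqs[1] - freqs[0]):
        raise ValueError(f"band {band.name} outside PSD frequency range")
    df = freqs[1] - freqs[0]
    mask = (freqs >= band.low) & (freqs < band.high)
    return float(np.sum(np.asarray(density)[..., mask], axis=-1) * df)


def relative_power(band_powers: np.ndarray) -> np.ndarray:
    """Band powers normalised to sum to one (order preserved)."""
    p = np.asarray(band_powers, dtype=float)
    total = p.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("all band powers are zero; relative power undefined")
    return p / total


def log_abs_power(power: float, eps: float = LOG_EPS) -> float:
    """Natural log of absolute band power, floored at ``eps``."""
    return float(np.log(max(float(power), eps)))


def asymmetry(power_right: float, power_left: float) -> float:
    """Signed normalised right-minus-left difference, in [-1, 1]."""
    denom = power_right + power_left
    if denom <= 0:
        raise ValueError("asymmetry undefined: both powers are zero")
    return float((power_right - power_left) / denom)


# ---------------------------------------------------------------------------
# feature vocabulary


def spectral_feature_names() -> list[str]:
    names = [f"{b}_rel_{ch}" for b in BAND_NAMES for ch in MONTAGE]
    names += [f"{b}_logabs_{ch}" for b in BAND_NAMES for ch in MONTAGE]
    names += [f"{b}_asym_{site}" for b in BAND_NAMES for site in ASYMMETRY_SITES]
    return names


def connectivity_feature_names() -> list[str]:
    return [
        f"{band}_coh_{a}_{b}" for band in COHERENCE_BANDS for a, b in CHANNEL_PAIRS
    ]


def fused_feature_names() -> list[str]:
    return spectral_feature_names() + connectivity_feature_names()


def export_vocabulary(path) -> None:
    """Write the canonical feature vocabulary as JSON."""
    vocab = {
        "spectral": spectral_feature_names(),
        "connectivity": connectivity_feature_names(),
        "fused": fused_feature_names(),
    }
    with open(path, "w") as fh:
        json.dump(vocab, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# per-segment vectors


def _band_power_matrix(seg: Segment, config: EstimatorConfig) -> np.ndarray:
    """(n_bands, n_channels) absolute band powers for one segment."""
    args = _welch_args(config.psd_window_s, config.overlap, seg.sampling_rate)
    freqs, dens = signal.welch(
        seg.samples, fs=seg.sampling_rate, window=config.window, **args
    )
    df = freqs[1] - freqs[0]
    out = np.empty((len(BANDS), seg.samples.shape[0]))
    for i, band in enumerate(BANDS):
        mask = (freqs >= band.low) & (freqs < band.high)
        out[i] = dens[:, mask].sum(axis=1) * df
    return out


def spectral_vector(segment: Segment,
                    config: EstimatorConfig = EstimatorConfig()) -> pd.Series:
    """90-dimensional asymmetry-aware spectral feature vector."""
    if tuple(segment.channels) != MONTAGE:
        raise ValueError("segment channels must be the canonical 8-channel montage")
    bp = _band_power_matrix(segment, config)  # (5, 8)
    rel = relative_power(bp.T).T              # per channel across bands
    ch_index = {ch: i for i, ch in enumerate(MONTAGE)}

    values: list[float] = []
    values += [rel[bi, ch_index[ch]] for bi in range(len(BANDS)) for ch in MONTAGE]
    values += [
        log_abs_power(bp[bi, ch_index[ch]])
        for bi in range(len(BANDS))
        for ch in MONTAGE
    ]
    # asymmetry on absolute band power; site value = mean of its two pairs
    for bi in range(len(BANDS)):
        for pairs in ASYMMETRY_SITES.values():
            vals = [
                asymmetry(bp[bi, ch_index[right]], bp[bi, ch_index[left]])
                for left, right in pairs
            ]
            values.append(float(np.mean(vals)))
    return pd.Series(values, index=spectral_feature_names(), dtype=float)


def coherence_spectrum(x: np.ndarray, y: np.ndarray, sampling_rate: float,
                       config: EstimatorConfig = EstimatorConfig()
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Welch magnitude-squared coherence |Pxy|^2 / (Pxx Pyy) per frequency bin."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("coherence requires equal-length signals")
    args = _welch_args(config.coherence_window_s, config.overlap, sampling_rate)
    step = args["nperseg"] - args["noverlap"]
    n_windows = 1 + max(0, (x.shape[-1] - args["nperseg"]) // step)
    if x.shape[-1] < args["nperseg"] or n_windows < 2:
        raise ValueError("coherence needs at least two Welch windows")
    freqs, coh = signal.coherence(
        x, y, fs=sampling_rate, window=config.window, **args
    )
    return freqs, np.clip(coh, 0.0, 1.0)


def connectivity_vector(segment: Segment,
                        config: EstimatorConfig = EstimatorConfig()) -> pd.Series:
    """56-dimensional coherence vector: alpha/beta mean MSC for 28 pairs."""
    if tuple(segment.channels) != MONTAGE:
        raise ValueError("segment channels must be the canonical 8-channel montage")
    fs = segment.sampling_rate
    args = _welch_args(config.coherence_window_s, config.overlap, fs)
    x = segment.samples
    freqs, pxx = signal.welch(x, fs=fs, window=config.window, **args)
    ia = [MONTAGE.index(a) for a, _ in CHANNEL_PAIRS]
    ib = [MONTAGE.index(b) for _, b in CHANNEL_PAIRS]
    _, pxy = signal.csd(x[ia], x[ib], fs=fs, window=config.window, **args)
    coh = np.abs(pxy) ** 2 / np.maximum(pxx[ia] * pxx[ib], 1e-300)
    coh = np.clip(coh, 0.0, 1.0)

    values: list[float] = []
    for band_name in COHERENCE_BANDS:
        band = next(b for b in BANDS if b.name == band_name)
        mask = (freqs >= band.low) & (freqs < band.high)
        values.extend(coh[:, mask].mean(axis=1))
    return pd.Series(values, index=connectivity_feature_names(), dtype=float)


def fuse(spectral: pd.Series, connectivity: pd.Series) -> pd.Series:
    """146-dimensional naive early fusion: spectral names first, then coherence.

    No rescaling or projection is applied; the fused vector is the plain
    concatenation.
    """
    if list(spectral.index) != spectral_feature_names():
        raise ValueError("spectral vector does not carry the canonical vocabulary")
    if list(connectivity.index) != connectivity_feature_names():
        raise ValueError("connectivity vector does not carry the canonical vocabulary")
    return pd.concat([spectral, connectivity])


# ---------------------------------------------------------------------------
# batch extraction

META_COLUMNS = ("subject_key", "condition", "segment_index")


def extract_features(segments: list[Segment],
                     config: EstimatorConfig = EstimatorConfig()) -> pd.DataFrame:
    """Feature table for a list of segments.

    Columns: subject_key, condition, segment_index, then the 146 fused
    feature names (spectral block first).
    """
    rows = []
    for seg in segments:
        fused = fuse(spectral_vector(seg, config), connectivity_vector(seg, config))
        meta = pd.Series(
            {"subject_key": seg.subject_key, "condition": seg.condition,
             "segment_index": seg.index}
        )
        rows.append(pd.concat([meta, fused]))
    return pd.DataFrame(rows).reset_index(drop=True)
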