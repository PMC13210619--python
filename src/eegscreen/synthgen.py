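"""Synthetic resting-state EEG cohort generator.

Emulates the statistical structure the downstream analysis assumes, written
out in the public-dataset class-folder layout (``<root>/MDD``, ``<root>/H``)
with raw subject identifiers restarted per folder so that IDs are reused
across diagnostic classes — the identity pathology the cohort reader must
correct.

Signal model per channel: a 1/f aperiodic background plus five band-limited
Gaussian processes (white noise filtered into the canonical bands) whose
variances carry the planted class effects and per-subject fingerprints, plus
a shared alpha-band latent source mixed into designated fronto-parietal
channel pairs with class-dependent coupling weights, plus occasional short
high-amplitude artefact bursts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .containers import CLASS_LABELS, MONTAGE, RawRecording
from .features import BAND_NAMES, BANDS

log = logging.getLogger(__name__)

#: Baseline band variances in µV² (total band variance 180 µV², background 40
#: µV² => signal RMS ~ 15 µV, keeping clean segments well inside a 100 µV
#: rejection threshold).
BASE_BAND_VAR: dict[str, float] = {
    "delta": 54.0,
    "theta": 27.0,
    "alpha": 54.0,
    "beta": 32.4,
    "gamma": 12.6,
}

#: Eyes-closed recordings show stronger posterior-dominant alpha.
CONDITION_ALPHA_GAIN: dict[str, float] = {"EO": 0.9, "EC": 1.25}

#: Channels carrying the elevated-relative-beta patient effect.
BETA_EFFECT_CHANNELS: tuple[str, ...] = ("F3", "F4", "C3", "C4")

#: Frontal channels carrying the alpha-asymmetry shift (left, right).
ASYM_EFFECT_CHANNELS: tuple[tuple[str, str], ...] = (("Fp1", "Fp2"), ("F3", "F4"))

ARTEFACT_DURATION_S = 0.2
ARTEFACT_AMP_RANGE_UV = (150.0, 400.0)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of one synthetic cohort; the cohort is a pure
    function of this spec (including its seed)."""

    n_patients: int = 31
    n_controls: int = 25
    sampling_rate: float = 256.0
    channels: tuple[str, ...] = MONTAGE
    #: inclusion probabilities for the per-subject condition inventory
    condition_probs: dict[str, float] = field(
        default_factory=lambda: {"both": 0.7, "EO": 0.15, "EC": 0.15}
    )
    duration_range: tuple[float, float] = (90.0, 130.0)
    #: multiplicative factor on fronto-central beta variance, patient class
    effect_beta_gain: float = 1.5
    #: signed shift of right-minus-left frontal alpha variance share, patients
    effect_alpha_asym_shift: float = 0.3
    coupling_pairs: tuple[tuple[str, str], ...] = (("F3", "P3"), ("F4", "P4"))
    coupling_control: float = 0.6
    coupling_mdd: float = 0.3
    #: spread (log scale) of stable per-subject per-band gain offsets
    fingerprint_sd: float = 0.15
    artefact_rate: float = 2.0      # expected bursts per minute
    aperiodic_exponent: float = 1.0  # 1/f slope of the background
    aperiodic_var: float = 40.0      # µV²
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("both classes need at least one subject")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if not (0.0 <= self.coupling_control <= 1.0
                and 0.0 <= self.coupling_mdd <= 1.0):
            raise ValueError("coupling weights must lie in [0, 1]")
        if self.duration_range[0] > self.duration_range[1]:
            raise ValueError("duration_range min must not exceed max")
        if abs(sum(self.condition_probs.values()) - 1.0) > 1e-9:
            raise ValueError("condition inclusion probabilities must sum to 1")


@dataclass(frozen=True)
class SubjectParams:
    """Ground-truth generative parameters for one subject.

    Regeneration from (class_label, subject_index, spec) is bit-identical;
    fingerprint offsets are drawn once and shared by all of the subject's
    recordings.
    """

    subject_key: str
    class_label: str
    raw_id: str
    #: per-band per-channel variance gains (fingerprint folded in), > 0
    gains: dict[str, dict[str, float]]
    #: per designated pair, in [0, 1]
    coupling: dict[tuple[str, str], float]
    #: stable per-band log-gain offsets (the identity fingerprint)
    fingerprint: dict[str, float]
    asymmetry_offset: float
    stream_seed: int


def _subject_seedseq(spec: CohortSpec, class_label: str, subject_index: int
                     ) -> np.random.SeedSequence:
    # per-subject streams derived by hashing (cohort seed, class, index)
    return np.random.SeedSequence(
        [int(spec.seed), CLASS_LABELS.index(class_label), int(subject_index)]
    )


def draw_subject_params(class_label: str, subject_index: int,
                        spec: CohortSpec) -> SubjectParams:
    """Draw the stable generative parameters for one subject.

    The expected fronto-central beta gain of the patient class exceeds the
    control class by exactly ``spec.effect_beta_gain`` (the fingerprint is a
    mean-one lognormal multiplier), and the designated fronto-parietal
    coupling weight is lower for patients by the configured contrast.
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {class_label!r}")
    ss = _subject_seedseq(spec, class_label, subject_index)
    rng = np.random.default_rng(ss)
    sd = spec.fingerprint_sd
    # mean-one lognormal: E[exp(N(-sd^2/2, sd))] = 1
    fingerprint = {
        b: float(rng.normal(-0.5 * sd * sd, sd)) if sd > 0 else 0.0
        for b in BAND_NAMES
    }

    gains: dict[str, dict[str, float]] = {}
    for band in BAND_NAMES:
        fp_mult = float(np.exp(fingerprint[band]))
        row: dict[str, float] = {}
        for ch in spec.channels:
            g = fp_mult
            if (class_label == "MDD" and band == "beta"
                    and ch in BETA_EFFECT_CHANNELS):
                g *= spec.effect_beta_gain
            if class_label == "MDD" and band == "alpha":
                shift = spec.effect_alpha_asym_shift
                for left, right in ASYM_EFFECT_CHANNELS:
                    if ch == right:
                        g *= 1.0 + shift
                    elif ch == left:
                        g *= 1.0 - shift
            row[ch] = g
        gains[band] = row

    w = spec.coupling_mdd if class_label == "MDD" else spec.coupling_control
    coupling = {pair: w for pair in spec.coupling_pairs}
    raw_id = f"S{subject_index + 1}"
    stream_seed = int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)
    return SubjectParams(
        subject_key=f"{class_label}_{raw_id}",
        class_label=class_label,
        raw_id=raw_id,
        gains=gains,
        coupling=coupling,
        fingerprint=fingerprint,
        asymmetry_offset=(spec.effect_alpha_asym_shift
                          if class_label == "MDD" else 0.0),
        stream_seed=stream_seed,
    )


# ---------------------------------------------------------------------------
# signal synthesis


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        low: float, high: float, m: int = 1) -> np.ndarray:
    """(m, n) unit-variance Gaussian processes band-limited to [low, high]."""
    sos = sp_signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, rng.standard_normal((m, n)), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _aperiodic_background(rng: np.random.Generator, n: int, fs: float,
                          exponent: float, var: float) -> np.ndarray:
    """1/f^exponent coloured noise with the requested variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x * np.sqrt(var)


def synth_recording(params: SubjectParams, condition: str, duration_s: float,
                    seed: int, spec: CohortSpec) -> RawRecording:
    """Synthesize one recording for a subject under one condition."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if condition not in CONDITION_ALPHA_GAIN:
        raise ValueError(f"unknown condition {condition!r}")
    fs = spec.sampling_rate
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(np.random.SeedSequence([params.stream_seed,
                                                        int(seed)]))
    n_ch = len(spec.channels)
    ch_index = {ch: i for i, ch in enumerate(spec.channels)}
    data = np.zeros((n_ch, n))

    if spec.aperiodic_var > 0:
        for i in range(n_ch):
            data[i] += _aperiodic_background(
                rng, n, fs, spec.aperiodic_exponent, spec.aperiodic_var
            )

    coupled: dict[str, float] = {}
    for (a, b), w in params.coupling.items():
        coupled[a] = w
        coupled[b] = w
    alpha_band = next(b for b in BANDS if b.name == "alpha")
    shared: dict[tuple[str, str], np.ndarray] = {
        pair: _band_limited_noise(rng, n, fs, alpha_band.low, alpha_band.high)[0]
        for pair in params.coupling
    }

    for band in BANDS:
        base_var = BASE_BAND_VAR[band.name]
        cond_gain = CONDITION_ALPHA_GAIN[condition] if band.name == "alpha" else 1.0
        private = _band_limited_noise(rng, n, fs, band.low, band.high, m=n_ch)
        for ch in spec.channels:
            i = ch_index[ch]
            var = base_var * cond_gain * params.gains[band.name][ch]
            if var <= 0:
                continue
            unit = private[i]
            if band.name == "alpha" and ch in coupled:
                w = coupled[ch]
                pair = next(p for p in params.coupling if ch in p)
                unit = (np.sqrt(1.0 - w) * private[i]
                        + np.sqrt(w) * shared[pair])
            data[i] += unit * np.sqrt(var)

    if spec.artefact_rate > 0:
        expected = spec.artefact_rate * duration_s / 60.0
        n_bursts = rng.poisson(expected)
        burst_len = int(round(ARTEFACT_DURATION_S * fs))
        window = sp_signal.windows.hann(burst_len)
        for _ in range(n_bursts):
            start = int(rng.integers(0, max(1, n - burst_len)))
            amp = rng.uniform(*ARTEFACT_AMP_RANGE_UV) * rng.choice([-1.0, 1.0])
            ch = int(rng.integers(0, n_ch))
            data[ch, start:start + burst_len] += amp * window

    return RawRecording(
        samples=data, sampling_rate=fs, channels=tuple(spec.channels),
        subject_key=params.subject_key, condition=condition,
    )


# ---------------------------------------------------------------------------
# cohort writing


def _draw_schedule(spec: CohortSpec, class_label: str, subject_index: int
                   ) -> list[tuple[str, float, int]]:
    """(condition, duration_s, recording_seed) inventory for one subject."""
    ss = _subject_seedseq(spec, class_label, subject_index).spawn(1)[0]
    rng = np.random.default_rng(ss)
    names = sorted(spec.condition_probs)
    probs = [spec.condition_probs[k] for k in names]
    choice = rng.choice(names, p=probs)
    conditions = ["EO", "EC"] if choice == "both" else [str(choice)]
    out = []
    for k, cond in enumerate(conditions):
        dur = float(rng.uniform(*spec.duration_range))
        out.append((cond, dur, k))
    return out


def _params_to_json(p: SubjectParams) -> dict:
    return {
        "subject_key": p.subject_key,
        "class_label": p.class_label,
        "raw_id": p.raw_id,
        "gains": p.gains,
        "coupling": {f"{a}-{b}": w for (a, b), w in p.coupling.items()},
        "fingerprint": p.fingerprint,
        "asymmetry_offset": p.asymmetry_offset,
        "stream_seed": p.stream_seed,
    }


def write_recording(rec: RawRecording, path: Path) -> None:
    """Write a recording as flat float32 binary plus a JSON sidecar header."""
    data = rec.samples.astype(np.float32)
    path.with_suffix(".dat").write_bytes(data.tobytes(order="C"))
    header = {
        "channels": list(rec.channels),
        "sampling_rate": rec.sampling_rate,
        "n_channels": data.shape[0],
        "n_samples": data.shape[1],
        "duration_s": data.shape[1] / rec.sampling_rate,
        "condition": rec.condition,
        "unit": "uV",
        "dtype": "float32",
    }
    path.with_suffix(".json").write_text(
        json.dumps(header, sort_keys=True, indent=1)
    )


def write_cohort(spec: CohortSpec, root) -> Path:
    """Write a full synthetic cohort in the class-folder layout.

    Raw IDs S1..Sn restart in each class folder, so every ID up to
    min(n_patients, n_controls) occurs in BOTH folders. A manifest at the
    root records the ground-truth subject parameters for recovery tests.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "spec": _spec_to_json(spec),
        "subjects": [],
    }
    for class_label, count in (("MDD", spec.n_patients), ("H", spec.n_controls)):
        folder = root / class_label
        folder.mkdir(exist_ok=True)
        for idx in range(count):
            params = draw_subject_params(class_label, idx, spec)
            schedule = _draw_schedule(spec, class_label, idx)
            recs = []
            for cond, dur, k in schedule:
                target = folder / f"{params.raw_id}_{cond}"
                if target.with_suffix(".dat").exists():
                    raise FileExistsError(f"path collision at {target}")
                rec = synth_recording(params, cond, dur, seed=k, spec=spec)
                write_recording(rec, target)
                recs.append({"condition": cond, "duration_s": dur,
                             "file": f"{class_label}/{params.raw_id}_{cond}.dat"})
            entry = _params_to_json(params)
            entry["recordings"] = recs
            manifest["subjects"].append(entry)
    (root / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1)
    )
    return root


def _spec_to_json(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["channels"] = list(spec.channels)
    d["coupling_pairs"] = [list(p) for p in spec.coupling_pairs]
    d["duration_range"] = list(spec.duration_range)
    return d


def load_manifest(root) -> dict:
    with open(Path(root) / "manifest.json") as fh:
        return json.load(fh)


# convenience cohort variants used throughout tests and the acceptance script


def null_spec(**overrides) -> CohortSpec:
    """Cohort with all class effects switched off (chance-level control)."""
    base = dict(effect_beta_gain=1.0, effect_alpha_asym_shift=0.0,
                coupling_mdd=0.6, coupling_control=0.6)
    base.update(overrides)
    return CohortSpec(**base)


def fingerprint_only_spec(**overrides) -> CohortSpec:
    """No class effects but strong stable subject fingerprints: the cohort on
    which segment-wise splitting inflates accuracy while subject-wise
    splitting stays at chance."""
    base = dict(effect_beta_gain=1.0, effect_alpha_asym_shift=0.0,
                coupling_mdd=0.6, coupling_control=0.6, fingerprint_sd=0.3)
    base.update(overrides)
    return CohortSpec(**base)
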