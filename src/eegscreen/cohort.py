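"""Identity-corrected cohort construction from a class-folder dataset.

The public-dataset layout groups recordings under one folder per diagnostic
class and reuses raw subject identifiers (S1, S7, ...) across folders while
referring to different individuals. Any pipeline keying on the raw ID alone
silently merges distinct participants across classes. The composite subject
key ``label + "_" + raw_id`` disambiguates them; all downstream grouping,
splitting and aggregation operates on that key.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CLASS_LABELS, RawRecording

log = logging.getLogger(__name__)

#: Folder-name aliases; the public release's folder naming is not canonical.
DEFAULT_FOLDER_ALIASES: dict[str, str] = {
    "MDD": "MDD",
    "H": "H",
    "Healthy": "H",
    "HC": "H",
}

KEY_SEPARATOR = "_"


def make_subject_key(label: str, raw_id: str) -> str:
    """Composite subject key: ``label`` and ``raw_id`` joined by ``"_"``."""
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {label!r}")
    if not raw_id:
        raise ValueError("raw_id must be nonempty")
    return f"{label}{KEY_SEPARATOR}{raw_id}"


def parse_subject_key(subject_key: str) -> tuple[str, str]:
    """Inverse of :func:`make_subject_key`; splits at the FIRST underscore
    only, since raw IDs may themselves contain underscores."""
    label, sep, raw_id = subject_key.partition(KEY_SEPARATOR)
    if not sep or label not in CLASS_LABELS or not raw_id:
        raise ValueError(f"malformed subject key {subject_key!r}")
    return label, raw_id


@dataclass
class RecordingRef:
    condition: str
    path: Path
    duration_s: float


@dataclass
class SubjectRecord:
    subject_key: str
    class_label: str
    raw_id: str
    recordings: list[RecordingRef] = field(default_factory=list)


@dataclass
class Roster:
    records: list[SubjectRecord]

    @property
    def subject_keys(self) -> list[str]:
        return [r.subject_key for r in self.records]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASS_LABELS}
        for r in self.records:
            counts[r.class_label] += 1
        return counts

    @property
    def reused_raw_ids(self) -> set[str]:
        by_class: dict[str, set[str]] = {c: set() for c in CLASS_LABELS}
        for r in self.records:
            by_class[r.class_label].add(r.raw_id)
        return by_class["MDD"] & by_class["H"]

    def labels(self) -> dict[str, str]:
        return {r.subject_key: r.class_label for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_key": r.subject_key,
                "class": r.class_label,
                "n_recordings": len(r.recordings),
                "total_duration_s": sum(x.duration_s for x in r.recordings),
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def export_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_recording(path, subject_key: str = "", condition: str = ""
                   ) -> RawRecording:
    """Read one recording: flat binary + JSON sidecar, or EDF when MNE is
    available."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, subject_key, condition)
    header = json.loads(path.with_suffix(".json").read_text())
    data = np.frombuffer(path.with_suffix(".dat").read_bytes(),
                         dtype=header["dtype"])
    data = data.reshape(header["n_channels"], header["n_samples"])
    return RawRecording(
        samples=data.astype(float),
        sampling_rate=float(header["sampling_rate"]),
        channels=tuple(header["channels"]),
        subject_key=subject_key,
        condition=condition or header.get("condition", ""),
    )


def _read_edf(path: Path, subject_key: str, condition: str) -> RawRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("reading EDF requires MNE-Python") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return RawRecording(
        samples=raw.get_data() * 1e6,  # volts -> µV
        sampling_rate=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        subject_key=subject_key,
        condition=condition,
    )


def _scan_class_folders(root: Path, aliases: dict[str, str]
                        ) -> dict[str, dict[str, list[tuple[str, Path, float]]]]:
    """{label: {raw_id: [(condition, path, duration_s), ...]}} from disk."""
    by_class: dict[str, dict[str, list[tuple[str, Path, float]]]] = {}
    folders = sorted(p for p in root.iterdir() if p.is_dir())
    if not folders:
        raise ValueError(f"no class folders under {root}")
    for folder in folders:
        if folder.name not in aliases:
            raise ValueError(f"unknown class folder {folder.name!r}")
        label = aliases[folder.name]
        subjects = by_class.setdefault(label, {})
        files = sorted(
            list(folder.glob("*.dat")) + list(folder.glob("*.edf"))
        )
        for f in files:
            raw_id, _, condition = f.stem.rpartition("_")
            if not raw_id:
                raw_id, condition = f.stem, ""
            if f.suffix == ".dat":
                header = json.loads(f.with_suffix(".json").read_text())
                duration = float(header["duration_s"])
                condition = header.get("condition", condition)
            else:
                duration = float("nan")
            entries = subjects.setdefault(raw_id, [])
            if any(c == condition for c, _, _ in entries):
                raise ValueError(
                    f"duplicate file for ({label}, {raw_id}, {condition})"
                )
            entries.append((condition, f, duration))
    return by_class


def build_roster(dataset_root, aliases: dict[str, str] | None = None) -> Roster:
    """One SubjectRecord per (class, raw_id), keyed by the composite key.

    Subjects with zero usable recordings are excluded with a logged warning.
    The result is invariant to file enumeration order.
    """
    root = Path(dataset_root)
    by_class = _scan_class_folders(root, aliases or DEFAULT_FOLDER_ALIASES)
    records: list[SubjectRecord] = []
    for label in sorted(by_class):
        for raw_id in sorted(by_class[label]):
            entries = sorted(by_class[label][raw_id])
            if not entries:
                log.warning("subject (%s, %s) has no usable recordings; dropped",
                            label, raw_id)
                continue
            records.append(
                SubjectRecord(
                    subject_key=make_subject_key(label, raw_id),
                    class_label=label,
                    raw_id=raw_id,
                    recordings=[RecordingRef(c, p, d) for c, p, d in entries],
                )
            )
    keys = [r.subject_key for r in records]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate composite subject keys in roster")
    return Roster(records=records)


@dataclass
class IdentityAuditReport:
    """What naive raw-ID-keyed grouping would do to this dataset."""

    reused_raw_ids: set[str]
    #: number of raw IDs whose records naive grouping would merge across classes
    merged_group_count: int
    #: total corrected subjects that would collapse into those merged groups
    records_merged: int
    per_class_raw_ids: dict[str, set[str]]


def audit_identity(dataset_root, aliases: dict[str, str] | None = None
                   ) -> IdentityAuditReport:
    """List raw IDs appearing in multiple classes and the record count that
    raw-ID-keyed grouping would silently merge."""
    root = Path(dataset_root)
    by_class = _scan_class_folders(root, aliases or DEFAULT_FOLDER_ALIASES)
    per_class = {label: set(subjects) for label, subjects in by_class.items()}
    classes = sorted(per_class)
    reused: set[str] = set()
    if len(classes) >= 2:
        reused = set.intersection(*(per_class[c] for c in classes))
    records_merged = sum(
        sum(1 for c in classes if rid in per_class[c]) for rid in reused
    )
    return IdentityAuditReport(
        reused_raw_ids=reused,
        merged_group_count=len(reused),
        records_merged=records_merged,
        per_class_raw_ids=per_class,
    )
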