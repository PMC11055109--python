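"""Reading and writing the pipeline's on-disk formats.

EEG interchange is plain CSV: ``#``-prefixed metadata lines carrying the
sampling rate and event marks, then a header row of channel labels with a
leading ``time`` column (seconds), then one row per sample.  KSS tables
are CSV with columns ``subject_id, group, time_min, score``.  A dataset
manifest is a YAML file listing every recording with its group and the
cohort's KSS table.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .recording import GROUPS, CohortDataset, EEGRecording, KSSRecord, kss_frame


class FormatError(ValueError):
    """A file does not parse under its declared format."""


# ---------------------------------------------------------------- EEG CSV

def write_eeg_csv(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording as CSV (floats at 6 significant digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {recording.sampling_rate:g}\n")
        for name, minute in sorted(recording.events.items()):
            fh.write(f"# event: {name}={minute:g}\n")
        fh.write("time," + ",".join(recording.channel_labels) + "\n")
        t = recording.times()
        data = np.vstack([t, recording.samples]).T
        np.savetxt(fh, data, fmt="%.6g", delimiter=",")
    return path


def read_eeg(path: str | Path, format: str = "csv") -> EEGRecording:
    """Read an EEG file into an :class:`EEGRecording`.

    Only the ``csv`` format tag is supported; the sampling rate is taken
    from the ``# sampling_rate_hz`` metadata line, or inferred from the
    ``time`` column when the line is absent.
    """
    if format != "csv":
        raise FormatError(f"unsupported EEG format {format!r}; supported: 'csv'")
    return read_eeg_csv(path)


def read_eeg_csv(path: str | Path) -> EEGRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sampling_rate: float | None = None
    events: dict[str, float] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                meta = stripped.lstrip("#").strip()
                if meta.startswith("sampling_rate_hz"):
                    sampling_rate = float(meta.split(":", 1)[1])
                elif meta.startswith("event"):
                    name, value = meta.split(":", 1)[1].split("=")
                    events[name.strip()] = float(value)
            elif stripped:
                body_lines.append(line)
    if not body_lines:
        raise FormatError(f"{path}: no data rows")
    raw = pd.read_csv(_io.StringIO("".join(body_lines)), dtype=str)
    raw.columns = [c.strip() for c in raw.columns]
    if raw.isna().any().any():
        r, c = np.argwhere(raw.isna().to_numpy())[0]
        raise FormatError(f"{path}: ragged/missing cell at data row {r + 1}, column {raw.columns[c]!r}")
    numeric = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise FormatError(
                f"{path}: non-numeric cell {raw[col].iloc[row]!r} at data row {row + 1}, "
                f"column {col!r}"
            )
        numeric[col] = converted.to_numpy(dtype=float)
    channel_cols = [c for c in raw.columns if c.lower() != "time"]
    if sampling_rate is None:
        if "time" not in [c.lower() for c in raw.columns]:
            raise FormatError(
                f"{path}: unknown sampling rate (no '# sampling_rate_hz' line and no time column)"
            )
        time_col = next(c for c in raw.columns if c.lower() == "time")
        dt = np.diff(numeric[time_col])
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-4):
            raise FormatError(f"{path}: time column is not uniformly sampled")
        sampling_rate = 1.0 / float(np.mean(dt))
    samples = np.vstack([numeric[c] for c in channel_cols])
    return EEGRecording(
        samples=samples,
        sampling_rate=float(sampling_rate),
        channel_labels=tuple(channel_cols),
        events=events,
    )


# ---------------------------------------------------------------- KSS CSV

KSS_COLUMNS = ("subject_id", "group", "time_min", "score")


def write_kss_csv(records: list[KSSRecord] | pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else kss_frame(records)
    df.to_csv(path, index=False)
    return path


def read_kss(path: str | Path) -> list[KSSRecord]:
    """Read and validate a KSS table (scores must be integers in 1..9)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(KSS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing KSS columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        score = int(row["score"])
        if not 1 <= score <= 9:
            raise FormatError(
                f"{path}: KSS score {row['score']} outside 1..9 for subject {row['subject_id']!r}"
            )
        records.append(
            KSSRecord(str(row["subject_id"]), str(row["group"]), float(row["time_min"]), score)
        )
    return records


# ---------------------------------------------------------------- manifest

@dataclass
class ManifestEntry:
    subject_id: str
    group: str
    eeg_path: str
    format: str = "csv"


@dataclass
class DatasetManifest:
    """A structured listing of one study's files (paths relative to the manifest)."""

    study: str
    kss_path: str
    entries: list[ManifestEntry] = field(default_factory=list)

    def validate(self, root: Path) -> None:
        for entry in self.entries:
            if entry.group not in GROUPS:
                raise FormatError(f"manifest entry {entry.subject_id}: unknown group {entry.group!r}")
            if not (root / entry.eeg_path).exists():
                raise FileNotFoundError(root / entry.eeg_path)
        if not (root / self.kss_path).exists():
            raise FileNotFoundError(root / self.kss_path)


def save_dataset(dataset: CohortDataset, out_dir: str | Path) -> Path:
    """Write every recording, the KSS table, and a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for group, by_subject in dataset.recordings.items():
        for sid, rec in by_subject.items():
            name = f"{group}_{sid}.csv"
            write_eeg_csv(rec, out / name)
            entries.append(ManifestEntry(subject_id=sid, group=group, eeg_path=name))
    write_kss_csv(dataset.kss, out / "kss.csv")
    manifest = {
        "study": dataset.study,
        "kss_path": "kss.csv",
        "entries": [vars(e) for e in entries],
    }
    path = out / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def load_dataset(manifest_path: str | Path) -> CohortDataset:
    """Read a manifest and every file it references into a :class:`CohortDataset`."""
    manifest_path = Path(manifest_path)
    raw = yaml.safe_load(manifest_path.read_text())
    manifest = DatasetManifest(
        study=raw["study"],
        kss_path=raw["kss_path"],
        entries=[ManifestEntry(**e) for e in raw["entries"]],
    )
    root = manifest_path.parent
    manifest.validate(root)
    recordings: dict[str, dict[str, EEGRecording]] = {}
    for entry in manifest.entries:
        recordings.setdefault(entry.group, {})[entry.subject_id] = read_eeg(
            root / entry.eeg_path, entry.format
        )
    kss = kss_frame(read_kss(root / manifest.kss_path))
    return CohortDataset(study=manifest.study, recordings=recordings, kss=kss)
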