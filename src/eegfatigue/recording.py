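"""Core data containers: recordings, epochs, sleepiness scores, cohorts."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("control", "peppermint", "grapefruit", "lavender")
SCENTS = ("peppermint", "grapefruit", "lavender")

#: Default derivation: the two temporal-lobe electrodes of a 10-20 montage.
TEMPORAL_CHANNELS = ("T7", "T8")


@dataclass
class EEGRecording:
    """A multichannel sampled EEG signal.

    Parameters
    ----------
    samples
        ``(n_channels, n_samples)`` float array, arbitrary signal units.
    sampling_rate
        Sampling frequency in Hz.
    channel_labels
        One label per row of ``samples``.
    events
        Named minute marks (e.g. ``{"task_start": 0.0, "intervention": 30.0}``).
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] = TEMPORAL_CHANNELS
    events: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} channel rows but "
                f"{len(self.channel_labels)} labels {list(self.channel_labels)}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not found; available: {list(self.channel_labels)}"
            ) from None
        return self.samples[idx]

    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class Epoch:
    """A fixed-length single-channel segment of a recording."""

    samples: np.ndarray
    sampling_rate: float
    start_min: float
    duration_s: float = 60.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        expected = int(round(self.duration_s * self.sampling_rate))
        if self.samples.size != expected:
            raise ValueError(
                f"epoch at minute {self.start_min}: {self.samples.size} samples, "
                f"expected {expected} ({self.duration_s} s at {self.sampling_rate} Hz)"
            )
        if self.start_min < 0:
            raise ValueError("start_min must be >= 0")


@dataclass(frozen=True)
class KSSRecord:
    """One Karolinska Sleepiness Scale answer (ordinal 1-9)."""

    subject_id: str
    group: str
    time_min: float
    score: int

    def __post_init__(self) -> None:
        if not (1 <= int(self.score) <= 9):
            raise ValueError(
                f"KSS score {self.score} for subject {self.subject_id!r} outside 1..9"
            )
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")


def kss_frame(records: list[KSSRecord]) -> pd.DataFrame:
    """Tabulate KSS records (columns: subject_id, group, time_min, score)."""
    return pd.DataFrame(
        [(r.subject_id, r.group, r.time_min, int(r.score)) for r in records],
        columns=["subject_id", "group", "time_min", "score"],
    )


@dataclass
class CohortDataset:
    """Recordings plus KSS answers for one study.

    ``recordings`` maps group -> subject_id -> EEGRecording; the
    identification study uses the single group ``"control"``.
    """

    study: str
    recordings: dict[str, dict[str, EEGRecording]]
    kss: pd.DataFrame

    def groups(self) -> list[str]:
        return list(self.recordings)

    def subjects(self, group: str) -> list[str]:
        return sorted(self.recordings[group])

    def kss_score(self, group: str, subject_id: str, time_min: float) -> int:
        df = self.kss
        row = df[
            (df.group == group) & (df.subject_id == subject_id) & (df.time_min == time_min)
        ]
        if len(row) != 1:
            raise KeyError(
                f"expected exactly one KSS score for {subject_id}/{group} at "
                f"minute {time_min}, found {len(row)}"
            )
        return int(row.score.iloc[0])
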