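"""Denoising and segmentation: causal high-pass, channel aggregation, epoching."""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .recording import EEGRecording, Epoch

#: Cutoff of the drift-removal stage, matching a first-order analog RC front end.
DEFAULT_HIGHPASS_HZ = 0.16


def highpass(
    recording: EEGRecording, cutoff_hz: float = DEFAULT_HIGHPASS_HZ, order: int = 1
) -> EEGRecording:
    """Remove DC and slow drift with a causal first-order high-pass filter.

    Realized as the bilinear transform of the analog RC high-pass (a
    first-order Butterworth), applied forward-only: the stage emulates a
    causal analog front end, so zero-phase two-pass filtering is
    deliberately not used.  The −3 dB point sits at ``cutoff_hz``; gain at
    10 Hz is within 0.5 % of unity for the default cutoff.
    """
    nyquist = recording.sampling_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie below Nyquist ({nyquist} Hz)")
    b, a = sps.butter(order, cutoff_hz, btype="highpass", fs=recording.sampling_rate)
    filtered = sps.lfilter(b, a, recording.samples, axis=1)
    return EEGRecording(
        samples=filtered,
        sampling_rate=recording.sampling_rate,
        channel_labels=recording.channel_labels,
        events=dict(recording.events),
    )


def aggregate_temporal(
    recording: EEGRecording, channels: tuple[str, ...] | None = None
) -> EEGRecording:
    """Average the temporal-lobe channels into one derived channel.

    With ``channels=None`` all channels of the recording are averaged.
    """
    if channels is None:
        data = recording.samples
    else:
        missing = [c for c in channels if c not in recording.channel_labels]
        if missing:
            raise KeyError(
                f"channels {missing} not in recording; available: "
                f"{list(recording.channel_labels)}"
            )
        rows = [recording.channel_labels.index(c) for c in channels]
        data = recording.samples[rows]
    return EEGRecording(
        samples=data.mean(axis=0, keepdims=True),
        sampling_rate=recording.sampling_rate,
        channel_labels=("temporal_mean",),
        events=dict(recording.events),
    )


def epoch_split(
    recording: EEGRecording, window_s: float = 60.0, step_s: float | None = None
) -> list[Epoch]:
    """Cut a single-channel recording into fixed windows (default 1 min, no overlap).

    Windows are left-aligned; a trailing partial window is dropped.
    """
    if recording.n_channels != 1:
        raise ValueError(
            f"epoching expects a single-channel recording (got {recording.n_channels}); "
            "aggregate channels first"
        )
    if step_s is None:
        step_s = window_s
    win = int(round(window_s * recording.sampling_rate))
    step = int(round(step_s * recording.sampling_rate))
    if win > recording.n_samples:
        raise ValueError(
            f"window of {window_s} s exceeds recording length "
            f"({recording.duration_s:.1f} s): no epochs"
        )
    x = recording.samples[0]
    epochs = []
    for start in range(0, recording.n_samples - win + 1, step):
        epochs.append(
            Epoch(
                samples=x[start : start + win],
                sampling_rate=recording.sampling_rate,
                start_min=start / recording.sampling_rate / 60.0,
                duration_s=window_s,
            )
        )
    return epochs


def preprocess(
    recording: EEGRecording,
    cutoff_hz: float = DEFAULT_HIGHPASS_HZ,
    channels: tuple[str, ...] | None = None,
    window_s: float = 60.0,
) -> list[Epoch]:
    """Full front end: high-pass, temporal average, 1-min epochs."""
    return epoch_split(
        aggregate_temporal(highpass(recording, cutoff_hz), channels), window_s
    )


def two_minute_means(values: np.ndarray) -> np.ndarray:
    """Collapse a per-minute series into 2-min means (pairs of consecutive minutes).

    A trailing odd minute is dropped.
    """
    v = np.asarray(values, dtype=float)
    n = (v.size // 2) * 2
    return v[:n].reshape(-1, 2).mean(axis=1)
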