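"""Synthetic EEG + KSS cohort generator.

Emulates the band-power structure of temporal-lobe EEG during a monotonous
simulated-driving task: slow-wave (theta) activity drifts up, fast-wave
(alpha, beta, gamma) activity drifts down — beta most — and a timed scent
release (peppermint, grapefruit or lavender) transiently restores the
alpha/beta balance with a scent-specific trough and recovery.  Subjective
sleepiness (KSS, ordinal 1-9) rises with time on task and drops after a
scent intervention.

The signal model for each channel is

    x(t) = sum_b a_b(t) * m_b(t) * s_b(t) + eps(t)

where ``s_b`` is a zero-mean unit-variance band-limited process (a sum of
random-phase sinusoids on a 0.1 Hz grid inside band ``b``), ``a_b(t)`` the
piecewise-linear fatigue envelope, ``m_b(t)`` the intervention multiplier
(identity before release and for the control condition), and ``eps`` white
Gaussian noise.  The variance a band contributes over a stationary minute
is ``(a_b * m_b)**2``, so band-average PSD tracks squared amplitude.

No attempt is made at physiologically realistic morphology (no 1/f
background, no artifacts); only the band-power structure the downstream
ratio analysis consumes is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import calibration as cal
from .bands import BAND_BY_NAME, BANDS, MAX_ANALYSIS_HZ
from .recording import (
    GROUPS,
    SCENTS,
    CohortDataset,
    EEGRecording,
    KSSRecord,
    kss_frame,
)

Trajectory = list[tuple[float, float]]  # piecewise-linear (abscissa, value) knots


def default_fatigue_envelopes() -> dict[str, Trajectory]:
    """Per-band amplitude envelopes (signal units vs minute) for a fatiguing drive.

    Theta rises slightly, alpha declines slightly, beta declines most of the
    four bands, gamma declines moderately; all are piecewise linear with the
    magnitudes in :mod:`eegfatigue.calibration`.
    """
    return {
        name: [(m, cal.BAND_BASELINE[name] * rel) for m, rel in cal.RELATIVE_ENVELOPE[name]]
        for name in BAND_BY_NAME
    }


def intervention_multiplier(
    scent: str, minutes_since_release: float | np.ndarray
) -> dict[str, np.ndarray]:
    """Per-band amplitude multipliers at ``minutes_since_release`` after a scent release.

    The arousal effect boosts beta and mildly suppresses alpha along a
    scent-specific piecewise-linear effect shape, placing the induced
    alpha/beta-index trough at release + 2 min (grapefruit), + 3 min
    (peppermint) or + 4 min (lavender), with recovery fastest for
    peppermint and slowest for lavender.  ``control`` yields identity
    multipliers.  Negative times (before release) yield identity.
    """
    if scent not in GROUPS:
        raise ValueError(f"unknown scent {scent!r}; expected one of {GROUPS}")
    tau = np.asarray(minutes_since_release, dtype=float)
    ones = np.ones_like(tau)
    if scent == "control":
        return {name: ones.copy() for name in BAND_BY_NAME}
    knots = cal.INTERVENTION_SHAPE[scent]
    xs, ys = zip(*knots)
    effect = np.interp(tau, xs, ys, left=0.0, right=ys[-1])
    effect = np.where(tau < 0, 0.0, effect)
    return {
        "theta": ones.copy(),
        "alpha": 1.0 - cal.ALPHA_SUPPRESS * effect,
        "beta": 1.0 + cal.BETA_BOOST * effect,
        "gamma": ones.copy(),
    }


def scent_effect_trajectories(group: str) -> dict[str, Trajectory]:
    """The default per-band multiplier trajectories (vs minutes since release)."""
    if group == "control":
        return {name: [(0.0, 1.0)] for name in BAND_BY_NAME}
    taus = sorted({t for t, _ in cal.INTERVENTION_SHAPE[group]})
    mult = intervention_multiplier(group, np.array(taus))
    return {name: list(zip(taus, mult[name].tolist())) for name in BAND_BY_NAME}


@dataclass
class ScenarioConfig:
    """Everything that defines one simulated condition.

    ``band_envelopes`` are absolute amplitude trajectories (signal units vs
    minute); ``intervention_effect`` are per-band multiplier trajectories vs
    minutes since release (``None`` derives them from ``group``).  Identical
    ``(config, seed)`` pairs reproduce identical output bit for bit.
    """

    duration_min: float = cal.IDENTIFICATION_DURATION_MIN
    sampling_rate: float = cal.DEFAULT_SAMPLING_RATE
    n_subjects: int = cal.IDENTIFICATION_N_SUBJECTS
    group: str = "control"
    intervention_minute: float | None = None
    band_envelopes: dict[str, Trajectory] = field(default_factory=default_fatigue_envelopes)
    intervention_effect: dict[str, Trajectory] | None = None
    noise_sd: float = cal.NOISE_SD
    minute_amp_sd: float = cal.MINUTE_AMP_LOG_SD
    seed: int = 0
    # KSS latent model
    kss_minutes: tuple[float, ...] = cal.IDENTIFICATION_KSS_MINUTES
    kss_baseline: float = cal.KSS_IDENTIFICATION["control"][0]
    kss_drift: float = cal.KSS_IDENTIFICATION["control"][1]
    kss_drop: float = 0.0
    kss_subject_sd: float = cal.KSS_SUBJECT_SD
    kss_noise_sd: float = cal.KSS_NOISE_SD
    # between-subject EEG variability
    subject_scale_log_sd: float = cal.SUBJECT_SCALE_LOG_SD
    subject_slope_sd: float = cal.SUBJECT_SLOPE_SD
    response_gain_sd: float = cal.RESPONSE_GAIN_SD

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")
        if self.sampling_rate < 2 * MAX_ANALYSIS_HZ:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz is below the Nyquist "
                f"requirement 2 x {MAX_ANALYSIS_HZ} Hz for the gamma band"
            )
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        for name, traj in self.band_envelopes.items():
            if name not in BAND_BY_NAME:
                raise ValueError(f"unknown band {name!r} in band_envelopes")
            if any(amp < 0 for _, amp in traj):
                raise ValueError(f"negative amplitude in {name} envelope")
        if self.intervention_effect is not None:
            for name, traj in self.intervention_effect.items():
                if any(mult <= 0 for _, mult in traj):
                    raise ValueError(f"non-positive multiplier in {name} intervention effect")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_min * 60 * self.sampling_rate))


def identification_scenario(
    n_subjects: int = cal.IDENTIFICATION_N_SUBJECTS, seed: int = 0, **overrides
) -> ScenarioConfig:
    """The 30-min fatigue-identification drive (no intervention)."""
    kwargs = dict(
        duration_min=cal.IDENTIFICATION_DURATION_MIN,
        n_subjects=n_subjects,
        group="control",
        intervention_minute=None,
        kss_minutes=cal.IDENTIFICATION_KSS_MINUTES,
        kss_baseline=cal.KSS_IDENTIFICATION["control"][0],
        kss_drift=cal.KSS_IDENTIFICATION["control"][1],
        kss_drop=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


def intervention_scenario(
    group: str,
    n_subjects: int = cal.INTERVENTION_N_SUBJECTS,
    seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """One condition of the 45-min scent-intervention study (release at 30 min)."""
    baseline, drift, drop = cal.KSS_INTERVENTION[group]
    kwargs = dict(
        duration_min=cal.INTERVENTION_DURATION_MIN,
        n_subjects=n_subjects,
        group=group,
        intervention_minute=cal.INTERVENTION_MINUTE,
        intervention_effect=scent_effect_trajectories(group),
        kss_minutes=cal.INTERVENTION_KSS_MINUTES,
        kss_baseline=baseline,
        kss_drift=drift,
        kss_drop=drop,
        seed=seed,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


@dataclass
class SubjectTraits:
    """Stable per-subject characteristics shared across that subject's conditions."""

    band_scale: dict[str, float]
    slope_gain: dict[str, float]
    kss_offset: float

    @classmethod
    def neutral(cls) -> "SubjectTraits":
        return cls(
            band_scale={b.name: 1.0 for b in BANDS},
            slope_gain={b.name: 1.0 for b in BANDS},
            kss_offset=0.0,
        )

    @classmethod
    def draw(cls, rng: np.random.Generator, config: ScenarioConfig) -> "SubjectTraits":
        return cls(
            band_scale={
                b.name: float(np.exp(rng.normal(0.0, config.subject_scale_log_sd)))
                for b in BANDS
            },
            slope_gain={
                b.name: float(np.clip(rng.normal(1.0, config.subject_slope_sd), 0.0, None))
                for b in BANDS
            },
            kss_offset=float(rng.normal(0.0, config.kss_subject_sd)),
        )


def _band_process(
    rng: np.random.Generator, low: float, high: float, n_samples: int, fs: float
) -> np.ndarray:
    """Zero-mean unit-variance process confined to ``[low, high)`` Hz.

    Sum of equal-amplitude random-phase sinusoids on the 0.1 Hz grid.  When
    every grid frequency falls on the DFT grid of the full record (true for
    durations that are multiples of 10 s) the sum is synthesized exactly by
    an inverse FFT; otherwise by a direct oscillator bank.
    """
    freqs = np.arange(low, high - 1e-9, cal.FREQ_GRID_HZ)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    amp = np.sqrt(2.0 / freqs.size)
    duration_s = n_samples / fs
    bins = freqs * duration_s
    on_grid = np.allclose(bins, np.round(bins), atol=1e-9)
    if on_grid and np.round(bins).max() < n_samples // 2:
        spectrum = np.zeros(n_samples // 2 + 1, dtype=complex)
        spectrum[np.round(bins).astype(int)] = (n_samples / 2.0) * amp * np.exp(1j * phases)
        return np.fft.irfft(spectrum, n=n_samples)
    t = np.arange(n_samples) / fs
    x = np.zeros(n_samples)
    for f, ph in zip(freqs, phases):
        x += amp * np.cos(2.0 * np.pi * f * t + ph)
    return x


def _envelope_for_subject(
    config: ScenarioConfig, band: str, minutes: np.ndarray, traits: SubjectTraits
) -> np.ndarray:
    xs, ys = zip(*config.band_envelopes[band])
    env = np.interp(minutes, xs, ys)
    base = ys[0]
    # subject scales the whole band; slope gain stretches the drift away from baseline
    subj = traits.band_scale[band] * (base + traits.slope_gain[band] * (env - base))
    return np.clip(subj, 0.0, None)


def _multiplier_for_subject(
    config: ScenarioConfig, band: str, minutes: np.ndarray, response_gain: float
) -> np.ndarray:
    if config.intervention_minute is None or config.intervention_effect is None:
        return np.ones_like(minutes)
    traj = config.intervention_effect.get(band)
    if traj is None:
        return np.ones_like(minutes)
    xs, ys = zip(*traj)
    tau = minutes - config.intervention_minute
    mult = np.interp(tau, xs, ys, left=1.0, right=ys[-1])
    mult = np.where(tau < 0, 1.0, mult)
    return 1.0 + response_gain * (mult - 1.0)


def simulate_eeg(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    traits: SubjectTraits | None = None,
    response_gain: float = 1.0,
) -> EEGRecording:
    """Simulate one subject's two-channel temporal-lobe recording.

    Both channels share the same latent band processes and differ only by
    independent white noise.  With ``traits=None`` the neutral subject
    (scale 1, slope gain 1) is generated.  ``minute_amp_sd > 0`` adds a
    piecewise-constant lognormal modulation of each band's amplitude per
    minute — the within-subject nonstationarity that gives the per-epoch
    band-power estimates realistic variability; set it to 0 for a strictly
    stationary generator.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if traits is None:
        traits = SubjectTraits.neutral()
    n = config.n_samples
    fs = config.sampling_rate
    minutes = np.arange(n) / fs / 60.0
    latent = np.zeros(n)
    for band in BANDS:
        traj = config.band_envelopes.get(band.name)
        if traj is None or all(amp == 0 for _, amp in traj):
            continue
        env = _envelope_for_subject(config, band.name, minutes, traits)
        mult = _multiplier_for_subject(config, band.name, minutes, response_gain)
        if config.minute_amp_sd > 0:
            n_minutes = int(np.ceil(config.duration_min))
            per_minute = np.exp(rng.normal(0.0, config.minute_amp_sd, n_minutes))
            mod = per_minute[np.minimum(minutes.astype(int), n_minutes - 1)]
        else:
            mod = 1.0
        s = _band_process(rng, band.low, band.high, n, fs)
        latent += env * mult * mod * s
    samples = np.empty((2, n))
    for ch in range(2):
        noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else 0.0
        samples[ch] = latent + noise
    events = {"task_start": 0.0}
    if config.intervention_minute is not None:
        events["intervention"] = float(config.intervention_minute)
    return EEGRecording(samples=samples, sampling_rate=fs, events=events)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def simulate_kss(
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    subject_ids: list[str] | None = None,
    offsets: list[float] | None = None,
) -> list[KSSRecord]:
    """Simulate the cohort's KSS answers at the scheduled questionnaire minutes.

    Latent sleepiness = baseline + drift*t − drop·1[t > release, scented]
    + subject offset + noise, rounded half-up and clipped to 1..9.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if subject_ids is None:
        subject_ids = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    if offsets is None:
        offsets = [
            float(rng.normal(0.0, config.kss_subject_sd)) if config.kss_subject_sd > 0 else 0.0
            for _ in subject_ids
        ]
    records: list[KSSRecord] = []
    scented = config.group in SCENTS and config.intervention_minute is not None
    for sid, offset in zip(subject_ids, offsets):
        for t in config.kss_minutes:
            latent = config.kss_baseline + config.kss_drift * t + offset
            if scented and t > config.intervention_minute:
                latent -= config.kss_drop
            if config.kss_noise_sd > 0:
                latent += float(rng.normal(0.0, config.kss_noise_sd))
            score = int(np.clip(_round_half_up(np.asarray(latent)), 1, 9))
            records.append(KSSRecord(sid, config.group, float(t), score))
    return records


def simulate_cohort(
    study: str,
    n_subjects: int | None = None,
    seed: int = 0,
    sampling_rate: float = cal.DEFAULT_SAMPLING_RATE,
    **overrides,
) -> CohortDataset:
    """Simulate a full study dataset.

    ``study="identification"``: 30-min recordings plus KSS at minutes 0 and
    30 for each subject.  ``study="intervention"``: all four conditions for
    every subject (within-subject design), 45-min recordings with release
    at minute 30 and KSS at minutes 28 and 40.  Subject traits are shared
    across a subject's conditions so between-condition contrasts pair up.
    """
    if study == "identification":
        groups = ["control"]
        make = lambda g, s: identification_scenario(  # noqa: E731
            n_subjects=n_subjects or cal.IDENTIFICATION_N_SUBJECTS,
            seed=s,
            sampling_rate=sampling_rate,
            **overrides,
        )
        n_subjects = n_subjects or cal.IDENTIFICATION_N_SUBJECTS
    elif study == "intervention":
        groups = list(GROUPS)
        make = lambda g, s: intervention_scenario(  # noqa: E731
            g,
            n_subjects=n_subjects or cal.INTERVENTION_N_SUBJECTS,
            seed=s,
            sampling_rate=sampling_rate,
            **overrides,
        )
        n_subjects = n_subjects or cal.INTERVENTION_N_SUBJECTS
    else:
        raise ValueError(f"unknown study {study!r}; expected 'identification' or 'intervention'")
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")

    root = np.random.SeedSequence(seed)
    trait_seq, *rec_seqs = root.spawn(1 + len(groups) * n_subjects + len(groups))
    trait_rng = np.random.default_rng(trait_seq)
    template = make(groups[0], seed)
    subject_ids = [f"S{i + 1:02d}" for i in range(n_subjects)]
    traits = {sid: SubjectTraits.draw(trait_rng, template) for sid in subject_ids}

    recordings: dict[str, dict[str, EEGRecording]] = {}
    kss_records: list[KSSRecord] = []
    seq_iter = iter(rec_seqs)
    for group in groups:
        config = make(group, seed)
        recordings[group] = {}
        for sid in subject_ids:
            rng = np.random.default_rng(next(seq_iter))
            if group in SCENTS:
                gain = float(np.clip(rng.normal(1.0, config.response_gain_sd), 0.05, None))
            else:
                gain = 1.0
            recordings[group][sid] = simulate_eeg(
                config, rng=rng, traits=traits[sid], response_gain=gain
            )
        kss_rng = np.random.default_rng(next(seq_iter))
        kss_records.extend(
            simulate_kss(
                config,
                rng=kss_rng,
                subject_ids=subject_ids,
                offsets=[traits[sid].kss_offset for sid in subject_ids],
            )
        )
    return CohortDataset(study=study, recordings=recordings, kss=kss_frame(kss_records))


def null_scenario(**overrides) -> ScenarioConfig:
    """A stationarity control: flat envelopes, no drift, no intervention."""
    flat = {name: [(0.0, cal.BAND_BASELINE[name])] for name in BAND_BY_NAME}
    defaults = dict(band_envelopes=flat, kss_drift=0.0)
    defaults.update(overrides)
    return identification_scenario(**defaults)
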