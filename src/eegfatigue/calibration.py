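"""Default constants of the synthetic cohort generator.

All magnitudes live here so the simulated study conditions are defined in
one place.  Amplitudes are in arbitrary signal units; since every analysis
index is a ratio of band powers, only amplitude *ratios* matter.  Baselines
are anchored so the cohort-mean alpha/beta index at task start is close to
1.13, and the fatigue drifts so that a 14-subject cohort shows a clearly
significant pre/post rise of that index.

Envelope trajectories are piecewise linear in minutes, ``[(minute, amp), ...]``.
Intervention effect shapes are piecewise linear in minutes since scent
release, ``[(minutes_since_release, effect 0..1), ...]``.
"""

from __future__ import annotations

# --- band amplitude baselines (signal units, minute 0) ---------------------
# beta is the reference; alpha/theta set the minute-0 ratio indices.
BAND_BASELINE = {
    "theta": 0.74,
    "alpha": 0.59,
    "beta": 1.00,
    "gamma": 0.80,
}

# --- fatigue drift over the driving task -----------------------------------
# Relative trajectories (fraction of baseline): slow waves up, fast waves
# down, beta with the most pronounced decline of the four.
RELATIVE_ENVELOPE = {
    "theta": [(0.0, 1.00), (30.0, 1.12), (45.0, 1.16)],
    "alpha": [(0.0, 1.00), (30.0, 0.95), (45.0, 0.93)],
    "beta": [(0.0, 1.00), (30.0, 0.78), (45.0, 0.70)],
    "gamma": [(0.0, 1.00), (30.0, 0.88), (45.0, 0.84)],
}

#: White measurement noise added to every channel (signal units, sd).
NOISE_SD = 0.25

#: sd of the per-minute lognormal modulation of each band's amplitude —
#: the within-subject physiological fluctuation that gives band-power
#: estimates realistic epoch-to-epoch variability.
MINUTE_AMP_LOG_SD = 0.06

#: Spacing of the sinusoid frequency grid inside each band (Hz).
FREQ_GRID_HZ = 0.1

# --- between-subject variability -------------------------------------------
#: sd of the log of a subject's per-band amplitude scale.
SUBJECT_SCALE_LOG_SD = 0.15
#: sd of a subject's per-band fatigue-slope gain (mean 1, truncated >= 0).
SUBJECT_SLOPE_SD = 0.35
#: sd of a subject's scent-response gain (mean 1, truncated >= 0.05).
RESPONSE_GAIN_SD = 0.30

# --- scent intervention -----------------------------------------------------
# Effect shape e(tau): 0 at release, peaks at the scent's nadir delay, then
# recovers; peppermint recovers fastest, lavender slowest.  The alpha/beta
# index trough falls at release + nadir delay (grapefruit 2 < peppermint 3
# < lavender 4 minutes).
INTERVENTION_SHAPE = {
    "peppermint": [(0.0, 0.0), (3.0, 1.0), (5.0, 0.15), (10.0, 0.12), (20.0, 0.0)],
    "grapefruit": [(0.0, 0.0), (2.0, 1.0), (5.0, 0.45), (12.0, 0.15), (18.0, 0.0)],
    "lavender": [(0.0, 0.0), (4.0, 1.0), (12.0, 0.60), (22.0, 0.0)],
}

#: Peak beta-amplitude boost at full effect (scent arousal restores fast waves).
BETA_BOOST = 0.35
#: Peak alpha-amplitude suppression at full effect.
ALPHA_SUPPRESS = 0.10

# --- KSS generator ----------------------------------------------------------
# Latent sleepiness = baseline + drift * minute - drop * (post-intervention,
# scented) + subject effect + noise; rounded half-up, clipped to 1..9.
#: (latent baseline at minute 0, drift per minute, post-intervention drop)
KSS_IDENTIFICATION = {"control": (2.929, 2.0 / 30.0, 0.0)}

_KSS_DRIFT_INTERVENTION = (5.273 - 3.000) / 12.0  # per minute, 28 -> 40 min
KSS_INTERVENTION = {
    "control": (3.000 - 28.0 * _KSS_DRIFT_INTERVENTION, _KSS_DRIFT_INTERVENTION, 0.0),
    "peppermint": (5.000 - 28.0 * _KSS_DRIFT_INTERVENTION, _KSS_DRIFT_INTERVENTION, 4.182),
    "grapefruit": (5.000 - 28.0 * _KSS_DRIFT_INTERVENTION, _KSS_DRIFT_INTERVENTION, 4.000),
    "lavender": (5.727 - 28.0 * _KSS_DRIFT_INTERVENTION, _KSS_DRIFT_INTERVENTION, 4.000),
}

#: sd of the per-subject latent sleepiness offset.
KSS_SUBJECT_SD = 1.0
#: sd of the per-answer latent noise.
KSS_NOISE_SD = 0.8

# --- study schedules ---------------------------------------------------------
IDENTIFICATION_DURATION_MIN = 30.0
IDENTIFICATION_N_SUBJECTS = 14
IDENTIFICATION_KSS_MINUTES = (0.0, 30.0)

INTERVENTION_DURATION_MIN = 45.0
INTERVENTION_N_SUBJECTS = 11
INTERVENTION_MINUTE = 30.0
INTERVENTION_KSS_MINUTES = (28.0, 40.0)

DEFAULT_SAMPLING_RATE = 128.0
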