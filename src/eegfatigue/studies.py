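"""End-to-end study pipelines and report rendering.

Two designs are implemented:

* the **fatigue-identification study** — a 30-min monotonous drive; each
  ratio index and the KSS are contrasted at minute 5 versus minute 30
  with paired t-tests, and cohort-mean 2-min series of the four band
  activities and three indices are produced;
* the **scent-intervention study** — a 45-min drive with a scent released
  at minute 30 under four within-subject conditions (control, peppermint,
  grapefruit, lavender); KSS is contrasted within group (28 vs 40 min)
  and against control at 40 min, the alpha/beta index at the 28-min
  baseline is contrasted against minutes 32–40, and a two-way
  within-subjects ANOVA (treatment × time) is run over the three scents
  and five post-release time points.  The analysis window is capped at
  40 min although driving continues to 45.

"The value at minute m" always denotes the 1-min epoch ending at m.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BANDS
from .indices import INDEX_NAMES, FatigueIndexSeries, index_series
from .preprocess import preprocess, two_minute_means
from .recording import SCENTS, CohortDataset, EEGRecording
from .spectral import band_power_frame, band_power_series
from .stats import (
    PairedTestResult,
    RMAnovaResult,
    normality_p,
    one_way_anova,
    paired_t,
    rm_anova,
)

logger = logging.getLogger("eegfatigue")

TEST_MINUTES = (32.0, 34.0, 36.0, 38.0, 40.0)
BASELINE_MINUTE = 28.0


@dataclass
class StudyResult:
    """Statistical output of one study, plus the tables a report prints."""

    kind: str
    paired: dict[str, PairedTestResult] = field(default_factory=dict)
    kss_within: dict[str, PairedTestResult] = field(default_factory=dict)
    kss_between: dict[str, PairedTestResult] = field(default_factory=dict)
    kss_anova: tuple[float, float] | None = None
    r_ab_tests: dict[str, dict[float, PairedTestResult]] = field(default_factory=dict)
    rm: RMAnovaResult | None = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def subject_pipeline(
    recording: EEGRecording,
    subject_id: str = "",
    condition: str = "",
    channels: tuple[str, ...] | None = None,
) -> tuple[FatigueIndexSeries, pd.DataFrame]:
    """Recording -> per-minute indices and band powers for one subject."""
    epochs = preprocess(recording, channels=channels)
    powers = band_power_series(epochs)
    return index_series(powers, subject_id, condition), band_power_frame(powers)


def _paired_with_normality(pre: np.ndarray, post: np.ndarray) -> PairedTestResult:
    from .stats import DegenerateInputError

    try:
        res = paired_t(pre, post)
    except DegenerateInputError:
        # identical nonzero change in every subject (possible with small
        # cohorts of integer scores): report an unbounded contrast
        pre, post = np.asarray(pre, float), np.asarray(post, float)
        diff = float(pre.mean() - post.mean())
        return PairedTestResult(
            mean_pre=float(pre.mean()), mean_post=float(post.mean()), diff=diff,
            t=float(np.sign(diff)) * np.inf, p=0.0, n=pre.size,
        )
    try:
        res.normality_p = normality_p(pre - post)
    except ValueError:
        res.normality_p = None
    return res


def run_identification_study(
    dataset: CohortDataset,
    pre_minute: float = 5.0,
    post_minute: float = 30.0,
    channels: tuple[str, ...] | None = None,
) -> StudyResult:
    """Paired pre/post contrasts of the three indices and the KSS.

    Recordings shorter than ``post_minute`` are excluded with a logged
    warning; at least two usable subjects are required.
    """
    (group,) = dataset.groups() if len(dataset.groups()) == 1 else ("control",)
    usable: dict[str, FatigueIndexSeries] = {}
    bands_by_subject: dict[str, pd.DataFrame] = {}
    for sid in dataset.subjects(group):
        rec = dataset.recordings[group][sid]
        if rec.duration_min < post_minute:
            logger.warning(
                "excluding subject %s: recording %.1f min < %.0f min required",
                sid, rec.duration_min, post_minute,
            )
            continue
        series, bp = subject_pipeline(rec, sid, group, channels)
        usable[sid] = series
        bands_by_subject[sid] = bp
    if len(usable) < 2:
        raise ValueError(f"need >= 2 usable subjects, have {len(usable)}")

    result = StudyResult(kind="identification")
    rows = []
    for name in INDEX_NAMES:
        pre = np.array([s.value_at_minute(pre_minute, name) for s in usable.values()])
        post = np.array([s.value_at_minute(post_minute, name) for s in usable.values()])
        result.paired[name] = _paired_with_normality(pre, post)
    kss_pre = np.array([dataset.kss_score(group, sid, 0.0) for sid in usable], dtype=float)
    kss_post = np.array(
        [dataset.kss_score(group, sid, post_minute) for sid in usable], dtype=float
    )
    result.paired["KSS"] = _paired_with_normality(kss_pre, kss_post)
    for name, res in result.paired.items():
        rows.append((name, res.mean_pre, res.mean_post, res.diff, res.t, res.p, res.normality_p))
    result.tables["identification_tests"] = pd.DataFrame(
        rows, columns=["variable", "pre", "post", "diff", "t", "p", "normality_p"]
    )

    # cohort-mean 2-min series of band activities and indices
    n_min = min(len(s) for s in usable.values())
    band_means = {
        f"G_{b.name}": np.mean(
            [bp[f"G_{b.name}"].to_numpy()[:n_min] for bp in bands_by_subject.values()], axis=0
        )
        for b in BANDS
    }
    idx_means = {
        name: np.mean([getattr(s, name)[:n_min] for s in usable.values()], axis=0)
        for name in INDEX_NAMES
    }
    starts_2min = np.arange(0, (n_min // 2) * 2, 2.0)
    result.tables["band_series_2min"] = pd.DataFrame(
        {"start_min": starts_2min, **{k: two_minute_means(v) for k, v in band_means.items()}}
    )
    result.tables["index_series_2min"] = pd.DataFrame(
        {"start_min": starts_2min, **{k: two_minute_means(v) for k, v in idx_means.items()}}
    )
    return result


def run_intervention_study(
    dataset: CohortDataset,
    baseline_minute: float = BASELINE_MINUTE,
    test_minutes: tuple[float, ...] = TEST_MINUTES,
    channels: tuple[str, ...] | None = None,
    between_paired: bool = True,
) -> StudyResult:
    """The scent-intervention analysis: KSS contrasts, per-minute index tests, RM ANOVA.

    ``between_paired`` pairs the 40-min KSS contrast against control across
    subjects (the same volunteers underwent all four conditions); set False
    for an unpaired two-sample t.
    """
    groups = dataset.groups()
    missing = [g for g in ("control", *SCENTS) if g not in groups]
    if missing:
        raise ValueError(f"intervention dataset is missing conditions: {missing}")
    kss_t = sorted(dataset.kss.time_min.unique())
    for needed in (28.0, 40.0):
        if needed not in kss_t:
            raise ValueError(f"KSS scores at minute {needed} are required (have {kss_t})")

    result = StudyResult(kind="intervention")
    subjects = dataset.subjects("control")

    def kss_vec(group: str, minute: float) -> np.ndarray:
        return np.array(
            [dataset.kss_score(group, sid, minute) for sid in subjects], dtype=float
        )

    # (a) within-group KSS 28 vs 40 min
    for group in ("peppermint", "grapefruit", "lavender", "control"):
        result.kss_within[group] = _paired_with_normality(kss_vec(group, 28.0), kss_vec(group, 40.0))
    # (b) each scent's 40-min KSS against control's
    ctrl40 = kss_vec("control", 40.0)
    for scent in SCENTS:
        scent40 = kss_vec(scent, 40.0)
        if between_paired:
            result.kss_between[scent] = _paired_with_normality(ctrl40, scent40)
        else:
            from scipy import stats as sst

            res = sst.ttest_ind(ctrl40, scent40)
            result.kss_between[scent] = PairedTestResult(
                mean_pre=float(ctrl40.mean()), mean_post=float(scent40.mean()),
                diff=float(ctrl40.mean() - scent40.mean()),
                t=float(res.statistic), p=float(res.pvalue), n=len(subjects),
            )
    # (c) one-way ANOVA over the scents' KSS improvements (28 − 40 min)
    deltas = [kss_vec(s, 28.0) - kss_vec(s, 40.0) for s in SCENTS]
    result.kss_anova = one_way_anova(deltas)

    # EEG: per-minute alpha/beta index per subject and condition
    series: dict[str, dict[str, FatigueIndexSeries]] = {}
    for group in ("control", *SCENTS):
        series[group] = {}
        for sid in subjects:
            rec = dataset.recordings[group][sid]
            if rec.duration_min < max(test_minutes):
                raise ValueError(
                    f"recording {group}/{sid} is {rec.duration_min:.1f} min; "
                    f">= {max(test_minutes):.0f} min required"
                )
            series[group][sid], _ = subject_pipeline(rec, sid, group, channels)

    def r_vec(group: str, minute: float) -> np.ndarray:
        return np.array([series[group][sid].value_at_minute(minute) for sid in subjects])

    # (d) per scent, baseline 28 min vs each post-release minute
    for scent in SCENTS:
        base = r_vec(scent, baseline_minute)
        result.r_ab_tests[scent] = {
            m: _paired_with_normality(base, r_vec(scent, m)) for m in test_minutes
        }
    # (e) two-way within-subjects ANOVA over scents × post-release minutes
    long_rows = [
        (sid, scent, m, series[scent][sid].value_at_minute(m))
        for scent in SCENTS
        for m in test_minutes
        for sid in subjects
    ]
    long = pd.DataFrame(long_rows, columns=["subject", "treatment", "time", "value"])
    result.rm = rm_anova(long)

    # tables
    kss_rows = []
    for group in ("peppermint", "grapefruit", "lavender", "control"):
        within = result.kss_within[group]
        sd28, sd40 = float(kss_vec(group, 28.0).std(ddof=1)), float(kss_vec(group, 40.0).std(ddof=1))
        between = result.kss_between.get(group)
        kss_rows.append(
            (group, within.mean_pre, sd28, within.mean_post, sd40,
             within.diff, within.t, within.p,
             between.diff if between else np.nan,
             between.t if between else np.nan,
             between.p if between else np.nan)
        )
    result.tables["kss_tests"] = pd.DataFrame(
        kss_rows,
        columns=["group", "M_28", "SD_28", "M_40", "SD_40", "diff", "t", "p",
                 "ctrl_diff", "ctrl_t", "ctrl_p"],
    )
    r_rows = [
        (scent, m, res.mean_pre, res.mean_post, res.diff, res.t, res.p)
        for scent, by_minute in result.r_ab_tests.items()
        for m, res in by_minute.items()
    ]
    result.tables["r_ab_tests"] = pd.DataFrame(
        r_rows, columns=["group", "minute", "M_28", "M_minute", "diff", "t", "p"]
    )
    result.tables["rm_anova"] = result.rm.to_frame()
    minutes = np.arange(1.0, np.floor(min(
        dataset.recordings[g][s].duration_min for g in series for s in subjects
    )) + 1.0)
    result.tables["r_ab_series"] = pd.DataFrame(
        {
            "minute": minutes,
            **{
                g: [np.mean([series[g][s].value_at_minute(m) for s in subjects]) for m in minutes]
                for g in ("control", *SCENTS)
            },
        }
    )
    result.tables["kss_anova"] = pd.DataFrame(
        [result.kss_anova], columns=["F", "p"]
    )
    return result


def _print_round(df: pd.DataFrame, mean_cols: dict[str, tuple[str, str]]) -> pd.DataFrame:
    """Round floats to 3 decimals; recompute diff columns from the *printed* means

    so that every printed diff equals the difference of its printed means.
    """
    out = df.copy()
    num = out.select_dtypes(include=[np.number]).columns
    out[num] = out[num].round(3)
    for diff_col, (pre_col, post_col) in mean_cols.items():
        if {pre_col, post_col} <= set(out.columns):
            out[diff_col] = (out[pre_col] - out[post_col]).round(3)
    return out


def render_report(result: StudyResult, out_dir: str | Path) -> list[Path]:
    """Write the study's CSV tables and a JSON summary (3-decimal floats)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    diff_map = {
        "identification_tests": {"diff": ("pre", "post")},
        "kss_tests": {"diff": ("M_28", "M_40")},
        "r_ab_tests": {"diff": ("M_28", "M_minute")},
    }
    for name, table in result.tables.items():
        printed = _print_round(table, diff_map.get(name, {}))
        path = out / f"{result.kind}_{name}.csv"
        printed.to_csv(path, index=False)
        written.append(path)
    summary: dict = {"study": result.kind}
    if result.paired:
        summary["paired"] = {k: v.to_dict() for k, v in result.paired.items()}
    if result.kss_within:
        summary["kss_within"] = {k: v.to_dict() for k, v in result.kss_within.items()}
        summary["kss_between"] = {k: v.to_dict() for k, v in result.kss_between.items()}
        summary["kss_anova"] = {"F": result.kss_anova[0], "p": result.kss_anova[1]}
    if result.rm is not None:
        summary["rm_anova"] = {
            name: vars(getattr(result.rm, name)) for name in ("treatment", "time", "interaction")
        }
    path = out / f"{result.kind}_summary.json"
    path.write_text(json.dumps(summary, indent=2, default=float) + "\n")
    written.append(path)
    return written
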