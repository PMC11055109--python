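"""Statistical machinery: normality screen, paired t, one-way and RM ANOVA.

Thin, contract-enforcing wrappers over scipy.stats and pingouin.  Sign
conventions follow the study tables: a paired contrast reports
``diff = mean_pre − mean_post`` and the t statistic carries the same sign
as the difference, so a quantity that *rises* over the drive yields a
negative diff and t.  All tests are two-sided at the conventional 0.05
level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst


class DegenerateInputError(ValueError):
    """The input has no variation where the test requires some."""


@dataclass
class PairedTestResult:
    """A paired-samples t contrast (diff = mean_pre − mean_post)."""

    mean_pre: float
    mean_post: float
    diff: float
    t: float
    p: float
    n: int
    normality_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "mean_pre": self.mean_pre,
            "mean_post": self.mean_post,
            "diff": self.diff,
            "t": self.t,
            "p": self.p,
            "n": self.n,
            "normality_p": self.normality_p,
        }


@dataclass
class EffectResult:
    """One ANOVA effect: F ratio, degrees of freedom, p-values."""

    F: float
    p: float
    df_num: float
    df_den: float
    p_gg: float | None = None  # Greenhouse–Geisser-corrected, where applicable


@dataclass
class RMAnovaResult:
    """Two-way within-subjects ANOVA: treatment, time, and their interaction."""

    treatment: EffectResult
    time: EffectResult
    interaction: EffectResult

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("treatment", "time", "interaction"):
            e: EffectResult = getattr(self, name)
            rows.append((name, e.F, e.p, e.df_num, e.df_den, e.p_gg))
        return pd.DataFrame(rows, columns=["effect", "F", "p", "df_num", "df_den", "p_gg"])


def normality_p(differences: np.ndarray) -> float:
    """Shapiro–Wilk p-value for the normality of a vector of paired differences."""
    d = np.asarray(differences, dtype=float)
    if d.size < 3:
        raise ValueError(f"normality screen needs n >= 3 (got {d.size})")
    if np.allclose(d, d[0]):
        raise DegenerateInputError("differences are constant; normality test undefined")
    return float(sst.shapiro(d).pvalue)


def paired_t(pre: np.ndarray, post: np.ndarray) -> PairedTestResult:
    """Classical paired-samples t-test with df = n − 1 and two-sided p.

    ``diff`` is reported as pre − post; its sign matches the t statistic.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D arrays of equal length")
    n = pre.size
    if n < 2:
        raise ValueError(f"paired t needs n >= 2 (got {n})")
    d = pre - post
    if np.allclose(d, d[0]) and not np.allclose(d, 0):
        raise DegenerateInputError("paired differences have zero variance")
    if np.allclose(d, 0):
        t_stat, p_val = 0.0, 1.0
    else:
        res = sst.ttest_rel(pre, post)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return PairedTestResult(
        mean_pre=float(pre.mean()),
        mean_post=float(post.mean()),
        diff=float(pre.mean() - post.mean()),
        t=t_stat,
        p=p_val,
        n=n,
    )


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical between-groups one-way ANOVA F test; returns (F, p)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-within-group warnings
        res = sst.f_oneway(*arrays)
    f_val = float(res.statistic)
    if not np.isfinite(f_val):
        raise DegenerateInputError("within-group variance is zero; F undefined")
    return f_val, float(res.pvalue)


def rm_anova(data: pd.DataFrame, dv: str = "value") -> RMAnovaResult:
    """Two-way fully within-subjects ANOVA (treatment × time).

    ``data`` must be a complete balanced long table with columns
    ``subject``, ``treatment``, ``time`` and the dependent variable: every
    subject observed once in every treatment × time cell (no imputation is
    attempted).  Reports uncorrected F/p per effect, plus the
    Greenhouse–Geisser-corrected p as an auxiliary field.
    """
    required = {"subject", "treatment", "time", dv}
    missing_cols = required - set(data.columns)
    if missing_cols:
        raise ValueError(f"rm_anova input is missing columns {sorted(missing_cols)}")
    counts = data.groupby(["subject", "treatment", "time"], observed=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1]
        raise ValueError(f"unbalanced design; offending cells:\n{bad}")
    subjects = data["subject"].unique()
    treatments = data["treatment"].unique()
    times = data["time"].unique()
    expected = len(subjects) * len(treatments) * len(times)
    if len(data) != expected:
        observed = set(map(tuple, data[["subject", "treatment", "time"]].itertuples(index=False)))
        full = {(s, tr, ti) for s in subjects for tr in treatments for ti in times}
        raise ValueError(f"missing cells: {sorted(full - observed)}")

    import pingouin as pg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.rm_anova(
            data=data, dv=dv, within=["treatment", "time"], subject="subject",
            detailed=True, effsize="np2",
        )
    table = table.set_index("Source")

    def effect(source: str) -> EffectResult:
        row = table.loc[source]
        p_col = "p_unc" if "p_unc" in row.index else "p-unc"
        gg_col = next((c for c in ("p_GG_corr", "p-GG-corr") if c in row.index), None)
        p_gg = float(row[gg_col]) if gg_col is not None and pd.notna(row[gg_col]) else None
        f_val, p_val = float(row["F"]), float(row[p_col])
        if abs(float(row["SS"])) <= 1e-10:  # no effect variance at all: F := 0
            f_val, p_val, p_gg = 0.0, 1.0, 1.0
        elif not np.isfinite(f_val) or f_val < 0:
            raise DegenerateInputError(f"F undefined for effect {source!r}")
        return EffectResult(
            F=f_val,
            p=p_val,
            df_num=float(row["ddof1"]),
            df_den=float(row["ddof2"]),
            p_gg=p_gg,
        )

    inter_key = next(s for s in table.index if "*" in s)
    return RMAnovaResult(
        treatment=effect("treatment"),
        time=effect("time"),
        interaction=effect(inter_key),
    )
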