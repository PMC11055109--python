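"""Statistical engine contracts, checked against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from eegfatigue.stats import (
    DegenerateInputError,
    normality_p,
    one_way_anova,
    paired_t,
    rm_anova,
)


def brute_force_rm_anova(data: pd.DataFrame):
    """Explicit sums-of-squares partition of the two-way within-subjects design.

    Independent of the implementation under test: plain loops over cell
    means following the textbook decomposition.
    """
    subjects = sorted(data.subject.unique())
    trs = sorted(data.treatment.unique())
    tis = sorted(data.time.unique())
    y = {
        (r.subject, r.treatment, r.time): r.value
        for r in data.itertuples()
    }
    ns, a, b = len(subjects), len(trs), len(tis)
    gm = np.mean(list(y.values()))
    m_s = {s: np.mean([y[(s, t, u)] for t in trs for u in tis]) for s in subjects}
    m_a = {t: np.mean([y[(s, t, u)] for s in subjects for u in tis]) for t in trs}
    m_b = {u: np.mean([y[(s, t, u)] for s in subjects for t in trs]) for u in tis}
    m_sa = {(s, t): np.mean([y[(s, t, u)] for u in tis]) for s in subjects for t in trs}
    m_sb = {(s, u): np.mean([y[(s, t, u)] for t in trs]) for s in subjects for u in tis}
    m_ab = {(t, u): np.mean([y[(s, t, u)] for s in subjects]) for t in trs for u in tis}

    ss_a = ns * b * sum((m_a[t] - gm) ** 2 for t in trs)
    ss_b = ns * a * sum((m_b[u] - gm) ** 2 for u in tis)
    ss_ab = ns * sum((m_ab[(t, u)] - m_a[t] - m_b[u] + gm) ** 2 for t in trs for u in tis)
    ss_sa = b * sum((m_sa[(s, t)] - m_s[s] - m_a[t] + gm) ** 2 for s in subjects for t in trs)
    ss_sb = a * sum((m_sb[(s, u)] - m_s[s] - m_b[u] + gm) ** 2 for s in subjects for u in tis)
    ss_sab = sum(
        (
            y[(s, t, u)] - m_sa[(s, t)] - m_sb[(s, u)] - m_ab[(t, u)]
            + m_s[s] + m_a[t] + m_b[u] - gm
        ) ** 2
        for s in subjects for t in trs for u in tis
    )
    f_a = (ss_a / (a - 1)) / (ss_sa / ((a - 1) * (ns - 1)))
    f_b = (ss_b / (b - 1)) / (ss_sb / ((b - 1) * (ns - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_sab / ((a - 1) * (b - 1) * (ns - 1)))
    return f_a, f_b, f_ab


def long_table(values, subjects, trs, tis):
    rows = []
    for i, s in enumerate(subjects):
        for j, t in enumerate(trs):
            for k, u in enumerate(tis):
                rows.append((s, t, u, values[i, j, k]))
    return pd.DataFrame(rows, columns=["subject", "treatment", "time", "value"])


class TestNormality:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_p([1.0, 2.0])

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normality_p(np.ones(10))

    def test_p_uniform_under_normal_null(self, rng):
        pvals = [normality_p(rng.normal(size=50)) for _ in range(500)]
        ks = sst.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_detects_lognormal_skew(self, rng):
        hits = sum(normality_p(np.exp(rng.normal(size=50))) < 0.05 for _ in range(200))
        assert hits / 200 >= 0.90


class TestPairedT:
    def test_no_change_gives_null_result(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t, res.p, res.diff) == (0.0, 1.0, 0.0)

    def test_closed_form_on_unit_steps(self):
        # differences {1,2,3}: mean 2, sd 1 -> t = 2 / (1/sqrt(3))
        res = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-9)
        assert res.p == pytest.approx(2 * sst.t.sf(2.0 * np.sqrt(3.0), df=2), rel=1e-9)
        assert res.n == 3

    def test_sign_convention_pre_minus_post(self):
        pre = np.array([3.0, 2.5, 3.5, 2.0, 3.0, 2.5, 4.0])
        post = pre + 2.0 + np.linspace(-0.2, 0.2, 7)
        res = paired_t(pre, post)
        assert res.diff == pytest.approx(res.mean_pre - res.mean_post, abs=1e-12)
        assert res.diff < 0 and res.t < 0

    def test_matches_one_sample_t_on_differences(self, rng):
        for _ in range(20):
            pre = rng.normal(size=9)
            post = rng.normal(size=9)
            res = paired_t(pre, post)
            oracle = sst.ttest_1samp(pre - post, 0.0)
            assert res.t == pytest.approx(oracle.statistic, abs=1e-8)
            assert res.p == pytest.approx(oracle.pvalue, abs=1e-8)

    def test_zero_variance_nonzero_diff_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_type_one_error_calibrated(self, rng):
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            pre = rng.normal(size=12)
            post = rng.normal(size=12)
            hits += paired_t(pre, post).p < 0.05
        assert 0.03 <= hits / n_rep <= 0.07


class TestOneWayAnova:
    def test_identical_groups_flat(self):
        f, p = one_way_anova([np.ones(5) * 2, np.ones(4) * 2])
        assert f == 0.0 and p == 1.0

    def test_two_groups_equals_t_squared(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=8)
        f, p = one_way_anova([a, b])
        t = sst.ttest_ind(a, b)
        assert f == pytest.approx(t.statistic**2, rel=1e-9)
        assert p == pytest.approx(t.pvalue, rel=1e-9)

    def test_type_one_error_calibrated(self, rng):
        hits = sum(
            one_way_anova([rng.normal(size=8) for _ in range(3)])[1] < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= hits / 1000 <= 0.07

    def test_rejects_degenerate_shapes(self):
        with pytest.raises(ValueError):
            one_way_anova([np.ones(3)])
        with pytest.raises(ValueError):
            one_way_anova([np.ones(3), np.array([1.0])])


class TestRMAnova:
    subjects = ["S1", "S2", "S3"]
    trs = ["peppermint", "grapefruit", "lavender"]
    tis = [32, 34, 36, 38, 40]

    def test_no_effects_all_f_zero(self, rng):
        offsets = rng.normal(size=3)
        values = np.tile(offsets[:, None, None], (1, 3, 5))
        res = rm_anova(long_table(values, self.subjects, self.trs, self.tis))
        assert res.treatment.F == 0.0 and res.time.F == 0.0 and res.interaction.F == 0.0

    def test_pure_time_effect(self, rng):
        base = np.asarray(self.tis, dtype=float) * 1.0
        values = base[None, None, :] + rng.normal(0, 0.01, size=(3, 3, 5))
        res = rm_anova(long_table(values, self.subjects, self.trs, self.tis))
        assert res.time.F > 100
        assert res.treatment.F < 10  # no systematic treatment signal

    def test_degrees_of_freedom_three_by_five(self, rng):
        values = rng.normal(size=(11, 3, 5))
        res = rm_anova(long_table(values, [f"S{i}" for i in range(11)], self.trs, self.tis))
        assert (res.treatment.df_num, res.time.df_num, res.interaction.df_num) == (2, 4, 8)
        assert res.interaction.df_den == 8 * 10

    def test_matches_brute_force_partition(self, rng):
        for _ in range(5):
            values = rng.normal(size=(3, 3, 5)) + rng.normal(size=(1, 3, 5))
            df = long_table(values, self.subjects, self.trs, self.tis)
            res = rm_anova(df)
            f_a, f_b, f_ab = brute_force_rm_anova(df)
            assert res.treatment.F == pytest.approx(f_a, abs=1e-8)
            assert res.time.F == pytest.approx(f_b, abs=1e-8)
            assert res.interaction.F == pytest.approx(f_ab, abs=1e-8)

    def test_missing_cell_reported(self, rng):
        values = rng.normal(size=(3, 3, 5))
        df = long_table(values, self.subjects, self.trs, self.tis)
        df = df.drop(df.index[7])
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova(df)
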