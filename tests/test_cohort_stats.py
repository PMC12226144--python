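"""Age trends, age-bin t tests, BCa bootstrap, confound regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isingbrain.cohort_stats import (
    DEFAULT_AGE_BINS,
    age_group_distance_table,
    bootstrap_compare_correlations,
    confound_regression,
    correlate,
    mean_excluded_pct,
)
from isingbrain.errors import CollinearityError, UndefinedCorrelationError
from isingbrain.ising_sim import critical_temperature


def records_frame(age, t_hat, motion=None, rotation=None):
    n = len(age)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["control"] * n,
            "age": age,
            "max_motion": motion if motion is not None else np.zeros(n) + 0.5,
            "max_rotation": rotation if rotation is not None else np.zeros(n) + 0.5,
            "T_hat": t_hat,
        }
    )


class TestCorrelate:
    def test_exact_negative_line(self):
        x = np.arange(10.0)
        rep = correlate(x, -2 * x + 1)
        assert rep.pearson_r == pytest.approx(-1.0)
        assert rep.spearman_rho == pytest.approx(-1.0)

    def test_spearman_rank_formula(self):
        # 1 - 6 * sum(d^2) / (n(n^2-1)) with d = (0, 1, -1, 0) -> 1 - 12/60
        rep = correlate([1, 2, 3, 4], [1, 3, 2, 4])
        assert rep.spearman_rho == pytest.approx(0.8)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a, b = correlate(x, y), correlate(y, x)
        assert a.pearson_r == pytest.approx(b.pearson_r)
        assert a.spearman_rho == pytest.approx(b.spearman_rho)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_null_simulation_calibration(self):
        """Independent Gaussians at n=1000: small r, non-tiny p, ~95% of runs."""
        rng = np.random.default_rng(42)
        ok = 0
        for _ in range(100):
            rep = correlate(rng.normal(size=1000), rng.normal(size=1000))
            ok += abs(rep.pearson_r) < 0.08 and rep.pearson_p > 0.01
        assert ok >= 95


class TestAgeGroupTable:
    def test_all_subjects_one_bin_degenerate(self):
        rec = records_frame(np.full(10, 8.0), np.full(10, 2.1))
        with pytest.warns(UserWarning):
            table = age_group_distance_table(rec)
        offdiag = table.pairwise_p.to_numpy()[~np.eye(7, dtype=bool)]
        assert np.isnan(offdiag).all()

    def test_separated_bins_welch_oracle(self):
        rng = np.random.default_rng(1)
        tc = critical_temperature()
        a = rng.normal(0.1, 0.05, 30)
        b = rng.normal(0.3, 0.05, 30)
        rec = records_frame(
            np.r_[np.full(30, 8.0), np.full(30, 10.0)], tc - np.r_[a, b]
        )
        with pytest.warns(UserWarning):  # five of the seven bins are empty
            table = age_group_distance_table(rec)
        p = table.pairwise_p.loc["7-9", "9-11"]
        assert p < 0.001
        # Welch formula evaluated independently
        t_stat = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 30 + b.var(ddof=1) / 30)
        v = (a.var(ddof=1) / 30 + b.var(ddof=1) / 30) ** 2 / (
            (a.var(ddof=1) / 30) ** 2 / 29 + (b.var(ddof=1) / 30) ** 2 / 29
        )
        assert p == pytest.approx(2 * stats.t.sf(abs(t_stat), v), rel=1e-9)

    def test_p_matrix_symmetric(self):
        rng = np.random.default_rng(2)
        rec = records_frame(rng.uniform(7, 21, 120), rng.normal(2.2, 0.1, 120))
        table = age_group_distance_table(rec)
        p = table.pairwise_p.to_numpy()
        mask = ~np.isnan(p)
        assert np.array_equal(mask, mask.T)
        assert np.allclose(p[mask], p.T[mask])

    def test_type_i_error_rate(self):
        """Two bins from one distribution: ~5% of replicates reject at 0.05."""
        rng = np.random.default_rng(3)
        rejections = 0
        for _ in range(500):
            p = stats.ttest_ind(
                rng.normal(0.2, 0.05, 200), rng.normal(0.2, 0.05, 200), equal_var=False
            ).pvalue
            rejections += p < 0.05
        assert 0.03 <= rejections / 500 <= 0.08

    def test_holm_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(4)
        rec = records_frame(rng.uniform(7, 21, 200), rng.normal(2.2, 0.1, 200))
        raw = age_group_distance_table(rec).pairwise_p.to_numpy()
        holm = age_group_distance_table(rec, adjust="holm").pairwise_p.to_numpy()
        mask = ~np.isnan(raw)
        assert (holm[mask] >= raw[mask] - 1e-12).all()

    def test_last_bin_closed_on_right(self):
        rec = records_frame([21.0, 20.0, 19.5], [2.1, 2.15, 2.2])
        with pytest.warns(UserWarning):
            table = age_group_distance_table(rec)
        assert table.samples[DEFAULT_AGE_BINS[-1]].size == 3


@pytest.fixture(scope="module")
def two_groups():
    rng = np.random.default_rng(10)
    age_a = rng.uniform(8, 20, 60)
    age_b = rng.uniform(8, 20, 50)
    rec_a = records_frame(age_a, 2.4 - 0.02 * age_a + rng.normal(0, 0.05, 60))
    rec_b = records_frame(age_b, 2.4 - 0.02 * age_b + rng.normal(0, 0.05, 50))
    return rec_a, rec_b


class TestBootstrap:
    def test_mean_excluded_fraction(self):
        pct = mean_excluded_pct(353, 1000, np.random.default_rng(0))
        assert pct == pytest.approx(36.8, abs=0.5)

    def test_same_seed_reproducible(self, two_groups):
        a, b = two_groups
        r1 = bootstrap_compare_correlations(a, b, n_boot=100, seed=5)
        r2 = bootstrap_compare_correlations(a, b, n_boot=100, seed=5)
        for key in r1.distributions:
            assert np.array_equal(r1.distributions[key], r2.distributions[key])
        assert r1.comparison_p == r2.comparison_p

    def test_self_comparison_p_near_one(self, two_groups):
        """Comparing a group with itself: the paired difference distribution is
        centred at zero, so p should rarely be small."""
        a, _ = two_groups
        big = 0
        for seed in range(50):
            res = bootstrap_compare_correlations(a, a, n_boot=200, seed=seed)
            big += res.comparison_p["pearson"] > 0.5
        assert big >= 48

    def test_intervals_cover_point_estimate(self, two_groups):
        a, b = two_groups
        res = bootstrap_compare_correlations(a, b, n_boot=500, seed=3)
        for key, (lo, hi) in res.intervals.items():
            assert -1.0 <= lo <= hi <= 1.0
            assert lo <= res.point_estimates[key] <= hi

    def test_degenerate_perfectly_linear_group(self):
        age = np.linspace(8, 20, 12)
        rec = records_frame(age, 3.0 - 0.05 * age)
        res = bootstrap_compare_correlations(rec, rec, n_boot=50, seed=0)
        lo, hi = res.intervals[("a", "pearson")]
        assert lo == pytest.approx(-1.0) and hi == pytest.approx(-1.0)

    def test_bca_interval_against_scipy(self, two_groups):
        """Independent oracle: scipy's BCa bootstrap on the same statistic."""
        a, _ = two_groups
        res = bootstrap_compare_correlations(a, a, n_boot=2000, seed=7)
        ref = stats.bootstrap(
            (a["age"].to_numpy(), a["T_hat"].to_numpy()),
            lambda x, y: stats.pearsonr(x, y).statistic,
            n_resamples=2000,
            paired=True,
            vectorized=False,
            method="BCa",
            random_state=np.random.default_rng(1),
        ).confidence_interval
        lo, hi = res.intervals[("a", "pearson")]
        assert lo == pytest.approx(ref.low, abs=0.05)
        assert hi == pytest.approx(ref.high, abs=0.05)

    def test_small_group_rejected(self, two_groups):
        a, _ = two_groups
        with pytest.raises(ValueError):
            bootstrap_compare_correlations(a.head(5), a, n_boot=10, seed=0)


class TestConfoundRegression:
    def test_pure_age_effect_recovered(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(8, 20, 50)
        rec = records_frame(
            age, 3.0 - 0.04 * age,
            motion=rng.normal(0.6, 0.2, 50), rotation=rng.normal(0.6, 0.2, 50),
        )
        res = confound_regression(rec)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.coefficients.loc["age", "beta"] == pytest.approx(-1.0, abs=1e-6)
        assert abs(res.coefficients.loc["max_motion", "beta"]) < 1e-6

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        n = 12
        age = rng.uniform(8, 20, n)
        motion = rng.normal(0.6, 0.2, n)
        rotation = rng.normal(0.6, 0.2, n)
        t_hat = 2.5 - 0.03 * age + 0.1 * motion + rng.normal(0, 0.02, n)
        rec = records_frame(age, t_hat, motion, rotation)
        res = confound_regression(rec)
        # closed-form solve on the same standardized design
        Xz = np.column_stack([motion, rotation, age])
        Xz = (Xz - Xz.mean(0)) / Xz.std(0, ddof=1)
        yz = (t_hat - t_hat.mean()) / t_hat.std(ddof=1)
        X1 = np.column_stack([np.ones(n), Xz])
        beta = np.linalg.solve(X1.T @ X1, X1.T @ yz)
        for i, name in enumerate(["max_motion", "max_rotation", "age"]):
            assert res.coefficients.loc[name, "beta"] == pytest.approx(beta[i + 1], abs=1e-10)

    def test_null_outcome_small_r2(self):
        rng = np.random.default_rng(2)
        ok = 0
        for _ in range(100):
            rec = records_frame(
                rng.uniform(8, 20, 300), rng.normal(2.2, 0.1, 300),
                motion=rng.normal(0.6, 0.2, 300), rotation=rng.normal(0.6, 0.2, 300),
            )
            ok += confound_regression(rec).r_squared < 0.05
        assert ok >= 95

    def test_collinearity_names_column(self):
        rng = np.random.default_rng(3)
        age = rng.uniform(8, 20, 30)
        rec = records_frame(age, rng.normal(2.2, 0.1, 30), motion=2 * age, rotation=rng.normal(0.6, 0.2, 30))
        with pytest.raises(CollinearityError):
            confound_regression(rec)
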