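"""Cohort-level statistics for estimated temperatures.

Given a table of subjects (id, group, age, motion covariates, estimated
temperature T_hat) the module reproduces a standard distance-from-criticality
analysis: Pearson/Spearman age trends, a 2-year age-bin table of |T - T_c|
with pairwise Welch t tests, a BCa bootstrap comparison of the two groups'
age-temperature correlations, and a confound regression of T_hat on motion
covariates and age with standardized coefficients.

The BCa machinery (bias correction z0 from the fraction of resampled
coefficients below the point estimate, acceleration a from jackknife
skewness) is implemented here because the per-resample distributions and the
paired difference p value are part of the reported surface; scipy's bootstrap
serves as an independent cross-check in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, DegenerateResampleError, UndefinedCorrelationError
from .ising_sim import critical_temperature

__all__ = [
    "CorrelationReport",
    "AgeGroupTable",
    "BootstrapComparison",
    "ConfoundRegression",
    "DEFAULT_AGE_BINS",
    "correlate",
    "age_group_distance_table",
    "mean_excluded_pct",
    "bootstrap_compare_correlations",
    "confound_regression",
]

#: Half-open 2-year bins [7,9), ..., [17,19); the last bin [19,21] is closed.
DEFAULT_AGE_BINS: list[tuple[float, float]] = [(7 + 2 * i, 9 + 2 * i) for i in range(7)]


@dataclass
class CorrelationReport:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float


def correlate(x, y) -> CorrelationReport:
    """Pearson and Spearman correlation with two-sided t-transform p values."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1D sequences of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("zero variance input; correlation undefined")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationReport(float(pr.statistic), float(pr.pvalue), float(sr.statistic), float(sr.pvalue))


@dataclass
class AgeGroupTable:
    """Per-bin |T_hat - T_c| samples and the pairwise Welch t-test p matrix."""

    bins: list[tuple[float, float]]
    samples: dict[tuple[float, float], np.ndarray]
    pairwise_p: pd.DataFrame

    def bin_labels(self) -> list[str]:
        return [f"{lo:g}-{hi:g}" for lo, hi in self.bins]


def _bin_index(age: float, bins) -> int | None:
    for i, (lo, hi) in enumerate(bins):
        last = i == len(bins) - 1
        if lo <= age < hi or (last and age == hi):
            return i
    return None


def age_group_distance_table(
    records: pd.DataFrame,
    bins=None,
    t_c: float | None = None,
    adjust: str | None = None,
) -> AgeGroupTable:
    """Distance from criticality per 2-year age bin, pairwise Welch t tests.

    Bins are half-open on the right except the last; bins holding fewer than
    two subjects yield NaN p values for all their pairs (with a warning).
    P values are unadjusted by default; ``adjust="holm"`` applies a Holm
    correction across the defined pairs.
    """
    bins = list(bins) if bins is not None else list(DEFAULT_AGE_BINS)
    if records.empty:
        raise ValueError("records table is empty")
    t_c = critical_temperature() if t_c is None else t_c
    abs_delta = (records["T_hat"] - t_c).abs().to_numpy()
    ages = records["age"].to_numpy()
    samples = {b: [] for b in bins}
    for a, d in zip(ages, abs_delta):
        i = _bin_index(float(a), bins)
        if i is not None:
            samples[bins[i]].append(d)
    samples = {b: np.asarray(v, dtype=np.float64) for b, v in samples.items()}
    small = [b for b, v in samples.items() if v.size < 2]
    if small:
        warnings.warn(f"{len(small)} age bin(s) hold fewer than 2 subjects; their p values are NaN", stacklevel=2)
    labels = [f"{lo:g}-{hi:g}" for lo, hi in bins]
    p = np.full((len(bins), len(bins)), np.nan)
    pairs = []
    for i in range(len(bins)):
        for j in range(i + 1, len(bins)):
            a, b = samples[bins[i]], samples[bins[j]]
            if a.size >= 2 and b.size >= 2:
                p[i, j] = p[j, i] = stats.ttest_ind(a, b, equal_var=False).pvalue
                pairs.append((i, j))
    if adjust == "holm" and pairs:
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests([p[i, j] for i, j in pairs], method="holm")[1]
        for (i, j), q in zip(pairs, adjusted):
            p[i, j] = p[j, i] = q
    elif adjust not in (None, "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    return AgeGroupTable(bins, samples, pd.DataFrame(p, index=labels, columns=labels))


@dataclass
class BootstrapComparison:
    """Resampled correlation distributions for two groups and their comparison."""

    n_boot: int
    distributions: dict  # (group, coef) -> np.ndarray of length n_boot
    comparison_p: dict   # coef -> two-sided p for the paired resample difference
    intervals: dict      # (group, coef) -> (lo, hi) BCa interval
    point_estimates: dict
    mean_excluded_pct: float
    n_redraws: int = 0
    conf: float = 0.95


def mean_excluded_pct(n: int, n_boot: int, rng: np.random.Generator) -> float:
    """Average % of distinct subjects absent from a with-replacement resample.

    Measured over n_boot actual index draws of size n (expectation
    100*(1-1/n)^n, about 36.8% for large cohorts).
    """
    miss = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        miss[b] = n - np.unique(idx).size
    return float(100.0 * miss.mean() / n)


def _bca_interval(boot: np.ndarray, theta_hat: float, jack: np.ndarray, conf: float) -> tuple[float, float]:
    """Bias-corrected and accelerated percentile interval."""
    b = boot.size
    prop = np.count_nonzero(boot < theta_hat) / b
    if prop == 0.0 or prop == 1.0 or np.ptp(boot) == 0:
        # degenerate distribution (e.g. r = 1 in every resample)
        return float(np.min(boot)), float(np.max(boot))
    z0 = stats.norm.ppf(prop)
    jm = jack.mean()
    num = ((jm - jack) ** 3).sum()
    den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
    a = num / den if den > 0 else 0.0
    alpha = (1.0 - conf) / 2.0
    lo_hi = []
    for za in (stats.norm.ppf(alpha), stats.norm.ppf(1.0 - alpha)):
        adj = stats.norm.cdf(z0 + (z0 + za) / (1.0 - a * (z0 + za)))
        lo_hi.append(float(np.quantile(boot, adj)))
    return lo_hi[0], lo_hi[1]


def _corr_pair(age: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    return (
        float(stats.pearsonr(age, t).statistic),
        float(stats.spearmanr(age, t).statistic),
    )


def bootstrap_compare_correlations(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    n_boot: int = 1000,
    conf: float = 0.95,
    seed: int | None = None,
    x_col: str = "age",
    y_col: str = "T_hat",
) -> BootstrapComparison:
    """Compare two groups' age-temperature correlations by paired bootstrap.

    Each group is resampled with replacement n_boot times and both
    correlation coefficients recomputed per resample; BCa intervals use the
    bias correction from the resample distribution and the acceleration from
    a leave-one-out jackknife. The comparison p pairs the i-th resample of
    each group, forms the difference, and reports
    2*min(P(diff <= 0), P(diff >= 0)). Zero-variance resamples are redrawn
    (counted, capped at 10 rounds each).
    """
    groups = {"a": records_a, "b": records_b}
    for name, rec in groups.items():
        if len(rec) < 10:
            raise ValueError(f"group {name} needs >= 10 subjects, got {len(rec)}")
    rng = np.random.default_rng(seed)
    distributions: dict = {}
    intervals: dict = {}
    point: dict = {}
    n_redraws = 0
    excl = []
    for name, rec in groups.items():
        x = rec[x_col].to_numpy(dtype=np.float64)
        y = rec[y_col].to_numpy(dtype=np.float64)
        n = x.size
        point[(name, "pearson")], point[(name, "spearman")] = _corr_pair(x, y)
        boot_p = np.empty(n_boot)
        boot_s = np.empty(n_boot)
        missing = 0
        for i in range(n_boot):
            for attempt in range(11):
                idx = rng.integers(0, n, size=n)
                if x[idx].std() > 0 and y[idx].std() > 0:
                    break
                n_redraws += 1
                if attempt == 10:
                    raise DegenerateResampleError(
                        f"group {name}: resample stayed degenerate after 10 redraws"
                    )
            boot_p[i], boot_s[i] = _corr_pair(x[idx], y[idx])
            missing += n - np.unique(idx).size
        excl.append(100.0 * missing / (n_boot * n))
        distributions[(name, "pearson")] = boot_p
        distributions[(name, "spearman")] = boot_s
        jack_p = np.empty(n)
        jack_s = np.empty(n)
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            jack_p[i], jack_s[i] = _corr_pair(x[mask], y[mask])
            mask[i] = True
        intervals[(name, "pearson")] = _bca_interval(boot_p, point[(name, "pearson")], jack_p, conf)
        intervals[(name, "spearman")] = _bca_interval(boot_s, point[(name, "spearman")], jack_s, conf)
    comparison_p = {}
    for coef in ("pearson", "spearman"):
        diff = distributions[("a", coef)] - distributions[("b", coef)]
        p_le = np.count_nonzero(diff <= 0) / n_boot
        p_ge = np.count_nonzero(diff >= 0) / n_boot
        comparison_p[coef] = min(1.0, 2.0 * min(p_le, p_ge))
    return BootstrapComparison(
        n_boot=n_boot,
        distributions=distributions,
        comparison_p=comparison_p,
        intervals=intervals,
        point_estimates=point,
        mean_excluded_pct=float(np.mean(excl)),
        n_redraws=n_redraws,
        conf=conf,
    )


@dataclass
class ConfoundRegression:
    """Standardized OLS of T_hat on motion covariates and age."""

    coefficients: pd.DataFrame  # index: predictor; columns: beta, p
    r_squared: float
    standardized: bool = True


_PREDICTORS = ["max_motion", "max_rotation", "age"]


def confound_regression(
    records: pd.DataFrame,
    predictors: list[str] | None = None,
    outcome: str = "T_hat",
    standardized: bool = True,
) -> ConfoundRegression:
    """OLS with intercept; by default both sides are z-scored so the betas are
    standardized coefficients comparable across units."""
    predictors = list(predictors) if predictors is not None else list(_PREDICTORS)
    if len(records) < 10:
        raise ValueError(f"need >= 10 records, got {len(records)}")
    X = records[predictors].to_numpy(dtype=np.float64)
    y = records[outcome].to_numpy(dtype=np.float64)
    if standardized:
        sds = X.std(axis=0, ddof=1)
        if (sds == 0).any():
            raise CollinearityError(
                f"zero-variance predictor: {predictors[int(np.argmax(sds == 0))]}",
                column=predictors[int(np.argmax(sds == 0))],
            )
        X = (X - X.mean(axis=0)) / sds
        y = (y - y.mean()) / y.std(ddof=1)
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name a column whose removal restores full rank
        for j, name in enumerate(predictors):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == reduced.shape[1]:
                raise CollinearityError(f"collinear predictor: {name}", column=name)
        raise CollinearityError("design matrix is rank deficient")
    fit = sm.OLS(y, design).fit()
    coef = pd.DataFrame(
        {"beta": fit.params[1:], "p": fit.pvalues[1:]}, index=predictors
    )
    return ConfoundRegression(coef, float(fit.rsquared), standardized)
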