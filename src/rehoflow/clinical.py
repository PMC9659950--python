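"""Non-imaging statistics: power analysis, normality testing, group
comparisons, correlation tests, Bonferroni adjustment, MoCA grouping and
apnea-hypopnea event scoring.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "PowerSpec", "RespiratoryEvent", "required_sample_size", "ks_normality_test",
    "student_t_from_summary", "two_sample_ttest", "mann_whitney_u",
    "pearson_corr_test", "pearson_p_from_r", "bonferroni_adjust",
    "classify_moca", "detect_respiratory_events", "compute_ahi",
    "classify_ahi_severity", "clinical_comparison_table",
]


@dataclass
class PowerSpec:
    """Design parameters for a two-sample t-test power analysis."""

    effect_size_d: float = 0.8
    alpha: float = 0.05
    power: float = 0.8
    tails: int = 2
    allocation_ratio: float = 1.0  # n2 / n1

    def __post_init__(self) -> None:
        if self.effect_size_d <= 0:
            raise ValueError("effect size d must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must be in (0,1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if self.allocation_ratio <= 0:
            raise ValueError("allocation ratio must be positive")


@dataclass
class RespiratoryEvent:
    """A scored apnea or hypopnea."""

    kind: str           # "apnea" or "hypopnea"
    onset: float        # s
    duration: float     # s
    min_desaturation: float  # % SpO2 drop below baseline within the lag window

    def __post_init__(self) -> None:
        if self.kind not in ("apnea", "hypopnea"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration < 10.0:
            raise ValueError("respiratory events must last >= 10 s")


def _t_power(n1: int, n2: int, d: float, alpha: float, tails: int) -> float:
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    if tails == 2:
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    tcrit = stats.t.ppf(1 - alpha, df)
    return stats.nct.sf(tcrit, df, ncp)


def required_sample_size(spec: PowerSpec) -> tuple:
    """Smallest per-group n achieving the target power (noncentral-t iteration).

    Returns (n per group 1, total). With allocation ratio r, group 2 gets
    ceil(r * n1). Power below any attainable level floors at n1 = 2.
    """
    r = spec.allocation_ratio
    for n1 in range(2, 100001):
        n2 = max(2, int(np.ceil(r * n1)))
        if _t_power(n1, n2, spec.effect_size_d, spec.alpha, spec.tails) >= spec.power:
            return n1, n1 + n2
    raise ValueError("no attainable sample size below 100000 per group")


def ks_normality_test(x, method: str = "lilliefors") -> tuple:
    """Kolmogorov-Smirnov normality test with estimated parameters.

    The default Lilliefors variant corrects the KS distribution for the fact
    that mean and SD are estimated from the sample; ``method='exact'`` runs
    the plain one-sample KS against Normal(mean(x), sd(x)) instead (valid only
    when the parameters are known a priori).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    if method == "lilliefors":
        stat, p = lilliefors(x, dist="norm")
        return float(stat), float(p)
    if method == "exact":
        res = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        return float(res.statistic), float(res.pvalue)
    raise ValueError("method must be 'lilliefors' or 'exact'")


def student_t_from_summary(m1: float, s1: float, n1: int,
                           m2: float, s2: float, n2: int,
                           equal_var: bool = True) -> tuple:
    """Two-sample t from group summaries (mean, SD, n): (t, df, two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SDs must be positive")
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    df = n1 + n2 - 2 if equal_var else res.df
    return float(res.statistic), float(df), float(res.pvalue)


def two_sample_ttest(x, y, equal_var: bool = True) -> tuple:
    """Two-sample t-test on raw data: (t, two-sided p)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x, y, method: str = "asymptotic") -> tuple:
    """Mann-Whitney U, two-sided: (U, p).

    The default asymptotic p uses the normal approximation with tie
    correction and continuity correction; ``method='exact'`` enumerates the
    null distribution (no ties only).
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("samples must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via t = r sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def pearson_corr_test(x, y) -> tuple:
    """Pearson correlation with two-sided p: (r, p)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, m * p); m defaults to len(p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size if m is None else m
    return np.minimum(1.0, m * p)


def classify_moca(score: float, cutoff: int = 26) -> str:
    """MCI iff the MoCA total score is below the cutoff (default 26)."""
    if not 0 <= score <= 30:
        raise ValueError(f"MoCA score must be in [0,30], got {score}")
    return "MCI" if score < cutoff else "nMCI"


# ---------------------------------------------------------------------------
# respiratory event scoring

def detect_respiratory_events(airflow, spo2, sampling_hz: float,
                              apnea_reduction: float = 0.9,
                              hypopnea_reduction: float = 0.3,
                              min_duration_s: float = 10.0,
                              desat_threshold: float = 4.0,
                              desat_lag_s: float = 30.0) -> list:
    """Score apneas and hypopneas from airflow and SpO2 traces.

    The airflow amplitude envelope (Hilbert magnitude, lightly smoothed) is
    compared with its record-wide median baseline. Contiguous spans with a
    >= ``apnea_reduction`` drop lasting >= ``min_duration_s`` are apneas;
    spans with a drop in [hypopnea_reduction, apnea_reduction) of sufficient
    duration are hypopneas when SpO2 falls >= ``desat_threshold`` % below its
    baseline within the event window extended by ``desat_lag_s``. Events are
    non-overlapping by construction. Assumes events occupy a minority of the
    record (the baseline is a global median).
    """
    airflow = np.asarray(airflow, dtype=float)
    spo2 = np.asarray(spo2, dtype=float)
    if airflow.shape != spo2.shape:
        raise ValueError("airflow and SpO2 traces must be aligned")
    if airflow.size < 60 * sampling_hz:
        raise ValueError("traces must cover at least 60 s")
    env = np.abs(signal.hilbert(airflow))
    env = ndimage.uniform_filter1d(env, size=max(1, int(2.0 * sampling_hz)))
    baseline = np.median(env)
    if baseline <= 0:
        raise ValueError("flat airflow trace")
    reduction = 1.0 - env / baseline
    spo2_baseline = np.median(spo2)

    events: list[RespiratoryEvent] = []
    min_len = int(min_duration_s * sampling_hz)
    lag = int(desat_lag_s * sampling_hz)
    for start, stop in _runs(reduction >= hypopnea_reduction):
        if stop - start < min_len:
            continue
        sub = reduction[start:stop]
        deep = _longest_run(sub >= apnea_reduction)
        onset = start / sampling_hz
        dur = (stop - start) / sampling_hz
        window = spo2[start:min(spo2.size, stop + lag)]
        desat = float(spo2_baseline - window.min())
        if deep >= min_len:
            events.append(RespiratoryEvent("apnea", onset, dur, max(0.0, desat)))
        elif desat >= desat_threshold:
            events.append(RespiratoryEvent("hypopnea", onset, dur, desat))
    return events


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of contiguous True runs."""
    padded = np.r_[False, mask, False]
    edges = np.diff(padded.astype(int))
    starts = np.nonzero(edges == 1)[0]
    stops = np.nonzero(edges == -1)[0]
    return list(zip(starts, stops))


def _longest_run(mask: np.ndarray) -> int:
    runs = _runs(mask)
    return max((stop - start for start, stop in runs), default=0)


def compute_ahi(events, sleep_hours: float) -> float:
    """Apnea-hypopnea index: events per hour of sleep."""
    if sleep_hours <= 0:
        raise ValueError("sleep_hours must be positive")
    return len(events) / sleep_hours


def classify_ahi_severity(ahi: float) -> str:
    """AHI severity bands: <5 normal, [5,15) mild, [15,30) moderate, >=30 severe."""
    if ahi < 0:
        raise ValueError("AHI must be >= 0")
    if ahi < 5:
        return "normal"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


# ---------------------------------------------------------------------------
# cohort-level report

CLINICAL_VARIABLES = [
    "age", "education", "bmi", "neck_circumference", "waistline", "ahi",
    "lsao2", "msao2", "sleep_efficiency", "ai", "odi", "sao2_below_90", "moca",
]


def clinical_comparison_table(table: pd.DataFrame, variables=None,
                              normality_alpha: float = 0.05) -> pd.DataFrame:
    """Group comparison per clinical variable, test chosen by normality.

    Each variable is tested for normality (Lilliefors) in both groups; normal
    variables are compared with the pooled two-sample t-test, the rest with
    the Mann-Whitney U. Returns per-variable group mean +/- SD, the test used
    and its p-value.
    """
    variables = CLINICAL_VARIABLES if variables is None else variables
    g1 = table[table["group"] == "MCI"]
    g2 = table[table["group"] == "nMCI"]
    rows = []
    for var in variables:
        x, y = g1[var].to_numpy(float), g2[var].to_numpy(float)
        try:
            normal = (ks_normality_test(x)[1] > normality_alpha and
                      ks_normality_test(y)[1] > normality_alpha)
        except ValueError:
            normal = False
        if normal:
            stat, p = two_sample_ttest(x, y)
            test = "student_t"
        else:
            stat, p = mann_whitney_u(x, y)
            test = "mann_whitney_u"
        rows.append({"variable": var,
                     "group1_mean": x.mean(), "group1_sd": x.std(ddof=1),
                     "group2_mean": y.mean(), "group2_sd": y.std(ddof=1),
                     "test": test, "statistic": stat, "p": p})
    return pd.DataFrame(rows)
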