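"""Cohort statistics for condylar morphometry trials.

Implements the analysis battery used for two-arm disc-displacement /
disc-repositioning cohorts: quartile summaries on the h = (n+1)p
percentile convention, exact and tie-corrected asymptotic Mann-Whitney U,
pooled and Welch two-sample t (from raw data or printed summaries),
two-way random-effects absolute-agreement single-measure ICC with an
F-based 95% CI, a dummy-coded general linear model for summed volume
change, noncentral-t sample-size calculation, bilateral summation of
per-condyle measurements, and the baseline directional-resorption
comparison of d_io and d_pipo between anteromedial and anterolateral
disc-displacement variants.

All tests are two-sided. No multiple-testing correction is applied: each
table's tests are marginal, and downstream users should treat the per-table
p-values accordingly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStats", "TestResult", "RegressionRow", "PowerSpec",
    "quartiles", "mann_whitney", "unpaired_t", "icc_inter_rater",
    "ols_dummy_regression", "required_sample_size", "sum_bilateral",
    "directional_resorption_analysis", "directional_displacement_proportion",
]

#: columns of the per-condyle, per-timepoint measurement table
MEASUREMENT_COLUMNS = (
    "patient_id", "group", "gender", "age_band", "diagnosis", "side",
    "timepoint", "volume",
    "h_i", "h_o", "h_a", "h_p", "h_pi", "h_po", "h_up",
    "d_io", "d_pipo", "disc_direction", "anb", "pn", "me",
)
HEIGHT_COLS = ("h_i", "h_o", "h_a", "h_p", "h_pi", "h_po", "h_up")


class StatsError(ValueError):
    """Invalid statistical input."""


@dataclass(frozen=True)
class SummaryStats:
    median: float
    q25: float
    q75: float
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    warning: str | None = None


@dataclass(frozen=True)
class RegressionRow:
    term: str
    b: float
    se: float
    ci_low: float
    ci_high: float
    t: float
    p: float


@dataclass(frozen=True)
class PowerSpec:
    """Design inputs for a two-sample t-test sample-size calculation."""

    mu1: float
    mu2: float
    sd1: float
    sd2: float
    alpha: float = 0.05
    power: float = 0.90
    dropout: float = 0.0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise StatsError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise StatsError("power must be in (0, 1)")
        if not 0 <= self.dropout < 1:
            raise StatsError("dropout must be in [0, 1)")
        if self.sd1 < 0 or self.sd2 < 0:
            raise StatsError("standard deviations must be non-negative")


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def quartiles(values) -> SummaryStats:
    """Median and quartiles with the weighted-average h = (n+1)p rule.

    This is the default percentile convention of the major commercial
    statistics packages (numpy's ``weibull`` method), so summaries are
    comparable with published clinical tables. Mean/SD use the n-1
    denominator; the SD of a single observation is reported as 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise StatsError("quartiles of an empty sample")
    q25, med, q75 = np.percentile(x, [25, 50, 75], method="weibull")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return SummaryStats(median=float(med), q25=float(q25), q75=float(q75),
                        mean=float(x.mean()), sd=sd, n=int(x.size))


# ---------------------------------------------------------------------------
# rank test
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of the first sample, with midrank tie handling."""
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    rx = ranks[: len(x)].sum()
    return float(rx - len(x) * (len(x) + 1) / 2.0)


def mann_whitney(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode='exact'`` enumerates all group-label assignments of the combined
    sample (feasible for n_x + n_y <= 16; the default switches to exact at
    <= 12). ``mode='asymptotic'`` uses the tie-corrected normal
    approximation without continuity correction, matching the large-sample
    output of standard clinical statistics software.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    total = nx + ny
    u_obs = _u_statistic(x, y)
    if mode == "auto":
        mode = "exact" if total <= 12 else "asymptotic"

    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return TestResult(u_obs, 1.0, f"mann-whitney ({mode})",
                          warning="all observations tied across groups")

    if mode == "exact":
        if total > 16:
            raise StatsError("exact enumeration limited to n_x + n_y <= 16")
        ranks = sps.rankdata(combined)
        center = nx * ny / 2.0
        dev_obs = abs(u_obs - center)
        n_extreme = 0
        n_total = 0
        base = np.arange(total)
        for pick in itertools.combinations(base, nx):
            rx = ranks[list(pick)].sum()
            u = rx - nx * (nx + 1) / 2.0
            n_total += 1
            if abs(u - center) >= dev_obs - 1e-12:
                n_extreme += 1
        return TestResult(u_obs, n_extreme / n_total, "mann-whitney (exact)")

    if mode != "asymptotic":
        raise StatsError(f"unknown mode {mode!r}")
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())
                     / (total * (total - 1)))
    var = nx * ny / 12.0 * ((total + 1) - tie_term)
    if var <= 0:
        return TestResult(u_obs, 1.0, "mann-whitney (asymptotic)",
                          warning="zero variance (all tied)")
    z = (u_obs - nx * ny / 2.0) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(u_obs, min(p, 1.0), "mann-whitney (asymptotic)")


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def _summarize(sample) -> tuple[int, float, float]:
    """Accept raw data (list/array) or an (n, mean, sd) summary tuple."""
    if isinstance(sample, tuple) and len(sample) == 3 \
            and np.isscalar(sample[0]):
        n, mean, sd = sample
        return int(n), float(mean), float(sd)
    x = np.asarray(sample, dtype=float).ravel()
    return len(x), float(x.mean()), float(np.std(x, ddof=1))


def unpaired_t(x, y, variant: str = "pooled") -> TestResult:
    """Two-sided unpaired t test from raw data or (n, mean, sd) summaries.

    The pooled-variance Student form is the default; ``variant='welch'``
    gives the unequal-variance test with Satterthwaite degrees of freedom.
    The raw-data and summary paths agree exactly.
    """
    n1, m1, s1 = _summarize(x)
    n2, m2, s2 = _summarize(y)
    if n1 < 2 or n2 < 2:
        raise StatsError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise StatsError("standard deviations must be non-negative")
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return TestResult(0.0, 1.0, f"t ({variant})",
                              warning="zero variance in both groups")
        raise StatsError("zero variance with unequal means: t undefined")
    if variant == "pooled":
        sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    elif variant == "welch":
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        raise StatsError(f"unknown variant {variant!r}")
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(min(p, 1.0)), f"t ({variant}, df={df:.4g})")


# ---------------------------------------------------------------------------
# inter-rater agreement
# ---------------------------------------------------------------------------

def icc_inter_rater(ratings, alpha: float = 0.05
                    ) -> tuple[float, float, float]:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is a subjects x raters matrix with no missing cells. The
    confidence interval follows McGraw & Wong (1996), using an
    F distribution with Satterthwaite degrees of freedom. A cohort with no
    between-subject variance yields ICC 0.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise StatsError("ratings must be a 2D subjects x raters matrix")
    n, k = m.shape
    if n < 5 or k < 2:
        raise StatsError("need >= 5 subjects and >= 2 raters")
    if not np.all(np.isfinite(m)):
        raise StatsError("missing or non-finite cells in ratings")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((m - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or msr <= mse:
        return 0.0, 0.0, 0.0
    icc = (msr - mse) / denom
    if icc >= 1.0 - 1e-12:  # perfect agreement: degenerate CI
        return 1.0, 1.0, 1.0

    a = k * icc / (n * (1 - icc))
    b = 1 + k * icc * (n - 1) / (n * (1 - icc))
    v = ((a * msc + b * mse) ** 2
         / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
    f_star = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (n * (msr - f_star * mse)
             / (f_star * (k * msc + (k * n - k - n) * mse) + n * msr))
    upper = (n * (f_l * msr - mse)
             / (k * msc + (k * n - k - n) * mse + n * f_l * msr))
    return float(icc), float(max(lower, -1.0)), float(min(upper, 1.0))


# ---------------------------------------------------------------------------
# general linear model
# ---------------------------------------------------------------------------

#: dummy coding: indicator 1 for these reference-contrast levels
DUMMY_LEVELS = {
    "gender": ("Gender (Female)", lambda df: df["gender"].eq("female")),
    "disc_position": ("Disc position (Reposited)", lambda df: df["group"].eq("DR")),
    "age_band": ("Age (10-18y)", lambda df: df["age_band"].eq("10-18")),
    "diagnosis": ("TMJ diagnosis (Unilateral)", lambda df: df["diagnosis"].eq("unilateral")),
}


def ols_dummy_regression(table: pd.DataFrame, response: str = "volume_change",
                         terms: Sequence[str] = ("gender", "disc_position",
                                                 "age_band", "diagnosis"),
                         ) -> list[RegressionRow]:
    """Multi-variable general linear model for a per-patient outcome.

    Each term enters as a 0/1 indicator for the contrast level (Female,
    Reposited, 10-18 years, Unilateral). Returns intercept plus one row per
    term with coefficient, SE, 95% CI, t and p.
    """
    import statsmodels.api as sm

    y = np.asarray(table[response], dtype=float)
    cols, labels = [], []
    for t in terms:
        if t not in DUMMY_LEVELS:
            raise StatsError(f"unknown regression term {t!r}")
        label, fn = DUMMY_LEVELS[t]
        cols.append(fn(table).to_numpy(dtype=float))
        labels.append(label)
    X = np.column_stack([np.ones(len(y))] + cols)
    if len(y) <= X.shape[1]:
        raise StatsError("fewer observations than parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = [labels[j - 1] for j in range(1, X.shape[1])
                   if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise StatsError(f"rank-deficient design; aliased terms: {aliased}")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    rows = []
    for j, name in enumerate(["Intercept"] + labels):
        rows.append(RegressionRow(
            term=name, b=float(fit.params[j]), se=float(fit.bse[j]),
            ci_low=float(ci[j][0]), ci_high=float(ci[j][1]),
            t=float(fit.tvalues[j]), p=float(fit.pvalues[j])))
    return rows


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------

def two_sample_t_power(n_per_group: int, spec: PowerSpec) -> float:
    """Power of the two-sided unequal-variance two-sample t test at equal n,
    by the noncentral-t distribution with Satterthwaite df."""
    n = n_per_group
    v1 = spec.sd1 ** 2 / n
    v2 = spec.sd2 ** 2 / n
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n - 1) + v2 ** 2 / (n - 1))
    ncp = abs(spec.mu1 - spec.mu2) / math.sqrt(v1 + v2)
    tcrit = sps.t.ppf(1 - spec.alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def required_sample_size(spec: PowerSpec, max_n: int = 1_000_000
                         ) -> tuple[int, int]:
    """Smallest equal per-group n reaching the target power, plus the
    dropout-inflated total enrolment.

    The per-group n is scanned upward using the noncentral-t power of the
    two-sided unequal-variance test, then inflated by 1/(1 - dropout) with
    ceiling rounding; the total is twice the inflated per-group n (1:1
    allocation, hence even).
    """
    if spec.mu1 == spec.mu2:
        raise StatsError("zero effect size: target power unattainable")
    n = 2
    while n <= max_n:
        if two_sample_t_power(n, spec) >= spec.power:
            break
        n += 1
    else:
        raise StatsError(f"power {spec.power} not reached by n = {max_n}")
    n_inflated = math.ceil(n / (1.0 - spec.dropout))
    return n_inflated, 2 * n_inflated


# ---------------------------------------------------------------------------
# cohort-table operations
# ---------------------------------------------------------------------------

def _require_columns(table: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise StatsError(f"measurement table missing columns: {missing}")


def sum_bilateral(table: pd.DataFrame) -> pd.DataFrame:
    """Sum left and right condylar measurements per patient and timepoint.

    Returns one row per patient with summed T0 values and T1 - T0 changes
    for volume and the seven heights, carrying the patient metadata.
    Patients missing a side or a timepoint raise an error naming them.
    """
    _require_columns(table, ("patient_id", "side", "timepoint", "volume")
                     + HEIGHT_COLS)
    bad = []
    for pid, g in table.groupby("patient_id", sort=True):
        for tp in ("T0", "T1"):
            sides = set(g.loc[g.timepoint == tp, "side"])
            if sides != {"left", "right"}:
                bad.append(f"{pid}@{tp}")
    if bad:
        raise StatsError(f"patients missing a side/timepoint: {bad}")
    meta_cols = [c for c in ("group", "gender", "age_band", "diagnosis")
                 if c in table.columns]
    value_cols = ["volume"] + list(HEIGHT_COLS)
    rows = []
    for pid, g in table.groupby("patient_id", sort=True):
        t0 = g[g.timepoint == "T0"][value_cols].sum()
        t1 = g[g.timepoint == "T1"][value_cols].sum()
        row = {"patient_id": pid}
        for c in meta_cols:
            row[c] = g[c].iloc[0]
        row["v_t0"] = t0["volume"]
        row["volume_change"] = t1["volume"] - t0["volume"]
        for c in HEIGHT_COLS:
            row[f"{c}_t0"] = t0[c]
            row[f"{c}_change"] = t1[c] - t0[c]
        for ceph in ("anb", "pn", "me"):
            if ceph in g.columns:
                c0 = g.loc[g.timepoint == "T0", ceph].dropna()
                c1 = g.loc[g.timepoint == "T1", ceph].dropna()
                if len(c0) and len(c1):
                    row[f"{ceph}_change"] = c1.mean() - c0.mean()
        rows.append(row)
    return pd.DataFrame(rows)


def directional_resorption_analysis(table: pd.DataFrame,
                                    variant: str = "pooled") -> dict:
    """Baseline d_io / d_pipo comparison by disc-displacement direction.

    Uses per-joint T0 rows labelled anteromedial or anterolateral; returns
    mean +- sd per group and a two-sided unpaired t test per measure.
    """
    _require_columns(table, ("timepoint", "disc_direction", "d_io", "d_pipo"))
    t0 = table[(table.timepoint == "T0")
               & table.disc_direction.isin(["anteromedial", "anterolateral"])]
    out: dict = {"groups": {}, "tests": {}}
    for direction, g in t0.groupby("disc_direction"):
        if len(g) < 2:
            raise StatsError(f"direction group {direction!r} has n < 2")
        out["groups"][direction] = {
            "n": int(len(g)),
            "d_io": quartiles(g.d_io), "d_pipo": quartiles(g.d_pipo)}
    if len(out["groups"]) < 2:
        raise StatsError("need both anteromedial and anterolateral joints")
    am = t0[t0.disc_direction == "anteromedial"]
    al = t0[t0.disc_direction == "anterolateral"]
    for meas in ("d_io", "d_pipo"):
        out["tests"][meas] = unpaired_t(am[meas].to_numpy(),
                                        al[meas].to_numpy(), variant=variant)
    return out


def directional_displacement_proportion(n_unilateral: int, n_bilateral: int,
                                        n_anteromedial: int,
                                        n_anterolateral: int) -> float:
    """Percent of affected joints whose displacement has a medial or lateral
    component. Unilateral patients contribute one affected joint, bilateral
    patients two."""
    affected = n_unilateral + 2 * n_bilateral
    if affected <= 0:
        raise StatsError("no affected joints")
    return 100.0 * (n_anteromedial + n_anterolateral) / affected
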