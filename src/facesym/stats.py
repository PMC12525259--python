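"""Statistical layer: correlation effect sizes, reliability, and exact power.

Covers the statistics used to relate skeletal PA-cephalometric measurements
to volumetric soft-tissue asymmetry:

* Pearson product–moment correlation with R² = r² and Cohen's effect-size
  classes for R² (very weak < 0.02 ≤ weak < 0.13 ≤ moderate < 0.26 ≤
  substantial);
* Dahlberg's technical error of measurement, TEM = √(Σd²/2n), and the
  reliability coefficient R = 1 − TEM²/σ²;
* the single-measure absolute-agreement intraclass correlation ICC(A,1)
  with Landis–Koch interpretation bands;
* exact sample-size / power computation for testing ρ = 0 under bivariate
  normality, using the exact sampling density of the sample correlation
  coefficient rather than the Fisher-z approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

__all__ = [
    "EFFECT_CLASSES",
    "CorrelationSummary",
    "ReliabilityReport",
    "pearson",
    "cohen_class",
    "dahlberg_tem",
    "reliability_coefficient",
    "icc_absolute_agreement",
    "landis_koch_label",
    "reliability_report",
    "fisher_z_sample_size",
    "exact_correlation_power",
    "correlation_sample_size",
    "correlation_table",
    "r2_matrix",
]

EFFECT_CLASSES = ("very_weak", "weak", "moderate", "substantial")

#: Lower-inclusive R² thresholds of Cohen's classes.
_COHEN_EDGES = ((0.26, "substantial"), (0.13, "moderate"), (0.02, "weak"))

VOLUME_COLUMNS = ("volume_whole", "volume_mid", "volume_lower")


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined (zero variance in an input)."""


@dataclass
class CorrelationSummary:
    """Pearson correlation with its derived effect size."""

    r: float
    r_squared: float
    p_value: float
    effect_class: str
    n: int


@dataclass
class ReliabilityReport:
    """Repeated-measurement reliability summary for one variable."""

    tem: float
    reliability_r: float
    icc: float
    icc_label: str
    n_pairs: int


# ---------------------------------------------------------------------------
# Correlation and effect size
# ---------------------------------------------------------------------------


def cohen_class(r_squared: float) -> str:
    """Cohen's effect-size class of a coefficient of determination.

    Boundaries are lower-inclusive: R² = 0.02 is weak, 0.13 moderate,
    0.26 substantial.
    """
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError(f"R² must lie in [0, 1], got {r_squared}")
    for edge, label in _COHEN_EDGES:
        if r_squared >= edge:
            return label
    return "very_weak"


def pearson(x, y) -> CorrelationSummary:
    """Pearson product–moment correlation with a two-sided t-test p-value.

    The p-value uses t = r√((n−2)/(1−r²)) with n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson needs two equal-length 1-d vectors with n >= 3")
    if np.std(x) < 1e-15 or np.std(y) < 1e-15:
        raise UndefinedCorrelationError("zero variance in an input vector")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    r2 = r * r
    return CorrelationSummary(
        r=r,
        r_squared=r2,
        p_value=float(res.pvalue),
        effect_class=cohen_class(min(r2, 1.0)),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------


def dahlberg_tem(x1, x2) -> float:
    """Dahlberg's technical error of measurement, √(Σ(x1−x2)²/(2n))."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1 or len(x1) < 1:
        raise ValueError("dahlberg_tem needs two equal-length non-empty vectors")
    d = x1 - x2
    return float(np.sqrt(np.sum(d * d) / (2.0 * len(d))))


def reliability_coefficient(tem: float, variance: float) -> float:
    """Coefficient of reliability R = 1 − TEM²/σ²; values near 1 mean the
    measurement error is negligible relative to between-subject variance."""
    if variance <= 0:
        raise ValueError("variance must be positive")
    return 1.0 - tem * tem / variance


def landis_koch_label(icc: float) -> str:
    """Landis–Koch agreement category for an ICC value."""
    if icc < 0.0:
        return "poor"
    if icc <= 0.20:
        return "slight"
    if icc <= 0.40:
        return "fair"
    if icc <= 0.60:
        return "moderate"
    if icc <= 0.80:
        return "substantial"
    return "almost_perfect"


def icc_absolute_agreement(ratings) -> tuple[float, str]:
    """Single-measure absolute-agreement ICC from a two-way model, ICC(A,1).

    ``ratings`` is an n×k table (subjects × sessions, k = 2 for test–retest).
    Uses the McGraw–Wong A,1 form
    ``(MS_R − MS_E) / (MS_R + (k−1) MS_E + k (MS_C − MS_E) / n)``
    from the two-way ANOVA mean squares. An all-identical table has no
    variance to decompose and returns 1 by convention.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("ratings must be an n x k table with n >= 2, k >= 2")
    n, k = X.shape
    grand = X.mean()
    if np.allclose(X, grand):
        return 1.0, landis_koch_label(1.0)
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)
    return float(icc), landis_koch_label(float(icc))


def reliability_report(x1, x2) -> ReliabilityReport:
    """TEM, reliability coefficient, and ICC(A,1) for one repeated variable."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    tem = dahlberg_tem(x1, x2)
    variance = float(np.var(np.concatenate([x1, x2]), ddof=1))
    rel = reliability_coefficient(tem, variance) if variance > 0 else 1.0
    icc, label = icc_absolute_agreement(np.column_stack([x1, x2]))
    return ReliabilityReport(tem=tem, reliability_r=rel, icc=icc,
                             icc_label=label, n_pairs=len(x1))


# ---------------------------------------------------------------------------
# Exact power for a correlation test
# ---------------------------------------------------------------------------


def _log_density_r(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Log of the exact sampling density of the sample correlation coefficient
    for n bivariate-normal observations with population correlation rho
    (hypergeometric-series form)."""
    r = np.asarray(r, dtype=float)
    lg = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        + 0.5 * (n - 1) * np.log1p(-rho * rho)
        + 0.5 * (n - 4) * np.log1p(-r * r)
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
    )
    return lg + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0))


def exact_correlation_power(
    rho_alt: float, n: int, alpha: float = 0.05, two_tailed: bool = True
) -> float:
    """Exact power of the t-test of ρ = 0 at sample size n when the true
    correlation is ``rho_alt``, under bivariate normality.

    The critical value on the r scale comes from the null t distribution;
    power integrates the exact non-null density of r over the rejection
    region by adaptive quadrature (tolerance 1e-6).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < rho_alt < 1:
        raise ValueError("rho_alt must be in (0, 1)")
    tail = alpha / 2 if two_tailed else alpha
    tcrit = sps.t.ppf(1 - tail, n - 2)
    rcrit = tcrit / np.sqrt(n - 2 + tcrit * tcrit)
    f = lambda r: np.exp(_log_density_r(r, rho_alt, n))
    upper, _ = integrate.quad(f, rcrit, 1.0, epsabs=1e-6, epsrel=1e-6, limit=200)
    power = upper
    if two_tailed:
        lower, _ = integrate.quad(f, -1.0, -rcrit, epsabs=1e-6, epsrel=1e-6, limit=200)
        power += lower
    return float(min(power, 1.0))


def correlation_sample_size(
    rho_alt: float,
    alpha: float = 0.05,
    power: float = 0.80,
    two_tailed: bool = True,
    n_max: int = 100_000,
) -> int:
    """Smallest n whose exact test of ρ = 0 reaches the target power.

    For ρ_alt = 0.50, α = 0.05 two-tailed and power 0.80 the exact bivariate
    normal computation yields n = 29 (the Fisher-z approximation gives 30).
    """
    if not 0 < rho_alt < 1 or not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("rho_alt, alpha and power must lie in (0, 1)")
    for n in range(4, n_max + 1):
        if exact_correlation_power(rho_alt, n, alpha, two_tailed) >= power:
            return n
    raise RuntimeError(
        f"target power {power} not attainable within n <= {n_max} for rho = {rho_alt}"
    )


def fisher_z_sample_size(
    rho_alt: float, alpha: float = 0.05, power: float = 0.80, two_tailed: bool = True
) -> int:
    """Fisher-z approximate sample size, for comparison with the exact value."""
    za = sps.norm.ppf(1 - (alpha / 2 if two_tailed else alpha))
    zb = sps.norm.ppf(power)
    return int(np.ceil(((za + zb) / np.arctanh(rho_alt)) ** 2 + 3))


# ---------------------------------------------------------------------------
# Cohort-level correlation table
# ---------------------------------------------------------------------------


def correlation_table(
    cohort: pd.DataFrame,
    measurement_columns: tuple[str, ...] | None = None,
    volume_columns: tuple[str, ...] = VOLUME_COLUMNS,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Correlate every cephalometric column with every regional asymmetry
    volume.

    Returns a tidy table with one row per (variable, region): Pearson r, R²,
    p-value, Cohen class, and the conventional stars ('*' moderate, '**'
    substantial effect). p-values are uncorrected by default, matching common
    practice for exploratory correlation screens; ``bh_correction`` applies
    Benjamini–Hochberg across all cells instead.
    """
    from .ceph import MEASUREMENT_IDS

    if measurement_columns is None:
        measurement_columns = tuple(c for c in MEASUREMENT_IDS if c in cohort.columns)
    missing = [c for c in (*measurement_columns, *volume_columns) if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table is missing columns: {', '.join(missing)}")
    rows = []
    for var in measurement_columns:
        for vol in volume_columns:
            try:
                s = pearson(cohort[var].to_numpy(), cohort[vol].to_numpy())
                cell = dict(
                    r=s.r, r_squared=s.r_squared, p_value=s.p_value,
                    effect_class=s.effect_class,
                    stars={"moderate": "*", "substantial": "**"}.get(s.effect_class, ""),
                    n=s.n,
                )
            except UndefinedCorrelationError:
                # a constant column (e.g. a perfectly symmetric cohort) has no
                # defined correlation; report the cell as undefined, unflagged
                cell = dict(r=np.nan, r_squared=np.nan, p_value=np.nan,
                            effect_class="undefined", stars="", n=len(cohort))
            rows.append(dict(variable=var, region=vol.removeprefix("volume_"), **cell))
    table = pd.DataFrame(rows)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table


def r2_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy correlation table into a variables × regions R² matrix
    with the effect-size stars appended."""
    from .ceph import MEASUREMENT_IDS

    wide = table.pivot(index="variable", columns="region", values="r_squared")
    stars = table.pivot(index="variable", columns="region", values="stars")
    out = wide.round(3).astype(str) + stars
    order = [m for m in MEASUREMENT_IDS if m in out.index]
    order += [m for m in out.index if m not in order]
    cols = [c for c in ("whole", "mid", "lower") if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    return out.loc[order, cols]
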