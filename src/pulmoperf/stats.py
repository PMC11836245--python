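"""Method-comparison statistics for paired perfusion measurements.

Implements the validation battery used to compare a test measurement set
against a reference (accuracy) or against a repeat of itself (precision):
ordinary least squares with 95% CIs, Pearson r, Lin's concordance
correlation coefficient, Bland–Altman limits of agreement, paired t-test,
Shapiro–Wilk normality checks, and the two root-mean-square summaries.

Definitions fixed by this package (both are often left undefined in
applied work): RMSE is the root-mean-square of the residuals about the
fitted regression line, RMSD the root-mean-square of the raw paired
differences y - x. The two coincide as the fit approaches the identity
line.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DataError, DegenerateInputError

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "linear_fit",
    "bland_altman",
    "lin_ccc",
    "rmsd_paired",
    "paired_t",
    "full_report",
]


@dataclass
class PairedMeasurements:
    """Two paired measurement vectors (mL/min/g) with optional pair labels."""

    x: np.ndarray
    y: np.ndarray
    labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise DataError("x and y must be 1D vectors of equal length")
        if self.x.size < 2:
            raise DataError("need at least 2 pairs")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise DataError("measurements must be finite")
        if self.labels is not None and len(self.labels) != self.x.size:
            raise DataError("labels length must match the number of pairs")

    @property
    def n(self) -> int:
        return int(self.x.size)


@dataclass
class AgreementReport:
    """All agreement statistics for one pair of measurement sets."""

    slope: float
    slope_ci: Tuple[float, float]
    intercept: float
    intercept_ci: Tuple[float, float]
    pearson_r: float
    pearson_r_ci: Tuple[float, float]
    lin_ccc: float
    lin_ccc_ci: Tuple[float, float]
    rmse: float
    rmsd: float
    mean_difference: float
    loa_low: float
    loa_high: float
    paired_t_stat: float
    paired_t_p: float
    shapiro_p_x: float
    shapiro_p_y: float
    n: int

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("slope_ci", "intercept_ci", "pearson_r_ci", "lin_ccc_ci"):
            d[k] = list(d[k])
        return d


def _require(pm: PairedMeasurements, n_min: int, what: str) -> None:
    if pm.n < n_min:
        raise DataError(f"{what} requires at least {n_min} pairs, got {pm.n}")


def linear_fit(pm: PairedMeasurements, alpha: float = 0.05):
    """OLS of y on x: (slope, intercept, slope_ci, intercept_ci, rmse).

    CIs use the t distribution with n-2 degrees of freedom; rmse is the
    root-mean-square regression residual.
    """
    _require(pm, 3, "linear_fit")
    if np.var(pm.x) == 0:
        raise DegenerateInputError("x has zero variance; regression is degenerate")
    res = sm.OLS(pm.y, sm.add_constant(pm.x)).fit()
    intercept, slope = res.params
    ci = res.conf_int(alpha=alpha)
    rmse = float(np.sqrt(np.mean(res.resid**2)))
    return (
        float(slope),
        float(intercept),
        (float(ci[1, 0]), float(ci[1, 1])),
        (float(ci[0, 0]), float(ci[0, 1])),
        rmse,
    )


def bland_altman(pm: PairedMeasurements) -> Tuple[float, float, float]:
    """(mean difference, lower LoA, upper LoA); LoA = mean ± 1.96·SD (n-1)."""
    d = pm.y - pm.x
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def _ccc_point(x: np.ndarray, y: np.ndarray) -> float:
    # population (1/n) moments, per Lin's original definition
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    sx2, sy2 = np.var(x), np.var(y)
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise DegenerateInputError("both variances and the mean shift are zero")
    return float(2.0 * sxy / denom)


def lin_ccc(
    pm: PairedMeasurements,
    alpha: float = 0.05,
    *,
    bootstrap: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
) -> Tuple[float, Tuple[float, float]]:
    """Lin's concordance correlation coefficient with a 95% CI.

    ccc = 2·cov(x,y) / (var(x) + var(y) + (mean x − mean y)²), population
    moments. The default CI uses Lin's Fisher-type z transform with his
    asymptotic variance; ``bootstrap=True`` substitutes a seeded percentile
    bootstrap.
    """
    _require(pm, 3, "lin_ccc")
    x, y = pm.x, pm.y
    if np.var(x) == 0 and np.var(y) == 0:
        raise DegenerateInputError("both measurement vectors are constant")
    ccc = _ccc_point(x, y)

    if bootstrap:
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, pm.n, pm.n)
            reps[i] = _ccc_point(x[idx], y[idx])
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        return ccc, (float(lo), float(hi))

    n = pm.n
    if abs(ccc) >= 1.0 - 1e-12:
        # perfect (anti)concordance: the asymptotic variance is undefined
        return ccc, (ccc, ccc)
    r = float(np.corrcoef(x, y)[0, 1])
    sx, sy = np.std(x), np.std(y)
    u = (x.mean() - y.mean()) / np.sqrt(sx * sy)
    # Lin (1989) asymptotic variance of z = atanh(ccc)
    c2 = ccc**2
    var_z = (
        (1 - r**2) * c2 / ((1 - c2) * r**2)
        + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - c2) ** 2)
        - c2**2 * u**4 / (2 * r**2 * (1 - c2) ** 2)
    ) / (n - 2)
    z = np.arctanh(np.clip(ccc, -1 + 1e-15, 1 - 1e-15))
    crit = sps.norm.ppf(1 - alpha / 2)
    half = crit * np.sqrt(max(var_z, 0.0))
    return ccc, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def rmsd_paired(pm: PairedMeasurements) -> float:
    """Root-mean-square paired deviation sqrt(mean (y-x)²)."""
    return float(np.sqrt(np.mean((pm.y - pm.x) ** 2)))


def paired_t(pm: PairedMeasurements) -> Tuple[float, float]:
    """Two-sided paired-sample t-test on y - x: (t statistic, p value)."""
    d = pm.y - pm.x
    if d.std(ddof=1) == 0:
        raise DegenerateInputError("paired differences have zero variance")
    res = sps.ttest_rel(pm.y, pm.x)
    return float(res.statistic), float(res.pvalue)


def _fisher_ci(r: float, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def full_report(pm: PairedMeasurements, alpha: float = 0.05) -> AgreementReport:
    """Assemble the complete agreement battery for one measurement pairing."""
    _require(pm, 3, "full_report")
    slope, intercept, slope_ci, intercept_ci, rmse = linear_fit(pm, alpha)
    mean_d, loa_low, loa_high = bland_altman(pm)
    ccc, ccc_ci = lin_ccc(pm, alpha)
    r = float(np.corrcoef(pm.x, pm.y)[0, 1])
    try:
        t_stat, t_p = paired_t(pm)
    except DegenerateInputError:
        # constant differences (e.g. identical vectors): t is undefined
        t_stat, t_p = float("nan"), float("nan")
    return AgreementReport(
        slope=slope,
        slope_ci=slope_ci,
        intercept=intercept,
        intercept_ci=intercept_ci,
        pearson_r=r,
        pearson_r_ci=_fisher_ci(r, pm.n, alpha),
        lin_ccc=ccc,
        lin_ccc_ci=ccc_ci,
        rmse=rmse,
        rmsd=rmsd_paired(pm),
        mean_difference=mean_d,
        loa_low=loa_low,
        loa_high=loa_high,
        paired_t_stat=t_stat,
        paired_t_p=t_p,
        shapiro_p_x=float(sps.shapiro(pm.x).pvalue),
        shapiro_p_y=float(sps.shapiro(pm.y).pvalue),
        n=pm.n,
    )
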