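"""Descriptive statistics, polynomial trend regression, decadal summaries,
and Pearson correlation matrices for seasonal climate/phenology tables.

Conventions (fixed, survey-style):

* variance and standard deviation use the sample (n−1) denominator;
* skewness is the adjusted Fisher–Pearson coefficient;
* kurtosis is *excess* kurtosis (a normal distribution scores 0).

Polynomial trends ``Y = β₀ + β₁X + β₂X² + … + ε`` default to degree 2 and are
fitted by ordinary least squares (statsmodels under the hood); the reported
p-value is the two-sided overall-F test of the model against the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "DescriptiveStats",
    "PolynomialTrend",
    "PhenologyRecord",
    "describe",
    "fit_polynomial",
    "decadal_summary",
    "pearson_matrix",
]


@dataclass(frozen=True)
class PhenologyRecord:
    """One season's phenology/yield observation."""

    harvest_year: int
    dta: float  # days to anthesis
    dtm: float  # days to maturity
    grain_yield: float  # t/ha

    def __post_init__(self):
        if not 0 < self.dta < self.dtm:
            raise ValueError(
                f"{self.harvest_year}: need 0 < DTA < DTM, got {self.dta}/{self.dtm}"
            )
        if self.grain_yield < 0:
            raise ValueError(f"{self.harvest_year}: negative yield")


@dataclass(frozen=True)
class DescriptiveStats:
    n: int
    range: float
    minimum: float
    maximum: float
    mean: float
    sd: float
    variance: float
    skewness: float
    kurtosis: float

    def to_dict(self) -> dict:
        return {
            "n": self.n, "range": self.range, "minimum": self.minimum,
            "maximum": self.maximum, "mean": self.mean, "sd": self.sd,
            "variance": self.variance, "skewness": self.skewness,
            "kurtosis": self.kurtosis,
        }


def describe(values, strict: bool = True) -> DescriptiveStats:
    """Eight-column descriptive summary of a numeric vector.

    With ``strict`` (default) a zero-variance vector raises, since the
    skewness/kurtosis of a constant are undefined; otherwise they are
    reported as 0 with sd = 0.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("describe needs a 1-D vector with n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values present")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        if strict:
            raise ValueError("zero-variance vector (constant input)")
        skew = kurt = 0.0
    else:
        skew = float(scipy.stats.skew(x, bias=False))
        kurt = float(scipy.stats.kurtosis(x, fisher=True, bias=False))
    return DescriptiveStats(
        n=len(x),
        range=float(x.max() - x.min()),
        minimum=float(x.min()),
        maximum=float(x.max()),
        mean=float(x.mean()),
        sd=sd,
        variance=sd**2,
        skewness=skew,
        kurtosis=kurt,
    )


class PolynomialTrend:
    """Fitted polynomial trend with OLS coefficients and diagnostics.

    Attributes
    ----------
    coefficients : ndarray, β₀..βₙ (ascending powers)
    r_squared : float
    p_value : float, overall model F-test
    residual_sd : float, √(SSE / (n − degree − 1))
    """

    def __init__(self, degree: int, results: sm.regression.linear_model.RegressionResults):
        self.degree = degree
        self._results = results
        self.coefficients = np.asarray(results.params)
        self.r_squared = float(results.rsquared)
        self.p_value = float(results.f_pvalue)
        self.residual_sd = float(np.sqrt(results.scale))
        self.nobs = int(results.nobs)

    @property
    def slope(self) -> float:
        """β₁ — the linear coefficient (the trend rate for degree-1 fits)."""
        return float(self.coefficients[1])

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(b * x**k for k, b in enumerate(self.coefficients))

    def residuals(self) -> np.ndarray:
        return np.asarray(self._results.resid)

    def summary(self):
        """Full statsmodels regression summary table."""
        return self._results.summary()

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "coefficients": self.coefficients.tolist(),
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "residual_sd": self.residual_sd,
            "n": self.nobs,
        }

    def __repr__(self):
        terms = " + ".join(
            f"{b:.4g}·x^{k}" if k else f"{b:.4g}"
            for k, b in enumerate(self.coefficients)
        )
        return f"<PolynomialTrend degree={self.degree}: y = {terms}, R²={self.r_squared:.3f}>"


def fit_polynomial(x, y, degree: int = 2) -> PolynomialTrend:
    """Least-squares polynomial trend of *y* on *x*.

    Raises on rank deficiency (e.g. all x identical) and when there are not
    enough points to leave a residual degree of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) <= degree + 1:
        raise ValueError(
            f"need n > degree + 1 points for a degree-{degree} fit, got {len(x)}"
        )
    design = np.vander(x, degree + 1, increasing=True)
    if np.linalg.matrix_rank(design) < degree + 1:
        raise ValueError(
            f"rank-deficient design: x has fewer than {degree + 1} distinct "
            "support points"
        )
    results = sm.OLS(y, design).fit()
    return PolynomialTrend(degree, results)


def decadal_summary(
    years, values, decades: list[tuple[int, int]]
) -> pd.DataFrame:
    """Per-decade min/max/mean of an annual series.

    *decades* is a list of inclusive (start_year, end_year) tuples, e.g.
    ``[(1980, 1990), (1991, 2000), (2001, 2010), (2011, 2020)]``.  A decade
    with no data is kept in the output flagged ``empty=True`` rather than
    silently dropped.
    """
    years = np.asarray(years, dtype=int)
    values = np.asarray(values, dtype=float)
    if years.shape != values.shape:
        raise ValueError("years and values must be equal length")
    rows = []
    for start, end in decades:
        mask = (years >= start) & (years <= end)
        label = f"{start}–{end}"
        if not mask.any():
            rows.append(
                {"decade": label, "minimum": np.nan, "maximum": np.nan,
                 "mean": np.nan, "range": "", "n": 0, "empty": True}
            )
            continue
        sub = values[mask]
        lo, hi = float(sub.min()), float(sub.max())
        rows.append(
            {
                "decade": label,
                "minimum": lo,
                "maximum": hi,
                "mean": float(sub.mean()),
                "range": f"{_fmt(lo)}–{_fmt(hi)}",
                "n": int(mask.sum()),
                "empty": False,
            }
        )
    return pd.DataFrame(rows)


def _fmt(v: float) -> str:
    return f"{v:.0f}" if float(v).is_integer() else f"{v:g}"


def pearson_matrix(columns: pd.DataFrame | dict) -> pd.DataFrame:
    """Full symmetric matrix of pairwise Pearson correlations.

    Raises on a zero-variance column, naming it.
    """
    df = pd.DataFrame(columns)
    if len(df) < 3:
        raise ValueError("need n >= 3 rows for correlation")
    if df.isna().any().any() or not np.all(np.isfinite(df.to_numpy(dtype=float))):
        raise ValueError("non-finite values present")
    stds = df.std(ddof=1)
    zero = stds.index[stds == 0].tolist()
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    return df.corr(method="pearson")
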