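"""Reduced-major-axis allometry, prediction intervals and group comparisons.

All fits are on log10-transformed data, the standard scale for comparative
allometry of skeletal dimensions. The reduced major axis (RMA, also called
standardized major axis) slope is sign(r) * sd(log y) / sd(log x), symmetric
in x and y up to inversion. A fossil individual's position relative to a
comparative group is scored two ways:

* in SEE units — its vertical log-scale residual from the group's RMA line
  divided by the fit's standard error of estimate; and
* against a 95% prediction interval with halfwidth

      t_{alpha(2), n-2} * sqrt( 2 * SEE^2 * [1 + 1/n + (xi - xbar)^2 / ssx] ) * |b|

  where ssx is the corrected sum of squares of log x. The sqrt(2) and |b|
  factors widen the usual regression prediction limit to account for the
  symmetric error structure assumed by RMA.

Elevation (intercept) differences between groups are tested with the
nonparametric Quick Test: classify every point of both groups as above or
below a pooled RMA line and apply Fisher's exact test to the resulting
group x side table. Slope differences use a seeded permutation test on the
absolute RMA slope difference under group-label shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AllometryError",
    "BivariateSample",
    "RMAFit",
    "QuickTestResult",
    "SlopeTestResult",
    "rma_fit",
    "prediction_interval",
    "pi_halfwidth",
    "see_units_deviation",
    "quick_test",
    "slope_equality_test",
]


class AllometryError(ValueError):
    """Raised on degenerate or invalid bivariate input."""


@dataclass
class BivariateSample:
    """A labelled group of paired positive measurements.

    If ``pre_logged`` is False (default), x and y are raw measurements and
    are log10-transformed by the fitting routines; all values must then be
    strictly positive. If True, x and y are taken to be already in log10
    units.
    """

    label: str
    x: np.ndarray
    y: np.ndarray
    log_base: float = 10.0
    pre_logged: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise AllometryError("x and y must be paired 1-D arrays")
        if self.x.size < 3:
            raise AllometryError(f"need at least 3 pairs, got {self.x.size}")
        if self.log_base != 10.0:
            raise AllometryError("only base-10 logs are supported")
        if not self.pre_logged and (np.any(self.x <= 0) or np.any(self.y <= 0)):
            raise AllometryError("raw measurements must be > 0 before log transform")

    @property
    def n(self) -> int:
        return int(self.x.size)

    def logged(self) -> tuple[np.ndarray, np.ndarray]:
        if self.pre_logged:
            return self.x, self.y
        return np.log10(self.x), np.log10(self.y)


@dataclass
class RMAFit:
    """A reduced-major-axis fit on the log10 scale."""

    label: str
    slope: float
    intercept: float
    r: float
    see: float
    n: int
    xbar: float
    ssx: float

    @property
    def df(self) -> int:
        return self.n - 2

    @property
    def pct_see(self) -> float:
        """%SEE = (10^SEE - 1) * 100, the SEE re-expressed as a percent."""
        return (10.0**self.see - 1.0) * 100.0

    def predict(self, xi):
        return self.intercept + self.slope * np.asarray(xi, dtype=float)


def rma_fit(sample: BivariateSample) -> RMAFit:
    """Fit a reduced major axis line to a bivariate sample on log10 scale.

    slope = sign(r) * sd(log y) / sd(log x); the intercept passes the line
    through the bivariate mean. SEE is the standard error of estimate of the
    vertical (y-direction) residuals about the RMA line with n - 2 degrees
    of freedom.
    """
    lx, ly = sample.logged()
    n = sample.n
    sx = lx.std(ddof=1)
    sy = ly.std(ddof=1)
    if sx == 0 or sy == 0:
        raise AllometryError(f"zero variance in group {sample.label!r}")
    r = float(np.corrcoef(lx, ly)[0, 1])
    slope = (sy / sx) * (1.0 if r >= 0 else -1.0)
    intercept = float(ly.mean() - slope * lx.mean())
    resid = ly - (intercept + slope * lx)
    see = float(np.sqrt((resid**2).sum() / (n - 2)))
    return RMAFit(
        label=sample.label,
        slope=float(slope),
        intercept=intercept,
        r=r,
        see=see,
        n=n,
        xbar=float(lx.mean()),
        ssx=float(((lx - lx.mean()) ** 2).sum()),
    )


def pi_halfwidth(fit: RMAFit, xi, alpha: float = 0.05):
    """Halfwidth of the prediction band at evaluation point(s) xi (log10)."""
    if not 0.0 < alpha < 1.0:
        raise AllometryError("alpha must lie in (0, 1)")
    if fit.df < 1:
        raise AllometryError("fit has no residual degrees of freedom")
    xi = np.asarray(xi, dtype=float)
    t = stats.t.ppf(1.0 - alpha / 2.0, fit.df)
    bracket = 1.0 + 1.0 / fit.n + (xi - fit.xbar) ** 2 / fit.ssx
    return t * np.sqrt(2.0 * fit.see**2 * bracket) * abs(fit.slope)


def prediction_interval(fit: RMAFit, xi, alpha: float = 0.05):
    """(lower, upper) prediction limits on the log10 scale at xi."""
    center = fit.predict(xi)
    hw = pi_halfwidth(fit, xi, alpha)
    return center - hw, center + hw


def see_units_deviation(fit: RMAFit, xi: float, yi: float) -> float:
    """Vertical deviation of a point from the RMA line, in SEE units.

    Positive above the line. xi and yi are log10 values.
    """
    if fit.see == 0:
        raise AllometryError("degenerate fit: SEE = 0, deviations undefined")
    return float((yi - fit.predict(xi)) / fit.see)


@dataclass
class QuickTestResult:
    """Outcome of the Quick Test for an elevation difference."""

    p_value: float
    table: np.ndarray  # rows: groups (a, b); cols: (above, below)
    n_excluded: int = 0
    pooled_fit: RMAFit | None = field(default=None, repr=False)


def quick_test(sample_a: BivariateSample, sample_b: BivariateSample) -> QuickTestResult:
    """Nonparametric test for an elevation difference between two groups.

    Fits a single RMA line to the pooled data, classifies every point of
    each group as above or below that line, and applies Fisher's exact test
    (two-sided) to the 2x2 group x side table. Points falling exactly on the
    pooled line (a floating-point tie) are excluded and counted in
    ``n_excluded``.
    """
    lx_a, ly_a = sample_a.logged()
    lx_b, ly_b = sample_b.logged()
    pooled = BivariateSample(
        label=f"{sample_a.label}+{sample_b.label}",
        x=np.concatenate([lx_a, lx_b]),
        y=np.concatenate([ly_a, ly_b]),
        pre_logged=True,
    )
    fit = rma_fit(pooled)
    table = np.zeros((2, 2), dtype=int)
    excluded = 0
    for i, (lx, ly) in enumerate([(lx_a, ly_a), (lx_b, ly_b)]):
        resid = ly - fit.predict(lx)
        table[i, 0] = int((resid > 0).sum())
        table[i, 1] = int((resid < 0).sum())
        excluded += int((resid == 0).sum())
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return QuickTestResult(p_value=p, table=table, n_excluded=excluded, pooled_fit=fit)


def _rma_slopes(lx: np.ndarray, ly: np.ndarray) -> float:
    sx = lx.std(ddof=1)
    sy = ly.std(ddof=1)
    r = np.corrcoef(lx, ly)[0, 1]
    return (sy / sx) * (1.0 if r >= 0 else -1.0)


@dataclass
class SlopeTestResult:
    p_value: float
    observed_diff: float
    n_perm: int


def slope_equality_test(
    sample_a: BivariateSample,
    sample_b: BivariateSample,
    n_perm: int = 999,
    seed: int | None = None,
) -> SlopeTestResult:
    """Permutation test for equality of RMA slopes between two groups.

    The statistic is |b_a - b_b|. Group labels are shuffled ``n_perm`` times
    (preserving group sizes) with a seeded generator, and the p-value uses
    the add-one estimator (observed arrangement counted among the
    permutations), which is exact-valid under exchangeability.
    """
    if n_perm < 100:
        raise AllometryError("n_perm must be at least 100")
    if sample_a.n < 3 or sample_b.n < 3:
        raise AllometryError("each group needs at least 3 pairs")
    lx_a, ly_a = sample_a.logged()
    lx_b, ly_b = sample_b.logged()
    obs = abs(_rma_slopes(lx_a, ly_a) - _rma_slopes(lx_b, ly_b))
    lx = np.concatenate([lx_a, lx_b])
    ly = np.concatenate([ly_a, ly_b])
    n_a = sample_a.n
    n_tot = lx.size
    rng = np.random.default_rng(seed)

    # vectorized permutation fits: (n_perm, n) index matrix
    idx = np.argsort(rng.random((n_perm, n_tot)), axis=1)
    px = lx[idx]
    py = ly[idx]
    b_a = _batch_rma_slope(px[:, :n_a], py[:, :n_a])
    b_b = _batch_rma_slope(px[:, n_a:], py[:, n_a:])
    count = int((np.abs(b_a - b_b) >= obs - 1e-12).sum())
    p = (1 + count) / (n_perm + 1)
    return SlopeTestResult(p_value=float(p), observed_diff=float(obs), n_perm=n_perm)


def _batch_rma_slope(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """RMA slopes row-wise for a (n_perm, n) batch of permuted groups."""
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    dx = x - xm
    dy = y - ym
    sxx = (dx * dx).sum(axis=1)
    syy = (dy * dy).sum(axis=1)
    sxy = (dx * dy).sum(axis=1)
    slope = np.sqrt(syy / sxx)
    return np.where(sxy >= 0, slope, -slope)
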