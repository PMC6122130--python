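"""Statistical layer: robust polynomial fits with a nested F-test,
repeated-measures Wilks' Lambda, linear trend contrasts, Bonferroni.

The linear-vs-cubic model selection for FA-vs-AFD profiles compares residual
sums of squares of nested polynomial fits:

    F = ((SS_small - SS_big) / (df_small - df_big)) / (SS_big / df_big)

on an F(df_small - df_big, df_big) distribution; a significant F prefers the
cubic (S-shaped) model.  Robust fits use iteratively reweighted least
squares with the Tukey bisquare function (c = 4.685, MAD scale); for the
nested test on robust fits the final robust weights are frozen and shared by
both models so the two SS values are comparable.

The repeated-measures test for a single within-subject factor with k levels
forms k-1 difference contrasts per subject, computes Hotelling's T^2 on the
contrast means, and converts

    Lambda = 1 / (1 + T^2/(n-1)),    F = ((n-k+1)/(k-1)) * (1-Lambda)/Lambda

with (k-1, n-k+1) degrees of freedom (exact for one factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class FitResult:
    degree: int
    coefficients: np.ndarray  # ascending powers
    ss: float  # (weighted) residual sum of squares
    df: int  # n - (degree + 1)
    n: int
    weights: np.ndarray  # robust weights (ones for OLS)
    ss_unweighted: float  # plain residual sum of squares at the same coefficients

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), self.coefficients)


@dataclass
class FitComparisonResult:
    F: float
    df_num: int
    df_den: int
    p_value: float
    preferred: str  # "linear" | "cubic"


@dataclass
class RMAnovaResult:
    wilks_lambda: float
    F: float
    hypothesis_df: float
    error_df: float
    p_value: float


def fit_polynomial_robust(
    x: np.ndarray, y: np.ndarray, degree: int, robust: bool = True
) -> FitResult:
    """Polynomial fit of given degree; Tukey-bisquare IRLS when robust.

    Robust estimation delegates to statsmodels RLM (TukeyBiweight c = 4.685,
    MAD scale, coefficient tolerance 1e-8, <= 50 iterations); ``robust=False``
    is ordinary least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise StatsError("x and y must be matching 1-D vectors")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise StatsError("x and y must be finite")
    n = len(x)
    if n <= degree + 1:
        raise StatsError(f"need more than {degree + 1} points for degree {degree}")
    if np.ptp(x) == 0:
        raise StatsError("degenerate x: all values equal")
    X = np.vander(x, degree + 1, increasing=True)
    if robust:
        import statsmodels.api as sm

        model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
        res = model.fit(maxiter=50, tol=1e-8, scale_est="mad")
        coef = res.params
        w = np.asarray(res.weights, dtype=float)
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        w = np.ones(n)
    resid = y - X @ coef
    return FitResult(
        degree=degree,
        coefficients=coef,
        ss=float(np.sum(w * resid**2)),
        df=n - (degree + 1),
        n=n,
        weights=w,
        ss_unweighted=float(np.sum(resid**2)),
    )


def refit_with_weights(x, y, degree: int, weights: np.ndarray) -> FitResult:
    """Weighted LS fit with frozen weights (for comparable nested SS)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    X = np.vander(x, degree + 1, increasing=True)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ coef
    return FitResult(
        degree=degree,
        coefficients=coef,
        ss=float(np.sum(w * resid**2)),
        df=len(x) - (degree + 1),
        n=len(x),
        weights=w,
        ss_unweighted=float(np.sum(resid**2)),
    )


def nested_f_test(small: FitResult, big: FitResult, alpha: float = 0.05) -> FitComparisonResult:
    """Extra-sum-of-squares F-test of the small (linear) vs big (cubic) model."""
    if small.n != big.n:
        raise StatsError("nested models must be fit on the same data")
    if small.df <= big.df:
        raise StatsError("the small model must have more residual df")
    df_num = small.df - big.df
    df_den = big.df
    if big.ss == 0:
        return FitComparisonResult(F=np.inf, df_num=df_num, df_den=df_den, p_value=0.0, preferred="cubic")
    F = ((small.ss - big.ss) / df_num) / (big.ss / df_den)
    if F < 0:  # possible only with robust weighting quirks; clamp and flag
        F = 0.0
    p = float(sps.f.sf(F, df_num, df_den))
    return FitComparisonResult(
        F=float(F),
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        preferred="cubic" if p < alpha else "linear",
    )


def compare_linear_cubic(
    x, y, alpha: float = 0.05, robust: bool = True
) -> tuple[FitResult, FitResult, FitComparisonResult]:
    """Fit both models and run the nested test.

    In robust mode the cubic fit's converged weights are frozen and both
    models are refit under them, so the two SS are measured on the same
    weighted data.
    """
    big = fit_polynomial_robust(x, y, 3, robust=robust)
    if robust:
        big = refit_with_weights(x, y, 3, big.weights)
        small = refit_with_weights(x, y, 1, big.weights)
    else:
        small = fit_polynomial_robust(x, y, 1, robust=False)
    return small, big, nested_f_test(small, big, alpha)


def wilks_lambda_repeated(data: np.ndarray) -> RMAnovaResult:
    """Single within-subject factor repeated-measures test (n subjects x k levels)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise StatsError("data must be an n x k matrix")
    n, k = data.shape
    if k < 2 or n <= k - 1:
        raise StatsError("need k >= 2 levels and n > k - 1 subjects")
    C = (np.eye(k)[:-1] - np.eye(k)[1:]).T  # successive-difference contrasts, k x (k-1)
    d = data @ C  # n x (k-1)
    if np.allclose(d, 0.0):
        return RMAnovaResult(wilks_lambda=1.0, F=0.0, hypothesis_df=k - 1, error_df=n - k + 1, p_value=1.0)
    dbar = d.mean(axis=0)
    S = np.atleast_2d(np.cov(d, rowvar=False, ddof=1))
    try:
        t2 = float(n * dbar @ np.linalg.solve(S, dbar))
    except np.linalg.LinAlgError as exc:
        raise StatsError("singular contrast covariance; reduce the number of levels") from exc
    lam = 1.0 / (1.0 + t2 / (n - 1))
    df1, df2 = k - 1, n - k + 1
    F = (df2 / df1) * (1 - lam) / lam
    p = float(sps.f.sf(F, df1, df2))
    return RMAnovaResult(wilks_lambda=lam, F=F, hypothesis_df=df1, error_df=df2, p_value=p)


def linear_trend_test(data: np.ndarray, level_scores: np.ndarray) -> tuple[float, float]:
    """Per-subject linear contrast across levels; returns (F, two-sided p)."""
    data = np.asarray(data, dtype=float)
    scores = np.asarray(level_scores, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(scores):
        raise StatsError("data must be n x k matching level_scores")
    if np.ptp(scores) == 0:
        raise StatsError("level scores must not all be equal")
    w = scores - scores.mean()
    c = data @ w
    if np.allclose(c - c.mean(), 0.0):
        if np.allclose(c, 0.0):
            return 0.0, 1.0
        return np.inf, 0.0  # perfect noiseless trend
    t, p = sps.ttest_1samp(c, 0.0)
    return float(t**2), float(p)


def bonferroni(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise StatsError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)
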