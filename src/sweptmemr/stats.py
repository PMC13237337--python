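"""Repeatability and association statistics for MEMR features.

Repeatability across repeated tests uses the intraclass correlation of
consistency for average measures, ICC(C,k): from the two-way
subjects × tests ANOVA, (MS_rows − MS_error)/MS_rows.  Associations with
behavioral scores use robust linear regression (iteratively reweighted
least squares with Tukey bisquare weights, tuning constant 4.685, scale
from the MAD); a slope whose 95% CI excludes zero suggests a relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["RegressionResult", "icc_c_k", "robust_slope"]


@dataclass
class RegressionResult:
    """Robust straight-line fit summary."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    r_squared: float
    weights: np.ndarray
    converged: bool

    @property
    def ci_excludes_zero(self) -> bool:
        return self.slope_ci[0] > 0.0 or self.slope_ci[1] < 0.0


def icc_c_k(table) -> float:
    """ICC type C-k: two-way consistency for the average of k measurements.

    ``table`` is subjects x repeated tests with no missing cells.  Column
    (test) main effects are removed by the consistency definition, so
    adding a fixed offset to any test leaves the ICC unchanged.  Returns
    (MS_rows − MS_error)/MS_rows; degenerate tables with zero
    between-subject mean square yield a non-positive defined value
    (−inf, or 1.0 for a perfectly constant table).
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 repeated tests")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not allowed")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_rows = k * np.sum((row_means - grand) ** 2) / (n - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ms_error = np.sum(resid**2) / ((n - 1) * (k - 1))
    if ms_rows == 0.0:
        return 1.0 if ms_error == 0.0 else float("-inf")
    return float((ms_rows - ms_error) / ms_rows)


def robust_slope(
    x,
    y,
    ci_level: float = 0.95,
    tuning_constant: float = 4.685,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> RegressionResult:
    """Bisquare-reweighted straight-line regression of y on x.

    IRLS with Tukey's bisquare, scale estimated by the MAD, iterated to
    weight convergence.  The slope CI comes from the asymptotic robust
    covariance; R² is computed from the final weighted sums of squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    exog = sm.add_constant(x)
    model = sm.RLM(y, exog, M=sm.robust.norms.TukeyBiweight(c=tuning_constant))
    res = model.fit(scale_est="mad", conv="weights", maxiter=max_iter, tol=tol)
    # an (effectively) exact fit drives the MAD scale to 0 and the weight
    # criterion never fires; that is convergence, not failure
    exact = res.scale <= 1e-12 * max(np.std(y), 1.0)
    converged = exact or len(res.fit_history["params"]) < max_iter
    ci = res.conf_int(alpha=1.0 - ci_level)[1]
    w = np.asarray(res.weights, dtype=float)
    resid = y - res.fittedvalues
    y_bar = np.sum(w * y) / np.sum(w)
    ss_res = np.sum(w * resid**2)
    ss_tot = np.sum(w * (y - y_bar) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_ci=(float(ci[0]), float(ci[1])),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        weights=w,
        converged=bool(converged),
    )
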