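"""Moving-window regression of richness on mean range size.

Time-slices are grouped into overlapping windows of 5 consecutive
slices (5000 years) advancing by one slice.  Within a window, every
(iteration, slice) pair with a defined mean range contributes one point
— 5 slices × 100 iterations = 500 points for a complete window.  An
ordinary least-squares regression of richness (response) on mean range
size (predictor) is fitted per window; uncertainty is propagated by
posterior simulation of the coefficients (draw a scaled-inverse-χ²
residual variance, then coefficients from the corresponding normal).
The window's relationship sign is classified from the Spearman rank
correlation: positive if R > 0.2, negative if R < −0.2, otherwise
indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig


class SingularFitError(ValueError):
    """Constant predictor: the OLS normal equations are singular."""


class UndefinedCorrelationError(ValueError):
    """Constant variable: rank correlation undefined."""


class EmptyWindowError(ValueError):
    """A window with no usable points."""


@dataclass(frozen=True)
class Window:
    """A block of consecutive slice indices with its age-span label."""

    slices: tuple[int, ...]

    @property
    def label(self) -> str:
        # slices are labelled by their old-age bound in ka; a window of
        # slices 19..23 spans 23–19 ka in that labelling
        return f"{max(self.slices)}–{min(self.slices)}ka"


def make_windows(n_slices: int, width: int = 5, step: int = 1) -> list[Window]:
    """Ordered list of ``n_slices − width + 1`` step-advancing windows."""
    if width > n_slices:
        raise ValueError(f"window width {width} exceeds {n_slices} slices")
    if width < 1 or step < 1:
        raise ValueError("width and step must be positive")
    return [Window(tuple(range(s, s + width)))
            for s in range(1, n_slices - width + 2, step)]


def window_points(
    summaries: pd.DataFrame,
    window: Window,
    metric: str = "mean_range_aoo",
) -> tuple[np.ndarray, np.ndarray]:
    """(range, richness) points of a window: one per (iteration, slice).

    Rows with an undefined mean range (empty slices) contribute nothing.
    """
    sub = summaries[summaries["slice_index"].isin(window.slices)]
    sub = sub[np.isfinite(sub[metric])]
    if sub.empty:
        raise EmptyWindowError(f"window {window.label} has no usable points")
    return sub[metric].to_numpy(float), sub["richness"].to_numpy(float)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    sigma: float
    cov: np.ndarray          # 2×2 coefficient covariance (intercept, slope)
    r_squared: float
    n: int
    xtx_inv: np.ndarray = field(repr=False, default=None)


def fit_linear(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """Ordinary least squares of y on x with an intercept.

    σ̂² = RSS/(n−2); coefficient covariance σ̂²(XᵀX)⁻¹.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise SingularFitError("constant predictor")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - 2)
    xtx_inv = np.linalg.inv(X.T @ X)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return LinearFit(float(beta[1]), float(beta[0]), float(np.sqrt(sigma2)),
                     sigma2 * xtx_inv, r2, n, xtx_inv)


def posterior_sim(
    fit: LinearFit, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Posterior slope draws for an OLS fit.

    Per draw: σ² = σ̂²·(n−2)/χ²ₙ₋₂, then coefficients from
    Normal(β̂, σ²(XᵀX)⁻¹); the slope components are returned.  A perfect
    fit (σ̂ = 0) degenerates to the point mass at β̂₁.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    if fit.sigma == 0:
        return np.full(n_draws, fit.slope)
    dof = fit.n - 2
    sigma2 = fit.sigma ** 2 * dof / rng.chisquare(dof, n_draws)
    chol = np.linalg.cholesky(fit.xtx_inv)
    z = rng.standard_normal((n_draws, 2))
    draws = np.array([fit.intercept, fit.slope]) + np.sqrt(sigma2)[:, None] * (z @ chol.T)
    return draws[:, 1]


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with average ranks and a t-based p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant variable")
    r, p = stats.spearmanr(x, y)
    if abs(r) == 1.0:
        p = 0.0
    return float(r), float(p)


def classify_relationship(r: float, threshold: float = 0.2) -> str:
    """Sign class of a richness/range correlation: strict |R| > threshold."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation outside [-1, 1]")
    if r > threshold:
        return "positive"
    if r < -threshold:
        return "negative"
    return "indeterminate"


@dataclass
class WindowResult:
    window: Window
    n: int
    slope: float
    intercept: float
    sigma: float
    r_squared: float
    spearman_r: float
    spearman_p: float
    sign_class: str
    slope_draws: np.ndarray = field(repr=False, default=None)

    @property
    def label(self) -> str:
        return self.window.label


def analyze_windows(
    summaries: pd.DataFrame,
    cfg: RunConfig,
    metric: str = "mean_range_aoo",
    n_draws: int = 100,
    rng: np.random.Generator | None = None,
) -> list[WindowResult]:
    """Fit, simulate and classify every moving window of a summary frame."""
    rng = rng or np.random.default_rng(cfg.rng_seed)
    results = []
    for window in make_windows(cfg.n_slices, cfg.window_width_slices,
                               cfg.window_step_slices):
        x, y = window_points(summaries, window, metric)
        fit = fit_linear(x, y)
        draws = posterior_sim(fit, n_draws, rng)
        r, p = spearman(x, y)
        results.append(WindowResult(
            window, fit.n, fit.slope, fit.intercept, fit.sigma, fit.r_squared,
            r, p, classify_relationship(r, cfg.r_class_threshold), draws,
        ))
    return results


def window_results_frame(results: list[WindowResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "window": w.label, "n": w.n, "slope": w.slope,
        "intercept": w.intercept, "sigma": w.sigma, "r_squared": w.r_squared,
        "spearman_r": w.spearman_r, "spearman_p": w.spearman_p,
        "sign_class": w.sign_class,
    } for w in results])


def window_iteration_classes(
    summaries: pd.DataFrame,
    cfg: RunConfig,
    metric: str = "mean_range_aoo",
) -> pd.DataFrame:
    """Per-(window, iteration) Spearman R and sign class.

    Each resampling iteration contributes its own 5 slice points per
    window; units whose correlation is undefined (constant values, too
    few points) are classed indeterminate.
    """
    windows = make_windows(cfg.n_slices, cfg.window_width_slices,
                           cfg.window_step_slices)
    rows = []
    for window in windows:
        sub = summaries[summaries["slice_index"].isin(window.slices)]
        sub = sub[np.isfinite(sub[metric])]
        for iteration, grp in sub.groupby("iteration"):
            x = grp[metric].to_numpy(float)
            y = grp["richness"].to_numpy(float)
            try:
                r, _ = spearman(x, y)
                cls = classify_relationship(r, cfg.r_class_threshold)
            except (ValueError, UndefinedCorrelationError):
                r, cls = np.nan, "indeterminate"
            rows.append((window.label, int(iteration), r, cls))
    return pd.DataFrame(rows, columns=["window", "iteration", "spearman_r",
                                       "sign_class"])
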