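"""Growth-form abundances and the interaction (binomial GLM) analysis.

Cushion-plant relative abundance proxies facilitation-dominated
environments; tree relative abundance proxies competition-dominated
ones.  Abundance of a group in a unit is its read-count share (percent)
of all reads in that unit.  The analysis fits two logistic regressions
with the per-(window, iteration) richness/range relationship sign as
the binary response (1 = positive, 0 = negative; indeterminate units
excluded) and, respectively, cushion and tree percentage as the
predictor.  The predictor per window-iteration unit is the median of
the member slices' percentages within that iteration.

The logistic fit is a hand-rolled maximum-likelihood Newton/IRLS with
step-halving (so the log-likelihood is non-decreasing); complete
separation is detected and surfaced as an error rather than silently
regularised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import TraitTable
from .rarefy import ResampleSet
from .windows import make_windows


class SeparationError(ValueError):
    """Complete separation: the MLE diverges.

    ``direction`` is +1 when the positive class sits at higher predictor
    values (the likelihood is maximised as slope → +∞), −1 otherwise.
    """

    def __init__(self, message: str, direction: int = 0) -> None:
        super().__init__(message)
        self.direction = direction


class DegenerateResponseError(ValueError):
    """Response contains a single class."""


class ConvergenceError(RuntimeError):
    pass


def group_abundance_series(
    rs: ResampleSet,
    traits: TraitTable,
    incidence: bool = False,
) -> pd.DataFrame:
    """Percent abundance of cushion and tree groups per (iteration, slice).

    By default abundance is the read-count share; ``incidence=True``
    switches to the share of taxon occurrences (presence records).
    """
    groups = traits.groups_for(list(rs.taxon_ids), list(rs.families))
    cushion = groups == "cushion"
    tree = groups == "tree"
    data = (rs.counts > 0) if incidence else rs.counts
    slice_vals = sorted(rs.samples["slice_index"].unique())
    sample_slice = rs.samples["slice_index"].to_numpy()
    rows = []
    for t in slice_vals:
        sel = sample_slice == t
        by_taxon = data[:, sel, :].sum(axis=1).astype(float)        # (iter, taxon)
        total = by_taxon.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c_pct = np.where(total > 0, 100.0 * by_taxon[:, cushion].sum(axis=1) / total, np.nan)
            t_pct = np.where(total > 0, 100.0 * by_taxon[:, tree].sum(axis=1) / total, np.nan)
        for i in range(rs.n_iterations):
            rows.append((i + 1, t, c_pct[i], t_pct[i]))
    return pd.DataFrame(rows, columns=["iteration", "slice_index",
                                       "cushion_pct", "tree_pct"])


def window_group_medians(
    series: pd.DataFrame, cfg: RunConfig
) -> pd.DataFrame:
    """Median group percentages over each window's member slices, per iteration."""
    rows = []
    for w in make_windows(cfg.n_slices, cfg.window_width_slices,
                          cfg.window_step_slices):
        sub = series[series["slice_index"].isin(w.slices)]
        med = sub.groupby("iteration")[["cushion_pct", "tree_pct"]].median()
        for iteration, r in med.iterrows():
            rows.append((w.label, int(iteration), r["cushion_pct"], r["tree_pct"]))
    return pd.DataFrame(rows, columns=["window", "iteration",
                                       "cushion_pct", "tree_pct"])


@dataclass(frozen=True)
class LogisticFit:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    converged: bool
    n_iter: int
    log_likelihood: float
    n: int


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe Bernoulli log-likelihood with logit link
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_irls(
    y: np.ndarray,
    x: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic regression of y on x with an intercept.

    Newton/IRLS with step-halving; convergence when the largest
    coefficient update falls below ``tol``.  Raises
    :class:`SeparationError` on complete separation and
    :class:`DegenerateResponseError` for a single-class response.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateResponseError("response contains a single class")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    if max(x[y == 0]) < min(x[y == 1]):
        raise SeparationError(
            "complete separation: classes split by predictor", direction=+1)
    if max(x[y == 1]) < min(x[y == 0]):
        raise SeparationError(
            "complete separation: classes split by predictor", direction=-1)

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll = _log_likelihood(y, X @ beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtWX = X.T @ (X * w[:, None])
        grad = X.T @ (y - p)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        # step-halving keeps the log-likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            ll_new = _log_likelihood(y, X @ candidate)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta_new = beta + scale * step
        delta = np.max(np.abs(beta_new - beta))
        beta, ll = beta_new, _log_likelihood(y, X @ beta_new)
        if np.max(np.abs(beta)) > 1e6:
            raise SeparationError("diverging coefficients (quasi-separation)")
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    cov = np.linalg.inv(X.T @ (X * (p * (1 - p))[:, None]))
    return LogisticFit(float(beta[0]), float(beta[1]),
                       float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1])),
                       converged, it, ll, len(y))


def _fit_or_separated(y: np.ndarray, x: np.ndarray,
                      allow_separation: bool) -> LogisticFit:
    try:
        return fit_logistic_irls(y, x)
    except SeparationError as exc:
        if not allow_separation:
            raise
        # the MLE diverges, but its slope sign is determined by the
        # direction in which the predictor separates the classes;
        # magnitude and standard errors are not estimable
        sign = exc.direction if exc.direction else (
            1 if x[y == 1].mean() > x[y == 0].mean() else -1)
        return LogisticFit(np.nan, float(sign) * np.inf, np.nan, np.nan,
                           False, 0, np.nan, len(y))


def interaction_analysis(
    classes: pd.DataFrame,
    abundances: pd.DataFrame,
    allow_separation: bool = True,
) -> tuple[LogisticFit, LogisticFit]:
    """Fit the cushion and tree GLMs over (window, iteration) units.

    ``classes`` must carry columns (window, iteration, sign_class) and
    ``abundances`` (window, iteration, cushion_pct, tree_pct).
    Indeterminate units are excluded; the response is 1 for positive
    and 0 for negative relationships.

    When a predictor completely separates the classes the maximum
    likelihood slope is infinite.  With ``allow_separation`` (the
    default) the returned fit carries ``converged=False`` and a
    ``±inf`` slope whose sign is the determined direction of
    separation; with ``allow_separation=False`` the condition is
    raised as :class:`SeparationError` instead.  No penalisation is
    ever applied.
    """
    merged = classes.merge(abundances, on=["window", "iteration"], how="inner")
    merged = merged[merged["sign_class"].isin(["positive", "negative"])]
    merged = merged.dropna(subset=["cushion_pct", "tree_pct"])
    if merged.empty or merged["sign_class"].nunique() < 2:
        raise DegenerateResponseError(
            "need both positive and negative units for the GLM"
        )
    y = (merged["sign_class"] == "positive").to_numpy(float)
    fit_cushion = _fit_or_separated(
        y, merged["cushion_pct"].to_numpy(float), allow_separation)
    fit_tree = _fit_or_separated(
        y, merged["tree_pct"].to_numpy(float), allow_separation)
    return fit_cushion, fit_tree
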