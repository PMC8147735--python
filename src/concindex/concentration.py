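"""Concentration-index estimation.

The concentration index (CI) summarizes socioeconomic inequality in a
health variable h: with respondents ranked from poorest to richest by
fractional rank r (weighted mean 1/2), the CI equals twice the weighted
covariance between h and r divided by the mean of h,

    CI = 2 cov_w(h, r) / mu_h,

which is also twice the area between the concentration curve and the
45-degree equality line. CI = 0 means no gradient; positive values are
pro-rich (the outcome concentrates among the wealthier), negative
pro-poor; for unbounded h the index lies in [-1, 1].

For bounded outcomes — binary indicators especially — the attainable
range of the standard CI shrinks with the mean, so estimates are not
comparable across prevalence levels. The Wagstaff normalization
restores the full [-1, 1] range: for a binary indicator it divides by
(1 - mu); for an indicator bounded on [a, b] the variable is first
rescaled to [0, 1], giving the general factor

    W = CI * mu * (b - a) / ((mu - a) * (b - mu)).

Point estimates come from the "convenient regression": the WLS slope of
y_i = 2 * var_w(r) * h_i / mu on r_i (weights w) equals the covariance
form exactly, and its conventional slope standard error provides the
inference. Both routes are implemented and tested against each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateIndexError, ValidationError
from .ranking import RankedSample

__all__ = [
    "CIEstimate",
    "ci_direct",
    "ci_regression",
    "wagstaff_normalize",
    "estimate",
    "concentration_curve_points",
    "ci_from_curve_area",
]

#: |CI| at or above which inequality is conventionally called "relevant".
RELEVANCE_THRESHOLD = 0.2


@dataclass
class CIEstimate:
    """A concentration-index point estimate with inference metadata.

    ``ci95`` is the normal-approximation interval value ± 1.96·se.
    ``normalized`` records whether the Wagstaff correction was applied;
    ``pro_rich`` is the sign of the estimate; ``relevant`` flags
    |value| ≥ the relevance threshold; ``significant`` is a two-sided
    z-test against zero at the stated alpha.
    """

    value: float
    se: float
    ci95: tuple[float, float]
    mu: float
    n: int
    normalized: bool
    pro_rich: bool
    significant: bool
    relevant: bool
    label: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if np.isfinite(self.se) and (
            abs(lo - (self.value - 1.96 * self.se)) > 1e-9
            or abs(hi - (self.value + 1.96 * self.se)) > 1e-9
        ):
            raise ValidationError("ci95 must equal value ± 1.96·se")
        if self.pro_rich != (self.value > 0):
            raise ValidationError("pro_rich flag contradicts the estimate's sign")


def _normalized_weights(sample: RankedSample) -> np.ndarray:
    return sample.w / sample.w.sum()


def ci_direct(sample: RankedSample) -> float:
    """Standard CI via the weighted covariance form 2·cov_w(h, r)/mu.

    Equivalent to (2/mu)·Σ w̃_i h_i r_i − 1 with w̃ summing to one,
    because the weighted mean of r is 1/2 by construction.
    """
    if sample.n < 2:
        raise DegenerateIndexError("CI undefined for a single respondent "
                                   "(fractional rank has zero variance)")
    mu = sample.mu
    if mu == 0:
        raise DegenerateIndexError("CI undefined: indicator mean is zero")
    wt = _normalized_weights(sample)
    cov = float(np.sum(wt * (sample.h - mu) * (sample.r - 0.5)))
    return 2.0 * cov / mu


def ci_regression(sample: RankedSample) -> CIEstimate:
    """CI by the convenient weighted regression, with a slope standard error.

    Fits y_i = 2·var_w(r)·h_i/mu on r_i by WLS with weights w (plus an
    intercept). The slope equals :func:`ci_direct` exactly; the
    conventional WLS slope SE supplies the significance test. No
    Wagstaff correction is applied here (``normalized=False``).
    """
    if sample.n < 2:
        raise DegenerateIndexError("CI undefined for a single respondent")
    mu = sample.mu
    if mu == 0:
        raise DegenerateIndexError("CI undefined: indicator mean is zero")
    wt = _normalized_weights(sample)
    var_r = float(np.sum(wt * (sample.r - 0.5) ** 2))
    if var_r == 0:
        raise DegenerateIndexError("fractional ranks have zero variance")

    y = 2.0 * var_r * sample.h / mu
    X = sm.add_constant(sample.r)
    fit = sm.WLS(y, X, weights=sample.w).fit()
    value = float(fit.params[1])
    se = float(fit.bse[1]) if sample.n >= 3 else float("inf")
    return CIEstimate(
        value=value,
        se=se,
        ci95=(value - 1.96 * se, value + 1.96 * se),
        mu=mu,
        n=sample.n,
        normalized=False,
        pro_rich=value > 0,
        significant=bool(abs(value / se) > stats.norm.ppf(0.975)) if np.isfinite(se) else False,
        relevant=bool(abs(value) >= RELEVANCE_THRESHOLD),
        label=sample.label,
    )


def wagstaff_factor(mu: float, bounds: tuple[float, float]) -> float:
    """Multiplier turning a standard CI into the Wagstaff-normalized CI."""
    a, b = bounds
    if not a < b:
        raise ValidationError(f"bounds must satisfy a < b, got {bounds}")
    if not a <= mu <= b or mu in (a, b):
        raise DegenerateIndexError(
            f"Wagstaff normalization undefined: mean {mu!r} at or outside "
            f"the bounds {bounds}"
        )
    return mu * (b - a) / ((mu - a) * (b - mu))


def wagstaff_normalize(ci: float, mu: float, bounds: tuple[float, float] = (0.0, 1.0)) -> float:
    """Wagstaff-normalized CI for an indicator bounded on [a, b].

    The indicator is conceptually rescaled to s = (h-a)/(b-a) — which
    multiplies the CI by mu/(mu-a) — and the binary-style correction
    1/(1-mu_s) is applied, giving CI·mu·(b-a)/((mu-a)(b-mu)). For a
    binary indicator (bounds (0,1)) this is exactly CI/(1-mu).
    """
    return ci * wagstaff_factor(mu, bounds)


def estimate(
    sample: RankedSample,
    normalize: bool = True,
    alpha: float = 0.05,
    relevance: float = RELEVANCE_THRESHOLD,
) -> CIEstimate:
    """Full CI estimate with optional Wagstaff normalization and flags.

    When ``normalize`` is true the point estimate and its SE are both
    multiplied by the Wagstaff factor (delta method with mu treated as
    fixed), so the z-statistic — and hence the significance flag — is
    unchanged by normalization. ``relevant`` compares |value| to the
    ``relevance`` threshold (default 0.2) on the reported scale.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha!r}")
    base = ci_regression(sample)
    value, se = base.value, base.se
    if normalize:
        factor = wagstaff_factor(base.mu, sample.bounds)
        value *= factor
        se *= abs(factor)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    return CIEstimate(
        value=value,
        se=se,
        ci95=(value - 1.96 * se, value + 1.96 * se),
        mu=base.mu,
        n=base.n,
        normalized=normalize,
        pro_rich=value > 0,
        significant=bool(abs(value / se) > z_crit) if np.isfinite(se) and se > 0 else False,
        relevant=bool(abs(value) >= relevance),
        label=sample.label,
    )


def concentration_curve_points(
    sample: RankedSample,
    grid: int | None = None,
) -> np.ndarray:
    """Concentration curve: cumulative h-share against cumulative
    population share, poorest first.

    Returns an (m, 2) array of (P_k, L_k) starting at (0,0) and ending
    at (1,1); the curve is non-decreasing for non-negative h. With
    ``grid=None`` one vertex per tie-block of respondents is returned;
    an integer ``grid`` ≥ 2 instead evaluates the curve by linear
    interpolation at grid+1 equally spaced population shares.
    """
    if (sample.h < 0).any():
        raise ValidationError("concentration curve undefined for negative h")
    if sample.mu <= 0:
        raise DegenerateIndexError("curve undefined: indicator mean is zero")
    if grid is not None and grid < 2:
        raise ValueError("grid must be ≥ 2")

    order = np.argsort(sample.r, kind="stable")
    r_s = sample.r[order]
    w_s = sample.w[order] / sample.w.sum()
    hw_s = sample.h[order] * w_s

    # Collapse tie blocks (equal rank) so vertices are unambiguous.
    block_start = np.r_[True, r_s[1:] != r_s[:-1]]
    block_id = np.cumsum(block_start) - 1
    P = np.r_[0.0, np.cumsum(np.bincount(block_id, weights=w_s))]
    L = np.r_[0.0, np.cumsum(np.bincount(block_id, weights=hw_s))]
    L = L / L[-1]
    P[-1] = 1.0  # guard float drift at the endpoint
    points = np.column_stack([P, L])

    if grid is None:
        return points
    p_grid = np.linspace(0.0, 1.0, grid + 1)
    return np.column_stack([p_grid, np.interp(p_grid, P, L)])


def ci_from_curve_area(points: np.ndarray) -> float:
    """CI as twice the area between the 45-degree line and the curve.

    Trapezoid rule on the curve's vertices; positive when the curve lies
    below the diagonal (pro-rich). Serves as a geometric cross-check of
    :func:`ci_direct`, agreeing within the O(1/n) discretization error.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 2:
        raise ValidationError("points must be an (m≥2, 2) array")
    P, L = points[:, 0], points[:, 1]
    if (np.diff(P) < 0).any():
        raise ValidationError("curve points must be sorted by population share")
    area_under_curve = float(np.trapezoid(L, P))
    return 2.0 * (0.5 - area_under_curve)
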