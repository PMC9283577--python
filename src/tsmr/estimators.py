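"""Causal-effect estimators for two-sample MR summary data.

The estimators are scikit-learn-style: ``fit`` takes the per-variant
SNP-exposure effects as ``X`` (shape ``(J,)`` or ``(J, 1)``), the SNP-outcome
effects as ``y``, and the outcome standard errors as a required ``se_out``
fit parameter; fitted quantities land in trailing-underscore attributes and
``predict`` evaluates the fitted genetic dose-response line.  A list of
:class:`~tsmr.instruments.HarmonizedInstrument` may be passed as ``X`` alone.

Statistical conventions (documented because the estimators are defined by
convention rather than by any single formula source):

* IVW is the weighted least-squares slope of beta_out on beta_exp through the
  origin with weights 1/se_out²; the multiplicative random-effects SE scales
  the fixed-effect SE by max(1, sqrt(Q/(J−1))) — overdispersion can widen the
  interval but under-dispersion never narrows it.
* MR-Egger adds an unconstrained intercept (the average directional
  pleiotropy) after orienting every variant to a non-negative exposure
  effect; SEs carry the same multiplicative scale with J−2 degrees of
  freedom, and p-values use the t distribution with J−2 df.
* The weighted median orders Wald ratios and takes the 50% point of the
  cumulative first-order inverse-variance weights (beta_exp²/se_out²), with
  linear interpolation; its SE comes from a parametric bootstrap with a
  mandatory seed.
* IVW and Wald p-values use the standard normal.  CIs are 95% with
  z = 1.959964.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .instruments import HarmonizedInstrument

__all__ = [
    "CausalEstimate",
    "OddsRatioResult",
    "HeterogeneityResult",
    "InsufficientInstrumentsError",
    "CollinearityError",
    "IVWEstimator",
    "EggerEstimator",
    "WeightedMedianEstimator",
    "wald_ratio",
    "ivw_mre",
    "egger",
    "weighted_median",
    "to_odds_ratio",
    "weighted_median_point",
]

Z95 = 1.959964


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator's minimum."""


class CollinearityError(ValueError):
    """Degenerate design (all exposure effects equal after orientation)."""


@dataclass
class CausalEstimate:
    """A causal-effect estimate on the exposure-unit → log-odds scale."""

    method: str  # wald | ivw_mre | egger_slope | egger_intercept | weighted_median
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.theta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        if self.se <= 0:
            raise ValueError("SE must be positive")


@dataclass
class OddsRatioResult:
    or_point: float
    or_low: float
    or_high: float
    pval: float

    def __post_init__(self) -> None:
        if not (0 < self.or_low <= self.or_point <= self.or_high):
            raise ValueError("odds ratios must be positive and ordered")


@dataclass
class HeterogeneityResult:
    """Cochran's Q with its df and upper-tail chi-square p-value."""

    method: str  # ivw | egger
    Q: float
    df: int
    pval: float


def _coerce(X, y, se_out, se_exp=None):
    """Accept (arrays) or (instrument list); return 1-d float arrays."""
    if len(X) and isinstance(X[0], HarmonizedInstrument):
        insts = list(X)
        bx = np.array([i.beta_exp for i in insts], dtype=float)
        by = np.array([i.beta_out for i in insts], dtype=float)
        so = np.array([i.se_out for i in insts], dtype=float)
        sx = np.array([i.se_exp for i in insts], dtype=float)
        return bx, by, so, sx
    bx = np.asarray(X, dtype=float).reshape(-1)
    by = np.asarray(y, dtype=float).reshape(-1)
    if se_out is None:
        raise ValueError("se_out is required when fitting from arrays")
    so = np.asarray(se_out, dtype=float).reshape(-1)
    sx = None if se_exp is None else np.asarray(se_exp, dtype=float).reshape(-1)
    if not (len(bx) == len(by) == len(so)) or (sx is not None and len(sx) != len(bx)):
        raise ValueError("beta_exp, beta_out and SE arrays must share one length")
    if not np.all(np.isfinite(bx)) or not np.all(np.isfinite(by)):
        raise ValueError("non-finite effect size")
    if np.any(so <= 0) or (sx is not None and np.any(sx <= 0)):
        raise ValueError("standard errors must be positive")
    return bx, by, so, sx


class IVWEstimator(BaseEstimator):
    """Inverse-variance-weighted MR with multiplicative random effects.

    Parameters
    ----------
    random_effects : bool, default True
        Scale the SE by max(1, sqrt(Q/(J−1))).  With ``False`` the
        fixed-effect SE is reported (scale_factor_ stays 1).
    """

    min_instruments = 2

    def __init__(self, random_effects: bool = True):
        self.random_effects = random_effects

    def fit(self, X, y=None, *, se_out=None, se_exp=None):
        bx, by, so, _ = _coerce(X, y, se_out, se_exp)
        J = len(bx)
        if J < self.min_instruments:
            raise InsufficientInstrumentsError(f"IVW needs >= 2 instruments, got {J}")
        w = 1.0 / so**2
        denom = float(np.sum(w * bx * bx))
        theta = float(np.sum(w * bx * by) / denom)
        Q = float(np.sum(w * (by - theta * bx) ** 2))
        df = J - 1
        scale = max(1.0, np.sqrt(Q / df)) if self.random_effects else 1.0
        se = float(np.sqrt(1.0 / denom) * scale)
        self.theta_ = theta
        self.se_ = se
        self.scale_factor_ = float(scale)
        self.n_snp_ = J
        self.q_ = Q
        self.q_df_ = df
        self.q_pval_ = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0
        self.pval_ = float(min(2 * stats.norm.sf(abs(theta) / se), 1.0))
        self.ci_ = (theta - Z95 * se, theta + Z95 * se)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.theta_ * x

    def to_estimate(self) -> CausalEstimate:
        return CausalEstimate(
            "ivw_mre", self.theta_, self.se_, self.ci_[0], self.ci_[1],
            self.pval_, self.n_snp_, self.scale_factor_,
        )

    def heterogeneity(self) -> HeterogeneityResult:
        return HeterogeneityResult("ivw", self.q_, self.q_df_, self.q_pval_)


class EggerEstimator(BaseEstimator):
    """MR-Egger weighted regression with an unconstrained intercept.

    With ``fit_intercept=False`` the regression runs through the origin and
    the slope reproduces IVW exactly (orientation leaves the weighted
    cross-products unchanged); that mode exists for the algebraic check and
    uses J−1 df.
    """

    min_instruments = 3

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y=None, *, se_out=None, se_exp=None):
        bx, by, so, _ = _coerce(X, y, se_out, se_exp)
        J = len(bx)
        if J < self.min_instruments:
            raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {J}")
        # orient every variant to a non-negative exposure effect
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        w = 1.0 / so**2
        if self.fit_intercept:
            if np.ptp(bx) == 0:
                raise CollinearityError("all exposure effects equal after orientation")
            design = np.column_stack([np.ones(J), bx])
        else:
            design = bx[:, None]
        xtwx = design.T @ (w[:, None] * design)
        xtwy = design.T @ (w * by)
        coef = np.linalg.solve(xtwx, xtwy)
        fitted = design @ coef
        Q = float(np.sum(w * (by - fitted) ** 2))
        df = J - design.shape[1]
        scale = max(1.0, np.sqrt(Q / df))
        cov = np.linalg.inv(xtwx) * scale**2
        ses = np.sqrt(np.diag(cov))
        tcrit = float(stats.t.ppf(0.975, df))

        def _summ(idx: int):
            est, se = float(coef[idx]), float(ses[idx])
            p = float(min(2 * stats.t.sf(abs(est) / se, df), 1.0))
            return est, se, (est - tcrit * se, est + tcrit * se), p

        if self.fit_intercept:
            self.intercept_, self.intercept_se_, self.intercept_ci_, self.intercept_pval_ = _summ(0)
            self.theta_, self.se_, self.ci_, self.pval_ = _summ(1)
        else:
            self.intercept_ = 0.0
            self.theta_, self.se_, self.ci_, self.pval_ = _summ(0)
        self.scale_factor_ = float(scale)
        self.n_snp_ = J
        self.q_ = Q
        self.q_df_ = df
        self.q_pval_ = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.theta_ * x

    def slope_estimate(self) -> CausalEstimate:
        return CausalEstimate(
            "egger_slope", self.theta_, self.se_, self.ci_[0], self.ci_[1],
            self.pval_, self.n_snp_, self.scale_factor_,
        )

    def intercept_estimate(self) -> CausalEstimate:
        return CausalEstimate(
            "egger_intercept", self.intercept_, self.intercept_se_,
            self.intercept_ci_[0], self.intercept_ci_[1],
            self.intercept_pval_, self.n_snp_, self.scale_factor_,
        )

    def heterogeneity(self) -> HeterogeneityResult:
        return HeterogeneityResult("egger", self.q_, self.q_df_, self.q_pval_)


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median of per-variant ratios.

    With normalized weights w and cumulative sums s, the breakpoints are
    p_j = s_j − w_j/2; the estimate is the ratio where some p_j hits 1/2
    exactly, otherwise the linear interpolation between the bracketing
    ratios (clamped to the extreme ratios when 1/2 falls outside).
    """
    order = np.argsort(ratios, kind="stable")
    r, w = np.asarray(ratios, float)[order], np.asarray(weights, float)[order]
    w = w / w.sum()
    p = np.cumsum(w) - w / 2
    return float(np.interp(0.5, p, r))


def _weighted_median_rows(R: np.ndarray, W: np.ndarray) -> np.ndarray:
    order = np.argsort(R, axis=1, kind="stable")
    Rs = np.take_along_axis(R, order, 1)
    Ws = np.take_along_axis(W, order, 1)
    Ws = Ws / Ws.sum(axis=1, keepdims=True)
    P = np.cumsum(Ws, axis=1) - Ws / 2
    return np.array([np.interp(0.5, P[b], Rs[b]) for b in range(R.shape[0])])


class WeightedMedianEstimator(BaseEstimator):
    """Weighted-median MR estimator (consistent when valid instruments carry
    more than half the weight), with a parametric-bootstrap SE.

    Parameters
    ----------
    n_boot : int, default 1000
        Bootstrap replicates (minimum 100).
    random_state : int
        Mandatory seed for the bootstrap.
    """

    min_instruments = 3

    def __init__(self, n_boot: int = 1000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y=None, *, se_out=None, se_exp=None):
        bx, by, so, sx = _coerce(X, y, se_out, se_exp)
        J = len(bx)
        if J < self.min_instruments:
            raise InsufficientInstrumentsError(
                f"weighted median needs >= 3 instruments, got {J}"
            )
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if self.random_state is None:
            raise ValueError("random_state is mandatory (bootstrap reproducibility)")
        if np.any(bx == 0):
            raise ValueError("zero exposure effect gives an undefined ratio")
        if sx is None:
            raise ValueError("se_exp is required for the parametric bootstrap")
        theta = weighted_median_point(by / bx, bx**2 / so**2)
        rng = np.random.default_rng(self.random_state)
        bx_b = bx + sx * rng.standard_normal((self.n_boot, J))
        by_b = by + so * rng.standard_normal((self.n_boot, J))
        ok = np.all(bx_b != 0, axis=1)
        thetas = _weighted_median_rows(by_b[ok] / bx_b[ok], bx_b[ok] ** 2 / so**2)
        se = float(np.std(thetas, ddof=1))
        self.theta_ = float(theta)
        self.se_ = se
        self.n_snp_ = J
        self.scale_factor_ = 1.0
        self.pval_ = float(min(2 * stats.norm.sf(abs(theta) / se), 1.0))
        self.ci_ = (theta - Z95 * se, theta + Z95 * se)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.theta_ * x

    def to_estimate(self) -> CausalEstimate:
        return CausalEstimate(
            "weighted_median", self.theta_, self.se_, self.ci_[0], self.ci_[1],
            self.pval_, self.n_snp_, 1.0,
        )


# ---------------------------------------------------------------------------
# thin functional wrappers operating on harmonized instrument lists


def wald_ratio(inst: HarmonizedInstrument) -> CausalEstimate:
    """Single-variant causal estimate theta = beta_out/beta_exp with the
    first-order SE se_out/|beta_exp|."""
    if inst.beta_exp == 0:
        raise ValueError(f"{inst.variant_id}: Wald ratio undefined for beta_exp = 0")
    theta = inst.beta_out / inst.beta_exp
    se = inst.se_out / abs(inst.beta_exp)
    p = float(min(2 * stats.norm.sf(abs(theta) / se), 1.0))
    return CausalEstimate("wald", theta, se, theta - Z95 * se, theta + Z95 * se, p, 1)


def ivw_mre(
    insts: list[HarmonizedInstrument],
) -> tuple[CausalEstimate, HeterogeneityResult]:
    model = IVWEstimator().fit(insts)
    return model.to_estimate(), model.heterogeneity()


def egger(
    insts: list[HarmonizedInstrument],
) -> tuple[CausalEstimate, CausalEstimate, HeterogeneityResult]:
    model = EggerEstimator().fit(insts)
    return model.slope_estimate(), model.intercept_estimate(), model.heterogeneity()


def weighted_median(
    insts: list[HarmonizedInstrument], n_boot: int = 1000, seed: int | None = None
) -> CausalEstimate:
    return WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit(insts).to_estimate()


def to_odds_ratio(est: CausalEstimate) -> OddsRatioResult:
    """exp-transform a log-odds estimate; monotone, so ordering is preserved."""
    return OddsRatioResult(
        float(np.exp(est.theta)), float(np.exp(est.ci_low)),
        float(np.exp(est.ci_high)), est.pval,
    )
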