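"""Heterogeneity, pleiotropy-outlier and robustness diagnostics.

Cochran's Q tests homogeneity of the per-variant causal estimates; MR-PRESSO
simulates the no-pleiotropy null to attach a p-value to the observed residual
sum of squares, flags per-variant outliers, and reports an outlier-corrected
estimate with a distortion test; leave-one-out re-estimates IVW after
dropping each instrument in turn.

MR-PRESSO requires at least 4 instruments; with fewer it returns a structured
``performed = False`` result rather than raising, since an analysis can
legitimately end up with 3 instruments and the downstream report must say so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import (
    CausalEstimate,
    HeterogeneityResult,
    InsufficientInstrumentsError,
    IVWEstimator,
)
from .instruments import HarmonizedInstrument

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "LeaveOneOutResult",
    "cochran_q",
    "mr_presso",
    "leave_one_out",
]


def cochran_q(
    insts: list[HarmonizedInstrument], theta: float, df_reduction: int = 1
) -> HeterogeneityResult:
    """Cochran's Q of the Wald ratios around ``theta`` with first-order ratio
    weights beta_exp²/se_out² (algebraically Σ w_j (beta_out_j − θ·beta_exp_j)²
    with w_j = 1/se_out²).  ``df_reduction`` is 1 for the IVW form and 2 for
    the Egger form; the p-value is the upper-tail chi-square probability."""
    J = len(insts)
    df = J - df_reduction
    if df <= 0:
        raise InsufficientInstrumentsError(
            f"Cochran's Q needs more than {df_reduction} instruments, got {J}"
        )
    bx = np.array([i.beta_exp for i in insts])
    by = np.array([i.beta_out for i in insts])
    so = np.array([i.se_out for i in insts])
    if np.any(bx == 0):
        raise ValueError("zero exposure effect gives an undefined ratio")
    w_ratio = bx**2 / so**2
    Q = float(np.sum(w_ratio * (by / bx - theta) ** 2))
    method = "ivw" if df_reduction == 1 else "egger"
    return HeterogeneityResult(method, Q, df, float(stats.chi2.sf(Q, df)))


@dataclass
class PressoResult:
    performed: bool
    rss_obs: float | None = None
    global_pval: float | None = None
    outlier_ids: list[str] = field(default_factory=list)
    outlier_pvals: dict[str, float] = field(default_factory=dict)
    distortion_pval: float | None = None
    theta_raw: float | None = None
    theta_corrected: float | None = None
    n_sim: int | None = None
    seed: int | None = None
    not_performed_reason: str | None = None


def _loo_thetas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW estimate excluding each variant in turn, O(J)."""
    s1, s2 = np.sum(w * bx * by), np.sum(w * bx * bx)
    return (s1 - w * bx * by) / (s2 - w * bx * bx)


def mr_presso(
    insts: list[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed residual sum RSS = Σ_j w_j (beta_out_j − θ̂₋j·beta_exp_j)²
    (w_j = 1/se_out², θ̂₋j the leave-one-out IVW estimate) is compared with
    its distribution under a simulated no-pleiotropy null: each replicate
    redraws beta_exp*_j ~ N(beta_exp_j, se_exp_j) and
    beta_out*_j ~ N(θ̂₋j·beta_exp_j, se_out_j) and recomputes the RSS with
    its own leave-one-out estimates.  Global and per-variant p-values use
    add-one smoothing, (1 + #exceed)/(1 + n_sim); per-variant p-values are
    Bonferroni-corrected by J and variants below ``outlier_alpha`` are
    flagged.  The distortion p-value compares the raw-vs-corrected estimate
    difference against differences from removing random subsets of the same
    size.  With zero flagged outliers the corrected estimate equals the raw
    one exactly and the distortion test is not applicable.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if seed is None:
        raise ValueError("seed is mandatory for MR-PRESSO")
    J = len(insts)
    if J < 4:
        return PressoResult(performed=False, not_performed_reason="insufficient_snps")

    bx = np.array([i.beta_exp for i in insts])
    by = np.array([i.beta_out for i in insts])
    sx = np.array([i.se_exp for i in insts])
    so = np.array([i.se_out for i in insts])
    ids = [i.variant_id for i in insts]
    w = 1.0 / so**2

    loo = _loo_thetas(bx, by, w)
    res_obs = w * (by - loo * bx) ** 2
    rss_obs = float(res_obs.sum())

    rng = np.random.default_rng(seed)
    bx_s = bx + sx * rng.standard_normal((n_sim, J))
    by_s = loo * bx + so * rng.standard_normal((n_sim, J))
    s1 = np.sum(w * bx_s * by_s, axis=1, keepdims=True)
    s2 = np.sum(w * bx_s**2, axis=1, keepdims=True)
    loo_s = (s1 - w * bx_s * by_s) / (s2 - w * bx_s**2)
    res_s = w * (by_s - loo_s * bx_s) ** 2
    rss_s = res_s.sum(axis=1)

    global_p = float((1 + np.sum(rss_s >= rss_obs)) / (1 + n_sim))
    p_var = (1 + np.sum(res_s >= res_obs, axis=0)) / (1 + n_sim)
    p_adj = np.minimum(p_var * J, 1.0)
    flagged = p_adj < outlier_alpha
    outlier_ids = [ids[j] for j in range(J) if flagged[j]]

    theta_raw = IVWEstimator().fit(insts).theta_
    distortion_p = None
    if outlier_ids:
        keep = [i for i, f in zip(insts, flagged) if not f]
        if len(keep) >= 2:
            theta_corrected = IVWEstimator().fit(keep).theta_
            obs_diff = abs(theta_raw - theta_corrected)
            n_out = len(outlier_ids)
            diffs = np.empty(n_sim)
            idx = np.arange(J)
            for b in range(n_sim):
                drop = rng.choice(idx, size=n_out, replace=False)
                mask = np.ones(J, bool)
                mask[drop] = False
                s1b = np.sum(w[mask] * bx[mask] * by[mask])
                s2b = np.sum(w[mask] * bx[mask] ** 2)
                diffs[b] = abs(theta_raw - s1b / s2b)
            distortion_p = float((1 + np.sum(diffs >= obs_diff)) / (1 + n_sim))
        else:  # nearly everything flagged — corrected estimate undefined
            theta_corrected = theta_raw
    else:
        theta_corrected = theta_raw

    return PressoResult(
        performed=True,
        rss_obs=rss_obs,
        global_pval=global_p,
        outlier_ids=outlier_ids,
        outlier_pvals={ids[j]: float(p_adj[j]) for j in range(J)},
        distortion_pval=distortion_p,
        theta_raw=float(theta_raw),
        theta_corrected=float(theta_corrected),
        n_sim=n_sim,
        seed=seed,
    )


@dataclass
class LeaveOneOutResult:
    rows: list[tuple[str, CausalEstimate]]
    full: CausalEstimate
    robust: bool

    def __len__(self) -> int:
        return len(self.rows)


def leave_one_out(insts: list[HarmonizedInstrument]) -> LeaveOneOutResult:
    """Multiplicative random-effects IVW after excluding each instrument.

    The robustness flag is set when the leave-one-out estimates agree with
    the full estimate about excluding zero: every reduced-set CI excludes
    zero exactly when the full CI does.
    """
    if len(insts) < 3:
        raise InsufficientInstrumentsError(
            f"leave-one-out needs >= 3 instruments, got {len(insts)}"
        )
    full = IVWEstimator().fit(insts).to_estimate()
    rows: list[tuple[str, CausalEstimate]] = []
    for j, inst in enumerate(insts):
        reduced = insts[:j] + insts[j + 1 :]
        rows.append((inst.variant_id, IVWEstimator().fit(reduced).to_estimate()))
    full_excl = full.ci_low > 0 or full.ci_high < 0
    rows_excl = all(e.ci_low > 0 or e.ci_high < 0 for _, e in rows)
    return LeaveOneOutResult(rows=rows, full=full, robust=rows_excl == full_excl)
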