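"""Replicated simulation studies over the synthetic scenarios.

These are the package's own calibration experiments: parameter recovery and
CI coverage for IVW, type-I error for IVW and the Egger intercept test,
weighted-median breakdown under directional pleiotropy, and MR-PRESSO null
calibration and planted-outlier recovery.  Both the test suite and the
acceptance script run them; replicate counts are part of the study design
(documented in the methods note) and every study takes an explicit seed.
"""

from __future__ import annotations

import numpy as np

from .estimators import EggerEstimator, IVWEstimator, WeightedMedianEstimator
from .instruments import HarmonizedInstrument, harmonize
from .sensitivity import mr_presso
from .simulate import GeneratedStudy, SyntheticScenario, generate_pair

__all__ = [
    "instruments_from_truth",
    "ivw_recovery_study",
    "type1_error_study",
    "median_breakdown_study",
    "presso_null_calibration",
    "presso_outlier_study",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible sub-seeds, each below 2**31."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def instruments_from_truth(study: GeneratedStudy) -> list[HarmonizedInstrument]:
    """Harmonized instruments for exactly the planted variants (bypasses the
    selection filters, so estimator calibration is not confounded by them)."""
    planted = set(study.truth.loc[study.truth.is_instrument, "variant_id"])
    insts, _ = harmonize(study.exposure.subset(planted), study.outcome)
    return insts


def ivw_recovery_study(
    scenario: SyntheticScenario, n_rep: int = 200, seed: int = 0
) -> dict:
    """Mean IVW estimate, mean bias and empirical 95% CI coverage."""
    seeds = _child_seeds(seed, n_rep)
    thetas, covered = [], 0
    for s in seeds:
        insts = instruments_from_truth(generate_pair(scenario.replace(seed=int(s))))
        model = IVWEstimator().fit(insts)
        thetas.append(model.theta_)
        if model.ci_[0] <= scenario.theta_true <= model.ci_[1]:
            covered += 1
    thetas = np.asarray(thetas)
    return {
        "theta_true": scenario.theta_true,
        "mean_theta": float(thetas.mean()),
        "mean_bias": float(thetas.mean() - scenario.theta_true),
        "coverage": covered / n_rep,
        "empirical_se": float(thetas.std(ddof=1)),
        "n_rep": n_rep,
    }


def type1_error_study(
    scenario: SyntheticScenario, n_rep: int = 1000, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Rejection rates under the null for the IVW estimate and the Egger
    intercept test."""
    seeds = _child_seeds(seed, n_rep)
    ivw_rej = egger_rej = 0
    for s in seeds:
        insts = instruments_from_truth(generate_pair(scenario.replace(seed=int(s))))
        if IVWEstimator().fit(insts).pval_ < alpha:
            ivw_rej += 1
        if EggerEstimator().fit(insts).intercept_pval_ < alpha:
            egger_rej += 1
    return {
        "ivw_rejection": ivw_rej / n_rep,
        "egger_intercept_rejection": egger_rej / n_rep,
        "n_rep": n_rep,
        "alpha": alpha,
    }


def median_breakdown_study(
    scenario: SyntheticScenario, n_rep: int = 200, seed: int = 0, n_boot: int = 200
) -> dict:
    """Absolute bias of the weighted-median estimate under the scenario's
    invalid-instrument weight fraction."""
    seeds = _child_seeds(seed, n_rep)
    thetas = []
    for s in seeds:
        insts = instruments_from_truth(generate_pair(scenario.replace(seed=int(s))))
        model = WeightedMedianEstimator(n_boot=n_boot, random_state=int(s)).fit(insts)
        thetas.append(model.theta_)
    thetas = np.asarray(thetas)
    return {
        "theta_true": scenario.theta_true,
        "mean_theta": float(thetas.mean()),
        "abs_bias": float(abs(thetas.mean() - scenario.theta_true)),
        "invalid_fraction": scenario.invalid_fraction,
        "n_rep": n_rep,
    }


def presso_null_calibration(
    scenario: SyntheticScenario, n_rep: int = 500, n_sim: int = 1000, seed: int = 0
) -> dict:
    """Empirical CDF of the MR-PRESSO global p-value at 0.1/0.5/0.9 under a
    no-pleiotropy null (uniformity check)."""
    seeds = _child_seeds(seed, n_rep)
    pvals = []
    for s in seeds:
        insts = instruments_from_truth(generate_pair(scenario.replace(seed=int(s))))
        res = mr_presso(insts, n_sim=n_sim, seed=int(s) + 1)
        pvals.append(res.global_pval)
    pvals = np.asarray(pvals)
    return {
        "cdf_0.1": float(np.mean(pvals <= 0.1)),
        "cdf_0.5": float(np.mean(pvals <= 0.5)),
        "cdf_0.9": float(np.mean(pvals <= 0.9)),
        "frac_above_0.05": float(np.mean(pvals > 0.05)),
        "n_rep": n_rep,
    }


def presso_outlier_study(
    scenario: SyntheticScenario,
    n_rep: int = 100,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_multiple: float = 10.0,
) -> dict:
    """Plant one pleiotropic outlier (effect = ``outlier_multiple`` × its
    residual SD) among otherwise valid instruments; report how often it is
    flagged and how often the corrected estimate lands closer to the truth
    than the raw one."""
    seeds = _child_seeds(seed, n_rep)
    flagged = improved = 0
    for s in seeds:
        insts = instruments_from_truth(generate_pair(scenario.replace(seed=int(s))))
        target = insts[0]
        insts[0] = HarmonizedInstrument(
            variant_id=target.variant_id,
            beta_exp=target.beta_exp, se_exp=target.se_exp,
            beta_out=target.beta_out + outlier_multiple * target.se_out,
            se_out=target.se_out,
            eaf_exp=target.eaf_exp, pval_exp=target.pval_exp,
            n_exp=target.n_exp, n_out=target.n_out,
        )
        res = mr_presso(insts, n_sim=n_sim, seed=int(s) + 1)
        if target.variant_id in res.outlier_ids:
            flagged += 1
        if abs(res.theta_corrected - scenario.theta_true) < abs(
            res.theta_raw - scenario.theta_true
        ):
            improved += 1
    return {
        "flag_rate": flagged / n_rep,
        "correction_improves_rate": improved / n_rep,
        "n_rep": n_rep,
    }
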