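"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generative model plants J instruments with true SNP-exposure effects
gamma_j on a standardized quantitative-trait scale and a causal effect
theta_true, so the true SNP-outcome effect is theta_true·gamma_j + alpha_j.
Valid instruments have alpha_j = 0 (exclusion restriction holds); a
configurable fraction are invalid, with alpha_j drawn balanced (mean zero)
or directional (non-zero mean), optionally correlated with gamma_j to
violate the InSIDE assumption that MR-Egger relies on.

Sampling noise follows the usual summary-statistic approximation
se ≈ 1/sqrt(2·maf·(1−maf)·n); for a binary outcome the SE is further
inflated by the case-control variance factor 1/sqrt(v·(1−v)) with case
fraction v, matching the geometry of a biobank outcome with few cases
(the defaults mirror an 8,591-case / 210,201-control glaucoma study against
a 17,706-sample imaging exposure).  Background null variants (gamma = 0)
pad the tables so that the significance filter has something to reject, and
the LD matrix is block-diagonal: each planted instrument is its own block
(instruments are mutually independent) while null variants are grouped into
correlated blocks.

The generator works at the summary level only — no individual-level
genotypes, no chromosome-scale LD, no phenotype simulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LdMatrix, SumStatsTable, VariantAssociation

__all__ = ["SyntheticScenario", "GeneratedStudy", "generate_pair", "scenario_presets"]

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of the generative model.  ``seed`` is mandatory: two runs
    of the same scenario are byte-identical."""

    seed: int
    theta_true: float = 0.0
    J: int = 50
    invalid_fraction: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.1   # directional mode only
    pleiotropy_sd: float = 0.05
    inside_violated: bool = False
    inside_rho: float = 0.8
    gamma_dist: tuple[float, float] = (0.15, 0.02)  # (mean, sd) of true effects
    n_exp: int = 17706
    n_out: int = 218792
    case_fraction: float | None = 8591 / 218792  # None -> quantitative outcome
    maf_range: tuple[float, float] = (0.2, 0.5)
    n_null_variants: int = 200
    ld_block_sizes: tuple[int, ...] | None = None  # None -> tile nulls in fives
    ld_within_block_r2: float = 0.8
    palindromic_fraction: float = 0.05
    strand_flip_fraction: float = 0.1
    allele_swap_fraction: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.pleiotropy_sd < 0 or self.gamma_dist[1] < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (0 <= self.invalid_fraction <= 1):
            raise ValueError("invalid_fraction must lie in [0, 1]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.J < 1 or self.n_exp < 1 or self.n_out < 1:
            raise ValueError("J and sample sizes must be positive")

    def replace(self, **kwargs) -> "SyntheticScenario":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GeneratedStudy:
    exposure: SumStatsTable
    outcome: SumStatsTable
    ld: LdMatrix
    truth: pd.DataFrame  # variant_id, gamma, alpha, is_instrument, is_valid


def _se(maf: np.ndarray, n: int, case_fraction: float | None) -> np.ndarray:
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    if case_fraction is not None:
        v = case_fraction
        se = se / np.sqrt(v * (1.0 - v))
    return se


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 1e-300, 1.0)


def _block_structure(scn: SyntheticScenario) -> list[list[int]]:
    """Index blocks over null variants (offsets relative to the null range)."""
    n = scn.n_null_variants
    if scn.ld_block_sizes is None:
        sizes: list[int] = [5] * (n // 5)
        if n % 5:
            sizes.append(n % 5)
    else:
        sizes = list(scn.ld_block_sizes)
        if any(s < 1 for s in sizes) or sum(sizes) > n:
            raise ValueError(
                f"ld_block_sizes {sizes} inconsistent with {n} null variants"
            )
        sizes += [1] * (n - sum(sizes))
    blocks, start = [], 0
    for s in sizes:
        blocks.append(list(range(start, start + s)))
        start += s
    return blocks


def generate_pair(scn: SyntheticScenario) -> GeneratedStudy:
    """Draw one exposure/outcome summary-statistic pair, its LD matrix, and
    the per-variant truth record."""
    rng = np.random.default_rng(scn.seed)
    J, n_null = scn.J, scn.n_null_variants
    n_total = J + n_null
    ids = [f"rs{i:06d}" for i in range(1, n_total + 1)]

    maf = rng.uniform(scn.maf_range[0], scn.maf_range[1], n_total)
    gamma = np.zeros(n_total)
    gamma[:J] = rng.normal(scn.gamma_dist[0], scn.gamma_dist[1], J)

    # invalid-instrument bookkeeping: count rounds half-up
    k_invalid = int(np.floor(scn.invalid_fraction * J + 0.5))
    invalid_idx = rng.choice(J, size=k_invalid, replace=False) if k_invalid else np.array([], int)
    is_valid = np.ones(n_total, bool)
    is_valid[invalid_idx] = False
    is_valid[J:] = True  # null variants carry no pleiotropy

    alpha = np.zeros(n_total)
    if k_invalid and scn.pleiotropy_mode != "none":
        mu = scn.pleiotropy_mean if scn.pleiotropy_mode == "directional" else 0.0
        if scn.inside_violated:
            gm, gs = scn.gamma_dist
            gs = max(gs, 1e-12)
            z_g = (gamma[invalid_idx] - gm) / gs
            noise = rng.normal(0.0, 1.0, k_invalid)
            alpha[invalid_idx] = mu + scn.pleiotropy_sd * (
                scn.inside_rho * z_g + np.sqrt(1 - scn.inside_rho**2) * noise
            )
        else:
            alpha[invalid_idx] = rng.normal(mu, scn.pleiotropy_sd, k_invalid)

    se_exp = _se(maf, scn.n_exp, None)
    se_out = _se(maf, scn.n_out, scn.case_fraction)
    beta_exp = gamma + se_exp * rng.standard_normal(n_total)
    beta_out = scn.theta_true * gamma + alpha + se_out * rng.standard_normal(n_total)

    # allele assignment: a configured fraction palindromic; outcome labels are
    # strand-complemented or swapped for configured fractions of the
    # non-palindromic variants (palindromes cannot be strand-resolved, so the
    # generator never flips their strand)
    pal = rng.uniform(size=n_total) < scn.palindromic_fraction
    pair_choice = rng.integers(0, 8, n_total)
    pal_choice = rng.integers(0, 4, n_total)
    ea = np.where(pal,
                  [ _PALINDROMIC_PAIRS[c][0] for c in pal_choice],
                  [ _NONPALINDROMIC_PAIRS[c][0] for c in pair_choice])
    oa = np.where(pal,
                  [ _PALINDROMIC_PAIRS[c][1] for c in pal_choice],
                  [ _NONPALINDROMIC_PAIRS[c][1] for c in pair_choice])
    strand_flip = (rng.uniform(size=n_total) < scn.strand_flip_fraction) & ~pal
    swap = rng.uniform(size=n_total) < scn.allele_swap_fraction

    p_exp = _pvals(beta_exp, se_exp)
    p_out = _pvals(beta_out, se_out)

    exp_records, out_records = [], []
    for i in range(n_total):
        exp_records.append(
            VariantAssociation(
                variant_id=ids[i], effect_allele=str(ea[i]), other_allele=str(oa[i]),
                beta=float(beta_exp[i]), se=float(se_exp[i]), pval=float(p_exp[i]),
                chrom="1", pos=i + 1, eaf=float(maf[i]), n=scn.n_exp,
            )
        )
        o_ea, o_oa, o_beta, o_eaf = str(ea[i]), str(oa[i]), float(beta_out[i]), float(maf[i])
        if strand_flip[i]:
            o_ea, o_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
        if swap[i]:
            o_ea, o_oa = o_oa, o_ea
            o_beta, o_eaf = -o_beta, 1.0 - o_eaf
        out_records.append(
            VariantAssociation(
                variant_id=ids[i], effect_allele=o_ea, other_allele=o_oa,
                beta=o_beta, se=float(se_out[i]), pval=float(p_out[i]),
                chrom="1", pos=i + 1, eaf=o_eaf, n=scn.n_out,
            )
        )

    r2 = np.eye(n_total)
    for block in _block_structure(scn):
        if len(block) > 1:
            idx = np.array(block) + J
            r2[np.ix_(idx, idx)] = scn.ld_within_block_r2
            r2[idx, idx] = 1.0

    truth = pd.DataFrame(
        dict(
            variant_id=ids,
            gamma=gamma,
            alpha=alpha,
            is_instrument=[i < J for i in range(n_total)],
            is_valid=is_valid,
        )
    )
    outcome_type = "binary" if scn.case_fraction is not None else "quantitative"
    return GeneratedStudy(
        exposure=SumStatsTable("synthetic_exposure", exp_records, "quantitative"),
        outcome=SumStatsTable("synthetic_outcome", out_records, outcome_type),
        ld=LdMatrix(ids, r2),
        truth=truth,
    )


def scenario_presets(seed: int = 20220733) -> dict[str, SyntheticScenario]:
    """Named study conditions.

    * ``null_model`` — no causal effect, no pleiotropy (type-I error checks).
    * ``valid_causal`` — theta 0.5, 50 valid instruments (parameter recovery).
    * ``balanced_pleiotropy`` / ``directional_pleiotropy`` — 30% invalid
      instruments with mean-zero vs. mean-0.1 pleiotropy.
    * ``inside_violated`` — directional pleiotropy correlated with the
      instrument strengths (breaks the Egger InSIDE assumption).
    * ``few_snps_3`` — exactly 3 instruments with a protective effect
      (theta = ln 0.65): exercises the path where MR-PRESSO cannot run.
    * ``many_weak`` — 100 weak instruments, most below genome-wide
      significance.
    * ``median_breakdown_40`` / ``median_breakdown_60`` — directional
      pleiotropy carrying 40% vs. 60% of the instrument weight, on a
      precisely measured quantitative outcome so the weighted median's
      breakdown at half the weight is visible above sampling noise.
    """
    base = SyntheticScenario(seed=seed)
    calib = base.replace(n_exp=20000, n_out=20000)
    breakdown = base.replace(
        theta_true=0.5, J=50, pleiotropy_mode="directional",
        pleiotropy_mean=0.1, pleiotropy_sd=0.02,
        n_exp=100000, n_out=100000, case_fraction=None,
        n_null_variants=0, palindromic_fraction=0.0,
        strand_flip_fraction=0.0, allele_swap_fraction=0.0,
    )
    return {
        "null_model": calib.replace(theta_true=0.0, J=20),
        "valid_causal": calib.replace(theta_true=0.5, J=50),
        "balanced_pleiotropy": calib.replace(
            theta_true=0.5, J=50, invalid_fraction=0.3, pleiotropy_mode="balanced"
        ),
        "directional_pleiotropy": calib.replace(
            theta_true=0.5, J=50, invalid_fraction=0.3, pleiotropy_mode="directional"
        ),
        "inside_violated": calib.replace(
            theta_true=0.5, J=50, invalid_fraction=0.3,
            pleiotropy_mode="directional", inside_violated=True,
        ),
        "few_snps_3": calib.replace(
            theta_true=float(np.log(0.65)), J=3, n_null_variants=50,
            palindromic_fraction=0.0,
        ),
        "many_weak": calib.replace(
            theta_true=0.5, J=100, gamma_dist=(0.03, 0.01), n_null_variants=100
        ),
        "median_breakdown_40": breakdown.replace(invalid_fraction=0.4),
        "median_breakdown_60": breakdown.replace(invalid_fraction=0.6),
    }
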