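"""Instrument selection and allele harmonization for two-sample MR.

Four filters turn an exposure GWAS into a harmonized instrument set:

1. genome-wide significance (p < 5e-8, strict);
2. greedy LD clumping against a user-supplied r² matrix (keep the best
   remaining variant by p-value, discard everything with r² at or above the
   threshold against it);
3. unconditional removal of palindromic (A/T, C/G) variants — no
   frequency-based rescue, so effect-allele frequency is never needed to
   resolve strand;
4. Steiger directionality filtering: a variant explaining more variance in
   the outcome than in the exposure is treated as a reverse-direction variant
   and dropped.

Between (3) and (4) the exposure and outcome associations are expressed on a
shared effect allele (the exposure study's), flipping outcome betas for
swapped alleles and complementing strand-flipped records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import LdMatrix, SumStatsTable, VariantAssociation

__all__ = [
    "HarmonizedInstrument",
    "SelectionReport",
    "SteigerDiagnostic",
    "select_by_pvalue",
    "ld_clump",
    "remove_palindromic",
    "harmonize",
    "steiger_filter",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

STAGES = (
    "candidates",
    "pass_pvalue",
    "pass_clump",
    "pass_palindrome",
    "pass_overlap_with_outcome",
    "pass_steiger",
)


@dataclass
class HarmonizedInstrument:
    """Exposure and outcome associations for one variant on the exposure
    study's effect allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    pval_exp: float | None = None
    n_exp: int | None = None
    n_out: int | None = None
    harmonization_action: str = "kept_as_is"  # kept_as_is | flipped | strand_complemented

    def __post_init__(self) -> None:
        if self.se_exp <= 0 or self.se_out <= 0:
            raise ValueError(f"{self.variant_id}: standard errors must be positive")


@dataclass
class SelectionReport:
    """Per-stage counts (non-increasing) and per-variant drop reasons."""

    stage_counts: list[tuple[str, int]] = field(default_factory=list)
    drop_reasons: dict[str, tuple[str, str]] = field(default_factory=dict)

    def add_stage(self, stage: str, count: int) -> None:
        if self.stage_counts and count > self.stage_counts[-1][1]:
            raise ValueError(
                f"stage {stage!r} count {count} exceeds previous "
                f"{self.stage_counts[-1]}"
            )
        self.stage_counts.append((stage, count))

    def record_drops(self, stage: str, reasons: dict[str, str]) -> None:
        for vid, why in reasons.items():
            self.drop_reasons[vid] = (stage, why)

    def counts(self) -> dict[str, int]:
        return dict(self.stage_counts)

    def write(self, stage_path, drops_path) -> None:
        with open(stage_path, "w") as fh:
            fh.write("stage\tcount\n")
            for stage, count in self.stage_counts:
                fh.write(f"{stage}\t{count}\n")
        with open(drops_path, "w") as fh:
            fh.write("variant_id\tstage\treason\n")
            for vid in sorted(self.drop_reasons):
                stage, why = self.drop_reasons[vid]
                fh.write(f"{vid}\t{stage}\t{why}\n")


def select_by_pvalue(table: SumStatsTable, threshold: float = 5e-8) -> SumStatsTable:
    """Keep records with exposure p strictly below ``threshold`` (order kept)."""
    if not (0 < threshold < 1):
        raise ValueError("p-value threshold must lie in (0, 1)")
    out = SumStatsTable(
        trait_name=table.trait_name,
        records=[r for r in table.records if r.pval < threshold],
        trait_type=table.trait_type,
    )
    return out


def _pval_order(records: list[VariantAssociation]) -> list[VariantAssociation]:
    return sorted(records, key=lambda r: (r.pval, r.variant_id))


def ld_clump(
    table: SumStatsTable,
    ld: LdMatrix,
    r2_threshold: float = 0.001,
    missing_policy: str = "drop",
) -> SumStatsTable:
    """Greedy LD clumping.

    Candidates are ranked by (p ascending, variant_id); the best remaining
    variant is kept and every other candidate with r² ≥ ``r2_threshold``
    against it is discarded.  Output is in rank order.  Variants absent from
    the LD matrix follow ``missing_policy``: "drop" (default, with a warning),
    "keep" (treated as uncorrelated) or "error".
    """
    if missing_policy not in ("drop", "keep", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    candidates = _pval_order(list(table.records))
    missing = [r.variant_id for r in candidates if r.variant_id not in ld]
    if missing:
        if missing_policy == "error":
            raise KeyError(f"variants missing from LD matrix: {missing[:5]}...")
        if missing_policy == "drop":
            warnings.warn(
                f"{len(missing)} variant(s) absent from LD matrix dropped during clumping",
                stacklevel=2,
            )
            candidates = [r for r in candidates if r.variant_id not in set(missing)]

    kept: list[VariantAssociation] = []
    remaining = candidates
    while remaining:
        best, rest = remaining[0], remaining[1:]
        kept.append(best)
        if best.variant_id in ld:
            remaining = [
                r
                for r in rest
                if r.variant_id not in ld
                or ld.r2_between(best.variant_id, r.variant_id) < r2_threshold
            ]
        else:  # missing under "keep": uncorrelated with everything
            remaining = rest
    return SumStatsTable(table.trait_name, kept, table.trait_type)


def remove_palindromic(table: SumStatsTable) -> SumStatsTable:
    """Drop every A/T and C/G record, regardless of allele frequency."""
    return SumStatsTable(
        trait_name=table.trait_name,
        records=[r for r in table.records if not r.is_palindromic],
        trait_type=table.trait_type,
    )


def harmonize(
    exposure: SumStatsTable, outcome: SumStatsTable
) -> tuple[list[HarmonizedInstrument], dict[str, str]]:
    """Express outcome associations on the exposure study's effect allele.

    For each variant shared between the two tables: matching alleles are kept
    as-is; swapped alleles negate the outcome beta (``flipped``); alleles on
    the opposite strand are base-complemented first (``strand_complemented``,
    with the sign rule applied after complementing); irreconcilable allele
    pairs are dropped with a reason.  Palindromic variants are expected to
    have been removed already.  Output is ordered by exposure p ascending
    (ties by variant id).

    Returns ``(instruments, drops)`` where ``drops`` maps variant id to the
    drop reason.
    """
    out_by_id = {r.variant_id: r for r in outcome.records}
    instruments: list[HarmonizedInstrument] = []
    drops: dict[str, str] = {}
    for exp in _pval_order(list(exposure.records)):
        out = out_by_id.get(exp.variant_id)
        if out is None:
            drops[exp.variant_id] = "absent_from_outcome"
            continue
        e = (exp.effect_allele, exp.other_allele)
        o = (out.effect_allele, out.other_allele)
        oc = (_COMPLEMENT[o[0]], _COMPLEMENT[o[1]])
        if o == e:
            beta_out, action = out.beta, "kept_as_is"
        elif o == (e[1], e[0]):
            beta_out, action = -out.beta, "flipped"
        elif oc == e:
            beta_out, action = out.beta, "strand_complemented"
        elif oc == (e[1], e[0]):
            beta_out, action = -out.beta, "strand_complemented"
        else:
            drops[exp.variant_id] = "allele_mismatch"
            continue
        instruments.append(
            HarmonizedInstrument(
                variant_id=exp.variant_id,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=exp.eaf,
                pval_exp=exp.pval,
                n_exp=exp.n,
                n_out=out.n,
                harmonization_action=action,
            )
        )
    return instruments, drops


@dataclass
class SteigerDiagnostic:
    variant_id: str
    r2_exp: float
    r2_out: float
    direction_pval: float
    kept: bool
    tie: bool = False


def _r2_from_t(beta: float, se: float, n: int) -> float:
    t = beta / se
    return t * t / (t * t + n - 2)


def steiger_filter(
    instruments: list[HarmonizedInstrument],
    n_exp: int | None = None,
    n_out: int | None = None,
    r2_method: str = "tstat",
) -> tuple[list[HarmonizedInstrument], list[SteigerDiagnostic]]:
    """Drop variants whose outcome variance explained exceeds their exposure
    variance explained (reverse-direction evidence).

    Variance explained is derived from the t statistic, r² = t²/(t² + n − 2);
    the same form is used as an approximation for a binary outcome, with
    ``r2_method="eaf"`` switching to the allele-frequency form
    2·eaf·(1−eaf)·beta² where frequencies are available.  The drop rule is
    strict (r²_out > r²_exp); exact ties are retained with a flag.  Each
    diagnostic carries the Steiger z-test p-value from comparing the two
    Fisher-transformed |correlations|.
    """
    if r2_method not in ("tstat", "eaf"):
        raise ValueError(f"unknown r2_method {r2_method!r}")
    kept: list[HarmonizedInstrument] = []
    diagnostics: list[SteigerDiagnostic] = []
    for inst in instruments:
        # explicit arguments override per-instrument sample sizes
        ne = n_exp if n_exp is not None else inst.n_exp
        no = n_out if n_out is not None else inst.n_out
        if ne is None or no is None:
            raise ValueError(f"{inst.variant_id}: sample sizes required for Steiger filtering")
        if ne < 3 or no < 3:
            raise ValueError("Steiger filtering needs n >= 3 in both studies")
        if r2_method == "eaf" and inst.eaf_exp is not None:
            f = inst.eaf_exp
            r2_exp = min(2 * f * (1 - f) * inst.beta_exp**2, 1.0 - 1e-12)
            r2_out = min(2 * f * (1 - f) * inst.beta_out**2, 1.0 - 1e-12)
        else:
            r2_exp = _r2_from_t(inst.beta_exp, inst.se_exp, ne)
            r2_out = _r2_from_t(inst.beta_out, inst.se_out, no)
        z_exp = np.arctanh(min(np.sqrt(r2_exp), 1 - 1e-15))
        z_out = np.arctanh(min(np.sqrt(r2_out), 1 - 1e-15))
        denom = np.sqrt(1.0 / (ne - 3) + 1.0 / (no - 3))
        z = (z_exp - z_out) / denom
        pval = float(2 * stats.norm.sf(abs(z)))
        tie = r2_out == r2_exp
        keep = not (r2_out > r2_exp)
        diagnostics.append(
            SteigerDiagnostic(inst.variant_id, float(r2_exp), float(r2_out), pval, keep, tie)
        )
        if keep:
            kept.append(inst)
    return kept, diagnostics
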