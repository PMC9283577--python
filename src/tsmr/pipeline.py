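"""End-to-end orchestration: one exposure-outcome pair, or a screen across
an exposure matrix, with report tables and run metadata.

The analysis order is fixed: significance filter → LD clumping → palindrome
removal → harmonization → Steiger filter → estimation → sensitivity.  The
estimator battery degrades gracefully with the surviving instrument count
(1 SNP: Wald only; 2: + IVW; ≥3: + Egger, weighted median, leave-one-out,
Cochran's Q; ≥4: + MR-PRESSO) and every skipped component carries a reason —
no silent absence.  The primary decision is the multiplicative
random-effects IVW p-value against the configured alpha; the weighted median
and Egger slope are reported as corroborating methods and never change the
decision.  No multiple-testing correction is applied by default (a screen at
nominal alpha); Bonferroni and Benjamini-Hochberg are available as options.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from .estimators import (
    CausalEstimate,
    HeterogeneityResult,
    OddsRatioResult,
    egger,
    ivw_mre,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from .instruments import (
    SelectionReport,
    harmonize,
    ld_clump,
    remove_palindromic,
    select_by_pvalue,
    steiger_filter,
)
from .sensitivity import LeaveOneOutResult, PressoResult, leave_one_out, mr_presso
from .sumstats import LdMatrix, SumStatsTable, table_checksum

__all__ = ["MrConfig", "PairResult", "MatrixReport", "run_pair", "run_matrix", "render_reports"]

_COMPONENTS = (
    "wald", "ivw", "egger", "weighted_median", "heterogeneity", "presso", "leave_one_out",
)


@dataclass(frozen=True)
class MrConfig:
    """Analysis thresholds; defaults follow the conventional two-sample MR
    screen (genome-wide significance, r² < 0.001 clumping, nominal 0.05)."""

    pval_threshold: float = 5e-8
    clump_r2: float = 0.001
    alpha: float = 0.05
    steiger: bool = True
    n_boot: int = 1000
    presso_n_sim: int = 1000
    outlier_alpha: float = 0.05
    seed: int = 0
    multiple_testing: str = "none"  # none | bonferroni | bh
    missing_ld_policy: str = "drop"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MrConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path


@dataclass
class PairResult:
    exposure_name: str
    selection: SelectionReport
    n_instruments: int
    estimates: dict[str, CausalEstimate] = field(default_factory=dict)
    odds_ratios: dict[str, OddsRatioResult] = field(default_factory=dict)
    heterogeneity: dict[str, HeterogeneityResult] = field(default_factory=dict)
    presso: PressoResult | None = None
    loo: LeaveOneOutResult | None = None
    skipped: dict[str, str] = field(default_factory=dict)
    decision: str = "not_significant"

    def component_status(self) -> dict[str, str]:
        """Each analysis component is either present or has a skip reason."""
        status = {}
        for comp in _COMPONENTS:
            if comp in self.skipped:
                status[comp] = f"skipped: {self.skipped[comp]}"
            else:
                status[comp] = "present"
        return status


@dataclass
class MatrixReport:
    pairs: list[PairResult]
    metadata: dict

    @property
    def significant(self) -> list[PairResult]:
        return [p for p in self.pairs if p.decision == "significant"]

    def total_instruments(self) -> int:
        return sum(p.n_instruments for p in self.pairs)


def run_pair(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    ld: LdMatrix,
    config: MrConfig = MrConfig(),
) -> PairResult:
    """Run the full single-pair analysis; a pair that ends with zero
    instruments yields a structured empty result, never an exception."""
    report = SelectionReport()
    report.add_stage("candidates", len(exposure))

    sig = select_by_pvalue(exposure, config.pval_threshold)
    report.record_drops(
        "pass_pvalue",
        {r.variant_id: "above_pvalue_threshold"
         for r in exposure.records if r.pval >= config.pval_threshold},
    )
    report.add_stage("pass_pvalue", len(sig))

    clumped = ld_clump(sig, ld, config.clump_r2, config.missing_ld_policy)
    kept_ids = set(clumped.ids())
    report.record_drops(
        "pass_clump",
        {v: "ld_clumped" for v in sig.ids() if v not in kept_ids},
    )
    report.add_stage("pass_clump", len(clumped))

    nonpal = remove_palindromic(clumped)
    report.record_drops(
        "pass_palindrome",
        {r.variant_id: "palindromic" for r in clumped.records if r.is_palindromic},
    )
    report.add_stage("pass_palindrome", len(nonpal))

    insts, harm_drops = harmonize(nonpal, outcome)
    report.record_drops("pass_overlap_with_outcome", harm_drops)
    report.add_stage("pass_overlap_with_outcome", len(insts))

    if config.steiger and insts:
        insts, diags = steiger_filter(insts)
        report.record_drops(
            "pass_steiger",
            {d.variant_id: "steiger_reverse_direction" for d in diags if not d.kept},
        )
    report.add_stage("pass_steiger", len(insts))

    result = PairResult(exposure.trait_name, report, n_instruments=len(insts))
    J = len(insts)
    if J == 0:
        for comp in _COMPONENTS:
            result.skipped[comp] = "no_instruments"
        return result

    if J == 1:
        result.estimates["wald"] = wald_ratio(insts[0])
        result.odds_ratios["wald"] = to_odds_ratio(result.estimates["wald"])
    else:
        result.skipped["wald"] = "combined_estimators_used"

    if J >= 2:
        est, het = ivw_mre(insts)
        result.estimates["ivw_mre"] = est
        result.odds_ratios["ivw_mre"] = to_odds_ratio(est)
        result.heterogeneity["ivw"] = het
    else:
        result.skipped["ivw"] = "needs_2_instruments"
        result.skipped["heterogeneity"] = "needs_2_instruments"

    if J >= 3:
        slope, intercept, het_e = egger(insts)
        result.estimates["egger_slope"] = slope
        result.estimates["egger_intercept"] = intercept
        result.odds_ratios["egger_slope"] = to_odds_ratio(slope)
        result.heterogeneity["egger"] = het_e
        wm = weighted_median(insts, n_boot=config.n_boot, seed=config.seed + 7919)
        result.estimates["weighted_median"] = wm
        result.odds_ratios["weighted_median"] = to_odds_ratio(wm)
        result.loo = leave_one_out(insts)
    else:
        for comp in ("egger", "weighted_median", "leave_one_out"):
            result.skipped[comp] = "needs_3_instruments"

    result.presso = mr_presso(
        insts, n_sim=config.presso_n_sim, seed=config.seed + 104729,
        outlier_alpha=config.outlier_alpha,
    )
    if not result.presso.performed:
        result.skipped["presso"] = result.presso.not_performed_reason or "not_performed"

    ivw_est = result.estimates.get("ivw_mre")
    if ivw_est is not None and ivw_est.pval < config.alpha:
        result.decision = "significant"
    if ivw_est is None:
        result.skipped.setdefault("ivw", "needs_2_instruments")
    return result


def run_matrix(
    exposures: Sequence[SumStatsTable],
    outcome: SumStatsTable,
    ld: LdMatrix,
    config: MrConfig = MrConfig(),
) -> MatrixReport:
    """Run every exposure against the outcome and aggregate."""
    if not exposures:
        raise ValueError("at least one exposure table is required")
    pairs = [run_pair(exp, outcome, ld, config) for exp in exposures]

    if config.multiple_testing != "none":
        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[config.multiple_testing]
        with_ivw = [p for p in pairs if "ivw_mre" in p.estimates]
        if with_ivw:
            raw = [p.estimates["ivw_mre"].pval for p in with_ivw]
            reject, _, _, _ = multipletests(raw, alpha=config.alpha, method=method)
            for p, rej in zip(with_ivw, reject):
                p.decision = "significant" if rej else "not_significant"

    metadata = {
        "package_version": __version__,
        "config": asdict(config),
        "outcome": {"name": outcome.trait_name, "checksum": table_checksum(outcome)},
        "exposures": [
            {"name": e.trait_name, "checksum": table_checksum(e)} for e in exposures
        ],
        "total_instruments": sum(p.n_instruments for p in pairs),
        "weighted_median_seed": config.seed + 7919,
        "presso_seed": config.seed + 104729,
    }
    return MatrixReport(pairs=pairs, metadata=metadata)


def _sig3(p: float) -> str:
    return f"{p:.3g}"


def render_reports(report: MatrixReport, out_dir: str | Path) -> list[Path]:
    """Write the table set: per-method estimates (OR scale, 2 decimals, p to
    3 significant figures), sensitivity statistics, MR-PRESSO, leave-one-out,
    selection accounting, the significant subset, and run metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    est_path = out_dir / "estimates.tsv"
    with open(est_path, "w") as fh:
        fh.write("exposure\tmethod\tn_snp\tOR\tci_low\tci_high\tpval\n")
        for pair in report.pairs:
            for method, est in pair.estimates.items():
                if method == "egger_intercept":
                    continue
                orr = pair.odds_ratios[method]
                fh.write(
                    f"{pair.exposure_name}\t{method}\t{est.n_snp}\t"
                    f"{orr.or_point:.2f}\t{orr.or_low:.2f}\t{orr.or_high:.2f}\t"
                    f"{_sig3(est.pval)}\n"
                )
    paths.append(est_path)

    sens_path = out_dir / "sensitivity.tsv"
    with open(sens_path, "w") as fh:
        fh.write("exposure\tmethod\tQ\tQ_pval\tegger_intercept\tintercept_pval\n")
        for pair in report.pairs:
            icept = pair.estimates.get("egger_intercept")
            for key in ("ivw", "egger"):
                het = pair.heterogeneity.get(key)
                if het is None:
                    continue
                i_val = f"{icept.theta:.3f}" if (icept and key == "ivw") else "NA"
                i_p = _sig3(icept.pval) if (icept and key == "ivw") else "NA"
                fh.write(
                    f"{pair.exposure_name}\t{key}\t{het.Q:.2f}\t{_sig3(het.pval)}\t"
                    f"{i_val}\t{i_p}\n"
                )
    paths.append(sens_path)

    presso_path = out_dir / "presso.tsv"
    with open(presso_path, "w") as fh:
        fh.write(
            "exposure\tperformed\tglobal_pval\toutliers\tdistortion_pval\t"
            "theta_raw\ttheta_corrected\treason\n"
        )
        for pair in report.pairs:
            pr = pair.presso
            if pr is None:
                continue
            if pr.performed:
                fh.write(
                    f"{pair.exposure_name}\ttrue\t{_sig3(pr.global_pval)}\t"
                    f"{','.join(pr.outlier_ids) or 'none'}\t"
                    f"{_sig3(pr.distortion_pval) if pr.distortion_pval is not None else 'NA'}\t"
                    f"{pr.theta_raw:.6g}\t{pr.theta_corrected:.6g}\tNA\n"
                )
            else:
                fh.write(
                    f"{pair.exposure_name}\tfalse\tNA\tNA\tNA\tNA\tNA\t"
                    f"{pr.not_performed_reason}\n"
                )
    paths.append(presso_path)

    loo_path = out_dir / "leave_one_out.tsv"
    with open(loo_path, "w") as fh:
        fh.write("exposure\texcluded_variant\ttheta\tse\tpval\n")
        for pair in report.pairs:
            if pair.loo is None:
                continue
            for vid, est in pair.loo.rows:
                fh.write(
                    f"{pair.exposure_name}\t{vid}\t{est.theta:.6g}\t"
                    f"{est.se:.6g}\t{_sig3(est.pval)}\n"
                )
            full = pair.loo.full
            fh.write(
                f"{pair.exposure_name}\t<none>\t{full.theta:.6g}\t"
                f"{full.se:.6g}\t{_sig3(full.pval)}\n"
            )
    paths.append(loo_path)

    sel_path = out_dir / "selection.tsv"
    with open(sel_path, "w") as fh:
        fh.write("exposure\tstage\tcount\n")
        for pair in report.pairs:
            for stage, count in pair.selection.stage_counts:
                fh.write(f"{pair.exposure_name}\t{stage}\t{count}\n")
    paths.append(sel_path)

    sig_path = out_dir / "significant.tsv"
    with open(sig_path, "w") as fh:
        fh.write("exposure\tn_snp\tOR\tci_low\tci_high\tpval\n")
        for pair in report.significant:
            est = pair.estimates["ivw_mre"]
            orr = pair.odds_ratios["ivw_mre"]
            fh.write(
                f"{pair.exposure_name}\t{est.n_snp}\t{orr.or_point:.2f}\t"
                f"{orr.or_low:.2f}\t{orr.or_high:.2f}\t{_sig3(est.pval)}\n"
            )
    paths.append(sig_path)

    meta_path = out_dir / "run_metadata.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(report.metadata, fh, sort_keys=True)
    paths.append(meta_path)

    json_path = out_dir / "results.json"
    with open(json_path, "w") as fh:
        json.dump(_report_to_dict(report), fh, indent=1, sort_keys=True)
    paths.append(json_path)
    return paths


def _to_jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _report_to_dict(report: MatrixReport) -> dict:
    pairs = []
    for p in report.pairs:
        pairs.append(
            {
                "exposure": p.exposure_name,
                "n_instruments": p.n_instruments,
                "decision": p.decision,
                "estimates": {k: asdict(v) for k, v in p.estimates.items()},
                "odds_ratios": {k: asdict(v) for k, v in p.odds_ratios.items()},
                "heterogeneity": {k: asdict(v) for k, v in p.heterogeneity.items()},
                "presso": asdict(p.presso) if p.presso else None,
                "selection": {
                    "stages": p.selection.stage_counts,
                    "drops": {v: list(r) for v, r in p.selection.drop_reasons.items()},
                },
                "skipped": p.skipped,
                "components": p.component_status(),
            }
        )
    return _to_jsonable({"metadata": report.metadata, "pairs": pairs})
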