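"""Instrument selection filters, harmonization and Steiger directionality."""

from __future__ import annotations

import numpy as np
import pytest
from _oracles import greedy_clump_ids

from tsmr.instruments import (
    harmonize,
    ld_clump,
    remove_palindromic,
    select_by_pvalue,
    steiger_filter,
    SelectionReport,
)
from tsmr.simulate import SyntheticScenario, generate_pair
from tsmr.sumstats import LdMatrix, SumStatsTable, VariantAssociation
from conftest import make_instruments


def _rec(vid, pval, ea="A", oa="G", beta=0.1, se=0.01, eaf=0.3):
    return VariantAssociation(vid, ea, oa, beta=beta, se=se, pval=pval, eaf=eaf, n=20000)


class TestPvalueFilter:
    def test_strict_inequality_at_boundary(self):
        t = SumStatsTable("e", [_rec("s1", 1e-9), _rec("s2", 5e-8), _rec("s3", 1e-7)])
        assert select_by_pvalue(t, 5e-8).ids() == ["s1"]

    def test_all_nonsignificant_gives_empty(self):
        t = SumStatsTable("e", [_rec("s1", 0.5), _rec("s2", 0.5)])
        assert len(select_by_pvalue(t)) == 0

    def test_exactly_planted_variants_survive(self):
        study = generate_pair(SyntheticScenario(seed=0, theta_true=0.3, J=30,
                                                n_null_variants=970))
        planted = set(study.truth.loc[study.truth.is_instrument, "variant_id"])
        survivors = set(select_by_pvalue(study.exposure, 5e-8).ids())
        assert survivors == planted

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            select_by_pvalue(SumStatsTable("e", []), 1.5)


def _ld(ids, pairs):
    k = len(ids)
    m = np.eye(k)
    idx = {v: i for i, v in enumerate(ids)}
    for (a, b), r2 in pairs.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = r2
    return LdMatrix(list(ids), m)


class TestLdClump:
    def test_greedy_keeps_index_and_independent_variant(self):
        t = SumStatsTable("e", [_rec("s1", 1e-12), _rec("s2", 1e-10), _rec("s3", 1e-9)])
        ld = _ld(["s1", "s2", "s3"],
                 {("s1", "s2"): 0.5, ("s1", "s3"): 0.0005, ("s2", "s3"): 0.4})
        assert ld_clump(t, ld, 0.001).ids() == ["s1", "s3"]

    def test_uncorrelated_all_kept(self):
        t = SumStatsTable("e", [_rec(f"s{i}", 10**-(9 + i)) for i in range(5)])
        ld = _ld([f"s{i}" for i in range(5)], {})
        assert len(ld_clump(t, ld)) == 5

    def test_perfect_ld_keeps_smaller_pval(self):
        t = SumStatsTable("e", [_rec("s1", 1e-9), _rec("s2", 1e-12)])
        ld = _ld(["s1", "s2"], {("s1", "s2"): 1.0})
        assert ld_clump(t, ld).ids() == ["s2"]

    def test_missing_variant_dropped_with_warning(self):
        t = SumStatsTable("e", [_rec("s1", 1e-9), _rec("sX", 1e-12)])
        ld = _ld(["s1"], {})
        with pytest.warns(UserWarning, match="absent"):
            out = ld_clump(t, ld)
        assert out.ids() == ["s1"]

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        for _ in range(60):
            k = int(rng.integers(2, 16))
            ids = [f"v{i}" for i in range(k)]
            pvals = 10 ** rng.uniform(-12, -4, k)
            corr = rng.uniform(0, 1, (k, k))
            m = (corr + corr.T) / 2
            m[m < 0.3] = 0.0  # sparsify so the threshold bites both ways
            np.fill_diagonal(m, 1.0)
            thr = float(rng.choice([0.001, 0.1, 0.5]))
            table = SumStatsTable("e", [_rec(ids[i], float(pvals[i])) for i in range(k)])
            got = ld_clump(table, LdMatrix(ids, m), thr).ids()
            lookup = {
                frozenset((ids[i], ids[j])): m[i, j]
                for i in range(k) for j in range(i + 1, k)
            }
            expected = greedy_clump_ids(list(zip(ids, pvals)), lookup, thr)
            assert got == expected

    def test_output_has_no_pair_above_threshold(self, rng):
        k = 30
        ids = [f"v{i}" for i in range(k)]
        corr = rng.uniform(0, 1, (k, k))
        m = (corr + corr.T) / 2
        np.fill_diagonal(m, 1.0)
        ld = LdMatrix(ids, m)
        pvals = 10 ** rng.uniform(-12, -4, k)
        table = SumStatsTable("e", [_rec(ids[i], float(pvals[i])) for i in range(k)])
        kept = ld_clump(table, ld, 0.4).ids()
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert ld.r2_between(a, b) < 0.4


class TestPalindromeRemoval:
    @pytest.mark.parametrize("ea,oa,removed", [
        ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
        ("A", "G", False), ("C", "T", False),
    ])
    def test_definition(self, ea, oa, removed):
        t = SumStatsTable("e", [_rec("s1", 1e-9, ea=ea, oa=oa)])
        assert (len(remove_palindromic(t)) == 0) == removed

    def test_accounting_in_selection_report(self):
        recs = [
            _rec("s1", 1e-9, "A", "T"), _rec("s2", 1e-9, "A", "G"),
            _rec("s3", 1e-9, "C", "G"), _rec("s4", 1e-9, "C", "T"),
            _rec("s5", 1e-9, "G", "A"), _rec("s6", 1e-9, "T", "C"),
        ]
        t = SumStatsTable("e", recs)
        out = remove_palindromic(t)
        assert len(out) == 4
        report = SelectionReport()
        report.add_stage("candidates", len(t))
        report.record_drops(
            "pass_palindrome",
            {r.variant_id: "palindromic" for r in recs if r.is_palindromic},
        )
        report.add_stage("pass_palindrome", len(out))
        assert sum(1 for s, _ in report.drop_reasons.values() if s == "pass_palindrome") == 2


def _outcome(vid, ea, oa, beta, se=0.02, pval=0.01):
    return VariantAssociation(vid, ea, oa, beta=beta, se=se, pval=pval, n=200000)


class TestHarmonize:
    def test_matching_swapped_and_complemented_alleles(self):
        exposure = SumStatsTable("e", [
            _rec("s1", 1e-9), _rec("s2", 1e-10), _rec("s3", 1e-11), _rec("s4", 1e-12),
        ])
        outcome = SumStatsTable("o", [
            _outcome("s1", "A", "G", 0.05),   # identical -> kept
            _outcome("s2", "G", "A", 0.05),   # swapped -> flipped
            _outcome("s3", "T", "C", 0.05),   # opposite strand -> complemented
            _outcome("s4", "C", "T", 0.05),   # complement + swap -> negated
        ])
        insts, drops = harmonize(exposure, outcome)
        by_id = {i.variant_id: i for i in insts}
        assert not drops
        assert by_id["s1"].beta_out == 0.05 and by_id["s1"].harmonization_action == "kept_as_is"
        assert by_id["s2"].beta_out == -0.05 and by_id["s2"].harmonization_action == "flipped"
        assert by_id["s3"].beta_out == 0.05 and by_id["s3"].harmonization_action == "strand_complemented"
        assert by_id["s4"].beta_out == -0.05 and by_id["s4"].harmonization_action == "strand_complemented"
        # ordered by exposure p ascending
        assert [i.variant_id for i in insts] == ["s4", "s3", "s2", "s1"]

    def test_irreconcilable_alleles_dropped_with_reason(self):
        exposure = SumStatsTable("e", [_rec("s1", 1e-9, "A", "G")])
        outcome = SumStatsTable("o", [_outcome("s1", "A", "C", 0.05)])
        insts, drops = harmonize(exposure, outcome)
        assert insts == [] and drops == {"s1": "allele_mismatch"}

    def test_variant_absent_from_outcome_dropped(self):
        exposure = SumStatsTable("e", [_rec("s1", 1e-9)])
        insts, drops = harmonize(exposure, SumStatsTable("o", []))
        assert insts == [] and drops == {"s1": "absent_from_outcome"}

    def test_idempotent_on_aligned_pair(self):
        exposure = SumStatsTable("e", [_rec("s1", 1e-9), _rec("s2", 1e-10)])
        outcome = SumStatsTable("o", [
            _outcome("s1", "A", "G", 0.05), _outcome("s2", "A", "G", -0.03),
        ])
        first, _ = harmonize(exposure, outcome)
        # rebuild an outcome table already expressed on the exposure alleles
        aligned = SumStatsTable("o2", [
            VariantAssociation(i.variant_id, "A", "G", beta=i.beta_out,
                               se=i.se_out, pval=0.01, n=i.n_out)
            for i in first
        ])
        second, _ = harmonize(exposure, aligned)
        assert [(i.variant_id, i.beta_out) for i in second] == \
               [(i.variant_id, i.beta_out) for i in first]
        assert all(i.harmonization_action == "kept_as_is" for i in second)


class TestSteigerFilter:
    def test_hand_evaluated_variance_explained(self):
        # t_exp = 10, t_out = 2, n = 10000 each
        insts = make_instruments([0.1], [0.02], se_out=[0.01], se_exp=[0.01])
        kept, diags = steiger_filter(insts, n_exp=10000, n_out=10000)
        d = diags[0]
        assert d.r2_exp == pytest.approx(100 / 10098, rel=1e-12)
        assert d.r2_out == pytest.approx(4 / 10002, rel=1e-12)
        assert kept == insts and 0 < d.direction_pval < 1

    def test_symmetric_association_kept_with_tie_flag(self):
        insts = make_instruments([0.1], [0.1], se_out=[0.01], se_exp=[0.01])
        kept, diags = steiger_filter(insts)
        assert kept == insts and diags[0].tie

    def test_outcome_dominant_variant_dropped(self):
        # t_exp = 1, t_out = 50
        insts = make_instruments([0.01], [0.5], se_out=[0.01], se_exp=[0.01])
        kept, diags = steiger_filter(insts)
        assert kept == [] and not diags[0].kept

    def test_decisions_match_direct_recomputation(self, rng):
        bx = rng.normal(0, 0.1, 40)
        by = rng.normal(0, 0.1, 40)
        insts = make_instruments(bx, by, se_out=[0.02] * 40, se_exp=[0.015] * 40)
        kept, diags = steiger_filter(insts)
        kept_ids = {i.variant_id for i in kept}
        for inst, d in zip(insts, diags):
            tx, ty = inst.beta_exp / inst.se_exp, inst.beta_out / inst.se_out
            r2x = tx**2 / (tx**2 + 20000 - 2)
            r2y = ty**2 / (ty**2 + 20000 - 2)
            assert (inst.variant_id in kept_ids) == (not r2y > r2x)
            assert d.r2_exp == pytest.approx(r2x) and d.r2_out == pytest.approx(r2y)

    def test_small_samples_rejected(self):
        insts = make_instruments([0.1], [0.1], se_out=[0.01])
        with pytest.raises(ValueError):
            steiger_filter(insts, n_exp=2, n_out=2)


def test_pipeline_monotonicity_of_filters(rng):
    """Each filter returns a subset of its input."""
    study = generate_pair(SyntheticScenario(seed=11, theta_true=0.3, J=20,
                                            n_null_variants=180,
                                            palindromic_fraction=0.2))
    t0 = study.exposure
    t1 = select_by_pvalue(t0)
    t2 = ld_clump(t1, study.ld)
    t3 = remove_palindromic(t2)
    for before, after in [(t0, t1), (t1, t2), (t2, t3)]:
        assert set(after.ids()) <= set(before.ids())
        assert len(after) <= len(before)
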