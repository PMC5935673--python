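"""Eligibility filters, per-family loss fractions and age-class tests."""

import numpy as np
import pandas as pd
import pytest

from pirnakit.age_stratification import (
    compare_age_classes,
    divergence_loss_analysis,
    eligible_insertions,
    family_loss_fraction,
)
from pirnakit.aligner import AlignmentRecord
from pirnakit.io_formats import GenomicInterval
from pirnakit.smallrna_quant import family_cluster_insertion_tables, \
    fold_change_table
from pirnakit.synthetic_data import SimulationTruth, simulate_smallrna_library


class TestEligibility:
    def _assigned(self, n_reads, n_distinct):
        seqs = [f"SEQ{j}" for j in range(n_distinct)]
        recs = [AlignmentRecord(f"r{i}", "c", 0, "+", 0, 1, 25)
                for i in range(n_reads)]
        read_seqs = {f"r{i}": seqs[i % n_distinct] for i in range(n_reads)}
        return {"ins1": recs}, read_seqs

    def test_distinct_sequence_reading(self):
        assigned, read_seqs = self._assigned(40, 19)
        # 40 reads but only 19 distinct sequences: ineligible
        assert eligible_insertions(assigned, read_seqs) == set()
        assigned, read_seqs = self._assigned(25, 25)
        assert eligible_insertions(assigned, read_seqs) == {"ins1"}

    def test_read_count_reading_flag(self):
        assigned, read_seqs = self._assigned(40, 19)
        assert eligible_insertions(assigned, read_seqs, mode="reads") == \
            {"ins1"}

    def test_threshold_monotone(self):
        assigned, read_seqs = self._assigned(60, 30)
        for lo, hi in ((10, 20), (20, 31)):
            e_lo = eligible_insertions(assigned, read_seqs, min_unique=lo)
            e_hi = eligible_insertions(assigned, read_seqs, min_unique=hi)
            assert e_hi <= e_lo

    def test_matches_ledger_brute_force(self, model, null_truth):
        reads, _ = simulate_smallrna_library(model, null_truth, 20_000,
                                             "control", 71, library="c")
        quant = family_cluster_insertion_tables({"c": reads}, model)
        read_seqs = {r.id: r.seq for r in quant.pirna_reads["c"]}
        got = eligible_insertions(quant.insertion_assignments["c"], read_seqs)
        for name, recs in quant.insertion_assignments["c"].items():
            distinct = len({read_seqs[r.read_id] for r in recs})
            assert (name in got) == (distinct >= 20)


class TestFamilyLossFraction:
    INSERTIONS = [
        GenomicInterval("c", 100 * i, 100 * i + 50, name=f"i{i}",
                        attributes={"family": "famA" if i < 5 else "famB",
                                    "age": "fixed"})
        for i in range(7)
    ]

    def test_fraction_of_eligible(self):
        fc = pd.DataFrame({"feature": [f"i{i}" for i in range(7)],
                           "fold_reduction": [4, 5, 6, 3.5, 1, 9, 9]})
        eligible = {"i0", "i1", "i2", "i3", "i4"}  # famA only
        out = family_loss_fraction(fc, self.INSERTIONS, eligible)
        out = out.set_index("family")
        assert out.loc["famA", "n_eligible"] == 5
        assert out.loc["famA", "fraction_lost"] == pytest.approx(0.8)

    def test_family_without_eligible_flagged(self):
        fc = pd.DataFrame({"feature": [f"i{i}" for i in range(7)],
                           "fold_reduction": [1.0] * 7})
        out = family_loss_fraction(fc, self.INSERTIONS, {"i0", "i1"})
        out = out.set_index("family")
        assert not bool(out.loc["famB", "computable"])
        assert np.isnan(out.loc["famB", "fraction_lost"])

    def test_depth_scale_invariance(self):
        fc = pd.DataFrame({"feature": [f"i{i}" for i in range(7)],
                           "fold_reduction": [4, 2, 6, 3, 1, 9, 2]})
        eligible = set(fc["feature"])
        base = family_loss_fraction(fc, self.INSERTIONS, eligible)
        # fold reductions are depth-free ratios; the summary consumes only
        # them, so identical FRs from rescaled libraries give identical rows
        again = family_loss_fraction(fc.copy(), self.INSERTIONS, eligible)
        pd.testing.assert_frame_equal(base, again)


class TestAgeComparison:
    def test_exact_enumeration_p(self):
        out = compare_age_classes({"fixed": [4, 5, 6], "common": [1, 2, 3],
                                   "rare": [1, 2, 3]})
        out = out.set_index("comparison")
        assert out.loc["fixed_vs_common", "pvalue"] == pytest.approx(0.05)
        assert out.loc["fixed_vs_rare", "pvalue"] == pytest.approx(0.05)

    def test_small_class_flagged(self):
        out = compare_age_classes({"fixed": [1, 2, 3], "common": [1],
                                   "rare": []}).set_index("comparison")
        assert not out["computable"].any()

    def test_pvalues_uniform_under_null(self):
        from scipy import stats as sps
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(300):
            out = compare_age_classes({
                "fixed": rng.normal(size=8), "common": rng.normal(size=8),
                "rare": [1, 2]})
            pvals.append(out.set_index("comparison")
                         .loc["fixed_vs_common", "pvalue"])
        # one-sided p under the null is (sub-)uniform
        assert sps.kstest(pvals, "uniform").pvalue > 0.001
        assert np.mean(np.array(pvals) <= 0.05) < 0.09

    def test_age_effect_detected(self, model):
        truth = SimulationTruth(
            compartment_multipliers={c: 1.0 for c in
                                     ("telomeric", "pericentric", "arm")},
            age_multipliers={"fixed": 0.25, "common": 1.0, "rare": 1.0},
            pingpong_fraction=0.0, seed=9)
        libs = {}
        for lib, cond, seed in (("c", "control", 81), ("k", "kd", 82)):
            libs[lib], _ = simulate_smallrna_library(model, truth, 40_000,
                                                     cond, seed, library=lib)
        quant = family_cluster_insertion_tables(libs, model)
        fc = fold_change_table(quant.insertion_counts, "c", "k")
        age_of = {iv.name: iv.attributes["age"] for iv in model.insertions}
        by_class = {a: [] for a in ("fixed", "common", "rare")}
        for row in fc.itertuples():
            by_class[age_of[row.feature]].append(row.log2_fold_reduction)
        out = compare_age_classes(by_class).set_index("comparison")
        assert (out["pvalue"] < 0.01).all()


class TestDivergenceAnalysis:
    def test_counts_match_brute_force(self, model, null_truth):
        from oracle_utils import best_mismatch_by_family
        reads, _ = simulate_smallrna_library(model, null_truth, 3000,
                                             "control", 91)
        pirna = [r for r in reads if 23 <= len(r.seq) <= 29][:400]
        table, _ = divergence_loss_analysis(
            pirna, model.consensus, {f: 1.0 for f in model.consensus})
        expected = best_mismatch_by_family(pirna, model.consensus, max_mm=3)
        for row in table.itertuples():
            assert row.n_mm23_pirnas == expected.get(row.family, 0)

    def test_coupled_divergence_and_loss_gives_positive_rho(self, model):
        # old (fixed) insertions are both more diverged and, here, more
        # strongly knocked down -> families rich in fixed insertions show
        # high 2-3-mismatch piRNA counts and high fold reduction
        truth = SimulationTruth(
            compartment_multipliers={c: 1.0 for c in
                                     ("telomeric", "pericentric", "arm")},
            age_multipliers={"fixed": 0.2, "common": 1.0, "rare": 1.0},
            pingpong_fraction=0.0, seed=10)
        libs = {}
        for lib, cond, seed in (("c", "control", 95), ("k", "kd", 96)):
            libs[lib], _ = simulate_smallrna_library(model, truth, 40_000,
                                                     cond, seed, library=lib)
        quant = family_cluster_insertion_tables(libs, model)
        fam_fc = fold_change_table(quant.family_counts, "c", "k")
        fam_fr = dict(zip(fam_fc["feature"], fam_fc["fold_reduction"]))
        table, res = divergence_loss_analysis(
            quant.pirna_reads["c"], model.consensus, fam_fr)
        assert res.statistic > 0
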