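"""Simulator contracts: determinism, geometry, divergence and effect recovery."""

import numpy as np
import pytest
from scipy import stats as sps

from pirnakit.io_formats import revcomp
from pirnakit.synthetic_data import (
    AGE_CLASSES,
    COMPARTMENTS,
    SimConfig,
    SimulationTruth,
    build_genome,
    simulate_chip_pair,
    simulate_rnaseq_library,
    simulate_smallrna_library,
    transcript_isoforms,
)


class TestGenomeConstruction:
    def test_same_seed_identical_genome(self, sim_config):
        a = build_genome(sim_config, seed=5)
        b = build_genome(sim_config, seed=5)
        assert a.chromosomes == b.chromosomes
        assert a.consensus == b.consensus
        assert [iv.attributes for iv in a.insertions] == \
            [iv.attributes for iv in b.insertions]

    def test_every_insertion_has_age_and_family(self, model):
        for iv in model.insertions:
            assert iv.attributes["age"] in AGE_CLASSES
            assert iv.attributes["family"] in model.consensus

    def test_compartments_and_bins_tile_chromosomes(self, model):
        for intervals in (model.compartments, model.cytolocations):
            for chrom, L in model.chrom_lengths.items():
                ivs = sorted((iv for iv in intervals if iv.chrom == chrom),
                             key=lambda iv: iv.start)
                assert ivs[0].start == 0 and ivs[-1].end == L
                for prev, cur in zip(ivs, ivs[1:]):
                    assert prev.end == cur.start  # no gap, no overlap

    def test_each_compartment_has_a_cluster(self, model):
        classes = {model.compartment_of(c.chrom, c.midpoint)
                   for c in model.clusters}
        assert classes == set(COMPARTMENTS)

    def test_fixed_insertion_divergence_within_binomial_bounds(self, model):
        # empirical substitution rate of each fixed-class insertion against
        # its consensus should fall inside a 99.9% binomial interval for d
        for iv in model.insertions:
            if iv.attributes["age"] != "fixed":
                continue
            d = float(iv.attributes["divergence"])
            seq = model.chromosomes[iv.chrom][iv.start:iv.end]
            fam = model.consensus[iv.attributes["family"]]
            mismatches = min(
                sum(a != b for a, b in zip(seq, fam)),
                sum(a != b for a, b in zip(revcomp(seq), fam)),
            )
            lo, hi = sps.binom.ppf([0.0005, 0.9995], len(fam), d)
            assert lo <= mismatches <= hi

    def test_insertions_do_not_overlap_clusters(self, model):
        spans = [(iv.chrom, iv.start, iv.end)
                 for iv in model.insertions + model.clusters]
        for chrom in model.chromosomes:
            ordered = sorted(s for s in spans if s[0] == chrom)
            for (_, _, e1), (_, s2, _) in zip(ordered, ordered[1:]):
                assert e1 <= s2

    def test_too_small_genome_raises_sizing_error(self):
        from pirnakit.synthetic_data import SizingError
        with pytest.raises(SizingError):
            build_genome(SimConfig(chrom_lengths=(90_000,)), seed=0)


class TestSmallRNASimulator:
    def test_same_seed_identical_reads(self, model, null_truth):
        a, _ = simulate_smallrna_library(model, null_truth, 2000, "control", 3)
        b, _ = simulate_smallrna_library(model, null_truth, 2000, "control", 3)
        assert a == b

    def test_pirna_lengths_in_window(self, model, null_truth):
        reads, ledger = simulate_smallrna_library(model, null_truth, 5000,
                                                  "control", 4)
        lengths = {r.id: len(r.seq) for r in reads}
        for row in ledger.itertuples():
            if row.category in ("pirna", "pingpong"):
                assert 23 <= lengths[row.read_id] <= 29

    def test_ledger_complete_and_ids_unique(self, model, null_truth):
        reads, ledger = simulate_smallrna_library(model, null_truth, 3000,
                                                  "control", 5)
        assert len(reads) == len(ledger)
        assert ledger["read_id"].is_unique
        assert {r.id for r in reads} == set(ledger["read_id"])

    def test_null_truth_balances_compartments(self, model, null_truth):
        n = 40_000
        _, ctrl = simulate_smallrna_library(model, null_truth, n, "control", 6)
        _, kd = simulate_smallrna_library(model, null_truth, n, "kd", 7)
        for comp in COMPARTMENTS:
            c = ((ctrl.category == "pirna") & (ctrl.compartment == comp)).sum()
            k = ((kd.category == "pirna") & (kd.compartment == comp)).sum()
            # 5 sigma on the count difference under equal sampling
            assert abs(c - k) < 5 * np.sqrt(c + k)

    def test_knockdown_ratio_matches_multiplier(self, model):
        truth = SimulationTruth(
            compartment_multipliers={"telomeric": 0.2, "pericentric": 1.0,
                                     "arm": 1.0},
            pingpong_fraction=0.0, seed=0)
        n = 100_000
        _, ctrl = simulate_smallrna_library(model, truth, n, "control", 8)
        _, kd = simulate_smallrna_library(model, truth, n, "kd", 9)
        c = ((ctrl.category == "pirna") &
             (ctrl.compartment == "telomeric")).sum()
        k = ((kd.category == "pirna") & (kd.compartment == "telomeric")).sum()
        # binomial oracle: E[k] = 0.2 c, sd from both counts
        sd = np.sqrt(0.2 * c * 0.8 + c)
        assert abs(k - 0.2 * c) < 3 * sd

    def test_pingpong_pairs_overlap_ten(self, model):
        truth = SimulationTruth(pingpong_fraction=1.0, seed=1)
        _, ledger = simulate_smallrna_library(model, truth, 2000, "control", 10)
        pp = ledger[ledger.category == "pingpong"]
        assert len(pp) > 0 and len(pp) % 2 == 0
        for i in range(0, len(pp), 2):
            sense, anti = pp.iloc[i], pp.iloc[i + 1]
            assert sense.strand == "+" and anti.strand == "-"
            # antisense 5' end (rightmost base) minus sense 5' end == 9
            anti_5p = anti.start + anti.length - 1
            assert anti_5p - sense.start == 9

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimulationTruth(pingpong_fraction=1.5)


class TestRnaSeqSimulator:
    def test_s_zero_no_junction_reads(self, model):
        truth = SimulationTruth(spliced_fraction_control=0.0, seed=2)
        reads, ledger = simulate_rnaseq_library(model, truth, 3000, "control",
                                                11, gene_spliced_fraction=0.0)
        assert (ledger.isoform == "unspliced").all()
        junctions = set()
        for feat in model.clusters:
            _, spliced, j, _ = transcript_isoforms(model, feat)
            junctions.add(spliced[j - 50:j + 50])
        for r in reads:
            assert not any(r.seq in jseq for jseq in junctions)

    def test_s_one_no_intron_interior_reads(self, model):
        truth = SimulationTruth(spliced_fraction_control=1.0, seed=2)
        reads, _ = simulate_rnaseq_library(model, truth, 3000, "control", 12,
                                           gene_spliced_fraction=1.0)
        introns = [model.chromosomes[f.chrom][
            int(f.attributes["intron_start"]):int(f.attributes["intron_end"])]
            for f in list(model.clusters) + list(model.genes)]
        for r in reads:
            assert not any(r.seq in intron for intron in introns)

    def test_recovered_spliced_fraction(self, model):
        s = 0.35
        truth = SimulationTruth(spliced_fraction_control=s, seed=2)
        _, ledger = simulate_rnaseq_library(model, truth, 20_000, "control", 13)
        cl = ledger[ledger.feature.str.startswith("cluster")]
        frac = (cl.isoform == "spliced").mean()
        assert abs(frac - s) < 3 * np.sqrt(s * (1 - s) / len(cl))


class TestChipSimulator:
    def test_same_seed_identical(self, model, null_truth):
        a, ai = simulate_chip_pair(model, null_truth, 2000, 14)
        b, bi = simulate_chip_pair(model, null_truth, 2000, 14)
        assert a == b and ai == bi

    def test_null_chip_igg_indistinguishable(self, model, null_truth):
        from pirnakit.aligner import align_genome_unique, unique_only
        from pirnakit.chip_enrichment import window_counts
        chip, igg = simulate_chip_pair(model, null_truth, 20_000, 15)
        counts = {}
        for name, reads in (("chip", chip), ("igg", igg)):
            recs = unique_only(align_genome_unique(reads, model.chromosomes))
            counts[name] = window_counts(recs, model.chrom_lengths)["count"]
        res = sps.ks_2samp(counts["chip"], counts["igg"])
        assert res.pvalue > 0.01

    def test_telomeric_enrichment_recovered(self, model):
        truth = SimulationTruth(seed=3)  # e_tel = 5
        chip, igg = simulate_chip_pair(model, truth, 30_000, 16)
        # Poisson oracle on expected telomeric read share
        segs = model.compartments
        tel_len = sum(len(s) for s in segs if s.name == "telomeric")
        total_w = sum(len(s) * truth.chip_enrichment[s.name] for s in segs)
        expect = 30_000 * tel_len * 5.0 / total_w
        # count chip reads that start inside a telomeric segment by alignment
        from pirnakit.aligner import align_genome_unique, unique_only
        recs = unique_only(align_genome_unique(chip, model.chromosomes))
        tel = sum(
            1 for r in recs
            if any(s.chrom == r.target and s.start <= r.pos < s.end
                   and s.name == "telomeric" for s in segs))
        # alignment loses a few multi-mapping reads; allow 5 sigma + 5% slack
        assert abs(tel - expect) < 5 * np.sqrt(expect) + 0.05 * expect
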