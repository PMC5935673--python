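"""Aligner contracts against exhaustive brute-force oracles."""

import numpy as np
import pytest

from pirnakit.aligner import (
    align_consensus,
    align_genome_unique,
    assign_to_features,
    unique_only,
)
from pirnakit.io_formats import GenomicInterval, Read, revcomp

# ---------------------------------------------------------------------------
# exhaustive oracle: scan every target x strand x position with numpy
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    # N encoded so it never equals any base, including another N
    table = {"A": 0, "C": 1, "G": 2, "T": 3}
    return np.array([table.get(c, -1 - i) for i, c in enumerate(seq)],
                    dtype=np.int64)


def brute_force_hits(read: Read, targets: dict[str, str], max_mm: int):
    """All (target, pos, strand, mm) placements with mm <= max_mm."""
    hits = []
    for strand, query in (("+", read.seq), ("-", revcomp(read.seq))):
        q = _encode(query)
        for name, seq in targets.items():
            if len(seq) < len(q):
                continue
            t = _encode(seq)
            windows = np.lib.stride_tricks.sliding_window_view(t, len(q))
            mm = (windows != q).sum(axis=1)
            for pos in np.nonzero(mm <= max_mm)[0]:
                hits.append((name, int(pos), strand, int(mm[pos])))
    return hits


def brute_force_best_stratum(read: Read, targets: dict[str, str], max_mm: int):
    hits = brute_force_hits(read, targets, max_mm)
    if not hits:
        return set()
    best = min(h[3] for h in hits)
    return {h for h in hits if h[3] == best}


def _random_reads(rng, targets, n, mutate_prob=0.5, length_range=(23, 29)):
    names = list(targets)
    reads = []
    for i in range(n):
        L = int(rng.integers(*length_range, endpoint=True))
        if rng.random() < 0.15:  # unrelated read
            seq = "".join("ACGT"[j] for j in rng.integers(0, 4, L))
        else:
            name = names[rng.integers(len(names))]
            start = int(rng.integers(0, len(targets[name]) - L + 1))
            seq = list(targets[name][start:start + L])
            if rng.random() < mutate_prob:
                for pos in rng.integers(0, L, size=rng.integers(1, 4)):
                    seq[pos] = "ACGT"[(("ACGT".index(seq[pos])) + 1) % 4]
            seq = "".join(seq)
            if rng.random() < 0.5:
                seq = revcomp(seq)
        reads.append(Read(f"r{i}", seq, "I" * L))
    return reads


@pytest.fixture(scope="module")
def toy_consensus():
    rng = np.random.default_rng(42)
    return {f"fam{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 400))
            for i in range(4)}


class TestConsensusAlignment:
    def test_exact_substring_single_hit(self, toy_consensus):
        seq = toy_consensus["fam1"][100:125]
        (rec,) = align_consensus([Read("r", seq, "I" * 25)], toy_consensus)
        assert (rec.target, rec.pos, rec.strand, rec.mismatches) == \
            ("fam1", 100, "+", 0)

    def test_three_mismatches_rejected_at_max_two(self, toy_consensus):
        seq = list(toy_consensus["fam1"][100:125])
        for pos in (2, 10, 20):
            seq[pos] = "ACGT"[("ACGT".index(seq[pos]) + 1) % 4]
        recs = align_consensus([Read("r", "".join(seq), "I" * 25)],
                               toy_consensus, max_mm=2)
        assert recs == []

    def test_minus_strand_position(self, toy_consensus):
        seq = revcomp(toy_consensus["fam2"][50:75])
        (rec,) = align_consensus([Read("r", seq, "I" * 25)], toy_consensus)
        assert (rec.target, rec.pos, rec.strand) == ("fam2", 50, "-")

    def test_record_set_identical_to_exhaustive_scan(self, toy_consensus):
        rng = np.random.default_rng(1)
        reads = _random_reads(rng, toy_consensus, 300)
        records = align_consensus(reads, toy_consensus, max_mm=2)
        got = {}
        for r in records:
            got.setdefault(r.read_id, set()).add(
                (r.target, r.pos, r.strand, r.mismatches))
        for read in reads:
            expected = brute_force_best_stratum(read, toy_consensus, 2)
            assert got.get(read.id, set()) == expected, read.id

    def test_strand_symmetry(self, toy_consensus):
        rng = np.random.default_rng(2)
        reads = _random_reads(rng, toy_consensus, 50)
        fwd = align_consensus(reads, toy_consensus)
        rc_reads = [Read(r.id, revcomp(r.seq), r.qual) for r in reads]
        rev = align_consensus(rc_reads, toy_consensus)
        flip = {"+": "-", "-": "+"}
        assert {(r.read_id, r.target, r.pos, flip[r.strand], r.mismatches)
                for r in fwd} == \
               {(r.read_id, r.target, r.pos, r.strand, r.mismatches)
                for r in rev}

    def test_zero_mm_subset_of_two_mm(self, toy_consensus):
        rng = np.random.default_rng(3)
        reads = _random_reads(rng, toy_consensus, 100)
        strict = {(r.read_id, r.target, r.pos, r.strand)
                  for r in align_consensus(reads, toy_consensus, max_mm=0)}
        loose = {(r.read_id, r.target, r.pos, r.strand)
                 for r in align_consensus(reads, toy_consensus, max_mm=2)
                 if r.mismatches == 0}
        assert strict == loose


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(9)
    seq = "".join("ACGT"[j] for j in rng.integers(0, 4, 8000))
    # duplicate a 200-bp block so some reads are non-unique
    seq = seq[:5000] + seq[1000:1200] + seq[5200:]
    return {"chrA": seq[:6000], "chrB": seq[6000:]}


class TestGenomeAlignment:

    def test_unique_read_n_hits_one(self, toy_genome):
        seq = toy_genome["chrA"][3000:3025]
        recs = align_genome_unique([Read("r", seq, "I" * 25)], toy_genome)
        assert len(recs) == 1 and recs[0].n_hits == 1

    def test_duplicated_read_n_hits_two_and_excluded(self, toy_genome):
        seq = toy_genome["chrA"][1050:1075]  # inside the duplicated block
        recs = align_genome_unique([Read("r", seq, "I" * 25)], toy_genome)
        assert len(recs) == 2 and all(r.n_hits == 2 for r in recs)
        assert unique_only(recs) == []

    def test_agreement_with_exhaustive_substring_search(self, toy_genome):
        rng = np.random.default_rng(4)
        reads = _random_reads(rng, toy_genome, 200, mutate_prob=0.3)
        records = align_genome_unique(reads, toy_genome)
        got = {}
        for r in records:
            got.setdefault(r.read_id, set()).add((r.target, r.pos, r.strand))
        for read in reads:
            expected = {(t, p, s) for t, p, s, mm
                        in brute_force_hits(read, toy_genome, 0)}
            assert got.get(read.id, set()) == expected
            if read.id in got:
                n = {r.n_hits for r in records if r.read_id == read.id}
                assert n == {len(expected)}


class TestFeatureAssignment:
    FEATURES = [GenomicInterval("chrA", 100, 200, name="f1"),
                GenomicInterval("chrA", 300, 420, name="f2"),
                GenomicInterval("chrB", 0, 150, name="f3")]

    def _rec(self, rid, chrom, pos, length=25):
        from pirnakit.aligner import AlignmentRecord
        return AlignmentRecord(rid, chrom, pos, "+", 0, 1, length)

    def test_contained_alignment_counted(self):
        out = assign_to_features([self._rec("a", "chrA", 150)], self.FEATURES)
        assert [r.read_id for r in out["f1"]] == ["a"]

    def test_straddling_alignment_not_counted(self):
        out = assign_to_features([self._rec("a", "chrA", 190)], self.FEATURES)
        assert all(len(v) == 0 for v in out.values())

    def test_overlapping_feature_set_rejected(self):
        bad = self.FEATURES + [GenomicInterval("chrA", 150, 250, name="f4")]
        with pytest.raises(ValueError, match="overlap"):
            assign_to_features([], bad)

    def test_counts_match_brute_force_containment(self):
        rng = np.random.default_rng(6)
        records = [self._rec(f"r{i}", ("chrA", "chrB")[rng.integers(2)],
                             int(rng.integers(0, 500)),
                             int(rng.integers(20, 30)))
                   for i in range(10_000)]
        out = assign_to_features(records, self.FEATURES)
        for iv in self.FEATURES:
            expected = [r.read_id for r in records
                        if r.target == iv.chrom and r.pos >= iv.start
                        and r.pos + r.length <= iv.end]
            assert sorted(r.read_id for r in out[iv.name]) == sorted(expected)
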