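"""Miniature genome and library simulator with known ground truth.

Emulates the data a germline-knockdown small-RNA study produces, at desk
scale: a few ~300-kb chromosomes carrying transposon insertions (consensus
copies diverged by an age-class-dependent substitution rate), piRNA clusters
built from fragmented consensus copies in both orientations with an
annotated intron, a telomeric / pericentric / arm compartment map tiling
each chromosome, fixed-width cytolocation bins, and surrogate protein-coding
genes used as splicing negative controls.

Three simulators emit FASTQ libraries plus a per-read truth ledger:

* small RNA: a fixed miRNA fraction (exact copies of the miRNA references),
  a uniform background fraction, and 23-29-nt piRNAs sampled from clusters
  and insertions with weights scaled, in the knockdown condition, by
  per-compartment multipliers (and optional per-age-class multipliers); a
  fraction ``phi`` of piRNA reads is emitted as sense/antisense pairs on
  consensus coordinates whose 5' ends overlap by exactly 10 nt (the
  ping-pong signature);
* RNA-seq: fragments from cluster precursors, spliced with condition-
  dependent probability (s in control, s' in knockdown), and from surrogate
  genes whose spliced fraction is condition-independent;
* ChIP/IgG: IgG reads uniform over the genome, ChIP reads weighted by a
  per-compartment enrichment factor.

Every simulator is a pure function of (config, truth, seed): the same seed
reproduces byte-identical output.  Reads are exact substrings of the genome
or consensus (no sequencing-error model), so mismatch counts downstream are
interpretable as evolutionary divergence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GenomicInterval,
    Read,
    log,
    read_bed,
    read_fasta,
    revcomp,
    write_bed,
    write_fasta,
    write_fastq,
    write_tsv,
)

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

COMPARTMENTS = ("telomeric", "pericentric", "arm")
AGE_CLASSES = ("fixed", "common", "rare")


class SizingError(ValueError):
    """Requested features do not fit in the configured genome."""


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth effect sizes the simulators encode.

    ``compartment_multipliers`` scale piRNA sampling weights in the KD
    library (1.0 everywhere = no knockdown effect); ``age_multipliers``
    optionally add an age-class-specific knockdown effect on insertions.
    ``spliced_fraction_control``/``_kd`` give the per-cluster probability
    that an RNA-seq fragment comes from the spliced isoform.
    ``pingpong_fraction`` is the fraction of piRNA reads emitted as 10-nt
    5'-overlap sense/antisense pairs.  ``chip_enrichment`` gives the
    per-compartment ChIP sampling weight relative to IgG.
    """

    compartment_multipliers: dict[str, float] = field(
        default_factory=lambda: {"telomeric": 0.2, "pericentric": 0.25, "arm": 1.0})
    age_multipliers: dict[str, float] = field(
        default_factory=lambda: {"fixed": 1.0, "common": 1.0, "rare": 1.0})
    spliced_fraction_control: float = 0.2
    spliced_fraction_kd: float = 0.5
    pingpong_fraction: float = 0.3
    chip_enrichment: dict[str, float] = field(
        default_factory=lambda: {"telomeric": 5.0, "pericentric": 5.0, "arm": 1.0})
    mirna_fraction: float = 0.15
    background_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.spliced_fraction_control, self.spliced_fraction_kd,
                     self.pingpong_fraction, self.mirna_fraction,
                     self.background_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        for m in (*self.compartment_multipliers.values(),
                  *self.age_multipliers.values(),
                  *self.chip_enrichment.values()):
            if m <= 0:
                raise ValueError("multipliers must be > 0")
        if set(self.compartment_multipliers) != set(COMPARTMENTS):
            raise ValueError("compartment_multipliers must cover all compartments")

    @classmethod
    def null(cls, seed: int = 0) -> "SimulationTruth":
        """No-effect truth: every downstream fold change should be ~1."""
        return cls(
            compartment_multipliers={c: 1.0 for c in COMPARTMENTS},
            age_multipliers={a: 1.0 for a in AGE_CLASSES},
            spliced_fraction_control=0.2,
            spliced_fraction_kd=0.2,
            pingpong_fraction=0.0,
            chip_enrichment={c: 1.0 for c in COMPARTMENTS},
            seed=seed,
        )


@dataclass(frozen=True)
class SimConfig:
    """Genome layout parameters for :func:`build_genome`."""

    chrom_lengths: tuple[int, ...] = (300_000, 300_000, 300_000)
    n_families: int = 12
    n_telomeric_families: int = 2
    consensus_length: int = 1500
    insertions_per_family: int = 8
    age_proportions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    divergence_by_age: dict[str, float] = field(
        default_factory=lambda: {"fixed": 0.08, "common": 0.04, "rare": 0.01})
    fixed_pericentric_bias: float = 0.7
    clusters_per_compartment: dict[str, int] = field(
        default_factory=lambda: {"telomeric": 1, "pericentric": 1, "arm": 2})
    cluster_length: int = 15_000
    cluster_fragment_range: tuple[int, int] = (300, 800)
    cluster_divergence: float = 0.10
    cluster_intron_length: int = 2_000
    n_genes: int = 5
    gene_length: int = 3_000
    gene_intron_length: int = 500
    gene_spliced_fraction: float = 0.8
    n_mirnas: int = 20
    mirna_length_range: tuple[int, int] = (21, 23)
    telomere_fraction: float = 0.10
    pericentric_fraction: float = 0.20
    cytolocation_bin: int = 30_000

    def __post_init__(self) -> None:
        if not 0 <= max(self.divergence_by_age.values()) <= 0.15:
            raise ValueError("divergence rates must lie in [0, 0.15]")
        if abs(sum(self.age_proportions) - 1.0) > 1e-9:
            raise ValueError("age_proportions must sum to 1")


@dataclass
class GenomeModel:
    """A miniature genome with all annotations the pipeline consumes."""

    chromosomes: dict[str, str]
    compartments: list[GenomicInterval]
    cytolocations: list[GenomicInterval]
    clusters: list[GenomicInterval]
    insertions: list[GenomicInterval]
    genes: list[GenomicInterval]
    consensus: dict[str, str]
    mirnas: dict[str, str]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def compartment_of(self, chrom: str, pos: int) -> str:
        """Compartment class of a position (half-open map intervals)."""
        for iv in self.compartments:
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                return iv.name
        raise ValueError(f"position {chrom}:{pos} outside compartment map")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.chromosomes.items(), outdir / "genome.fa")
        write_fasta(self.consensus.items(), outdir / "consensus.fa")
        write_fasta(self.mirnas.items(), outdir / "mirna.fa")
        write_bed(self.compartments, outdir / "compartments.bed")
        write_bed(self.cytolocations, outdir / "cytolocations.bed")
        write_bed(self.clusters, outdir / "clusters.bed")
        write_bed(self.insertions, outdir / "insertions.bed")
        write_bed(self.genes, outdir / "genes.bed")

    @classmethod
    def load(cls, outdir: str | Path) -> "GenomeModel":
        outdir = Path(outdir)
        return cls(
            chromosomes=dict(read_fasta(outdir / "genome.fa")),
            compartments=read_bed(outdir / "compartments.bed"),
            cytolocations=read_bed(outdir / "cytolocations.bed"),
            clusters=read_bed(outdir / "clusters.bed",
                              allowed_attributes={"intron_start", "intron_end"}),
            insertions=read_bed(outdir / "insertions.bed",
                                allowed_attributes={"family", "age", "divergence"},
                                required_attributes={"family", "age"}),
            genes=read_bed(outdir / "genes.bed",
                           allowed_attributes={"intron_start", "intron_end"}),
            consensus=dict(read_fasta(outdir / "consensus.fa")),
            mirnas=dict(read_fasta(outdir / "mirna.fa")),
        )


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq
    idx = np.array([_BASE_INDEX[c] for c in seq])
    hit = rng.random(len(seq)) < rate
    idx[hit] = (idx[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return "".join(_BASES[idx])


class _Allocator:
    """Tracks free space per compartment class and places features in it."""

    def __init__(self) -> None:
        self.free: dict[str, list[tuple[str, int, int]]] = defaultdict(list)

    def add(self, cls: str, chrom: str, start: int, end: int) -> None:
        self.free[cls].append((chrom, start, end))

    def place(self, cls: str, length: int, rng: np.random.Generator,
              gap: int = 100) -> tuple[str, int]:
        segments = self.free[cls]
        usable = [i for i, (_, s, e) in enumerate(segments)
                  if e - s >= length + 2 * gap]
        if not usable:
            raise SizingError(
                f"no room for a {length}-bp feature in {cls!r} compartment; "
                "increase chromosome lengths or reduce feature counts"
            )
        caps = np.array([segments[i][2] - segments[i][1] - length - 2 * gap + 1
                         for i in usable], dtype=float)
        pick = usable[rng.choice(len(usable), p=caps / caps.sum())]
        chrom, s, e = segments.pop(pick)
        offset = int(rng.integers(0, e - s - length - 2 * gap + 1))
        start = s + gap + offset
        if start - s > 2 * gap:
            self.free[cls].append((chrom, s, start))
        if e - (start + length) > 2 * gap:
            self.free[cls].append((chrom, start + length, e))
        return chrom, start


def _round_to(value: float, unit: int) -> int:
    return max(unit, int(round(value / unit)) * unit)


def build_genome(config: SimConfig = SimConfig(), seed: int = 0) -> GenomeModel:
    """Build the miniature genome, annotations and reference sets.

    Compartment geometry: the outer ``telomere_fraction`` of each chromosome
    end is telomeric; a central ``pericentric_fraction`` band around the
    simulated metacentric centromere is pericentric; the remainder is arm.
    Boundaries are rounded to the cytolocation bin width so compartments and
    bins share edges.  Insertions of telomere-restricted families are placed
    in telomeric compartments; evolutionarily fixed insertions are biased
    into the pericentric compartment.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    seqs = {name: list(_random_seq(rng, L))
            for name, L in zip(chrom_names, config.chrom_lengths)}

    # compartment map + cytolocation bins
    compartments: list[GenomicInterval] = []
    cytolocations: list[GenomicInterval] = []
    alloc = _Allocator()
    for name, L in zip(chrom_names, config.chrom_lengths):
        bin_w = config.cytolocation_bin
        tel = _round_to(L * config.telomere_fraction, bin_w)
        peri_len = _round_to(L * config.pericentric_fraction, bin_w)
        c0 = _round_to(L / 2 - peri_len / 2, bin_w)
        c1 = c0 + peri_len
        if not (tel < c0 and c1 < L - tel):
            raise SizingError(f"chromosome {name} too short for compartment layout")
        spans = [(0, tel, "telomeric"), (tel, c0, "arm"), (c0, c1, "pericentric"),
                 (c1, L - tel, "arm"), (L - tel, L, "telomeric")]
        for s, e, cls in spans:
            compartments.append(GenomicInterval(name, s, e, ".", cls))
            alloc.add(cls, name, s, e)
        for i, s in enumerate(range(0, L, bin_w)):
            cytolocations.append(
                GenomicInterval(name, s, min(s + bin_w, L), ".", f"{name}_b{i:02d}"))

    consensus = {f"family{i + 1:02d}": _random_seq(rng, config.consensus_length)
                 for i in range(config.n_families)}
    telomeric_families = set(list(consensus)[:config.n_telomeric_families])
    mirnas = {
        f"mir{i + 1:03d}": _random_seq(
            rng, int(rng.integers(config.mirna_length_range[0],
                                  config.mirna_length_range[1] + 1)))
        for i in range(config.n_mirnas)
    }

    # clusters: concatenated fragmented consensus copies, both orientations
    clusters: list[GenomicInterval] = []
    fam_names = list(consensus)
    k = 0
    for cls in COMPARTMENTS:
        for _ in range(config.clusters_per_compartment.get(cls, 0)):
            k += 1
            chunks: list[str] = []
            size = 0
            while size < config.cluster_length:
                fam = fam_names[rng.integers(0, len(fam_names))]
                lo, hi = config.cluster_fragment_range
                frag_len = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, len(consensus[fam]) - frag_len + 1))
                frag = consensus[fam][start:start + frag_len]
                if rng.random() < 0.5:
                    frag = revcomp(frag)
                frag = _mutate(frag, config.cluster_divergence, rng)
                chunks.append(frag)
                size += frag_len
            seq = "".join(chunks)[:config.cluster_length]
            chrom, start = alloc.place(cls, len(seq), rng)
            seqs[chrom][start:start + len(seq)] = list(seq)
            intron_start = start + (len(seq) - config.cluster_intron_length) // 2
            clusters.append(GenomicInterval(
                chrom, start, start + len(seq), "+", f"cluster{k:02d}",
                attributes={
                    "intron_start": str(intron_start),
                    "intron_end": str(intron_start + config.cluster_intron_length),
                }))

    # surrogate protein-coding genes (background sequence, annotated intron)
    genes: list[GenomicInterval] = []
    for g in range(config.n_genes):
        chrom, start = alloc.place("arm", config.gene_length, rng)
        intron_start = start + (config.gene_length - config.gene_intron_length) // 2
        genes.append(GenomicInterval(
            chrom, start, start + config.gene_length, "+", f"gene{g + 1:02d}",
            attributes={
                "intron_start": str(intron_start),
                "intron_end": str(intron_start + config.gene_intron_length),
            }))

    # insertions: consensus copies with age-class-dependent divergence
    insertions: list[GenomicInterval] = []
    i = 0
    for fam in fam_names:
        for _ in range(config.insertions_per_family):
            i += 1
            age = AGE_CLASSES[rng.choice(3, p=np.array(config.age_proportions))]
            if fam in telomeric_families:
                cls = "telomeric"
            elif age == "fixed" and rng.random() < config.fixed_pericentric_bias:
                cls = "pericentric"
            else:
                cls = "arm"
            d = config.divergence_by_age[age]
            seq = _mutate(consensus[fam], d, rng)
            if rng.random() < 0.5:
                seq = revcomp(seq)
                strand = "-"
            else:
                strand = "+"
            chrom, start = alloc.place(cls, len(seq), rng)
            seqs[chrom][start:start + len(seq)] = list(seq)
            insertions.append(GenomicInterval(
                chrom, start, start + len(seq), strand, f"ins{i:03d}",
                attributes={"family": fam, "age": age, "divergence": f"{d:g}"}))

    model = GenomeModel(
        chromosomes={name: "".join(chars) for name, chars in seqs.items()},
        compartments=compartments,
        cytolocations=cytolocations,
        clusters=clusters,
        insertions=insertions,
        genes=genes,
        consensus=consensus,
        mirnas=mirnas,
    )
    log.info("built genome: %d chromosomes, %d clusters, %d insertions, %d genes",
             len(model.chromosomes), len(clusters), len(insertions), len(genes))
    return model


# ---------------------------------------------------------------------------
# Small RNA library
# ---------------------------------------------------------------------------

def _pirna_loci(model: GenomeModel, truth: SimulationTruth, condition: str
                ) -> tuple[list[GenomicInterval], np.ndarray, list[str]]:
    """piRNA source loci (clusters + insertions) with sampling weights.

    Base weight is locus length; in the KD condition it is additionally
    scaled by the compartment multiplier and, for insertions, the age-class
    multiplier.
    """
    loci = list(model.clusters) + list(model.insertions)
    weights = np.empty(len(loci))
    comps = []
    for j, locus in enumerate(loci):
        comp = model.compartment_of(locus.chrom, locus.midpoint)
        comps.append(comp)
        w = float(len(locus))
        if condition == "kd":
            w *= truth.compartment_multipliers[comp]
            age = locus.attributes.get("age")
            if age is not None:
                w *= truth.age_multipliers.get(age, 1.0)
        weights[j] = w
    return loci, weights, comps


def simulate_smallrna_library(
    model: GenomeModel,
    truth: SimulationTruth,
    n_reads: int,
    condition: str,
    seed: int,
    library: str | None = None,
    pirna_len_range: tuple[int, int] = (23, 29),
    background_len_range: tuple[int, int] = (18, 30),
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate one small-RNA library; returns (reads, truth ledger).

    Composition (miRNA / background / ping-pong / regular piRNA counts) is
    deterministic given ``n_reads``; which locus each piRNA read comes from
    is stochastic with the truth-defined weights.  The ledger has one row
    per emitted read recording its true source.
    """
    if condition not in ("control", "kd"):
        raise ValueError(f"condition must be 'control' or 'kd', got {condition!r}")
    rng = np.random.default_rng(seed)
    library = library or f"{condition}_s{seed}"

    n_mirna = round(truth.mirna_fraction * n_reads)
    n_bg = round(truth.background_fraction * n_reads)
    n_pi = n_reads - n_mirna - n_bg

    loci, weights, comps = _pirna_loci(model, truth, condition)
    if condition == "kd":
        # knockdown thins the piRNA pool: miRNA and background absolute
        # abundances are unaffected, so the KD library is smaller and the
        # per-locus expected read count scales exactly by its multiplier
        base = np.array([float(len(locus)) for locus in loci])
        thinning = weights.sum() / base.sum()
        n_pi = round(n_pi * thinning)
    n_pairs = round(truth.pingpong_fraction * n_pi / 2)
    n_regular = n_pi - 2 * n_pairs
    p = weights / weights.sum()
    lmin, lmax = pirna_len_range

    reads: list[Read] = []
    ledger_rows: list[tuple] = []
    serial = 0

    def emit(seq: str, category: str, source: str, family: str, comp: str,
             chrom: str, start: int, strand: str) -> None:
        nonlocal serial
        serial += 1
        rid = f"{library}_{serial:07d}"
        reads.append(Read(rid, seq, "I" * len(seq)))
        ledger_rows.append((rid, category, source, family, comp, chrom,
                            start, strand, len(seq)))

    # regular piRNAs from genomic loci
    locus_idx = rng.choice(len(loci), size=n_regular, p=p)
    lengths = rng.integers(lmin, lmax + 1, size=n_regular)
    strands = rng.integers(0, 2, size=n_regular)
    offsets = rng.random(n_regular)
    for j in range(n_regular):
        locus = loci[locus_idx[j]]
        L = int(lengths[j])
        start = locus.start + int(offsets[j] * (len(locus) - L + 1))
        seq = model.chromosomes[locus.chrom][start:start + L]
        strand = "+" if strands[j] == 0 else "-"
        if strand == "-":
            seq = revcomp(seq)
        emit(seq, "pirna", locus.name, locus.attributes.get("family", ""),
             comps[locus_idx[j]], locus.chrom, start, strand)

    # ping-pong pairs on consensus coordinates: sense 5' at p, antisense 5'
    # at p + 9 (forward coordinate), i.e. a 10-nt 5' overlap
    fam_weight: dict[str, float] = defaultdict(float)
    for j, locus in enumerate(loci):
        fam = locus.attributes.get("family")
        if fam:
            fam_weight[fam] += weights[j]
    pp_fams = sorted(fam_weight)
    pp_p = np.array([fam_weight[f] for f in pp_fams])
    pp_p = pp_p / pp_p.sum()
    for _ in range(n_pairs):
        fam = pp_fams[rng.choice(len(pp_fams), p=pp_p)]
        cons = model.consensus[fam]
        l1 = int(rng.integers(lmin, lmax + 1))
        l2 = int(rng.integers(lmin, lmax + 1))
        pos = int(rng.integers(lmax - 10, len(cons) - lmax))
        sense = cons[pos:pos + l1]
        antisense = revcomp(cons[pos + 10 - l2:pos + 10])
        emit(sense, "pingpong", fam, fam, "", fam, pos, "+")
        emit(antisense, "pingpong", fam, fam, "", fam, pos + 10 - l2, "-")

    # exact miRNA copies
    mirna_names = sorted(model.mirnas)
    for idx in rng.integers(0, len(mirna_names), size=n_mirna):
        name = mirna_names[idx]
        emit(model.mirnas[name], "mirna", name, "", "", name, 0, "+")

    # uniform genomic background
    chroms = sorted(model.chromosomes)
    chrom_p = np.array([len(model.chromosomes[c]) for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()
    bmin, bmax = background_len_range
    for _ in range(n_bg):
        chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
        L = int(rng.integers(bmin, bmax + 1))
        start = int(rng.integers(0, len(model.chromosomes[chrom]) - L + 1))
        seq = model.chromosomes[chrom][start:start + L]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if strand == "-":
            seq = revcomp(seq)
        emit(seq, "background", "background", "", "", chrom, start, strand)

    ledger = pd.DataFrame(
        ledger_rows,
        columns=["read_id", "category", "source", "family", "compartment",
                 "chrom", "start", "strand", "length"])
    log.info("simulated small-RNA library %s: %d reads "
             "(%d piRNA, %d ping-pong, %d miRNA, %d background)",
             library, len(reads), n_regular, 2 * n_pairs, n_mirna, n_bg)
    return reads, ledger


# ---------------------------------------------------------------------------
# RNA-seq library
# ---------------------------------------------------------------------------

def transcript_isoforms(model: GenomeModel, feature: GenomicInterval
                        ) -> tuple[str, str, int, tuple[int, int]]:
    """Unspliced and spliced isoform sequences of a cluster or gene.

    Returns ``(precursor, spliced, junction, intron_span)`` in transcript
    (5'->3') coordinates; ``junction`` is the position in the spliced
    isoform where the two exons meet, ``intron_span`` the half-open intron
    interval in the precursor.
    """
    try:
        i0 = int(feature.attributes["intron_start"])
        i1 = int(feature.attributes["intron_end"])
    except KeyError:
        raise ValueError(f"feature {feature.name!r} has no intron annotation")
    if not (feature.start <= i0 < i1 <= feature.end):
        raise ValueError(f"intron of {feature.name!r} outside feature span")
    precursor = model.chromosomes[feature.chrom][feature.start:feature.end]
    j0, j1 = i0 - feature.start, i1 - feature.start
    if feature.strand == "-":
        precursor = revcomp(precursor)
        j0, j1 = len(precursor) - j1, len(precursor) - j0
    spliced = precursor[:j0] + precursor[j1:]
    return precursor, spliced, j0, (j0, j1)


def simulate_rnaseq_library(
    model: GenomeModel,
    truth: SimulationTruth,
    n_fragments: int,
    condition: str,
    seed: int,
    read_length: int = 100,
    gene_spliced_fraction: float = 0.8,
    library: str | None = None,
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate a stranded RNA-seq library over cluster precursors and genes.

    Each fragment comes from the spliced isoform with probability ``s``
    (control) or ``s'`` (knockdown) for clusters, and with a condition-
    independent probability for the surrogate genes (negative control).
    """
    if condition not in ("control", "kd"):
        raise ValueError(f"condition must be 'control' or 'kd', got {condition!r}")
    rng = np.random.default_rng(seed)
    library = library or f"rna_{condition}_s{seed}"
    s_cluster = (truth.spliced_fraction_control if condition == "control"
                 else truth.spliced_fraction_kd)

    features = list(model.clusters) + list(model.genes)
    isoforms = {f.name: transcript_isoforms(model, f) for f in features}
    weights = np.array([float(len(f)) for f in features])
    p = weights / weights.sum()

    reads: list[Read] = []
    rows: list[tuple] = []
    feat_idx = rng.choice(len(features), size=n_fragments, p=p)
    spliced_draw = rng.random(n_fragments)
    offsets = rng.random(n_fragments)
    for j in range(n_fragments):
        feat = features[feat_idx[j]]
        s = s_cluster if feat.name.startswith("cluster") else gene_spliced_fraction
        precursor, spliced, _, _ = isoforms[feat.name]
        is_spliced = spliced_draw[j] < s
        source = spliced if is_spliced else precursor
        if len(source) < read_length:
            raise SizingError(f"feature {feat.name} shorter than read length")
        start = int(offsets[j] * (len(source) - read_length + 1))
        seq = source[start:start + read_length]
        rid = f"{library}_{j + 1:07d}"
        reads.append(Read(rid, seq, "I" * read_length))
        rows.append((rid, feat.name, "spliced" if is_spliced else "unspliced", start))
    ledger = pd.DataFrame(rows, columns=["read_id", "feature", "isoform", "start"])
    log.info("simulated RNA-seq library %s: %d fragments", library, len(reads))
    return reads, ledger


# ---------------------------------------------------------------------------
# ChIP / IgG pair
# ---------------------------------------------------------------------------

def simulate_chip_pair(
    model: GenomeModel,
    truth: SimulationTruth,
    n_reads: int,
    seed: int,
    read_length: int = 50,
) -> tuple[list[Read], list[Read]]:
    """Simulate a (ChIP, IgG) library pair.

    IgG reads are uniform over the genome; ChIP reads sample compartment
    segments with weight proportional to segment length times the
    compartment enrichment factor, uniformly within the segment.
    """
    rng = np.random.default_rng(seed)
    segments = [iv for iv in model.compartments if len(iv) >= read_length]

    def sample(weight_by_class: dict[str, float], prefix: str) -> list[Read]:
        w = np.array([len(iv) * weight_by_class[iv.name] for iv in segments])
        p = w / w.sum()
        seg_idx = rng.choice(len(segments), size=n_reads, p=p)
        offsets = rng.random(n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        out = []
        for j in range(n_reads):
            iv = segments[seg_idx[j]]
            hi = min(iv.end, len(model.chromosomes[iv.chrom])) - read_length
            start = iv.start + int(offsets[j] * (hi - iv.start + 1))
            seq = model.chromosomes[iv.chrom][start:start + read_length]
            if strands[j] == 1:
                seq = revcomp(seq)
            out.append(Read(f"{prefix}_{j + 1:07d}", seq, "I" * read_length))
        return out

    chip = sample(truth.chip_enrichment, f"chip_s{seed}")
    igg = sample({c: 1.0 for c in COMPARTMENTS}, f"igg_s{seed}")
    log.info("simulated ChIP pair: %d reads each", n_reads)
    return chip, igg


# ---------------------------------------------------------------------------
# Dataset writer (CLI `simulate`)
# ---------------------------------------------------------------------------

def write_dataset(
    outdir: str | Path,
    sim_config: SimConfig = SimConfig(),
    truth: SimulationTruth = SimulationTruth(),
    n_smallrna: int = 100_000,
    n_rnaseq: int = 20_000,
    n_chip: int = 50_000,
) -> GenomeModel:
    """Generate a complete dataset under one directory.

    Writes genome.fa, consensus.fa, mirna.fa, the annotation BEDs, paired
    control/KD small-RNA and RNA-seq FASTQs, a ChIP/IgG FASTQ pair, the
    per-read truth ledgers and a truth.tsv summary.  Deterministic in
    ``truth.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = truth.seed
    model = build_genome(sim_config, seed=seed)
    model.write(outdir)

    for i, condition in enumerate(("control", "kd")):
        reads, ledger = simulate_smallrna_library(
            model, truth, n_smallrna, condition, seed=seed + 11 + i,
            library=f"smallrna_{condition}")
        write_fastq(reads, outdir / f"smallrna_{condition}.fastq")
        write_tsv(ledger, outdir / f"smallrna_{condition}.ledger.tsv")
        rreads, rledger = simulate_rnaseq_library(
            model, truth, n_rnaseq, condition, seed=seed + 21 + i,
            read_length=100, gene_spliced_fraction=sim_config.gene_spliced_fraction,
            library=f"rnaseq_{condition}")
        write_fastq(rreads, outdir / f"rnaseq_{condition}.fastq")
        write_tsv(rledger, outdir / f"rnaseq_{condition}.ledger.tsv")

    chip, igg = simulate_chip_pair(model, truth, n_chip, seed=seed + 31)
    write_fastq(chip, outdir / "chip.fastq")
    write_fastq(igg, outdir / "igg.fastq")

    rows = [("seed", seed)]
    rows += [(f"m_{c}", truth.compartment_multipliers[c]) for c in COMPARTMENTS]
    rows += [(f"m_age_{a}", truth.age_multipliers.get(a, 1.0)) for a in AGE_CLASSES]
    rows += [("spliced_fraction_control", truth.spliced_fraction_control),
             ("spliced_fraction_kd", truth.spliced_fraction_kd),
             ("pingpong_fraction", truth.pingpong_fraction),
             ("mirna_fraction", truth.mirna_fraction),
             ("background_fraction", truth.background_fraction)]
    rows += [(f"e_{c}", truth.chip_enrichment[c]) for c in COMPARTMENTS]
    write_tsv(pd.DataFrame(rows, columns=["parameter", "value"]),
              outdir / "truth.tsv")
    return model
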