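"""piRNA size filtering, count tables, normalization and fold changes.

Reads surviving the 23-29-nt size filter are quantified three ways: per
transposon family (consensus alignment, up to two mismatches, a read
counted once per family it aligns to), per piRNA cluster and per individual
insertion (zero-mismatch genome alignment, uniquely mapping reads only,
full-containment assignment).  Counts are normalized per million either by
library depth or by the library's miRNA-mapping read count; fold reduction
between control and knockdown is computed on normalized counts with a
pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aligner
from .io_formats import Read, RunConfig, log, log_stage
from .synthetic_data import GenomeModel


@dataclass
class CountMatrix:
    """Per-feature, per-library raw counts plus normalization denominators.

    ``normalized(method)`` scales each library to reads per million of
    either total depth or miRNA-mapping reads; a library with zero miRNA
    reads falls back to depth normalization with a logged warning.
    """

    counts: pd.DataFrame  # features x libraries, raw integer counts
    depth: dict[str, int]
    mirna_counts: dict[str, int]

    def normalized(self, method: str = "mirna", scale: float = 1e6) -> pd.DataFrame:
        out = {}
        for lib in self.counts.columns:
            denom = self._denominator(lib, method)
            out[lib] = normalize(self.counts[lib].to_numpy(float), denom, scale)
        return pd.DataFrame(out, index=self.counts.index)

    def _denominator(self, lib: str, method: str) -> float:
        if method == "depth":
            denom = self.depth[lib]
        elif method == "mirna":
            denom = self.mirna_counts.get(lib, 0)
            if denom == 0:
                log.warning("library %s has no miRNA-mapping reads; "
                            "falling back to depth normalization", lib)
                denom = self.depth[lib]
        else:
            raise ValueError(f"unknown normalization method {method!r}")
        if denom <= 0:
            raise ValueError(
                f"normalization denominator for {lib!r} is zero; "
                "supply a non-empty library or use the other method")
        return float(denom)


@dataclass
class FoldChangeRecord:
    """Control/KD normalized counts and both fold-change conventions."""

    feature: str
    control: float
    kd: float
    pseudocount: float = 1.0
    fold_reduction: float = field(init=False)
    fold_upregulation: float = field(init=False)

    def __post_init__(self) -> None:
        if self.control < 0 or self.kd < 0:
            raise ValueError("normalized counts must be non-negative")
        self.fold_reduction = (self.control + self.pseudocount) / \
            (self.kd + self.pseudocount)
        self.fold_upregulation = 1.0 / self.fold_reduction


def filter_pirna_length(reads: list[Read], min_len: int = 23, max_len: int = 29,
                        library: str = "library") -> list[Read]:
    """Keep reads in the piRNA size window; logs survival counts."""
    kept = [r for r in reads if min_len <= len(r.seq) <= max_len]
    log_stage("piRNA length filter", library, len(reads), len(kept))
    return kept


def count_mirna_reads(reads: list[Read], mirnas: dict[str, str],
                      both_orientations: bool = False) -> int:
    """Number of reads exactly matching a miRNA reference full-length."""
    refs = {seq.upper() for seq in mirnas.values()}
    if both_orientations:
        from .io_formats import revcomp
        refs |= {revcomp(s) for s in refs}
    return sum(1 for r in reads if r.seq in refs)


def normalize(raw, denominator: float, scale: float = 1e6):
    """Reads-per-``scale`` normalization: raw * scale / denominator."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0; use depth fallback for "
                         "libraries without miRNA reads")
    return np.asarray(raw, dtype=float) * scale / denominator


def fold_change(control_norm: float, kd_norm: float, pseudocount: float = 1.0,
                feature: str = "") -> FoldChangeRecord:
    """Fold reduction (control + psi) / (KD + psi) and its reciprocal."""
    return FoldChangeRecord(feature, control_norm, kd_norm, pseudocount)


def fold_change_table(cm: CountMatrix, control: str, kd: str | list[str],
                      pseudocount: float = 1.0, method: str = "mirna",
                      ) -> pd.DataFrame:
    """Per-feature fold changes; replicate KDs are averaged on log2 scale.

    With several knockdown libraries the fold reduction is computed per
    replicate and the mean log2 fold reduction reported (``fold_reduction``
    is then 2 ** mean log2).
    """
    kds = [kd] if isinstance(kd, str) else list(kd)
    norm = cm.normalized(method=method)
    ctrl = norm[control]
    log2_frs = []
    for k in kds:
        fr = (ctrl + pseudocount) / (norm[k] + pseudocount)
        log2_frs.append(np.log2(fr))
    log2_fr = pd.concat(log2_frs, axis=1).mean(axis=1)
    table = pd.DataFrame({
        "feature": norm.index,
        "control_norm": ctrl.to_numpy(),
        "kd_norm": norm[kds].mean(axis=1).to_numpy(),
        "log2_fold_reduction": log2_fr.to_numpy(),
        "fold_reduction": np.exp2(log2_fr.to_numpy()),
    })
    table["fold_upregulation"] = 1.0 / table["fold_reduction"]
    return table.reset_index(drop=True)


@dataclass
class SmallRNAQuant:
    """All per-library products of the small-RNA quantification stage."""

    pirna_reads: dict[str, list[Read]]
    consensus_alignments: dict[str, list[aligner.AlignmentRecord]]
    unique_genome_alignments: dict[str, list[aligner.AlignmentRecord]]
    cluster_assignments: dict[str, dict[str, list[aligner.AlignmentRecord]]]
    insertion_assignments: dict[str, dict[str, list[aligner.AlignmentRecord]]]
    family_counts: CountMatrix
    cluster_counts: CountMatrix
    insertion_counts: CountMatrix


def family_cluster_insertion_tables(
    libraries: dict[str, list[Read]],
    model: GenomeModel,
    config: RunConfig = RunConfig(),
    genome_index: aligner.GenomeIndex | None = None,
) -> SmallRNAQuant:
    """Build the family, cluster and insertion count tables for all libraries.

    Family counts come from consensus alignments at up to
    ``config.consensus_max_mm`` mismatches (best stratum, one count per
    family a read aligns to).  Cluster and insertion counts come from
    zero-mismatch genome alignments restricted to uniquely mapping reads
    (``n_hits == 1``), assigned by full containment.
    """
    families = sorted(model.consensus)
    cluster_ivs = list(model.clusters)
    insertion_ivs = list(model.insertions)
    if genome_index is None:
        genome_index = aligner.GenomeIndex(model.chromosomes)

    depth: dict[str, int] = {}
    mirna: dict[str, int] = {}
    pirna_reads: dict[str, list[Read]] = {}
    cons_aln: dict[str, list[aligner.AlignmentRecord]] = {}
    uniq_aln: dict[str, list[aligner.AlignmentRecord]] = {}
    cl_assign: dict[str, dict[str, list[aligner.AlignmentRecord]]] = {}
    ins_assign: dict[str, dict[str, list[aligner.AlignmentRecord]]] = {}
    fam_counts: dict[str, pd.Series] = {}
    cl_counts: dict[str, pd.Series] = {}
    ins_counts: dict[str, pd.Series] = {}

    for lib, reads in libraries.items():
        depth[lib] = len(reads)
        mirna[lib] = count_mirna_reads(reads, model.mirnas)
        pirna = filter_pirna_length(reads, config.pirna_min_len,
                                    config.pirna_max_len, library=lib)
        pirna_reads[lib] = pirna

        cons = aligner.align_consensus(pirna, model.consensus,
                                       max_mm=config.consensus_max_mm)
        cons_aln[lib] = cons
        per_family = {(r.read_id, r.target) for r in cons}
        fam_series = pd.Series(0, index=families, dtype=int)
        for _, fam in per_family:
            fam_series[fam] += 1
        fam_counts[lib] = fam_series
        log_stage("consensus alignment", lib, len(pirna),
                  len({r.read_id for r in cons}))

        genome_recs = aligner.align_genome_unique(pirna, genome_index)
        unique = aligner.unique_only(genome_recs)
        uniq_aln[lib] = unique
        log_stage("unique genome alignment", lib, len(pirna), len(unique))

        cl = aligner.assign_to_features(unique, cluster_ivs)
        ins = aligner.assign_to_features(unique, insertion_ivs)
        cl_assign[lib], ins_assign[lib] = cl, ins
        cl_counts[lib] = pd.Series({name: len(v) for name, v in cl.items()},
                                   dtype=int).reindex([c.name for c in cluster_ivs])
        ins_counts[lib] = pd.Series({name: len(v) for name, v in ins.items()},
                                    dtype=int).reindex([i.name for i in insertion_ivs])

    return SmallRNAQuant(
        pirna_reads=pirna_reads,
        consensus_alignments=cons_aln,
        unique_genome_alignments=uniq_aln,
        cluster_assignments=cl_assign,
        insertion_assignments=ins_assign,
        family_counts=CountMatrix(pd.DataFrame(fam_counts), depth, mirna),
        cluster_counts=CountMatrix(pd.DataFrame(cl_counts), depth, mirna),
        insertion_counts=CountMatrix(pd.DataFrame(ins_counts), depth, mirna),
    )
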