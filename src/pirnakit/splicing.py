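"""Spliced vs. unspliced precursor quantification: SSR and FPKM.

Cluster precursors are transcribed with their intron; loss of the
heterochromatic state de-represses splicing, so the knockdown accumulates
the spliced isoform.  Splice-aware alignment at desk scale is realized by
exact matching against both the unspliced (genomic) precursor and a
precomputed spliced-isoform sequence: a read is *spliced* when it matches
the spliced isoform across the exon-exon junction with at least ``anchor``
nt on each side, *unspliced* when it lies wholly inside the intron or
crosses an exon-intron boundary with at least ``anchor`` nt in the intron,
and *unassigned* otherwise (exon-interior reads are compatible with both
isoforms).

SSR = spliced / unspliced per cluster; FPKM = count * 1e9 /
(isoform length * total mapped reads).  Surrogate protein-coding genes with
condition-independent splicing serve as the negative control.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

import numpy as np
import pandas as pd

from .io_formats import Read, log_stage
from .synthetic_data import GenomeModel, transcript_isoforms


@dataclass
class SpliceQuant:
    """Junction-read counts, SSR and FPKM for one feature in one library."""

    feature: str
    condition: str
    spliced: int
    unspliced: int
    unassigned: int
    ssr: float
    ssr_defined: bool
    fpkm_spliced: float
    fpkm_unspliced: float


def _occurrences(needle: str, haystack: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def count_junction_reads(reads: list[Read], precursor: str, spliced_seq: str,
                         junction: int, intron_span: tuple[int, int],
                         anchor: int = 5) -> tuple[int, int, int]:
    """Classify reads of one feature as (spliced, unspliced, unassigned).

    ``junction`` is the exon-exon junction position in the spliced isoform;
    ``intron_span`` the half-open intron interval in the precursor, both in
    transcript coordinates.  Reads not matching the feature at all are not
    counted.
    """
    if reads and anchor > len(reads[0].seq) // 2:
        raise ValueError(f"anchor {anchor} longer than half the read length")
    i0, i1 = intron_span
    spliced = unspliced = unassigned = 0
    for read in reads:
        L = len(read.seq)
        is_spliced = any(
            start <= junction - anchor and start + L >= junction + anchor
            for start in _occurrences(read.seq, spliced_seq)
        )
        if is_spliced:
            spliced += 1
            continue
        hit_precursor = False
        is_unspliced = False
        for start in _occurrences(read.seq, precursor):
            hit_precursor = True
            end = start + L
            if start >= i0 and end <= i1:  # wholly intronic
                is_unspliced = True
                break
            in_intron = min(end, i1) - max(start, i0)
            crosses = (start < i0 < end) or (start < i1 < end)
            if crosses and in_intron >= anchor:
                is_unspliced = True
                break
        if is_unspliced:
            unspliced += 1
        elif hit_precursor or _occurrences(read.seq, spliced_seq):
            unassigned += 1
    return spliced, unspliced, unassigned


def ssr(spliced: int, unspliced: int) -> tuple[float, bool]:
    """Spliced-to-unspliced ratio; flagged undefined when unspliced = 0."""
    if spliced < 0 or unspliced < 0:
        raise ValueError("counts must be non-negative")
    if unspliced == 0:
        return nan, False
    return spliced / unspliced, True


def ssr_fold_change(ssr_kd: float, ssr_control: float) -> float:
    """Knockdown-over-control SSR fold change."""
    if not (np.isfinite(ssr_kd) and np.isfinite(ssr_control)) or ssr_control == 0:
        return nan
    return ssr_kd / ssr_control


def fpkm(count: int, length_bp: int, total_mapped: int) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if length_bp <= 0 or total_mapped <= 0:
        raise ValueError("length and total mapped reads must be > 0")
    return count * 1e9 / (length_bp * total_mapped)


def spliced_fold_increase(fpkm_kd: float, fpkm_control: float,
                          pseudocount: float = 0.1) -> float:
    """Fold increase of the spliced transcript, pseudocount-stabilized."""
    return (fpkm_kd + pseudocount) / (fpkm_control + pseudocount)


def quantify_splicing(model: GenomeModel,
                      reads_by_condition: dict[str, list[Read]],
                      anchor: int = 5) -> pd.DataFrame:
    """SSR and FPKM per cluster and surrogate gene per condition.

    ``reads_by_condition`` maps condition labels (e.g. control / kd) to
    RNA-seq read lists; FPKM totals use all mapped reads in the library.
    """
    features = list(model.clusters) + list(model.genes)
    rows = []
    for condition, reads in reads_by_condition.items():
        total = len(reads)
        n_assigned = 0
        for feat in features:
            precursor, spliced_seq, junction, intron_span = \
                transcript_isoforms(model, feat)
            s, u, a = count_junction_reads(reads, precursor, spliced_seq,
                                           junction, intron_span, anchor)
            n_assigned += s + u + a
            ratio, defined = ssr(s, u)
            rows.append(SpliceQuant(
                feature=feat.name, condition=condition, spliced=s,
                unspliced=u, unassigned=a, ssr=ratio, ssr_defined=defined,
                fpkm_spliced=fpkm(s, len(spliced_seq), total),
                fpkm_unspliced=fpkm(u, len(precursor), total),
            ))
        log_stage("splice quantification", condition, total, n_assigned)
    return pd.DataFrame([vars(r) for r in rows])


def splicing_fold_table(quant: pd.DataFrame, control: str = "control",
                        kd: str = "kd", pseudocount: float = 0.1) -> pd.DataFrame:
    """Per-feature SSR fold change and spliced-FPKM fold increase (KD vs control)."""
    ctrl = quant[quant["condition"] == control].set_index("feature")
    kdq = quant[quant["condition"] == kd].set_index("feature")
    rows = []
    for feat in ctrl.index:
        rows.append({
            "feature": feat,
            "ssr_control": ctrl.loc[feat, "ssr"],
            "ssr_kd": kdq.loc[feat, "ssr"],
            "ssr_fold_change": ssr_fold_change(kdq.loc[feat, "ssr"],
                                               ctrl.loc[feat, "ssr"]),
            "spliced_fold_increase": spliced_fold_increase(
                kdq.loc[feat, "fpkm_spliced"], ctrl.loc[feat, "fpkm_spliced"],
                pseudocount),
        })
    return pd.DataFrame(rows)
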