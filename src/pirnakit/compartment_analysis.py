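"""Cytolocation consolidation, compartment classification and loess smoothing.

Insertion-level piRNA counts are consolidated per cytolocation bin (an
insertion belongs to the unique bin containing its midpoint), the
>1000-control-read filter is applied, each bin and cluster is classified
into the telomeric / pericentric / arm compartment containing its midpoint,
and log2 fold reduction is smoothed along each chromosome with local
quadratic regression under tricube weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval
from .smallrna_quant import CountMatrix


def classify_compartment(interval: GenomicInterval,
                         compartment_map: Sequence[GenomicInterval]) -> str:
    """Compartment class of the half-open map interval containing the midpoint."""
    mid = interval.midpoint
    for iv in compartment_map:
        if iv.chrom == interval.chrom and iv.start <= mid < iv.end:
            return iv.name
    raise ValueError(
        f"midpoint of {interval.name or interval.display()} outside compartment map")


def consolidate_by_cytolocation(
    insertion_counts: CountMatrix,
    insertions: Sequence[GenomicInterval],
    bins: Sequence[GenomicInterval],
    compartment_map: Sequence[GenomicInterval],
    control: str,
    kd: str | list[str],
    min_control_reads: int = 1000,
    pseudocount: float = 1.0,
    method: str = "mirna",
) -> pd.DataFrame:
    """Per-cytolocation consolidated counts, fold reduction and filter flag.

    Every insertion is assigned to the unique bin containing its midpoint
    (an insertion outside all bins is a validation error).  ``passes_filter``
    encodes the rule that a cytolocation needs more than
    ``min_control_reads`` uniquely mapping piRNA reads in the control
    library raw counts.
    """
    kds = [kd] if isinstance(kd, str) else list(kd)
    by_name = {iv.name: iv for iv in insertions}
    bin_of: dict[str, str] = {}
    for ins in insertions:
        mid = ins.midpoint
        home = [b for b in bins if b.chrom == ins.chrom and b.start <= mid < b.end]
        if len(home) != 1:
            raise ValueError(
                f"insertion {ins.name} midpoint lies in {len(home)} cytolocation bins")
        bin_of[ins.name] = home[0].name

    raw = insertion_counts.counts
    norm = insertion_counts.normalized(method=method)
    rows = []
    for b in bins:
        members = [name for name, home in bin_of.items() if home == b.name]
        ctrl_raw = int(raw.loc[members, control].sum()) if members else 0
        ctrl_norm = float(norm.loc[members, control].sum()) if members else 0.0
        kd_norm = float(norm.loc[members, kds].sum(axis=0).mean()) if members else 0.0
        log2_fr = float(np.mean([
            np.log2((ctrl_norm + pseudocount) /
                    (norm.loc[members, k].sum() + pseudocount))
            for k in kds])) if members else 0.0
        rows.append({
            "cytolocation": b.name,
            "chrom": b.chrom,
            "start": b.start,
            "end": b.end,
            "compartment": classify_compartment(b, compartment_map),
            "n_insertions": len(members),
            "control_raw": ctrl_raw,
            "control_norm": ctrl_norm,
            "kd_norm": kd_norm,
            "log2_fold_reduction": log2_fr,
            "fold_reduction": 2.0 ** log2_fr,
            "passes_filter": ctrl_raw > min_control_reads,
        })
    return pd.DataFrame(rows)


@dataclass
class SmoothedTrack:
    """Positions, raw values and loess-fitted values along one axis."""

    positions: np.ndarray
    values: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int


def loess_smooth(positions, values, span: float = 0.3, degree: int = 2
                 ) -> SmoothedTrack:
    """Local polynomial regression with tricube weights (no robustness pass).

    At each input position the ``ceil(span * n)`` nearest neighbours are fit
    with a weighted least-squares polynomial of the given degree, weights
    tricube in scaled distance; the fitted value at that position is
    returned.  Constant input reproduces the constant; exactly polynomial
    input of degree <= ``degree`` is reproduced up to rounding.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    n = len(x)
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    if np.any(np.diff(x) < 0):
        raise ValueError("positions must be sorted ascending")
    k = max(int(np.ceil(span * n)), degree + 1)
    k = min(k, n)
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        if h == 0:
            # all neighbours at the same position: weighted mean
            fitted[i] = y[idx].mean()
            continue
        w = (1.0 - np.minimum(d[idx] / h, 1.0) ** 3) ** 3
        # boundary neighbourhoods can zero out the farthest point; keep a
        # strictly positive floor so the design stays well posed
        w = np.maximum(w, 1e-9)
        design = np.vander(x[idx] - x[i], degree + 1, increasing=True)
        sw = np.sqrt(w)
        coeffs, _, rank, _ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw,
                                             rcond=None)
        if rank < degree + 1:
            raise ValueError(
                "local design matrix is singular; increase the loess span")
        fitted[i] = coeffs[0]
    return SmoothedTrack(x, y, fitted, span, degree)


def compartment_loss_report(cytolocation_summary: pd.DataFrame,
                            cluster_fold_changes: pd.DataFrame,
                            clusters: Sequence[GenomicInterval],
                            compartment_map: Sequence[GenomicInterval],
                            loss_threshold: float = 2.5,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-compartment summary of piRNA loss plus the ordered cluster table.

    The summary has one row per compartment class present among filtered
    cytolocations: feature count, median fold reduction and the fraction of
    features above ``loss_threshold``.  The cluster table carries each
    cluster's compartment and fold reduction ordered by genomic position.
    """
    passing = cytolocation_summary[cytolocation_summary["passes_filter"]]
    rows = []
    for comp, group in passing.groupby("compartment"):
        fr = group["fold_reduction"].to_numpy()
        rows.append({
            "compartment": comp,
            "n_features": len(fr),
            "median_fold_reduction": float(np.median(fr)),
            "fraction_above_threshold": float(np.mean(fr >= loss_threshold)),
        })
    columns = ["compartment", "n_features", "median_fold_reduction",
               "fraction_above_threshold"]
    report = pd.DataFrame(rows, columns=columns) \
        .sort_values("compartment").reset_index(drop=True)

    by_name = {c.name: c for c in clusters}
    ct = cluster_fold_changes.copy()
    ct["chrom"] = [by_name[f].chrom for f in ct["feature"]]
    ct["start"] = [by_name[f].start for f in ct["feature"]]
    ct["compartment"] = [classify_compartment(by_name[f], compartment_map)
                         for f in ct["feature"]]
    ct = ct.sort_values(["chrom", "start"]).reset_index(drop=True)
    return report, ct
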