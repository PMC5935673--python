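"""Window-based ChIP enrichment with IgG subtraction.

ChIP and IgG alignments are binned into a 10-kb window grid per chromosome
(windows assigned by alignment midpoint, half-open), each library is
depth-normalized to reads per million, and the per-window enrichment is
E = ChIP_norm - IgG_norm (subtraction, not ratio; E may be negative).
Per-cytolocation mean enrichment is then related to piRNA loss with a
Spearman rank correlation.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aligner import AlignmentRecord
from .io_formats import GenomicInterval
from .stats import TestResult, spearman_rho


def window_grid(chrom_lengths: dict[str, int], window: int = 10_000
                ) -> pd.DataFrame:
    """Non-overlapping window tiling; the last window of a chromosome may be short."""
    rows = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        for start in range(0, L, window):
            rows.append({"chrom": chrom, "start": start, "end": min(start + window, L)})
    return pd.DataFrame(rows)


def window_counts(records: Iterable[AlignmentRecord],
                  chrom_lengths: dict[str, int], window: int = 10_000,
                  ) -> pd.DataFrame:
    """Per-window alignment counts, depth-normalized to reads per million.

    Each alignment is assigned to the window containing its midpoint.
    Depth normalization uses the total number of assigned alignments, so
    window totals conserve the library size by construction.
    """
    grid = window_grid(chrom_lengths, window)
    key = {(row.chrom, row.start): i for i, row in enumerate(grid.itertuples())}
    counts = np.zeros(len(grid))
    total = 0
    for rec in records:
        mid = rec.pos + rec.length // 2
        idx = key.get((rec.target, (mid // window) * window))
        if idx is not None:
            counts[idx] += 1
            total += 1
    grid = grid.copy()
    grid["count"] = counts.astype(int)
    grid["norm"] = counts * 1e6 / total if total else counts
    return grid


def subtract_control(chip: pd.DataFrame, igg: pd.DataFrame) -> pd.DataFrame:
    """Enrichment track E = ChIP_norm - IgG_norm on an identical window grid."""
    if not (chip[["chrom", "start", "end"]]
            .equals(igg[["chrom", "start", "end"]])):
        raise ValueError("ChIP and IgG tracks are on different window grids")
    track = chip[["chrom", "start", "end"]].copy()
    track["chip_norm"] = chip["norm"].to_numpy()
    track["igg_norm"] = igg["norm"].to_numpy()
    track["enrichment"] = track["chip_norm"] - track["igg_norm"]
    return track


def enrichment_by_cytolocation(track: pd.DataFrame,
                               bins: Sequence[GenomicInterval]) -> pd.DataFrame:
    """Mean window enrichment per cytolocation (windows assigned by midpoint).

    Bins containing no window midpoint are flagged empty (mean = nan).
    """
    mids = (track["start"] + track["end"]) // 2
    rows = []
    for b in bins:
        mask = ((track["chrom"] == b.chrom) & (mids >= b.start) & (mids < b.end))
        values = track.loc[mask, "enrichment"]
        rows.append({
            "cytolocation": b.name,
            "chrom": b.chrom,
            "start": b.start,
            "end": b.end,
            "n_windows": int(mask.sum()),
            "mean_enrichment": float(values.mean()) if mask.any() else float("nan"),
            "empty": not bool(mask.any()),
        })
    return pd.DataFrame(rows)


def correlate_enrichment_loss(per_bin_enrichment: pd.Series,
                              per_bin_log2_fr: pd.Series) -> TestResult:
    """Spearman correlation of mean enrichment vs. log2 fold reduction.

    Both series are indexed by cytolocation; only bins present and finite
    in both (i.e. passing both upstream filters) enter the correlation.
    """
    joined = pd.concat([per_bin_enrichment.rename("e"),
                        per_bin_log2_fr.rename("fr")], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 cytolocations pass both filters")
    return spearman_rho(joined["e"], joined["fr"])
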