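"""Ping-pong signature: 5'-overlap histograms and the z-score.

Secondary piRNA biogenesis produces sense/antisense piRNA pairs whose 5'
ends overlap by exactly 10 nt.  For each transposon family the overlap
histogram N_k counts, for k = 1..20, all opposite-strand read pairs on the
consensus whose 5' ends overlap by exactly k nt, as a product of
per-position 5'-end depths.  The z-score is the probability of a 10-nt
overlap minus the mean probability of the background overlaps (2-9 and
11-20 nt), divided by the standard deviation of those background
probabilities.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .aligner import AlignmentRecord

K_MAX = 20
DEFAULT_SUPPORT = tuple(range(2, K_MAX + 1))
FOCAL_OVERLAP = 10


@dataclass
class OverlapHistogram:
    """5'-overlap pair counts N_k for k = 1..K_MAX and their probabilities.

    ``support`` is the overlap range used for normalization and the z-score
    background (k = 1 is excluded by default, matching the background set
    2-9, 11-20).
    """

    counts: np.ndarray  # index k-1 holds N_k, k = 1..K_MAX
    support: tuple[int, ...] = DEFAULT_SUPPORT

    def __post_init__(self) -> None:
        if len(self.counts) != K_MAX:
            raise ValueError(f"expected {K_MAX} overlap counts")
        if np.any(self.counts < 0):
            raise ValueError("overlap counts must be non-negative")

    def n(self, k: int) -> float:
        return float(self.counts[k - 1])

    @property
    def total(self) -> float:
        return float(sum(self.n(k) for k in self.support))

    def probabilities(self) -> dict[int, float]:
        """p_k = N_k / sum over the support; zeros when the support is empty."""
        total = self.total
        if total == 0:
            return {k: 0.0 for k in self.support}
        return {k: self.n(k) / total for k in self.support}


def overlap_histogram(plus_5p_depth: Mapping[int, float],
                      minus_5p_depth: Mapping[int, float],
                      support: tuple[int, ...] = DEFAULT_SUPPORT,
                      ) -> OverlapHistogram:
    """Histogram of opposite-strand 5'-end overlaps from depth vectors.

    Positions are forward-strand coordinates; a minus-strand read's 5' end
    is its rightmost base.  N_k = sum_p plus(p) * minus(p + k - 1), i.e. the
    number of read pairs (product of depths) overlapping by exactly k nt.
    """
    counts = np.zeros(K_MAX)
    for k in range(1, K_MAX + 1):
        counts[k - 1] = sum(
            depth * minus_5p_depth.get(p + k - 1, 0.0)
            for p, depth in plus_5p_depth.items()
        )
    return OverlapHistogram(counts, support)


def pingpong_zscore(hist: OverlapHistogram, focal: int = FOCAL_OVERLAP,
                    sample_sd: bool = False) -> tuple[float, bool]:
    """Ping-pong z from an overlap histogram; returns (z, defined).

    z = (p_focal - mean(p_background)) / sd(p_background), where the
    background is the support minus the focal overlap (2-9, 11-20 by
    default) and sd is the population standard deviation unless
    ``sample_sd``.  The result is flagged undefined (z = nan,
    defined = False) when no pairs exist or the background sd is zero —
    never silently reported as 0.
    """
    if focal not in hist.support:
        raise ValueError(f"focal overlap {focal} not in support")
    if hist.total == 0:
        return float("nan"), False
    probs = hist.probabilities()
    background = np.array([probs[k] for k in hist.support if k != focal])
    sd = background.std(ddof=1 if sample_sd else 0)
    # identical background probabilities can leave a ~1e-17 residual sd
    if sd <= 1e-12 * max(float(background.mean()), np.finfo(float).tiny):
        return float("nan"), False
    return float((probs[focal] - background.mean()) / sd), True


def alignment_5p_depths(records: Iterable[AlignmentRecord]
                        ) -> tuple[dict[int, float], dict[int, float]]:
    """Per-position 5'-end depth vectors (plus, minus) in forward coordinates."""
    plus: dict[int, float] = defaultdict(float)
    minus: dict[int, float] = defaultdict(float)
    for rec in records:
        if rec.strand == "+":
            plus[rec.pos] += 1.0
        else:
            minus[rec.pos + rec.length - 1] += 1.0
    return dict(plus), dict(minus)


def pingpong_per_family(consensus_records: Iterable[AlignmentRecord],
                        support: tuple[int, ...] = DEFAULT_SUPPORT,
                        sample_sd: bool = False) -> pd.DataFrame:
    """One overlap histogram and z-score per transposon family.

    Input is the consensus alignment record set of one library; records are
    grouped by target family.  Families with reads on only one strand (or
    otherwise degenerate histograms) are flagged undefined.
    """
    by_family: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in consensus_records:
        by_family[rec.target].append(rec)

    rows = []
    for family in sorted(by_family):
        plus, minus = alignment_5p_depths(by_family[family])
        hist = overlap_histogram(plus, minus, support)
        z, defined = pingpong_zscore(hist, sample_sd=sample_sd)
        row = {"family": family}
        row.update({f"N_{k}": hist.n(k) for k in range(2, K_MAX + 1)})
        row["z"] = z
        row["flag"] = "ok" if defined else "undefined"
        rows.append(row)
    return pd.DataFrame(rows)
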