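"""Shared brute-force oracles, independent of the package's aligner."""

import numpy as np

from pirnakit.io_formats import revcomp


def _encode(seq: str) -> np.ndarray:
    table = {"A": 0, "C": 1, "G": 2, "T": 3}
    # N (or anything else) encoded uniquely per position so it never matches
    return np.array([table.get(c, -1 - i) for i, c in enumerate(seq)],
                    dtype=np.int64)


def best_mismatch_by_family(reads, consensus: dict[str, str], max_mm: int
                            ) -> dict[str, int]:
    """Per family, count reads whose best consensus placement has 2-3
    mismatches, by exhaustive scan over every position and strand."""
    counts = {fam: 0 for fam in consensus}
    encoded = {fam: _encode(seq) for fam, seq in consensus.items()}
    for read in reads:
        best = max_mm + 1
        best_fams: set[str] = set()
        for query in (read.seq, revcomp(read.seq)):
            q = _encode(query)
            for fam, t in encoded.items():
                if len(t) < len(q):
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(t, len(q))
                mm = int((windows != q).sum(axis=1).min())
                if mm < best:
                    best, best_fams = mm, {fam}
                elif mm == best:
                    best_fams.add(fam)
        if best in (2, 3) and best <= max_mm:
            for fam in best_fams:
                counts[fam] += 1
    return counts
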