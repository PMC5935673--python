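"""Evolutionary-age-stratified piRNA loss.

Insertions carry an age class (fixed / common / rare: population frequency
of the insertion, fixed being evolutionarily old).  Eligible insertions —
those targeted by at least 20 unique piRNAs in the control library, read by
default as 20 *distinct read sequences* uniquely mapping within the
insertion — are scored for at least three-fold loss of uniquely mapping
piRNAs, summarized per family, and the log2 fold reductions are compared
across age classes with one-sided Mann-Whitney tests (fixed insertions are
expected to lose more).  A separate consensus-alignment pass permitting
three mismatches counts, per family, piRNAs whose best alignment carries
2-3 mismatches; across families that count is rank-correlated with the
family fold reduction (older, more diverged families are expected to show
more loss).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import aligner
from .io_formats import GenomicInterval, Read, log_stage
from .stats import TestResult, mann_whitney_u, spearman_rho

AGE_CLASSES = ("fixed", "common", "rare")


def eligible_insertions(
    assigned: Mapping[str, Sequence[aligner.AlignmentRecord]],
    read_seqs: Mapping[str, str],
    min_unique: int = 20,
    mode: str = "distinct",
) -> set[str]:
    """Insertions targeted by at least ``min_unique`` unique piRNAs in control.

    ``assigned`` maps insertion name to the uniquely mapping control
    alignments contained in it.  Under ``mode='distinct'`` (default) the
    criterion counts distinct read sequences; ``mode='reads'`` switches to
    the plain read-count reading.
    """
    if mode not in ("distinct", "reads"):
        raise ValueError(f"unknown eligibility mode {mode!r}")
    eligible = set()
    for name, records in assigned.items():
        if mode == "distinct":
            n = len({read_seqs[r.read_id] for r in records})
        else:
            n = len(records)
        if n >= min_unique:
            eligible.add(name)
    return eligible


def family_loss_fraction(
    fold_changes: pd.DataFrame,
    insertions: Sequence[GenomicInterval],
    eligible: set[str],
    threshold: float = 3.0,
) -> pd.DataFrame:
    """Fraction of eligible insertions per family with fold reduction >= threshold.

    ``fold_changes`` is the per-insertion fold-change table (columns
    ``feature`` and ``fold_reduction``).  Families with no eligible
    insertion are flagged not-computable (fraction = nan); ``n_eligible``
    is reported alongside every fraction.
    """
    family_of = {iv.name: iv.attributes["family"] for iv in insertions}
    fr = fold_changes.set_index("feature")["fold_reduction"]
    per_family: dict[str, list[float]] = defaultdict(list)
    for name in eligible:
        per_family[family_of[name]].append(float(fr[name]))
    rows = []
    for family in sorted({family_of[iv.name] for iv in insertions}):
        values = per_family.get(family, [])
        rows.append({
            "family": family,
            "n_eligible": len(values),
            "n_lost": int(sum(v >= threshold for v in values)),
            "fraction_lost": (sum(v >= threshold for v in values) / len(values)
                              if values else float("nan")),
            "computable": bool(values),
        })
    return pd.DataFrame(rows)


def compare_age_classes(log2_fr_by_class: Mapping[str, Sequence[float]]
                        ) -> pd.DataFrame:
    """One-sided Mann-Whitney tests that fixed-class loss exceeds common / rare.

    Returns one row per comparison with the U statistic and one-sided
    p-value (alternative: fixed log2 fold reductions stochastically
    larger); comparisons where either class has fewer than 2 members are
    flagged not-computable.
    """
    fixed = list(log2_fr_by_class.get("fixed", []))
    rows = []
    for other in ("common", "rare"):
        values = list(log2_fr_by_class.get(other, []))
        row = {"comparison": f"fixed_vs_{other}", "n_fixed": len(fixed),
               "n_other": len(values)}
        if len(fixed) < 2 or len(values) < 2:
            row.update({"statistic": float("nan"), "pvalue": float("nan"),
                        "computable": False})
        else:
            res: TestResult = mann_whitney_u(fixed, values, alternative="greater")
            row.update({"statistic": res.statistic, "pvalue": res.pvalue,
                        "computable": True, "method": res.method})
        rows.append(row)
    return pd.DataFrame(rows)


def divergence_loss_analysis(
    pirna_reads: Sequence[Read],
    consensus: dict[str, str],
    family_fold_reduction: Mapping[str, float],
    max_mm: int = 3,
) -> tuple[pd.DataFrame, TestResult]:
    """Per-family count of 2-3-mismatch piRNAs vs. family fold reduction.

    Runs a dedicated consensus alignment pass permitting up to ``max_mm``
    mismatches, counts reads whose best placement on a family carries 2 or
    3 mismatches, and rank-correlates that count with the family's piRNA
    fold reduction.
    """
    records = aligner.align_consensus(pirna_reads, consensus, max_mm=max_mm)
    log_stage("divergence alignment", "pirna", len(pirna_reads),
              len({r.read_id for r in records}))
    counted: set[tuple[str, str]] = set()
    n_mm23: dict[str, int] = {fam: 0 for fam in consensus}
    for rec in records:
        if rec.mismatches in (2, 3) and (rec.read_id, rec.target) not in counted:
            counted.add((rec.read_id, rec.target))
            n_mm23[rec.target] += 1
    table = pd.DataFrame({
        "family": sorted(consensus),
        "n_mm23_pirnas": [n_mm23[f] for f in sorted(consensus)],
        "fold_reduction": [float(family_fold_reduction.get(f, np.nan))
                           for f in sorted(consensus)],
    }).dropna()
    res = spearman_rho(table["n_mm23_pirnas"], table["fold_reduction"])
    return table, res
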