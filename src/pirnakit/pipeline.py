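"""File-level orchestration: run analysis stages over a simulated dataset.

Reads only the files a `simulate` run (or an equivalently laid out real
dataset) leaves in a directory — genome.fa, consensus.fa, mirna.fa, the
annotation BEDs and the FASTQ libraries — and writes one TSV per analysis
product.  Never touches the truth ledgers: recovery is measured from reads
alone.  All stages are deterministic, so two runs over the same inputs
produce byte-identical TSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import chip_enrichment, splicing
from .age_stratification import (
    compare_age_classes,
    divergence_loss_analysis,
    eligible_insertions,
    family_loss_fraction,
)
from .aligner import GenomeIndex, align_genome_unique, unique_only
from .compartment_analysis import (
    compartment_loss_report,
    consolidate_by_cytolocation,
    loess_smooth,
)
from .io_formats import RunConfig, read_fastq, write_tsv
from .pingpong import pingpong_per_family
from .smallrna_quant import SmallRNAQuant, family_cluster_insertion_tables, \
    fold_change_table
from .synthetic_data import GenomeModel

CONTROL, KD = "smallrna_control", "smallrna_kd"
ALL_STAGES = ("smallrna", "compartments", "pingpong", "splice", "chip", "age")


class Analysis:
    """Lazily computed analysis products over one dataset directory."""

    def __init__(self, data_dir: str | Path, config: RunConfig | None = None):
        self.data_dir = Path(data_dir)
        self.config = config or RunConfig()
        self.model = GenomeModel.load(self.data_dir)
        self._quant: SmallRNAQuant | None = None
        self._fold_tables: dict[str, pd.DataFrame] | None = None
        self._cyto: pd.DataFrame | None = None
        self._genome_index: GenomeIndex | None = None

    @property
    def genome_index(self) -> GenomeIndex:
        if self._genome_index is None:
            self._genome_index = GenomeIndex(self.model.chromosomes)
        return self._genome_index

    def _fastq(self, name: str):
        return list(read_fastq(self.data_dir / f"{name}.fastq"))

    # -- small RNA quantification -------------------------------------------
    @property
    def quant(self) -> SmallRNAQuant:
        if self._quant is None:
            libraries = {lib: self._fastq(lib) for lib in (CONTROL, KD)}
            self._quant = family_cluster_insertion_tables(
                libraries, self.model, self.config,
                genome_index=self.genome_index)
        return self._quant

    @property
    def fold_tables(self) -> dict[str, pd.DataFrame]:
        if self._fold_tables is None:
            psi = self.config.pseudocount
            self._fold_tables = {
                "family": fold_change_table(self.quant.family_counts, CONTROL, KD, psi),
                "cluster": fold_change_table(self.quant.cluster_counts, CONTROL, KD, psi),
                "insertion": fold_change_table(self.quant.insertion_counts,
                                               CONTROL, KD, psi),
            }
        return self._fold_tables

    @property
    def cytolocation_summary(self) -> pd.DataFrame:
        if self._cyto is None:
            self._cyto = consolidate_by_cytolocation(
                self.quant.insertion_counts, self.model.insertions,
                self.model.cytolocations, self.model.compartments,
                CONTROL, KD,
                min_control_reads=self.config.cytolocation_min_control_reads,
                pseudocount=self.config.pseudocount)
        return self._cyto

    # -- stage writers -------------------------------------------------------
    def write_smallrna(self, out: Path) -> None:
        for kind, cm in (("family", self.quant.family_counts),
                         ("cluster", self.quant.cluster_counts),
                         ("insertion", self.quant.insertion_counts)):
            table = cm.counts.reset_index(names="feature")
            write_tsv(table, out / f"{kind}_counts.tsv")
        fold = pd.concat(
            [t.assign(feature_type=k) for k, t in self.fold_tables.items()],
            ignore_index=True)
        write_tsv(fold, out / "foldchange.tsv")

    def write_compartments(self, out: Path) -> None:
        write_tsv(self.cytolocation_summary, out / "cytolocation_summary.tsv")
        ins_by_name = {iv.name: iv for iv in self.model.insertions}
        fc = self.fold_tables["insertion"].set_index("feature")
        tracks = []
        for chrom in sorted(self.model.chromosomes):
            rows = sorted(
                ((ins_by_name[f].midpoint, float(fc.loc[f, "log2_fold_reduction"]))
                 for f in fc.index if ins_by_name[f].chrom == chrom),
                key=lambda t: t[0])
            if len(rows) < self.config.loess_degree + 2:
                continue
            pos = np.array([r[0] for r in rows], dtype=float)
            val = np.array([r[1] for r in rows])
            track = loess_smooth(pos, val, span=self.config.loess_span,
                                 degree=self.config.loess_degree)
            tracks.append(pd.DataFrame({
                "chrom": chrom, "position": track.positions.astype(int),
                "log2_fold_reduction": track.values, "loess_fit": track.fitted}))
        write_tsv(pd.concat(tracks, ignore_index=True), out / "smoothed_track.tsv")
        report, cluster_table = compartment_loss_report(
            self.cytolocation_summary, self.fold_tables["cluster"],
            self.model.clusters, self.model.compartments,
            loss_threshold=self.config.cluster_loss_threshold)
        write_tsv(report, out / "compartment_report.tsv")
        write_tsv(cluster_table, out / "cluster_foldchange.tsv")

    def write_pingpong(self, out: Path) -> None:
        tables = []
        for lib in (CONTROL, KD):
            t = pingpong_per_family(self.quant.consensus_alignments[lib])
            tables.append(t.assign(library=lib))
        write_tsv(pd.concat(tables, ignore_index=True), out / "pingpong.tsv")

    def write_splice(self, out: Path) -> None:
        reads = {cond: self._fastq(f"rnaseq_{cond}") for cond in ("control", "kd")}
        quant = splicing.quantify_splicing(self.model, reads,
                                           anchor=self.config.junction_anchor)
        fold = splicing.splicing_fold_table(quant)
        merged = quant.merge(fold[["feature", "ssr_fold_change",
                                   "spliced_fold_increase"]], on="feature")
        write_tsv(merged, out / "splice_quant.tsv")

    def write_chip(self, out: Path) -> None:
        lengths = self.model.chrom_lengths
        tracks = {}
        for lib in ("chip", "igg"):
            records = unique_only(align_genome_unique(self._fastq(lib),
                                                      self.genome_index))
            tracks[lib] = chip_enrichment.window_counts(
                records, lengths, window=self.config.window_size)
        track = chip_enrichment.subtract_control(tracks["chip"], tracks["igg"])
        write_tsv(track, out / "enrichment_track.tsv")
        by_bin = chip_enrichment.enrichment_by_cytolocation(
            track, self.model.cytolocations)
        write_tsv(by_bin, out / "enrichment_by_bin.tsv")
        cyto = self.cytolocation_summary
        passing = cyto[cyto["passes_filter"]].set_index("cytolocation")
        e = by_bin[~by_bin["empty"]].set_index("cytolocation")["mean_enrichment"]
        try:
            res = chip_enrichment.correlate_enrichment_loss(
                e, passing["log2_fold_reduction"])
            row = {"rho": res.statistic, "pvalue": res.pvalue, "n": res.n[0],
                   "method": res.method}
        except ValueError:  # too few bins pass the control-count filter
            row = {"rho": float("nan"), "pvalue": float("nan"),
                   "n": int(len(passing)), "method": "not-computable"}
        write_tsv(pd.DataFrame([row]), out / "correlation.tsv")

    def write_age(self, out: Path) -> None:
        cfg = self.config
        read_seqs = {r.id: r.seq for r in self.quant.pirna_reads[CONTROL]}
        eligible = eligible_insertions(
            self.quant.insertion_assignments[CONTROL], read_seqs,
            min_unique=cfg.min_unique_pirnas)
        fc = self.fold_tables["insertion"]
        loss = family_loss_fraction(fc, self.model.insertions, eligible,
                                    threshold=cfg.insertion_loss_threshold)
        write_tsv(loss, out / "family_loss_fraction.tsv")

        age_of = {iv.name: iv.attributes["age"] for iv in self.model.insertions}
        fr = fc.set_index("feature")["log2_fold_reduction"]
        by_class: dict[str, list[float]] = {"fixed": [], "common": [], "rare": []}
        for name in eligible:
            by_class[age_of[name]].append(float(fr[name]))
        write_tsv(compare_age_classes(by_class), out / "age_class_tests.tsv")

        fam_fr = self.fold_tables["family"].set_index("feature")["fold_reduction"]
        table, res = divergence_loss_analysis(
            self.quant.pirna_reads[CONTROL], self.model.consensus,
            fam_fr.to_dict())
        table = table.copy()
        table["spearman_rho"] = res.statistic
        table["spearman_p"] = res.pvalue
        write_tsv(table, out / "divergence_vs_loss.tsv")


def run_analysis(data_dir: str | Path, out_dir: str | Path,
                 config: RunConfig | None = None,
                 stages: tuple[str, ...] = ALL_STAGES) -> Analysis:
    """Run the requested stages over ``data_dir``, writing TSVs to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analysis = Analysis(data_dir, config)
    writers = {
        "smallrna": analysis.write_smallrna,
        "compartments": analysis.write_compartments,
        "pingpong": analysis.write_pingpong,
        "splice": analysis.write_splice,
        "chip": analysis.write_chip,
        "age": analysis.write_age,
    }
    for stage in stages:
        writers[stage](out)
    return analysis
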