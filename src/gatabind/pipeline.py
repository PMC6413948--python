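"""End-to-end orchestration: from inputs (or a simulation) to a report.

``run_pipeline`` wires the stages together: binding calls from peaks,
GATA-site counting over motif windows, regulation classes from counts,
every pairwise contingency table with its chi-square test, rank-sum
comparisons of expression across binding classes, and per-class metagene
profiles. Results are written as TSV/JSON under the output directory along
with a machine-readable manifest of every parameter that affected them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx

from . import __version__
from . import annotation, binding, expression, metagene, motifs, stats

log = logging.getLogger("gatabind")


@dataclass
class RunConfig:
    """Paths and tunables for one pipeline run."""

    annotation_path: str
    genome_path: str
    peaks_path: str
    counts_path: str
    samples_path: str
    tagged_track_path: str | None = None
    untagged_track_path: str | None = None
    out_dir: str = "gatabind_out"
    # promoter / binding
    promoter_far: int = 350
    promoter_near: int = 100
    overlap_threshold: float = 0.75
    union_coverage: bool = False
    # motifs
    motif_far: int = 500
    motif_near: int = 0
    max_mismatch: int = 0
    min_gap: int = 15
    max_gap: int = 35
    # expression
    fc_up: float = 2.0
    fc_down: float = 0.5
    alpha: float = 0.01
    condition_ref_nitrogen: str = "WT_gln"
    condition_alt_nitrogen: str = "WT_pro"
    condition_ref_dal80: str = "WT_pro"
    condition_alt_dal80: str = "dal80_pro"
    de_table_path: str | None = None  # external fc/p table replaces stand-in
    # metagene
    metagene_half_width: int = 600
    heatmap_half_width: int = 500
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value (YAML) config file with CLI overrides."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _contig_lengths(genome: pyfaidx.Fasta) -> dict[str, int]:
    return {name: len(genome[name]) for name in genome.keys()}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path_attr in ("annotation_path", "genome_path", "peaks_path",
                      "counts_path", "samples_path"):
        p = getattr(config, path_attr)
        if not Path(p).exists():
            raise FileNotFoundError(f"{path_attr}: no such file: {p}")

    log.info("loading annotation and genome")
    genes = annotation.read_annotation(config.annotation_path)
    genome = pyfaidx.Fasta(config.genome_path)
    contig_lengths = _contig_lengths(genome)
    peaks = binding.read_peaks(config.peaks_path)

    log.info("stage binding: promoter/ORF calls on %d genes, %d peaks",
             len(genes), len(peaks))
    promoter_calls = binding.call_promoter_bound(
        genes, peaks, config.overlap_threshold, config.promoter_far,
        config.promoter_near, contig_lengths, config.union_coverage)
    orf_calls = binding.call_orf_bound(genes, peaks,
                                       config.overlap_threshold,
                                       config.union_coverage)
    calls = binding.classify_genes(promoter_calls, orf_calls)
    binding.write_binding_calls(calls, out / "binding_calls.tsv")
    counts_by_class = binding.class_counts(calls)

    log.info("stage motifs: scanning %d promoter windows", len(genes))
    windows = {g.gene_id: annotation.motif_window(
        g, config.motif_far, config.motif_near, contig_lengths[g.contig])
        for g in genes}
    sites = motifs.sites_per_window(windows, genome, config.max_mismatch,
                                    config.min_gap, config.max_gap)
    sites.to_csv(out / "motif_sites.tsv", sep="\t")
    histogram = motifs.site_histogram(sites["n_sites"])
    cluster_by_bound = {
        "bound": float((sites.loc[calls["promoter_bound"], "n_clusters"] > 0)
                       .mean()) if calls["promoter_bound"].any() else None,
        "unbound": float((sites.loc[~calls["promoter_bound"], "n_clusters"] > 0)
                         .mean()) if (~calls["promoter_bound"]).any() else None,
    }

    log.info("stage expression: regulation classes")
    counts, lengths = expression.read_counts(config.counts_path)
    sheet = expression.read_sample_sheet(config.samples_path, counts)
    densities = expression.normalize_density(
        counts, lengths, sheet.set_index("sample")["library_size"])
    cond_means = expression.condition_means(densities, sheet)
    cond_means.to_csv(out / "densities.tsv", sep="\t")
    if config.de_table_path:
        de = pd.read_csv(config.de_table_path, sep="\t", index_col="gene_id")
        nitrogen_de = de[["fc_pro_vs_gln", "p_pro_vs_gln"]].rename(columns={
            "fc_pro_vs_gln": "fold_change", "p_pro_vs_gln": "p_value"})
        dal80_de = de[["fc_mut_vs_wt", "p_mut_vs_wt"]].rename(columns={
            "fc_mut_vs_wt": "fold_change", "p_mut_vs_wt": "p_value"})
        nitrogen_de["method"] = dal80_de["method"] = "external"
    else:
        nitrogen_de = expression.de_table(
            counts, lengths, sheet, config.condition_ref_nitrogen,
            config.condition_alt_nitrogen)
        dal80_de = expression.de_table(
            counts, lengths, sheet, config.condition_ref_dal80,
            config.condition_alt_dal80)
    regulation = expression.classify_regulation(
        nitrogen_de, dal80_de, config.fc_up, config.fc_down, config.alpha)
    regulation.to_csv(out / "regulation_calls.tsv", sep="\t")

    log.info("stage stats: contingency tables and tests")
    shared = calls.index.intersection(regulation.index)
    bound_label = pd.Series(
        np.where(calls.loc[shared, "promoter_bound"], "bound", "unbound"),
        index=shared, name="binding")
    tests = {}
    tables = {}
    for name, (a, b) in {
        "bound_x_nitrogen": (bound_label, regulation.loc[shared,
                                                         "nitrogen_class"]),
        "bound_x_dal80": (bound_label, regulation.loc[shared, "dal80_class"]),
        "class_x_nitrogen": (calls.loc[shared, "class"],
                             regulation.loc[shared, "nitrogen_class"]),
        "class_x_dal80": (calls.loc[shared, "class"],
                          regulation.loc[shared, "dal80_class"]),
    }.items():
        table = stats.contingency(a, b)
        result = stats.chi_square_independence(table)
        tables[name] = table
        tests[name] = result.to_dict()
        table.table.to_csv(out / f"contingency_{name}.tsv", sep="\t")

    # expression comparisons across binding classes (anchor condition)
    anchor = config.condition_ref_dal80
    log_dens = np.log2(cond_means[anchor] + 1e-9)
    rank_tests = {}
    by_class = {label: log_dens[calls.loc[shared, "class"] == label]
                for label in binding.CLASS_LABELS}
    for a, b in (("P&O", "P"), ("P&O", "unbound"), ("P", "unbound")):
        if len(by_class[a]) and len(by_class[b]):
            rank_tests[f"{a}_vs_{b}"] = stats.rank_sum(
                by_class[a], by_class[b]).to_dict()

    profiles_summary = {}
    if config.tagged_track_path:
        log.info("stage metagene: per-class profiles")
        track = metagene.read_bedgraph(config.tagged_track_path,
                                       contig_lengths)
        profiles = metagene.class_profiles(
            track, genes, calls["class"], config.metagene_half_width,
            seed=config.seed)
        for label, prof in profiles.items():
            safe = label.replace("&", "and")
            prof.to_csv(out / f"metagene_{safe}.tsv", sep="\t", index=False)
            profiles_summary[label] = {
                "n_genes": int(prof["n"].max()),
                "mean_at_atg": float(
                    prof.loc[prof["position"] == 0, "mean"].iloc[0]),
            }
        vectors = {g.gene_id: metagene.window_coverage(
            track, g, config.heatmap_half_width)
            for g in genes if calls.loc[g.gene_id, "promoter_bound"]}
        if vectors:
            metagene.heatmap_matrix(vectors).to_csv(
                out / "heatmap_bound.tsv", sep="\t")

    summary = {
        "n_genes": len(genes),
        "n_peaks": len(peaks),
        "binding_class_counts": counts_by_class,
        "nitrogen_class_counts": {
            k: int(v) for k, v in
            regulation["nitrogen_class"].value_counts().items()},
        "dal80_class_counts": {
            k: int(v) for k, v in
            regulation["dal80_class"].value_counts().items()},
        "motif_histogram": histogram,
        "cluster_fraction_by_binding": cluster_by_bound,
        "chi_square_tests": tests,
        "rank_sum_tests": rank_tests,
        "metagene": profiles_summary,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")

    manifest = {
        "package": "gatabind",
        "version": __version__,
        "parameters": asdict(config),
        "assumptions": {
            "gene_universe": "genes shared by annotation and count table "
                             f"(n={len(shared)})",
            "de_method": str(regulation["method"].iloc[0]),
            "coverage_rule": "union" if config.union_coverage else
                             "single peak, strict inequality",
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    log.info("report written to %s", out)
    return summary
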