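"""Ground-truthed synthetic data for the whole pipeline.

The generator emits a random genome with non-overlapping genes on both
strands, implants GATA clusters into bound promoters, lays down ChIP
coverage (Poisson background, a promoter bump for P/P&O genes, an ORF
plateau for P&O/O genes) together with the peaks that produced it, and
draws negative-binomial count matrices for three conditions (WT glutamine,
WT proline, dal80-delta proline) with designated fold-changes for
NCR/revNCR and Dal80-activated/-repressed genes.

Peaks are emitted directly by the generator — fully covering the promoter
window and/or the gene body — so the >75% binding rule recovers the true
classes exactly. A naive threshold peak caller is included for integration
tests only; it is not part of the analysed method.

Everything derives from one ``numpy`` Generator seeded by the config, so a
fixed config yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord, promoter_region
from .binding import Peak

CONDITIONS = ("WT_gln", "WT_pro", "dal80_pro")


@dataclass
class SimulationConfig:
    """The stated world of the synthetic dataset.

    Class fractions follow the structure of the published genome-wide
    counts (P 1125, P&O 144, O 45 of 5798 genes; NCR 754, revNCR 928;
    Dal80-activated 314, -repressed 232), scaled to ``n_genes``. Effect
    sizes default to |log2FC| = 3 with NB dispersion 0.05 and 4 replicates,
    the regime under which the stand-in test guarantees >= 95% sensitivity.
    """

    seed: int = 0
    n_genes: int = 500
    contig_name: str = "chrS"
    gene_length: tuple[int, int] = (500, 2000)
    # intergenic gaps wide enough that neighboring promoter windows (and the
    # +/-10 bp peak padding) never collide, keeping binding classes exactly
    # identifiable from the emitted peaks
    spacing: tuple[int, int] = (720, 1200)
    # binding classes (remainder unbound)
    frac_p: float = 1125 / 5798
    frac_po: float = 144 / 5798
    frac_o: float = 45 / 5798
    # regulation classes (remainders unaffected / insensitive)
    frac_ncr: float = 754 / 5798
    frac_revncr: float = 928 / 5798
    frac_activated: float = 314 / 5798
    frac_repressed: float = 232 / 5798
    bound_regulation_odds: float = 3.0  # enrichment of regulated among bound
    log2fc: float = 3.0
    nb_dispersion: float = 0.05
    n_replicates: int = 4
    # mean expression strata (expected counts per gene): P&O genes are drawn
    # from a higher-mean stratum than P, which exceeds the background
    base_mean: float = 200.0
    p_mean_factor: float = 2.0
    po_mean_factor: float = 8.0
    lognorm_sigma: float = 0.5
    # ChIP coverage (tag/nt)
    background_rate: float = 1.0
    promoter_height: float = 8.0
    orf_height: float = 5.0
    n_decoy_peaks: int = 20
    decoy_width: int = 150
    # motif implanting
    sites_per_bound_promoter: int = 2
    cluster_gap: tuple[int, int] = (15, 35)
    frac_gataless: float = 0.2  # bound promoters left without implants
    promoter_far: int = 350
    promoter_near: int = 100

    def validate(self) -> None:
        if self.frac_p + self.frac_po + self.frac_o > 1:
            raise ValueError("binding-class fractions sum above 1")
        if self.frac_ncr + self.frac_revncr > 1:
            raise ValueError("nitrogen-class fractions sum above 1")
        if self.frac_activated + self.frac_repressed > 1:
            raise ValueError("Dal80-class fractions sum above 1")
        if min(self.gene_length) <= 0 or min(self.spacing) < 0:
            raise ValueError("lengths and spacings must be positive")
        if self.nb_dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("rates must be positive")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")


@dataclass
class GroundTruth:
    """Per-gene true classes plus implanted motif coordinates."""

    table: pd.DataFrame  # gene_id-indexed: binding/nitrogen/dal80 class
    motifs: pd.DataFrame  # contig, start, strand, motif, gene_id

    def to_files(self, outdir: Path) -> None:
        self.table.to_csv(outdir / "truth.tsv", sep="\t")
        self.motifs.to_csv(outdir / "truth_motifs.tsv", sep="\t", index=False)


def _counts_per_class(n: int, fracs: Sequence[float]) -> list[int]:
    counts = [int(round(f * n)) for f in fracs]
    if sum(counts) > n:
        raise ValueError("class fractions leave no room for the null class")
    return counts


def _assign_classes(rng: np.random.Generator, gene_ids: Sequence[str],
                    counts: Sequence[int], labels: Sequence[str],
                    null_label: str,
                    weights: np.ndarray | None = None) -> pd.Series:
    """Draw disjoint class memberships with optional per-gene odds weights."""
    out = pd.Series(null_label, index=list(gene_ids), dtype=object)
    available = np.array(gene_ids, dtype=object)
    w = np.ones(len(available)) if weights is None else weights.astype(float)
    for count, label in zip(counts, labels):
        if count == 0 or len(available) == 0:
            continue
        p = w / w.sum()
        chosen = rng.choice(len(available), size=count, replace=False, p=p)
        out.loc[available[chosen]] = label
        keep = np.ones(len(available), dtype=bool)
        keep[chosen] = False
        available, w = available[keep], w[keep]
    return out


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[str, list[GeneRecord], GroundTruth]:
    """Random genome + gene layout + implanted GATA clusters + truth."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_genes

    genes: list[GeneRecord] = []
    cursor = 600  # room for the first promoter/motif window
    for i in range(n):
        cursor += int(rng.integers(config.spacing[0], config.spacing[1] + 1))
        length = int(rng.integers(config.gene_length[0],
                                  config.gene_length[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(config.contig_name, cursor, cursor + length,
                                strand, f"g{i:04d}"))
        cursor += length
    contig_len = cursor + 600

    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=contig_len)

    gene_ids = [g.gene_id for g in genes]
    n_p, n_po, n_o = _counts_per_class(
        n, (config.frac_p, config.frac_po, config.frac_o))
    binding = _assign_classes(rng, gene_ids, (n_p, n_po, n_o),
                              ("P", "P&O", "O"), "unbound")

    bound_mask = binding.isin(["P", "P&O"]).to_numpy()
    odds = np.where(bound_mask, config.bound_regulation_odds, 1.0)
    n_ncr, n_rev = _counts_per_class(n, (config.frac_ncr, config.frac_revncr))
    nitrogen = _assign_classes(rng, gene_ids, (n_ncr, n_rev),
                               ("NCR", "revNCR"), "unaffected", odds)
    n_act, n_rep = _counts_per_class(
        n, (config.frac_activated, config.frac_repressed))
    dal80 = _assign_classes(rng, gene_ids, (n_act, n_rep),
                            ("activated", "repressed"), "insensitive", odds)

    motif_rows = _implant_motifs(config, rng, seq, genes, binding)

    truth = GroundTruth(
        table=pd.DataFrame({
            "binding_class": binding,
            "nitrogen_class": nitrogen,
            "dal80_class": dal80,
        }).rename_axis("gene_id"),
        motifs=pd.DataFrame(
            motif_rows, columns=["contig", "start", "strand", "motif",
                                 "gene_id"]),
    )
    return seq.tobytes().decode("ascii"), genes, truth


def _implant_motifs(config: SimulationConfig, rng: np.random.Generator,
                    seq: np.ndarray, genes: list[GeneRecord],
                    binding: pd.Series) -> list[tuple]:
    """Write GATA clusters into bound promoters, avoiding implant overlap.

    A configurable fraction of bound promoters receives no implant at all,
    mirroring the observed GATA-less bound promoters.
    """
    from .motifs import CONSENSUS, revcomp

    rows: list[tuple] = []
    occupied: list[tuple[int, int]] = []
    for gene in genes:
        if binding.loc[gene.gene_id] not in ("P", "P&O"):
            continue
        if rng.random() < config.frac_gataless:
            continue
        window = promoter_region(gene, config.promoter_far,
                                 config.promoter_near, len(seq))
        if window.empty:
            continue
        for _attempt in range(20):
            motifs = [str(rng.choice(CONSENSUS))
                      for _ in range(config.sites_per_bound_promoter)]
            gaps = [int(rng.integers(config.cluster_gap[0],
                                     config.cluster_gap[1] + 1))
                    for _ in range(config.sites_per_bound_promoter - 1)]
            span = sum(len(m) for m in motifs) + sum(gaps)
            if span > window.length:
                continue
            start = int(rng.integers(window.start, window.end - span + 1))
            if any(start < e and start + span > s for s, e in occupied):
                continue
            pos = start
            placed = []
            for k, motif in enumerate(motifs):
                strand = "+" if rng.random() < 0.5 else "-"
                written = motif if strand == "+" else revcomp(motif)
                seq[pos:pos + len(motif)] = np.frombuffer(
                    written.encode("ascii"), dtype=np.uint8)
                placed.append((gene.contig, pos, strand, motif, gene.gene_id))
                pos += len(motif)
                if k < len(gaps):
                    pos += gaps[k]
            occupied.append((start, start + span))
            rows.extend(placed)
            break
    return rows


def simulate_chip(config: SimulationConfig, genes: Sequence[GeneRecord],
                  truth: GroundTruth, contig_len: int,
                  rng: np.random.Generator
                  ) -> tuple[dict, dict, list[Peak]]:
    """Tagged and untagged coverage tracks plus the peaks that explain them."""
    contig = config.contig_name
    tagged = rng.poisson(config.background_rate, contig_len).astype(float)
    untagged = {contig: rng.poisson(config.background_rate,
                                    contig_len).astype(float)}
    peaks: list[Peak] = []
    forbidden: list[tuple[int, int]] = []
    classes = truth.table["binding_class"]
    k = 0
    for gene in genes:
        label = classes.loc[gene.gene_id]
        promoter = promoter_region(gene, config.promoter_far,
                                   config.promoter_near, contig_len)
        forbidden.append((promoter.start, promoter.end))
        forbidden.append((gene.start, gene.end))
        if label in ("P", "P&O") and not promoter.empty:
            tagged[promoter.start:promoter.end] += config.promoter_height
            pad_lo = max(promoter.start - 10, 0)
            pad_hi = min(promoter.end + 10, contig_len)
            peaks.append(Peak(contig, pad_lo, pad_hi, f"peak_{k:05d}",
                              score=config.promoter_height))
            k += 1
        if label in ("P&O", "O"):
            tagged[gene.start:gene.end] += config.orf_height
            pad_lo = max(gene.start - 10, 0)
            pad_hi = min(gene.end + 10, contig_len)
            peaks.append(Peak(contig, pad_lo, pad_hi, f"peak_{k:05d}",
                              score=config.orf_height))
            k += 1
    # background decoys well away from every promoter and gene body
    for _ in range(config.n_decoy_peaks):
        for _attempt in range(50):
            start = int(rng.integers(0, contig_len - config.decoy_width))
            end = start + config.decoy_width
            if not any(start < e and end > s for s, e in forbidden):
                peaks.append(Peak(contig, start, end, f"peak_{k:05d}",
                                  score=config.background_rate))
                k += 1
                break
    return {contig: tagged}, untagged, peaks


def simulate_counts(config: SimulationConfig, genes: Sequence[GeneRecord],
                    truth: GroundTruth, rng: np.random.Generator
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix and its sample sheet.

    Base means are log-normal within binding-class strata (P&O > P >
    background). Designated genes carry the configured |log2FC|: NCR up in
    proline vs glutamine, revNCR down; Dal80-repressed up in the mutant,
    Dal80-activated down. WT proline is the anchor condition, so the
    expression ordering across binding classes holds there by construction.
    """
    table = truth.table
    n = len(genes)
    factor = np.select(
        [table["binding_class"] == "P&O", table["binding_class"] == "P"],
        [config.po_mean_factor, config.p_mean_factor], default=1.0)
    base = (config.base_mean * factor
            * rng.lognormal(0.0, config.lognorm_sigma, n))

    # Repression-only multiplicative model: ``base`` is the fully derepressed
    # level and each regulated gene is reduced fc-fold in the conditions
    # where it is repressed (NCR in glutamine; revNCR in proline;
    # Dal80-repressed in any DAL80+ strain; Dal80-activated in the mutant).
    # Keeping every multiplier <= 1 leaves the per-condition transcriptome
    # mass nearly balanced, so total-count density normalization does not
    # shift the fold-changes of unregulated genes.
    fc = 2.0 ** config.log2fc
    ncr = (table["nitrogen_class"] == "NCR").to_numpy()
    rev = (table["nitrogen_class"] == "revNCR").to_numpy()
    rep = (table["dal80_class"] == "repressed").to_numpy()
    act = (table["dal80_class"] == "activated").to_numpy()
    down = lambda mask: np.where(mask, 1.0 / fc, 1.0)  # noqa: E731
    mean_gln = base * down(ncr) * down(rep)
    mean_pro = base * down(rev) * down(rep)
    mean_mut = base * down(rev) * down(act)
    means = {"WT_gln": mean_gln, "WT_pro": mean_pro, "dal80_pro": mean_mut}

    d = config.nb_dispersion
    data, samples = {}, []
    for condition in CONDITIONS:
        mu = means[condition]
        for rep in range(1, config.n_replicates + 1):
            sample = f"{condition}_r{rep}"
            # NB with variance mu + d*mu^2: n = 1/d, p = 1/(1 + d*mu)
            data[sample] = rng.negative_binomial(1.0 / d, 1.0 / (1.0 + d * mu))
            samples.append({"sample": sample, "condition": condition,
                            "replicate": rep})
    counts = pd.DataFrame(data, index=table.index)
    counts.insert(0, "length", [g.length for g in genes])
    sheet = pd.DataFrame(samples)
    sheet["library_size"] = sheet["sample"].map(
        counts.drop(columns="length").sum(axis=0))
    return counts, sheet


def naive_peak_caller(track: dict[str, np.ndarray], background: float,
                      fold: float = 4.0, min_length: int = 100) -> list[Peak]:
    """Threshold caller (coverage > fold * background over >= min_length bp).

    For integration tests only — the analysed datasets come with called
    peaks, and this is not the peak-calling procedure used on the real data.
    """
    peaks = []
    k = 0
    for contig, vec in track.items():
        above = np.concatenate([[False], vec > fold * background, [False]])
        edges = np.flatnonzero(np.diff(above.astype(int)))
        for start, end in zip(edges[::2], edges[1::2]):
            if end - start >= min_length:
                peaks.append(Peak(contig, int(start), int(end),
                                  f"naive_{k:05d}"))
                k += 1
    return peaks


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run the whole generator and write every artifact under ``outdir``.

    Writes FASTA, BED6 annotation, peaks BED, two bedGraph tracks, the count
    TSV with sample sheet, and the ground truth; returns the in-memory
    objects keyed by name.
    """
    from .annotation import write_bed6
    from .metagene import write_bedgraph

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sequence, genes, truth = simulate_genome(config, rng)
    tagged, untagged, peaks = simulate_chip(config, genes, truth,
                                            len(sequence), rng)
    counts, sheet = simulate_counts(config, genes, truth, rng)

    with open(outdir / "genome.fa", "w") as fh:
        fh.write(f">{config.contig_name}\n")
        for i in range(0, len(sequence), 80):
            fh.write(sequence[i:i + 80] + "\n")
    write_bed6(genes, outdir / "genes.bed")
    with open(outdir / "peaks.bed", "w") as fh:
        for p in peaks:
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{p.peak_id}\t"
                     f"{p.score:g}\t.\n")
    write_bedgraph(tagged, outdir / "chip_tagged.bedgraph")
    write_bedgraph(untagged, outdir / "chip_untagged.bedgraph")
    counts.rename_axis("gene_id").to_csv(outdir / "counts.tsv", sep="\t")
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    truth.to_files(outdir)
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)
        fh.write("\n")
    return {"sequence": sequence, "genes": genes, "truth": truth,
            "tagged": tagged, "untagged": untagged, "peaks": peaks,
            "counts": counts, "sheet": sheet,
            "contig_lengths": {config.contig_name: len(sequence)}}
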