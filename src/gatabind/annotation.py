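"""Gene annotation handling and strand-aware upstream windows.

All coordinates are 0-based half-open internally. BED input is used as-is;
GFF3 (1-based, closed) is converted on read. The ATG anchor of a gene is its
first coding base in transcript orientation: ``start`` on the + strand and
``end - 1`` on the - strand.

Two upstream windows matter downstream:

* the *promoter window* (default 350..100 bp upstream of the ATG, length 250),
  used for binding calls against ChIP peaks;
* the *motif window* (default the 500 bases immediately upstream of the ATG,
  offsets -500..-1), used for GATA consensus counting.

Both are clamped at contig edges rather than erroring; truncation and
emptiness are flagged on the returned interval so callers can decide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

VALID_STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene (0-based half-open, explicit strand)."""

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str
    tss: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: require 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")

    @property
    def atg(self) -> int:
        """First coding base in transcript orientation."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval, optionally stranded, with clamping flags."""

    contig: str
    start: int
    end: int
    strand: str | None = None
    truncated: bool = False
    name: str | None = None
    #: requested offsets relative to the ATG in transcript orientation,
    #: (-far, -near); recorded before any clamping
    atg_offsets: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def empty(self) -> bool:
        return self.start >= self.end


def _clamp(contig: str, start: int, end: int, strand: str, name: str,
           contig_length: int | None,
           atg_offsets: tuple[int, int]) -> GenomicInterval:
    lo, hi = max(start, 0), end
    if contig_length is not None:
        hi = min(hi, contig_length)
    hi = max(hi, lo)
    truncated = (lo, hi) != (start, end)
    return GenomicInterval(contig, lo, hi, strand=strand, truncated=truncated,
                           name=name, atg_offsets=atg_offsets)


def upstream_window(gene: GeneRecord, far: int, near: int,
                    contig_length: int | None = None) -> GenomicInterval:
    """Half-open window covering offsets [-far, -near) upstream of the ATG.

    On the + strand this is ``[ATG - far, ATG - near)``; on the - strand the
    mirror image ``[ATG + near + 1, ATG + far + 1)``. Length is ``far - near``
    unless clamped at a contig edge (flagged ``truncated``).
    """
    if not far >= near >= 0:
        raise ValueError(f"require far >= near >= 0, got far={far}, near={near}")
    atg = gene.atg
    if gene.strand == "+":
        start, end = atg - far, atg - near
    else:
        start, end = atg + near + 1, atg + far + 1
    return _clamp(gene.contig, start, end, gene.strand, gene.gene_id,
                  contig_length, (-far, -near))


def promoter_region(gene: GeneRecord, far: int = 350, near: int = 100,
                    contig_length: int | None = None) -> GenomicInterval:
    """Promoter window used for binding calls (default -350..-100, 250 bp).

    The upstream boundary is inclusive and the near boundary exclusive under
    the half-open convention; pass ``near=99`` to reproduce a 251-bp reading
    inclusive of the -100 base.
    """
    return upstream_window(gene, far, near, contig_length)


def motif_window(gene: GeneRecord, far: int = 500, near: int = 0,
                 contig_length: int | None = None) -> GenomicInterval:
    """Window used for GATA site counting: the ``far`` bases immediately
    upstream of the ATG (offsets -far..-near-1; default -500..-1, 500 bp)."""
    return upstream_window(gene, far, near, contig_length)


def orf_interval(gene: GeneRecord) -> GenomicInterval:
    """The gene body [start, end) as a stranded interval."""
    return GenomicInterval(gene.contig, gene.start, gene.end,
                           strand=gene.strand, name=gene.gene_id)


# ---------------------------------------------------------------------------
# I/O


def _parse_bed_line(line: str, lineno: int) -> GeneRecord | None:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 6:
        raise ValueError(
            f"BED line {lineno}: need >= 6 fields for stranded genes, got "
            f"{len(fields)}"
        )
    contig, start, end, name = fields[0], fields[1], fields[2], fields[3]
    strand = fields[5]
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise ValueError(f"BED line {lineno}: non-integer coordinates") from exc
    if strand not in VALID_STRANDS:
        warnings.warn(
            f"BED line {lineno}: skipping record {name!r} with strand {strand!r}"
        )
        return None
    return GeneRecord(contig, start_i, end_i, strand, name)


def _read_bed(path: Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            rec = _parse_bed_line(line, lineno)
            if rec is not None:
                genes.append(rec)
    return genes


def _read_gff3(path: Path, feature_types: Sequence[str]) -> list[GeneRecord]:
    # DataIterator streams features without building a database.
    from gffutils.iterators import DataIterator

    genes: list[GeneRecord] = []
    for feat in DataIterator(str(path)):
        if feature_types and feat.featuretype not in feature_types:
            continue
        if feat.strand not in VALID_STRANDS:
            warnings.warn(
                f"GFF3 feature {feat.id!r}: skipping record with strand "
                f"{feat.strand!r}"
            )
            continue
        gene_id = (feat.attributes.get("ID") or feat.attributes.get("Name")
                   or [f"{feat.seqid}:{feat.start}-{feat.end}"])[0]
        # GFF3 is 1-based closed; convert to 0-based half-open.
        genes.append(GeneRecord(feat.seqid, feat.start - 1, feat.end,
                                feat.strand, gene_id))
    return genes


def read_annotation(path: str | Path, format: str | None = None,
                    feature_types: Sequence[str] = ("gene",)) -> list[GeneRecord]:
    """Read gene records from BED6/BED12 or GFF3.

    ``format`` is inferred from the extension when omitted. GFF3 coordinates
    are converted to 0-based half-open; BED passes through unchanged.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "gff3" if suffix in (".gff", ".gff3") else "bed"
    if format == "bed":
        return _read_bed(path)
    if format == "gff3":
        return _read_gff3(path, feature_types)
    raise ValueError(f"unknown annotation format {format!r}")


def write_bed6(records: Iterable[GeneRecord | GenomicInterval],
               path: str | Path) -> None:
    """Write genes or derived windows as BED6 (name=gene_id/name, score=0)."""
    with open(path, "w") as fh:
        for rec in records:
            name = rec.gene_id if isinstance(rec, GeneRecord) else (rec.name or ".")
            strand = rec.strand or "."
            fh.write(f"{rec.contig}\t{rec.start}\t{rec.end}\t{name}\t0\t{strand}\n")


def with_tss(genes: Sequence[GeneRecord],
             tss_by_gene: Mapping[str, int]) -> list[GeneRecord]:
    """Attach TSS coordinates (same contig assumed) to matching genes."""
    return [replace(g, tss=tss_by_gene[g.gene_id]) if g.gene_id in tss_by_gene
            else g for g in genes]


def tss_atg_summary(genes: Iterable[GeneRecord]) -> dict:
    """Median/mean strand-aware TSS-to-ATG distance over genes with a TSS.

    The distance is measured in transcript orientation (positive when the TSS
    lies upstream of the ATG). Negative distances are excluded from the
    summary and counted separately.
    """
    distances = []
    n_excluded = 0
    for g in genes:
        if g.tss is None:
            continue
        d = g.atg - g.tss if g.strand == "+" else g.tss - g.atg
        if d < 0:
            n_excluded += 1
        else:
            distances.append(d)
    if not distances:
        return {"median": None, "mean": None, "n": 0, "n_excluded": n_excluded}
    arr = np.asarray(distances, dtype=float)
    return {
        "median": float(np.median(arr)),
        "mean": float(arr.mean()),
        "n": int(arr.size),
        "n_excluded": n_excluded,
    }
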