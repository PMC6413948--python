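"""GATA consensus scanning, cluster detection and orientation classes.

The yeast GATA factors recognize three consensus spellings — GATAA, GATAAG
and GATTAG — and functional binding platforms (UAS_NTR) consist of two sites
15-35 bp apart. Scanning supports an optional one-mismatch budget; windows
containing N are never reported as matches, even within the mismatch budget.

A GATAA nested at the core of a GATAAG match on the same strand is one site:
candidates sharing a strand-local start are merged, keeping the fewest
mismatches and, at equal mismatch count, the longest consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONSENSUS = ("GATAA", "GATAAG", "GATTAG")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Orientation = str  # one of "H-H", "H-T", "T-H", "T-T"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class MotifHit:
    """One consensus match in forward-strand coordinates of its leftmost base."""

    contig: str
    start: int
    strand: str
    motif: str
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.motif)


@dataclass(frozen=True)
class GataCluster:
    """A qualifying pair of GATA sites in genomic order."""

    hit_a: MotifHit
    hit_b: MotifHit
    gap: int

    @property
    def orientation(self) -> Orientation:
        return classify_orientation(self.hit_a.strand, self.hit_b.strand)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan_one_strand(seq: str, max_mismatch: int) -> list[tuple[int, str, int]]:
    """(local_start, motif, mismatches) for the best candidate at each start."""
    n = len(seq)
    arr = _encode(seq)
    is_n = arr == ord("N")
    best: dict[int, tuple[int, int, str]] = {}  # start -> (mm, -len, motif)
    for motif in CONSENSUS:
        L = len(motif)
        if n < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(arr, L)
        mm = (windows != _encode(motif)).sum(axis=1)
        # any N inside the window disqualifies the match outright
        has_n = np.lib.stride_tricks.sliding_window_view(is_n, L).any(axis=1)
        ok = np.flatnonzero((mm <= max_mismatch) & ~has_n)
        for s in ok:
            cand = (int(mm[s]), -L, motif)
            if s not in best or cand < best[s]:
                best[int(s)] = cand
    return [(s, motif, m) for s, (m, _negl, motif) in sorted(best.items())]


def scan_gata(seq: str, max_mismatch: int = 0, strands: str = "both",
              contig: str = ".", offset: int = 0) -> list[MotifHit]:
    """Scan a sequence for GATA consensus sites.

    Parameters
    ----------
    seq : nucleotide string over {A, C, G, T, N} (case-insensitive).
    max_mismatch : 0 or 1 tolerated mismatches per site.
    strands : "both" or "forward".
    contig, offset : coordinates to report hits under (offset = genomic
        position of ``seq[0]``).

    Minus-strand hits are reported at the forward-strand coordinate of their
    leftmost base. Overlapping spellings starting at the same strand-local
    base are merged into the single best site (fewest mismatches, then
    longest motif).
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    if strands not in ("both", "forward"):
        raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")
    hits = [MotifHit(contig, offset + s, "+", motif, mm)
            for s, motif, mm in _scan_one_strand(seq, max_mismatch)]
    if strands == "both":
        rc = revcomp(seq)
        n = len(seq)
        hits += [
            MotifHit(contig, offset + n - s - len(motif), "-", motif, mm)
            for s, motif, mm in _scan_one_strand(rc, max_mismatch)
        ]
    return sorted(hits, key=lambda h: (h.start, h.strand, h.motif))


def find_clusters(hits: Iterable[MotifHit], min_gap: int = 15,
                  max_gap: int = 35, ruler: str = "edge") -> list[GataCluster]:
    """All ordered pairs of hits spaced ``min_gap``..``max_gap`` bp apart.

    ``ruler="edge"`` measures intervening bases (downstream start minus
    upstream end, the default); ``ruler="start"`` measures start-to-start.
    A hit may participate in several clusters.
    """
    if ruler not in ("edge", "start"):
        raise ValueError(f"ruler must be 'edge' or 'start', got {ruler!r}")
    ordered = sorted(hits, key=lambda h: (h.start, h.end, h.strand))
    clusters = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if a.contig != b.contig:
                continue
            gap = b.start - (a.end if ruler == "edge" else a.start)
            if gap > max_gap:
                break
            if gap >= min_gap:
                clusters.append(GataCluster(a, b, gap))
    return clusters


def classify_orientation(strand_up: str, strand_down: str) -> Orientation:
    """Orientation label of an ordered site pair.

    A + strand motif has its head at the 5' (left) end and tail at the right;
    a - strand motif the mirror. The label reads the inward-facing ends left
    to right: (-,+) -> H-H, (+,-) -> T-T (converging), (+,+) -> T-H,
    (-,-) -> H-T.
    """
    return {("-", "+"): "H-H", ("+", "-"): "T-T",
            ("+", "+"): "T-H", ("-", "-"): "H-T"}[(strand_up, strand_down)]


def _fetch(genome, contig: str, start: int, end: int) -> str:
    if contig not in genome:
        raise KeyError(f"contig {contig!r} absent from FASTA")
    return str(genome[contig][max(start, 0):end]).upper()


def sites_per_window(windows: Mapping[str, "GenomicInterval"],
                     genome, max_mismatch: int = 0,
                     min_gap: int = 15, max_gap: int = 35) -> pd.DataFrame:
    """Count merged GATA sites (and clusters) per promoter window.

    ``genome`` is a ``pyfaidx.Fasta`` (or any mapping of contig to sliceable
    sequence). Returns a frame indexed by gene id with columns ``n_sites``
    and ``n_clusters``.
    """
    rows = []
    for gene_id, win in windows.items():
        if win.empty:
            rows.append({"gene_id": gene_id, "n_sites": 0, "n_clusters": 0})
            continue
        seq = _fetch(genome, win.contig, win.start, win.end)
        hits = scan_gata(seq, max_mismatch=max_mismatch, contig=win.contig,
                         offset=win.start)
        clusters = find_clusters(hits, min_gap, max_gap)
        rows.append({"gene_id": gene_id, "n_sites": len(hits),
                     "n_clusters": len(clusters)})
    return pd.DataFrame(rows).set_index("gene_id")


def site_histogram(counts: pd.Series) -> dict[str, int]:
    """Histogram of per-window site counts with the headline ">=2" bin."""
    vc = counts.value_counts().sort_index()
    hist = {str(int(k)): int(v) for k, v in vc.items()}
    hist["ge2"] = int((counts >= 2).sum())
    return hist


def scan_fasta(genome, max_mismatch: int = 0) -> list[MotifHit]:
    """Scan every contig of a pyfaidx.Fasta on both strands."""
    hits: list[MotifHit] = []
    for name in genome.keys():
        seq = str(genome[name][:]).upper()
        hits += scan_gata(seq, max_mismatch=max_mismatch, contig=name)
    return hits


def write_hits_bed(hits: Sequence[MotifHit], path: str | Path) -> None:
    """BED6 of hits, name = motif:mismatches."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.contig}\t{h.start}\t{h.end}\t"
                     f"{h.motif}:{h.mismatches}\t0\t{h.strand}\n")


def write_clusters_bed(clusters: Sequence[GataCluster], path: str | Path) -> None:
    """BED6 spanning each cluster, name = orientation, strand '.'."""
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.hit_a.contig}\t{c.hit_a.start}\t{c.hit_b.end}\t"
                     f"{c.orientation}\t0\t.\n")
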