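"""Peak-to-gene binding calls and the P / P&O / O / unbound partition.

A gene is *promoter-bound* when a single peak covers strictly more than 75%
of its promoter window, and *ORF-bound* when a single peak covers strictly
more than 75% of its gene body. The two boolean flags partition the gene
universe into four classes:

=========  ==============  =========
class      promoter bound  ORF bound
=========  ==============  =========
P          yes             no
P&O        yes             yes
O          no              yes
unbound    no              no
=========  ==============  =========

By default the >75% rule is evaluated against individual peaks; set
``union=True`` to measure coverage by the union of all peaks instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord, GenomicInterval, orf_interval, promoter_region

CLASS_LABELS = ("P", "P&O", "O", "unbound")


@dataclass(frozen=True)
class Peak:
    """One called enriched region (0-based half-open)."""

    contig: str
    start: int
    end: int
    peak_id: str = "."
    score: float | None = None
    summit: int | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.peak_id!r}: start must be < end")
        if self.summit is not None and not 0 <= self.summit < self.end - self.start:
            raise ValueError(f"peak {self.peak_id!r}: summit offset out of range")


def read_peaks(path: str | Path) -> list[Peak]:
    """Read peaks from BED3/BED6 or ENCODE narrowPeak (10-column).

    narrowPeak is recognized by its column count; its 10th column (summit
    offset, -1 for none) and 7th (signalValue) are carried through.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 3:
                raise ValueError(f"peak file line {lineno}: fewer than 3 fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(
                    f"peak file line {lineno}: non-integer coordinates") from exc
            name = f[3] if len(f) > 3 and f[3] != "" else f"peak_{lineno}"
            score: float | None = None
            summit: int | None = None
            if len(f) >= 10:  # narrowPeak
                score = float(f[6])
                s = int(f[9])
                summit = s if s >= 0 else None
            elif len(f) >= 5:
                try:
                    score = float(f[4])
                except ValueError:
                    score = None
            peaks.append(Peak(f[0], start, end, name, score, summit))
    return peaks


def overlap_fraction(region: GenomicInterval, peak: Peak) -> float:
    """Fraction of ``region`` covered by ``peak`` (0 for empty regions)."""
    if region.empty:
        warnings.warn(f"empty region {region.name!r}: overlap fraction set to 0")
        return 0.0
    if region.contig != peak.contig:
        return 0.0
    inter = min(region.end, peak.end) - max(region.start, peak.start)
    return max(inter, 0) / region.length


class _PeakIndex:
    """Per-contig vectorized peak coordinates for fast max-overlap queries."""

    def __init__(self, peaks: Sequence[Peak]):
        self.by_contig: dict[str, dict[str, np.ndarray]] = {}
        self.peaks_by_contig: dict[str, list[Peak]] = {}
        for contig in {p.contig for p in peaks}:
            sub = sorted((p for p in peaks if p.contig == contig),
                         key=lambda p: (p.start, p.end))
            self.peaks_by_contig[contig] = sub
            self.by_contig[contig] = {
                "start": np.array([p.start for p in sub]),
                "end": np.array([p.end for p in sub]),
                "score": np.array([p.score if p.score is not None else -np.inf
                                   for p in sub]),
            }

    def best_fraction(self, region: GenomicInterval) -> tuple[float, Peak | None]:
        """Max single-peak overlap fraction and the peak achieving it.

        Ties broken by leftmost peak start, then by higher score.
        """
        if region.empty or region.contig not in self.by_contig:
            return 0.0, None
        arr = self.by_contig[region.contig]
        inter = (np.minimum(region.end, arr["end"])
                 - np.maximum(region.start, arr["start"]))
        frac = np.clip(inter, 0, None) / region.length
        best = frac.max(initial=0.0)
        if best <= 0.0:
            return 0.0, None
        idx = np.flatnonzero(frac == best)
        if idx.size > 1:  # leftmost start (already sorted), then higher score
            starts = arr["start"][idx]
            idx = idx[starts == starts.min()]
            if idx.size > 1:
                idx = idx[np.argsort(-arr["score"][idx], kind="stable")]
        peak = self.peaks_by_contig[region.contig][int(idx[0])]
        return float(best), peak

    def union_fraction(self, region: GenomicInterval) -> float:
        """Fraction of the region covered by the union of all peaks."""
        if region.empty or region.contig not in self.by_contig:
            return 0.0
        arr = self.by_contig[region.contig]
        covered = np.zeros(region.length, dtype=bool)
        lo = np.maximum(arr["start"] - region.start, 0)
        hi = np.minimum(arr["end"] - region.start, region.length)
        for a, b in zip(lo, hi):
            if b > a:
                covered[a:b] = True
        return float(covered.mean())


def _call_bound(regions: Mapping[str, GenomicInterval], peaks: Sequence[Peak],
                threshold: float, union: bool) -> pd.DataFrame:
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    index = _PeakIndex(peaks)
    rows = []
    for gene_id, region in regions.items():
        if union:
            frac, best = index.union_fraction(region), None
        else:
            frac, best = index.best_fraction(region)
        rows.append({
            "gene_id": gene_id,
            "bound": frac > threshold,  # strict: exactly 75% is NOT bound
            "fraction": frac,
            "best_peak": best.peak_id if best is not None else "",
        })
    return pd.DataFrame(rows).set_index("gene_id")


def call_promoter_bound(genes: Sequence[GeneRecord], peaks: Sequence[Peak],
                        threshold: float = 0.75, far: int = 350, near: int = 100,
                        contig_lengths: Mapping[str, int] | None = None,
                        union: bool = False) -> pd.DataFrame:
    """Flag genes whose promoter window is covered > ``threshold`` by a peak."""
    regions = {
        g.gene_id: promoter_region(
            g, far, near,
            contig_lengths.get(g.contig) if contig_lengths else None)
        for g in genes
    }
    return _call_bound(regions, peaks, threshold, union)


def call_orf_bound(genes: Sequence[GeneRecord], peaks: Sequence[Peak],
                   threshold: float = 0.75,
                   union: bool = False) -> pd.DataFrame:
    """Flag genes whose gene body [start, end) is covered > ``threshold``."""
    regions = {g.gene_id: orf_interval(g) for g in genes}
    return _call_bound(regions, peaks, threshold, union)


def classify_genes(promoter_calls: pd.DataFrame,
                   orf_calls: pd.DataFrame) -> pd.DataFrame:
    """Combine promoter and ORF flags into the exhaustive 4-class partition."""
    sym = set(promoter_calls.index).symmetric_difference(orf_calls.index)
    if sym:
        raise ValueError(
            f"promoter and ORF calls cover different gene universes; "
            f"symmetric difference: {sorted(sym)}")
    orf = orf_calls.loc[promoter_calls.index]
    p, o = promoter_calls["bound"].to_numpy(), orf["bound"].to_numpy()
    label = np.select([p & ~o, p & o, ~p & o], ["P", "P&O", "O"],
                      default="unbound")
    return pd.DataFrame({
        "promoter_bound": p,
        "orf_bound": o,
        "class": label,
        "promoter_fraction": promoter_calls["fraction"],
        "orf_fraction": orf["fraction"],
        "best_promoter_peak": promoter_calls["best_peak"],
        "best_orf_peak": orf["best_peak"],
    }, index=promoter_calls.index)


def peak_promoter_multiplicity(peaks: Sequence[Peak],
                               genes: Sequence[GeneRecord],
                               threshold: float = 0.75, far: int = 350,
                               near: int = 100,
                               contig_lengths: Mapping[str, int] | None = None,
                               ) -> pd.DataFrame:
    """Per-peak count of promoters covered > threshold, with divergence flag.

    A peak is flagged ``divergent`` when at least two of the promoters it
    covers belong to genes on opposite strands transcribed away from each
    other (the - strand gene entirely to the left of the + strand gene).
    """
    promoters = [
        (g, promoter_region(g, far, near,
                            contig_lengths.get(g.contig) if contig_lengths else None))
        for g in genes
    ]
    rows = []
    for peak in peaks:
        hit_genes = [g for g, region in promoters
                     if overlap_fraction(region, peak) > threshold]
        divergent = any(
            a.strand == "-" and b.strand == "+" and a.end <= b.start
            for a in hit_genes for b in hit_genes
        )
        rows.append({
            "peak_id": peak.peak_id,
            "n_promoters": len(hit_genes),
            "divergent": divergent,
            "gene_ids": ",".join(g.gene_id for g in hit_genes),
        })
    return pd.DataFrame(rows).set_index("peak_id")


def write_binding_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t")


def class_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Counts per binding class, all four classes always reported."""
    counts = calls["class"].value_counts()
    return {label: int(counts.get(label, 0)) for label in CLASS_LABELS}
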