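"""ATG-anchored coverage windows, metagene profiles and heatmap matrices.

Coverage tracks are dense per-contig vectors of normalized signal (tag/nt),
read from 4-column bedGraph. Windows are extracted strand-aware around the
ATG (default +/- 600 bp) and oriented 5'->3' of the gene, so positive axis
positions always point into the gene body. Positions clamped off a contig
edge are missing (NaN), and per-position sample sizes adjust accordingly —
no zero-filling.

The default 95% confidence band is the normal approximation, mean +/-
1.96 * SEM per position; a seeded bootstrap alternative is provided.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


def read_bedgraph(path: str | Path,
                  contig_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Expand a 4-column bedGraph (0-based half-open) into dense vectors."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["contig", "start", "end", "value"],
                     comment="#", dtype={"contig": str})
    track = {c: np.zeros(length, dtype=float)
             for c, length in contig_lengths.items()}
    for contig, sub in df.groupby("contig", sort=False):
        if contig not in track:
            raise KeyError(f"contig {contig!r} absent from contig_lengths")
        vec = track[contig]
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            if end > len(vec):
                raise ValueError(f"bedGraph interval [{start},{end}) exceeds "
                                 f"contig {contig!r} length {len(vec)}")
            vec[start:end] = value
    return track


def write_bedgraph(track: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Run-length encode dense vectors back to bedGraph (zeros included)."""
    with open(path, "w") as fh:
        for contig in track:
            vec = np.asarray(track[contig])
            if vec.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [vec.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{vec[s]:g}\n")


def window_coverage(track: Mapping[str, np.ndarray], gene: GeneRecord,
                    half_width: int = 600) -> np.ndarray:
    """Signal over ATG +/- ``half_width``, oriented 5'->3' of the gene.

    Returns a vector of length ``2 * half_width + 1`` whose middle entry is
    the ATG base; out-of-contig positions are NaN.
    """
    if gene.contig not in track:
        raise KeyError(f"contig {gene.contig!r} absent from coverage track")
    vec = track[gene.contig]
    atg = gene.atg
    out = np.full(2 * half_width + 1, np.nan)
    lo, hi = atg - half_width, atg + half_width + 1
    src_lo, src_hi = max(lo, 0), min(hi, len(vec))
    if src_hi > src_lo:
        out[src_lo - lo:src_hi - lo] = vec[src_lo:src_hi]
    if gene.strand == "-":
        out = out[::-1]
    return out


def profile(vectors: Sequence[np.ndarray], ci: str = "normal",
            n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Average window vectors into a metagene profile with a 95% CI band.

    Missing positions are excluded per position (``n`` adjusts). Positions
    with a single available gene get a zero half-width band and are counted
    in ``n``; positions with none are NaN throughout.
    """
    if len(vectors) == 0:
        raise ValueError("need at least one window vector")
    mat = np.vstack(vectors)
    half_width = (mat.shape[1] - 1) // 2
    n = (~np.isnan(mat)).sum(axis=0)
    denom = np.maximum(n, 1)
    mean = np.where(n > 0, np.nansum(mat, axis=0) / denom, np.nan)
    if ci == "normal":
        # nan-safe sample SD without nanstd's all-NaN RuntimeWarning
        sq = np.nansum((mat - np.where(n > 0, mean, 0.0)) ** 2, axis=0)
        sd = np.sqrt(sq / np.maximum(n - 1, 1))
        half = np.where(n > 1, Z_95 * sd / np.sqrt(denom), 0.0)
    elif ci == "bootstrap":
        half = _bootstrap_halfwidth(mat, mean, n_boot, seed)
    else:
        raise ValueError(f"ci must be 'normal' or 'bootstrap', got {ci!r}")
    half = np.where(n > 0, half, np.nan)
    return pd.DataFrame({
        "position": np.arange(-half_width, half_width + 1),
        "mean": mean,
        "ci_low": mean - half,
        "ci_high": mean + half,
        "n": n,
    })


def _bootstrap_halfwidth(mat: np.ndarray, mean: np.ndarray, n_boot: int,
                         seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n_genes = mat.shape[0]
    boots = np.empty((n_boot, mat.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n_genes, size=n_genes)
        boots[b] = np.nanmean(mat[idx], axis=0)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return np.maximum(hi - mean, mean - lo)


def heatmap_matrix(vectors: Mapping[str, np.ndarray],
                   sort_key: str = "total") -> pd.DataFrame:
    """Gene x position matrix, rows sorted by signal, descending.

    ``sort_key``: "total" sums the whole window; "promoter" sums the
    upstream half (negative axis positions only). Missing cells stay NaN.
    """
    if sort_key not in ("total", "promoter"):
        raise ValueError(f"sort_key must be 'total' or 'promoter', got {sort_key!r}")
    ids = list(vectors)
    mat = np.vstack([vectors[g] for g in ids])
    half_width = (mat.shape[1] - 1) // 2
    region = mat[:, :half_width] if sort_key == "promoter" else mat
    with np.errstate(invalid="ignore"):
        keys = np.nansum(region, axis=1)
    order = np.argsort(-keys, kind="stable")
    return pd.DataFrame(mat[order], index=[ids[i] for i in order],
                        columns=np.arange(-half_width, half_width + 1))


def class_profiles(track: Mapping[str, np.ndarray],
                   genes: Sequence[GeneRecord], classes: pd.Series,
                   half_width: int = 600, ci: str = "normal",
                   per_gene_max_norm: bool = False,
                   seed: int = 0) -> dict[str, pd.DataFrame]:
    """One metagene profile per binding class present in ``classes``."""
    by_class: dict[str, list[np.ndarray]] = {}
    for gene in genes:
        vec = window_coverage(track, gene, half_width)
        if per_gene_max_norm:
            peak = np.nanmax(vec)
            if peak > 0:
                vec = vec / peak
        by_class.setdefault(str(classes.loc[gene.gene_id]), []).append(vec)
    return {label: profile(vecs, ci=ci, seed=seed)
            for label, vecs in sorted(by_class.items())}
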