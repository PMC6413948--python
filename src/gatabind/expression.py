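"""Tag-density normalization and regulation-class assignment.

Densities are tag/nt per million mapped reads: ``count / gene_length /
library_size * 1e6``, with library size the total reads uniquely mapped to
ORFs (column sums when no sample sheet value is given). Replicates are
aggregated by the arithmetic mean of densities.

Two fold-change/p-value rules classify genes, both with *inclusive*
thresholds (ratio >= 2 or <= 0.5, p <= 0.01):

* nitrogen class from proline vs glutamine in wild type: up in proline is
  NCR-sensitive, down is revNCR-sensitive, otherwise unaffected;
* Dal80 class from dal80-delta vs wild type (proline): up in the mutant is
  Dal80-repressed, down is Dal80-activated, otherwise insensitive.

The bundled differential test is a documented stand-in (Welch t on log2
densities with a 0.5 pseudocount on raw counts), not the negative-binomial
test used on the original data; every result carries a method tag, and an
externally computed fold-change/p table can be supplied instead.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

NITROGEN_CLASSES = ("NCR", "revNCR", "unaffected")
DAL80_CLASSES = ("activated", "repressed", "insensitive")

STANDIN_METHOD = "welch_t_log2_density"


def read_counts(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a count TSV (gene_id, length, one column per sample).

    Returns (counts indexed by gene_id, lengths in nt).
    """
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "length" not in df.columns:
        raise ValueError("count table must carry a 'length' column")
    lengths = df["length"].astype(float)
    counts = df.drop(columns="length")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts in table")
    if (lengths <= 0).any():
        raise ValueError("non-positive gene lengths in table")
    return counts, lengths


def read_sample_sheet(path: str | Path,
                      counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a sample sheet (sample, condition, replicate[, library_size]).

    Missing library sizes are filled from the column sums of ``counts``.
    """
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample", "condition", "replicate"}
    if missing := required - set(sheet.columns):
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if "library_size" not in sheet.columns:
        if counts is None:
            raise ValueError("no library_size column and no counts to sum")
        sheet["library_size"] = sheet["sample"].map(counts.sum(axis=0))
    return sheet


def normalize_density(counts: pd.DataFrame, lengths: pd.Series,
                      library_sizes: pd.Series) -> pd.DataFrame:
    """Per-gene, per-sample density: count / length / library_size * 1e6."""
    lengths = lengths.reindex(counts.index)
    library_sizes = library_sizes.reindex(counts.columns)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths, axis=0).div(library_sizes, axis=1) * 1e6


def condition_means(densities: pd.DataFrame,
                    sheet: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean density per condition (columns = conditions)."""
    groups = sheet.groupby("condition")["sample"].apply(list)
    return pd.DataFrame({cond: densities[samples].mean(axis=1)
                         for cond, samples in groups.items()})


def standin_de_test(counts_ref: Sequence[float], counts_alt: Sequence[float],
                    length: float = 1.0,
                    lib_ref: Sequence[float] | None = None,
                    lib_alt: Sequence[float] | None = None,
                    pseudocount: float = 0.5) -> dict:
    """Stand-in differential test for one gene.

    ``fold_change`` is the ratio of mean pseudocounted densities,
    alt over ref (so the reference condition is the denominator);
    ``p_value`` comes from a two-sided Welch t test on log2 densities.
    """
    a = np.asarray(counts_ref, dtype=float)
    b = np.asarray(counts_alt, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per condition")
    la = np.ones_like(a) if lib_ref is None else np.asarray(lib_ref, dtype=float)
    lb = np.ones_like(b) if lib_alt is None else np.asarray(lib_alt, dtype=float)
    dens_a = (a + pseudocount) / length / la * 1e6
    dens_b = (b + pseudocount) / length / lb * 1e6
    fc = dens_b.mean() / dens_a.mean()
    p = _welch_p(np.log2(dens_a)[None, :], np.log2(dens_b)[None, :])[0]
    return {"fold_change": float(fc), "p_value": float(p),
            "method": STANDIN_METHOD}


def _welch_p(log_a: np.ndarray, log_b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch t p-values with degenerate-variance guards."""
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # near-constant groups trigger scipy's precision-loss warning; the
        # degenerate cases are resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(log_a, log_b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    # both groups constant: p = 1 when the means agree, 0 otherwise
    degenerate = np.isnan(p)
    if degenerate.any():
        same = np.isclose(log_a.mean(axis=1), log_b.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return p


def de_table(counts: pd.DataFrame, lengths: pd.Series, sheet: pd.DataFrame,
             condition_ref: str, condition_alt: str,
             pseudocount: float = 0.5) -> pd.DataFrame:
    """Vectorized stand-in test for every gene, alt vs ref.

    Returns a frame with ``fold_change``, ``p_value`` and ``method``.
    """
    sheet = sheet.set_index("sample")
    ref_samples = sheet.index[sheet["condition"] == condition_ref]
    alt_samples = sheet.index[sheet["condition"] == condition_alt]
    if len(ref_samples) < 2 or len(alt_samples) < 2:
        raise ValueError("need >= 2 replicates per condition")
    libs = sheet["library_size"]
    dens = normalize_density(counts + pseudocount, lengths, libs)
    a = dens[ref_samples].to_numpy()
    b = dens[alt_samples].to_numpy()
    fc = b.mean(axis=1) / a.mean(axis=1)
    p = _welch_p(np.log2(a), np.log2(b))
    return pd.DataFrame({"fold_change": fc, "p_value": p,
                         "method": STANDIN_METHOD}, index=counts.index)


def _classify(fc, p, labels: tuple[str, str, str], up: float, down: float,
              alpha: float):
    """Shared inclusive-threshold rule: (up_label, down_label, null_label)."""
    fc = np.asarray(fc, dtype=float)
    p = np.asarray(p, dtype=float)
    undefined = ~np.isfinite(fc)
    out = np.select(
        [~undefined & (fc >= up) & (p <= alpha),
         ~undefined & (fc <= down) & (p <= alpha)],
        [labels[0], labels[1]], default=labels[2])
    return out, undefined


def classify_nitrogen(fc, p, up: float = 2.0, down: float = 0.5,
                      alpha: float = 0.01):
    """NCR / revNCR / unaffected from the proline-vs-glutamine ratio."""
    out, _ = _classify(fc, p, ("NCR", "revNCR", "unaffected"), up, down, alpha)
    return out if out.ndim else str(out)


def classify_dal80(fc, p, up: float = 2.0, down: float = 0.5,
                   alpha: float = 0.01):
    """repressed / activated / insensitive from the mutant-vs-WT ratio."""
    out, _ = _classify(fc, p, ("repressed", "activated", "insensitive"),
                       up, down, alpha)
    return out if out.ndim else str(out)


def classify_regulation(nitrogen_de: pd.DataFrame, dal80_de: pd.DataFrame,
                        up: float = 2.0, down: float = 0.5,
                        alpha: float = 0.01) -> pd.DataFrame:
    """Combine both fold-change/p tables into per-gene RegulationCall rows."""
    sym = set(nitrogen_de.index).symmetric_difference(dal80_de.index)
    if sym:
        raise ValueError(f"gene universes differ; symmetric difference: "
                         f"{sorted(sym)}")
    dal80_de = dal80_de.loc[nitrogen_de.index]
    return pd.DataFrame({
        "nitrogen_class": classify_nitrogen(
            nitrogen_de["fold_change"], nitrogen_de["p_value"], up, down, alpha),
        "dal80_class": classify_dal80(
            dal80_de["fold_change"], dal80_de["p_value"], up, down, alpha),
        "fc_pro_vs_gln": nitrogen_de["fold_change"],
        "p_pro_vs_gln": nitrogen_de["p_value"],
        "fc_mut_vs_wt": dal80_de["fold_change"],
        "p_mut_vs_wt": dal80_de["p_value"],
        "method": nitrogen_de.get("method", STANDIN_METHOD),
    }, index=nitrogen_de.index)
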