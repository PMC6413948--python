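"""Contingency tables, chi-square independence tests and rank-sum tests.

The chi-square test is the plain Pearson test of independence: statistic
``sum((o - e)^2 / e)`` with ``e_ij = row_i * col_j / N``, degrees of freedom
``(r - 1)(c - 1)``, and upper-tail p-value evaluated through the regularized
upper incomplete gamma function. No continuity correction is applied by
default; expected cells below 5 raise a warning flag, not an error.

The rank-sum test is the two-sided Wilcoxon/Mann-Whitney test: exact by full
enumeration of the rank-sum distribution when both samples have at most
``exact_max_n`` observations (default 8, midranks for ties), otherwise the
normal approximation with tie correction.

``set_enrichment`` expresses an overlap between a fixed gene list and a hit
set within a common universe as a 2x2 table tested the same way, with the
fold over the independence expectation reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

#: Universe size used for reconstructing the published genome-wide tables:
#: unaffected + NCR + revNCR protein-coding genes (4116 + 754 + 928).
PUBLISHED_UNIVERSE = 5798


@dataclass
class ContingencyTable:
    """An r x c table of joint counts with derived margins and expecteds."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.table.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative cell counts")
        if arr.sum() <= 0:
            raise ValueError("grand total must be positive")

    @property
    def observed(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    @property
    def row_totals(self) -> np.ndarray:
        return self.observed.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.observed.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.observed.sum())

    @property
    def expected(self) -> np.ndarray:
        return np.outer(self.row_totals, self.col_totals) / self.total


@dataclass
class TestResult:
    """Outcome of one statistical test, JSON-serializable."""

    statistic: float
    p_value: float
    method: str
    df: int | None = None
    warnings: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"statistic": self.statistic, "p_value": self.p_value,
               "method": self.method}
        if self.df is not None:
            out["df"] = self.df
        if self.warnings:
            out["warnings"] = self.warnings
        out.update(self.extra)
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def contingency(labels_a: pd.Series, labels_b: pd.Series) -> ContingencyTable:
    """Joint-count table of two per-gene categorical labelings."""
    if len(labels_a) == 0 or len(labels_b) == 0:
        raise ValueError("empty label sets")
    sym = set(labels_a.index).symmetric_difference(labels_b.index)
    if sym:
        raise ValueError(f"label universes differ; symmetric difference: "
                         f"{sorted(sym)}")
    return ContingencyTable(pd.crosstab(labels_a, labels_b.loc[labels_a.index]))


def chi_square_upper_tail(statistic: float, df: int) -> float:
    """Upper-tail chi-square probability via the regularized upper
    incomplete gamma function Q(df/2, x/2)."""
    return float(special.gammaincc(df / 2.0, statistic / 2.0))


def chi_square_independence(table: ContingencyTable,
                            yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c table."""
    obs = table.observed
    if (table.row_totals == 0).any() or (table.col_totals == 0).any():
        raise ValueError("zero row or column margin")
    exp = table.expected
    diff = np.abs(obs - exp)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / exp).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    warns = []
    if (exp < 5).any():
        warns.append(f"{int((exp < 5).sum())} expected cell(s) < 5")
    p = chi_square_upper_tail(stat, df) if df > 0 else 1.0
    return TestResult(stat, p, "pearson_chi_square" + ("_yates" if yates else ""),
                      df=df, warnings=warns)


def _midranks(values: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties) of a 1-D array."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _exact_rank_sum_p(ranks: np.ndarray, n_x: int, w_obs: float) -> float:
    """Two-sided exact p by enumerating all C(n, n_x) rank assignments."""
    total = comb(len(ranks), n_x)
    n_le = n_ge = 0
    eps = 1e-9
    for combo in combinations(ranks, n_x):
        w = sum(combo)
        if w <= w_obs + eps:
            n_le += 1
        if w >= w_obs - eps:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def rank_sum(x: Sequence[float], y: Sequence[float],
             exact_max_n: int = 8) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both samples have <= ``exact_max_n`` values;
    otherwise the normal approximation with tie correction and no
    continuity correction. Midranks are used for ties throughout.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n_x, n_y = x.size, y.size
    w = float(ranks[:n_x].sum())
    u = w - n_x * (n_x + 1) / 2.0
    if n_x <= exact_max_n and n_y <= exact_max_n:
        p = _exact_rank_sum_p(ranks, n_x, w)
        return TestResult(u, p, "wilcoxon_rank_sum_exact",
                          extra={"U": u, "W": w})
    n = n_x + n_y
    mu = n_x * n_y / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n_x * n_y / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:  # all values identical
        return TestResult(u, 1.0, "wilcoxon_rank_sum_normal",
                          warnings=["zero variance (all values tied)"],
                          extra={"U": u, "W": w, "z": 0.0})
    z = (u - mu) / np.sqrt(sigma2)
    p = float(2.0 * special.ndtr(-abs(z)))
    return TestResult(u, p, "wilcoxon_rank_sum_normal",
                      extra={"U": u, "W": w, "z": float(z)})


def set_enrichment(list_hits: int, list_size: int, universe_hits: int,
                   universe_size: int) -> tuple[ContingencyTable, TestResult]:
    """Overlap of a gene list with a hit set, as a 2x2 chi-square test.

    Rows: in-list vs out-of-list; columns: hit vs non-hit. The fold over the
    independence expectation (``list_size * universe_hits / universe_size``)
    is reported in the result's extras.
    """
    remainder = universe_size - list_size - universe_hits + list_hits
    cells = {
        ("list", "hit"): list_hits,
        ("list", "non_hit"): list_size - list_hits,
        ("rest", "hit"): universe_hits - list_hits,
        ("rest", "non_hit"): remainder,
    }
    if any(v < 0 for v in cells.values()):
        raise ValueError(f"inconsistent counts: {cells}")
    table = ContingencyTable(pd.DataFrame(
        [[cells[("list", "hit")], cells[("list", "non_hit")]],
         [cells[("rest", "hit")], cells[("rest", "non_hit")]]],
        index=["list", "rest"], columns=["hit", "non_hit"]))
    result = chi_square_independence(table)
    expected_hits = list_size * universe_hits / universe_size
    result.extra.update({
        "expected_hits": expected_hits,
        "fold_enrichment": list_hits / expected_hits if expected_hits else np.nan,
    })
    return table, result
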