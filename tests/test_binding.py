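import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gatabind.annotation import GeneRecord, GenomicInterval, promoter_region
from gatabind.binding import (Peak, call_orf_bound, call_promoter_bound,
                              class_counts, classify_genes, overlap_fraction,
                              peak_promoter_multiplicity, read_peaks)


class TestOverlapFraction:
    region = GenomicInterval("chrI", 650, 900)

    @pytest.mark.parametrize("peak, expected", [
        (Peak("chrI", 600, 900), 1.0),
        (Peak("chrI", 700, 900), 0.8),
        (Peak("chrI", 0, 100), 0.0),
        (Peak("chrII", 650, 900), 0.0),  # different contig
    ])
    def test_examples(self, peak, expected):
        assert overlap_fraction(self.region, peak) == pytest.approx(expected)

    def test_empty_region_is_zero_with_warning(self):
        empty = GenomicInterval("chrI", 100, 100, name="x")
        with pytest.warns(UserWarning):
            assert overlap_fraction(empty, Peak("chrI", 0, 500)) == 0.0


class TestBoundaryRule:
    """The >75% rule is a strict inequality on single-peak coverage."""

    def test_250bp_promoter_boundary_cases(self, plus_gene):
        # promoter [650, 900); peaks covering 187, 188 (=0.752) and 200 bp
        for peak_start, bound in ((713, False), (712, True), (700, True)):
            calls = call_promoter_bound([plus_gene],
                                        [Peak("chrI", peak_start, 900)])
            assert bool(calls.loc["geneA", "bound"]) is bound

    def test_fraction_exactly_three_quarters_is_unbound(self, plus_gene):
        peak = Peak("chrI", 650, 650 + 188, "p")  # 188/250 = 0.752
        calls = call_promoter_bound([plus_gene], [peak])
        assert calls.loc["geneA", "fraction"] == pytest.approx(0.752)
        exact = call_promoter_bound([plus_gene],
                                    [Peak("chrI", 650, 650 + 187)])
        # 187.5 is not an integer bp; use the ORF rule for the exact case
        orf_gene = GeneRecord("chrI", 0, 1000, "+", "g")
        at_threshold = call_orf_bound([orf_gene], [Peak("chrI", 0, 750)])
        above = call_orf_bound([orf_gene], [Peak("chrI", 0, 760)])
        assert not at_threshold.loc["g", "bound"]
        assert at_threshold.loc["g", "fraction"] == pytest.approx(0.75)
        assert above.loc["g", "bound"]
        assert not exact.loc["geneA", "bound"]

    def test_single_peak_rule_vs_union(self, plus_gene):
        # two peaks covering 60% + 40% of the promoter: unbound under the
        # single-peak rule, bound when union coverage is requested
        peaks = [Peak("chrI", 650, 800, "a"), Peak("chrI", 800, 900, "b")]
        single = call_promoter_bound([plus_gene], peaks)
        union = call_promoter_bound([plus_gene], peaks, union=True)
        assert not single.loc["geneA", "bound"]
        assert union.loc["geneA", "bound"]
        assert union.loc["geneA", "fraction"] == pytest.approx(1.0)

    def test_tie_broken_by_leftmost_start(self, plus_gene):
        peaks = [Peak("chrI", 700, 900, "right"), Peak("chrI", 650, 850, "left")]
        calls = call_promoter_bound([plus_gene], peaks)
        assert calls.loc["geneA", "best_peak"] == "left"


class TestClassification:
    def test_flag_combinations(self):
        idx = ["a", "b", "c", "d"]
        prom = pd.DataFrame({"bound": [True, True, False, False],
                             "fraction": 0.9, "best_peak": "p"}, index=idx)
        orf = pd.DataFrame({"bound": [False, True, True, False],
                            "fraction": 0.9, "best_peak": "p"}, index=idx)
        calls = classify_genes(prom, orf)
        assert list(calls["class"]) == ["P", "P&O", "O", "unbound"]

    def test_universe_mismatch_reports_difference(self):
        prom = pd.DataFrame({"bound": [True], "fraction": 1.0,
                             "best_peak": ""}, index=["a"])
        orf = pd.DataFrame({"bound": [True], "fraction": 1.0,
                            "best_peak": ""}, index=["b"])
        with pytest.raises(ValueError, match="'a'.*'b'|'b'.*'a'"):
            classify_genes(prom, orf)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(flags=st.lists(st.tuples(st.booleans(), st.booleans()),
                          min_size=1, max_size=30))
    def test_partition_property(self, flags):
        """|P| + |P&O| + |O| + |unbound| equals the universe size, always."""
        idx = [f"g{i}" for i in range(len(flags))]
        prom = pd.DataFrame({"bound": [p for p, _ in flags],
                             "fraction": 0.0, "best_peak": ""}, index=idx)
        orf = pd.DataFrame({"bound": [o for _, o in flags],
                            "fraction": 0.0, "best_peak": ""}, index=idx)
        counts = class_counts(classify_genes(prom, orf))
        assert sum(counts.values()) == len(flags)


class TestOracleEquivalence:
    """Vectorized calls match a per-base brute force on toy inputs."""

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(data=st.data())
    def test_matches_per_base_count(self, data):
        n_genes = data.draw(st.integers(1, 12))
        n_peaks = data.draw(st.integers(0, 12))
        genes = []
        pos = 500
        for i in range(n_genes):
            length = data.draw(st.integers(50, 400))
            genes.append(GeneRecord("c", pos, pos + length,
                                    data.draw(st.sampled_from("+-")), f"g{i}"))
            pos += length + data.draw(st.integers(400, 800))
        peaks = [
            Peak("c", s, s + data.draw(st.integers(1, 600)), f"p{j}")
            for j in range(n_peaks)
            for s in [data.draw(st.integers(0, pos))]
        ]
        calls = call_orf_bound(genes, peaks)
        for gene in genes:
            best = 0.0
            for peak in peaks:
                covered = sum(1 for b in range(gene.start, gene.end)
                              if peak.start <= b < peak.end)
                best = max(best, covered / gene.length)
            assert calls.loc[gene.gene_id, "fraction"] == pytest.approx(best)
            assert bool(calls.loc[gene.gene_id, "bound"]) == (best > 0.75)

    def test_threshold_monotonicity(self, rng):
        genes = [GeneRecord("c", 1000 * i + 500, 1000 * i + 900, "+", f"g{i}")
                 for i in range(10)]
        starts = rng.integers(0, 10_000, size=15)
        peaks = [Peak("c", int(s), int(s) + int(w), f"p{i}") for i, (s, w) in
                 enumerate(zip(starts, rng.integers(50, 800, size=15)))]
        lo = call_promoter_bound(genes, peaks, threshold=0.5)
        hi = call_promoter_bound(genes, peaks, threshold=0.9)
        assert set(hi.index[hi["bound"]]) <= set(lo.index[lo["bound"]])


class TestMultiplicity:
    def test_divergent_pair_flagged(self):
        left = GeneRecord("c", 500, 1500, "-", "left")    # promoter ~[1600,1850)
        right = GeneRecord("c", 2100, 3000, "+", "right")  # promoter [1750,2000)
        peak = Peak("c", 1500, 2100, "big")
        table = peak_promoter_multiplicity([peak], [left, right])
        assert table.loc["big", "n_promoters"] == 2
        assert bool(table.loc["big", "divergent"])

    def test_single_and_zero_promoter_peaks(self, plus_gene):
        table = peak_promoter_multiplicity(
            [Peak("chrI", 640, 910, "cover"), Peak("chrI", 5000, 5200, "far")],
            [plus_gene])
        assert table.loc["cover", "n_promoters"] == 1
        assert not table.loc["cover", "divergent"]
        assert table.loc["far", "n_promoters"] == 0

    def test_convergent_pair_not_divergent(self):
        # +/- genes transcribed toward each other share no promoter gap
        a = GeneRecord("c", 500, 1500, "+", "a")
        b = GeneRecord("c", 2000, 3000, "-", "b")
        peak = Peak("c", 0, 4000, "huge")
        table = peak_promoter_multiplicity([peak], [a, b])
        assert table.loc["huge", "n_promoters"] == 2
        assert not bool(table.loc["huge", "divergent"])


class TestPeakIO:
    def test_narrowpeak_summit_and_score(self, tmp_path):
        path = tmp_path / "peaks.narrowPeak"
        path.write_text("chrI\t100\t400\tpk1\t900\t.\t12.5\t30.1\t25.0\t150\n"
                        "chrI\t600\t800\tpk2\t500\t.\t8.0\t10.0\t9.0\t-1\n")
        peaks = read_peaks(path)
        assert peaks[0].summit == 150 and peaks[0].score == 12.5
        assert peaks[1].summit is None

    def test_bed3_gets_generated_ids(self, tmp_path):
        path = tmp_path / "peaks.bed"
        path.write_text("chrI\t0\t100\nchrI\t200\t300\n")
        peaks = read_peaks(path)
        assert [p.peak_id for p in peaks] == ["peak_1", "peak_2"]

    def test_genes_on_peakless_contig_unbound(self, plus_gene):
        calls = call_promoter_bound([plus_gene], [Peak("chrX", 0, 100)])
        assert not calls.loc["geneA", "bound"]
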