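# Methods

This note records the scientific conventions, default parameters and design
choices behind `gatabind`, and what the synthetic-data tests do and do not
establish.

## Coordinates and windows

All internal coordinates are 0-based half-open; BED passes through, GFF3 is
converted on read. The anchor for every upstream window is the ATG (first
coding base), not the TSS: TSSs are unevenly annotated in yeast, and the
TSS–ATG distance is short (the `tss_atg_summary` helper quantifies it for
any annotation that carries TSSs).

Two windows are derived per gene, both strand-aware and clamped (never
errored) at contig edges:

| window   | offsets from ATG | length | used for        |
|----------|------------------|--------|-----------------|
| promoter | −350..−101       | 250 bp | binding calls   |
| motif    | −500..−1         | 500 bp | GATA counting   |

The promoter window is the half-open reading of "−350 to −100": upstream
bound inclusive, near bound exclusive. The source convention is ambiguous
(250 vs 251 bp); both bounds are parameters, so the inclusive reading
(`near=99`) is one keyword away. The motif window is defined as the 500
bases immediately upstream of the ATG; with the same half-open formula this
corresponds to `far=500, near=0`.

## Binding rule

A region is bound when a **single** peak covers **strictly more** than the
threshold (default 0.75) of it. Single-peak coverage is the literal reading
of the rule; a `union=True` switch measures coverage by the union of peaks
instead. Ties between peaks at the same maximal fraction resolve to the
leftmost start, then the higher score, for determinism. Genes on contigs
absent from the peak set are unbound, not errors. Each promoter is assessed
independently even when one peak spans several promoters; the
`peak_promoter_multiplicity` table reports those cases and flags divergent
pairs (a − strand gene entirely left of a + strand gene, transcribed apart).

## GATA motif scanning

Consensus spellings: GATAA, GATAAG, GATTAG, scanned on both strands with a
mismatch budget of 0 or 1. Matches containing N are disqualified outright,
even within the budget — conservative by intent. Candidates sharing a
strand-local start merge into one site keeping the fewest mismatches, then
the longest spelling: an exact GATAAG therefore reports once (not as a
nested GATAA too), and an exact GATAA is never displaced by a degenerate
longer spelling.

Cluster spacing (default 15–35 bp) is measured as intervening bases between
motif edges — end of the upstream site to start of the downstream site,
inclusive bounds — matching the protein-spacing intuition; a
`ruler="start"` option reproduces start-to-start measurements since the
original convention is not derivable from the text. The orientation of an
ordered pair follows from the strands, with "head" fixed as the 5' end of
the consensus as written: (−,+) → H-H, (+,−) → T-T (converging sites),
(+,+) → T-H, (−,−) → H-T. This mapping is itself a convention and is
documented rather than discovered.

## Expression and regulation classes

Density is count / gene length (nt) / library size × 10⁶ (tag/nt per
million mapped), with library sizes taken from the sample sheet or column
sums. Replicates aggregate by the arithmetic mean of densities — the
simplest defensible choice where no aggregation is specified.

Classification thresholds are inclusive: ratio ≥ 2 or ≤ 0.5 with p ≤ 0.01.
The bundled differential test is a **stand-in**, not a negative-binomial
model: fold change is the ratio of mean densities after adding a 0.5
pseudocount to raw counts (descriptive densities carry no pseudocount), and
the p-value is a two-sided Welch t test on log2 densities. Every result
carries the tag `welch_t_log2_density` so downstream consumers can never
mistake it for a DESeq result, and an externally computed per-gene
fold-change/p table can be supplied to bypass it entirely. With two
replicates the Welch test is underpowered at α = 0.01; four replicates per
condition are needed for reliable calls at the default effect size.

## Statistical tests

*Chi-square.* Plain Pearson statistic with expected counts from the
margins; p is the regularized upper incomplete gamma function Q(df/2, x/2).
No Yates correction by default (available as a flag) — the genome-wide
tables this targets have large expected counts. Expected cells below 5
raise a warning flag rather than an error, since toy inputs are expected.
For reconstructing the published genome-wide tables the universe is
N = 5798 (4116 unaffected + 754 NCR + 928 revNCR; equivalently
1125 P + 144 P&O + 45 O + 4484 unbound).

*Rank-sum.* Two-sided Wilcoxon/Mann-Whitney with midranks. Both samples
≤ 8: exact enumeration of the rank-sum distribution, p = 2·min(tail
probabilities) capped at 1. Larger: normal approximation with tie
correction and no continuity correction.

*Set enrichment.* 2×2 table (in-list/out-of-list × hit/non-hit) tested by
the same chi-square; the fold over the independence expectation is reported
alongside.

## Metagene profiles

Windows are ATG ± 600 bp (heatmaps ± 500 bp), oriented 5'→3' of the gene so
positive positions point into the gene body. Contig-edge positions are
missing, and the per-position n adjusts — no zero-filling, avoiding edge
artifacts on short contigs. The 95% band is mean ± 1.96·SEM per position
(sample SD, ddof 1); a seeded bootstrap (1000 resamples) is available. No
per-gene rescaling is applied by default; a per-gene max-normalization
switch exists. A single gene yields a zero-width band with n = 1 recorded.

## The simulator's stated world

Defaults: 500 genes on one contig, lengths uniform on 500–2000 bp,
intergenic gaps uniform on 720–1200 bp. The gap minimum is chosen so that
neighboring promoter windows (plus the ±10 bp peak padding) can never
collide, which keeps binding classes exactly identifiable from the emitted
peaks — with narrower gaps a bound promoter's peak can legitimately cover
>75% of a divergent neighbor's promoter, as indeed happens in the real
genome.

Class fractions scale the published structure: P 1125/5798, P&O 144/5798,
O 45/5798; NCR 754/5798, revNCR 928/5798; Dal80-activated 314/5798,
-repressed 232/5798. Regulated genes are drawn with 3-fold odds among bound
genes, emulating the observed binding–regulation association. Bound
promoters receive implanted GATA clusters (2 sites, gaps 15–35 bp, random
strands); 20% of bound promoters are left GATA-less, as observed. Random
background sequence also contains chance GATA sites — deliberately, since
real unbound promoters do too.

Counts are negative binomial (variance μ + 0.05μ²) with 4 replicates per
condition — the regime under which the stand-in test achieves ≥ 95%
sensitivity at ≤ 1% false calls; the study's own 3 × 2 layout is available
via `n_replicates=2` but is underpowered for the stand-in. Expression
strata order P&O (8×) > P (2×) > background (mean 200 counts, log-normal
spread σ = 0.5). Regulation uses a repression-only multiplicative model:
the base mean is the fully derepressed level and each regulated gene is
reduced 2^|log2FC|-fold in the conditions where it is repressed (NCR in
glutamine; revNCR in proline; Dal80-repressed in DAL80+ strains;
Dal80-activated in the mutant). Keeping every multiplier ≤ 1 keeps
per-condition transcriptome mass nearly balanced, so total-count density
normalization does not bias the fold-changes of unregulated genes — an
amplification model (regulated genes multiplied ~8× in one condition)
distorts library totals enough to push null genes over the 2-fold
threshold, which is the classic composition-bias failure of total-count
normalization.

ChIP coverage is per-base Poisson background (rate 1 tag/nt) plus a
promoter bump (+8) for P/P&O genes and an ORF plateau (+5) for P&O/O genes;
the untagged control is background only. Peaks are emitted directly by the
generator (fully covering the enriched window, ±10 bp), keeping peak
calling out of the loop; 20 decoy peaks land in intergenic space away from
every promoter and ORF. A naive threshold peak caller ships for integration
tests only and is explicitly not part of the analysed method.

Everything derives from a single seeded generator: identical config + seed
gives byte-identical files.

### What a green synthetic test establishes — and what it does not

The simulation exercises coordinate arithmetic, the strict overlap rule,
motif recovery, the classification rules, the test statistics and the
plumbing end to end against known truth. It does **not** emulate mappability
artifacts, fragment-length smearing, peak-boundary uncertainty,
hyper-ChIPable loci, isoform structure, or DESeq's shrinkage behavior —
results on real data depend on those, and the 100%-recovery property holds
only because simulated peaks are constructed to clear the threshold.

## Known limitations

* The stand-in DE test is not exchangeable with DESeq on real data; use the
  external-table path for publication-grade regulation calls.
* Exact rank-sum enumeration is combinatorial; beyond 8 + 8 observations
  the implementation switches to the asymptotic form.
* bigWig is not supported; coverage I/O is bedGraph only.
* Multiple-testing correction across enrichment batteries is deliberately
  absent (raw p-values, as in the analyses this mirrors).
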