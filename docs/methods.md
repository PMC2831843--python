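# Methods

## Problem and scope

Homopolymeric tracts (HTs) — maximal runs of a single nucleotide inside a
coding gene — are a mutational engine of bacterial phase variation:
slipped-strand mispairing in a tract inserts or deletes one base at high
frequency, reversibly shifting the reading frame.  `htract` implements the
statistical machinery of a genome-scale HT survey: tract detection, an
over/under-representation test against a composition-based null,
positional-bias statistics (are long tracts, and the codons and amino acids
that can form them, concentrated near the 5' end of genes?), and estimation
of frameshift-reversion frequencies from selective-plating experiments.
Gene sets are supplied as multi-FASTA (one record per coding gene, 5'→3');
nothing in the package downloads or selects genomes, and phylogenetic tree
building is out of scope.

## Tract detection

A tract of exact length k is flanked on both sides by a different base or a
gene boundary, so a run of 8 As is one A8 tract and contributes nothing to
the A7 count.  Detection run-length-encodes the byte sequence (numpy), which
partitions every non-N position of a gene into exactly one maximal run; `N`
bases terminate runs and belong to none.  A run touching position 1 or L of
a gene counts as maximal with a single non-matching flank — the expectation
model below uses the same convention, and the choice is declared rather than
inferred (per-record pattern matching behaves this way).  Coordinates are
1-based inclusive throughout.  The default census range is k = 1..20; longer
runs are still reported with their true length so the partition invariant
holds.

## Expectation model and Z-score

Under the null, coding sequence is i.i.d. nucleotides with frequencies `f_i`
estimated from the gene set itself (non-N positions only).  The expected
number of maximal runs of base i, exact length k, in a gene of length L is

    E_gene = (L − k − 1)·f^k·(1−f)^2 + 2·f^k·(1−f)   for L ≥ k+1
    E_gene = f^k                                       for L = k
    E_gene = 0                                         for L < k

(interior starts need two non-matching flanks, boundary starts one).
Summed over n genes of total length N (all longer than k) this collapses to

    E = (N − n(k+1))·f^k·(1−f)^2 + 2n·f^k·(1−f).

Both forms are implemented; they differ only when genes of length ≤ k
exist, which is negligible at genome scale.  The per-gene form is exact for
the i.i.d. model, verified against Monte-Carlo enumeration in the tests,
and the aggregate form reproduces the standard check value E ≈ 0.33 (≈ 0.3)
for poly(A) tracts of 8 bases in 1.8 Mb of coding sequence at 70% GC.

The observed count O is scored as Z = (O − E)/sqrt(N·q·(1−q)) with
q = E/N — a binomial-variance normal approximation over the N trial sites.
Because q ≤ 10⁻³ in practice this is numerically the Poisson form
(O − E)/sqrt(E), which is exposed as an option.  Z > 1.64 is the one-sided
5% over-representation call; |Z| > 1.96 is the two-sided display cut-off.
Cells with E < 0.05 (configurable) are reported `untestable`: when a
fraction of a tract is expected, under-representation cannot be observed.
No multiple-testing correction is applied across the base × length grid by
default (each cell is reported as its own test); a Benjamini–Hochberg
adjustment is available off the default path (`add_bh_correction`).
Per-group censuses (e.g. functional role categories, supplied as a TSV of
free-text labels) recompute composition, E and Z within each label's
subset; cross-set comparisons of per-genome Z-scores use the one-sided
Wilcoxon rank-sum below.

## Positional statistics

The relative location of a feature is rl = ((first + last)/2)/L ∈ (0, 1]:
the unrounded midpoint of its nt (or residue) span over the host gene
(protein) length.  Codon rl uses the codon's 3-nt span within the gene, not
codon units, keeping one convention across features (a 1/L-order
difference).  Three tests operate on pooled rl values:

* **Ladder test** — one-sided Wilcoxon rank-sum of rl for length-k tracts
  against length-(k−1) tracts (alternative: longer tracts sit closer to
  the 5' end).
* **First-fraction enrichment** — a pseudo-dataset of Uniform(0,1) draws of
  the same size as the observed list is generated with a recorded seed;
  the 2×2 table of in/out counts at threshold t (default the 5'-most 10%)
  gives the cross-product odds ratio, a 95% CI from the log-OR normal
  approximation (Haldane–Anscombe 0.5 correction on zero cells), and a
  one-sided Fisher exact p.  The default is a single pseudo-draw, matching
  common practice; a resampling mode averages the expected cells over B
  draws for stability.
* **Terminal tests** — codon-vs-synonym position comparisons (e.g. AAA vs
  AAG) use the rank-sum directly; amino-acid terminal bias compares rl of
  one residue type against an equal-size uniform pseudo-null, toward a
  chosen terminus.

The Wilcoxon implementation uses mid-ranks and is exact — full enumeration
of all C(n, n1) rank splits, ties handled exactly — for combined n ≤ 20,
switching to the normal approximation with tie-corrected variance and a
0.5 continuity correction above that.  Exactness at small n matters because
per-(base, k) tract lists can be tiny; scipy's implementation serves as an
independent cross-check in the tests, not as the implementation.
Positional histograms use 20 windows of 5% of gene length.

## Reversion-frequency estimation

In the plating assay, a frameshift at an engineered tract restores an
antibiotic-resistance fusion.  Per replicate:

    OCD = CFU·DF_total/VP          original cell density   [cells/ml]
    RD  = TC·(R/CS)·DF_sel/VP      revertant density       [/ml]
    FR  = RD/OCD                   reversion frequency     [–]

CFU = mean colonies per non-selective plate, VP = volume plated (ml),
DF = dilution factors, TC = total large colonies on selective plates,
CS = large colonies sequenced, R = confirmed revertants.  Colonies > 8 px
in plate images are "large" (mostly true revertants, a subset sequenced
for confirmation); colonies < 9 px are slow-growing non-revertants and
excluded.  Replicates are summarised by the arithmetic mean FR (median
optional).  When no replicate confirms a revertant, the detection limit is
the frequency one revertant colony among all pooled screened cells
(Σ OCD·VP/DF_sel) would have implied.  FR is a per-cell frequency, not a
per-generation rate: no fluctuation-test (Luria–Delbrück) correction is
applied, because the estimand here is the population frequency itself.

## Synthetic data: what it emulates and what it does not

`make_null_geneset` draws genes as i.i.d. nucleotides at a chosen
composition — exactly the null the expectation model assumes — so analytic
E can be validated against observed counts and false-positive rates
calibrated.  `plant_hts` overwrites maximal runs at midpoint positions
drawn from a uniform or Beta(α, β) law over relative position (Beta(1, 9),
mean 0.1, is the 5'-skew fixture), forcing both flanks to differ so every
planted run is recoverable by the scanner with its exact coordinates.
`simulate_plating` draws Poisson revertant cells at a true per-cell
frequency φ, binomially thins them onto selective plates, and draws a
two-component colony-size mixture (revertants ~ Poisson(15 px), background
non-revertants ~ 1 + Poisson(3 px)) so the > 8 px classifier and the
sequencing-confirmation rule (all large colonies when < 20, else 10) are
exercised end to end.

Real coding genes are not i.i.d.: they have codon structure, start/stop
grammar, within-gene GC gradients and correlated repeat content, none of
which the generators emulate.  Passing calibration and recovery tests
therefore demonstrates that the statistics are correct under their stated
null and powerful against their stated alternatives — not that any real
genome is free of sequence features that inflate or damp tract counts
relative to the i.i.d. expectation.

## Numerical and design choices

* Single global seed per generator call (numpy `default_rng`); identical
  seeds give bit-identical gene sets, pseudo-nulls and plating draws.
* Exact rational midpoint ((first+last)/2 may be half-integer) before the
  single division by L; rl is never rounded.
* Wilcoxon exact/approximate switch at combined n = 20; mid-ranks with tie
  correction; continuity correction 0.5 in the normal path.
* Untestable floor E < 0.05; one-sided z = 1.64; two-sided display 1.96;
  first-fraction threshold t = 0.10 — all configurable.
* Degenerate inputs: empty gene sets, absent codon pairs, zero-cell 2×2
  tables (Haldane–Anscombe), TC > 0 with CS = 0, and genes too short to
  host a planted run all raise explicit `ValueError`s rather than
  propagating NaNs; empty (base, k) cells in reports are emitted as NA
  rows.
* Ambiguity codes other than N are rejected by default (`strict`) or
  mapped to N (`map-to-n`); handling of ambiguous bases in source data is
  an open choice, so both modes are exposed.

## Validation problem sizes

The test suite validates at sizes chosen for a single CPU: scanner ≡ regex
oracle on 10⁴ random sequences; Wilcoxon/Fisher ≡ exhaustive enumeration
for all sampled instances with combined n ≤ 10 (ranks) and table totals
≤ 50; null calibration over 2,000 simulated genomes of 300 genes × 300 nt
at GC 50% (the Z > 1.64 over-call rate for cells with E ≥ 20 must lie in
[2.5%, 7.5%], and counts track E within 3·sqrt(E) for E ≥ 5 on a 4.5 Mb
null set); positional recovery with 500 Beta(1,9)-planted A7 tracts
(first-10% OR with CI excluding 1, ladder p < 0.001) and CI coverage ≥ 90%
over 40 uniform-planted seeds; reversion recovery with 100 simulated
triplicates at φ ∈ {10⁻⁸, 5×10⁻⁷, 10⁻⁵} (median mean-FR within a factor of
2 of φ).

## Known limitations

* The expectation model conditions on single-nucleotide composition only;
  genomes with strong dinucleotide bias or GC skew will deviate from the
  null in ways the Z-score attributes to selection on tracts.
* The binomial variance slightly overstates the true variance of maximal-
  run counts (overlapping runs are mutually exclusive), an O(q) effect
  that is invisible at genome scale.
* Per-genome Z-scores compared across groups are treated as exchangeable
  observations; no phylogenetic correction is attempted.
* The plating estimator assumes large colonies are an unbiased sampling
  frame for sequencing confirmation and ignores revertants arising after
  plating.
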