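# htract

Statistics for homopolymeric tracts in prokaryotic coding genes: tract
detection, over-representation testing, 5'-positional bias, and
frameshift-reversion frequency estimation.

## The problem

Homopolymeric tracts (HTs) — maximal runs of one nucleotide such as
`AAAAAAA` inside a coding gene — mutate at high frequency by slipped-strand
mispairing: a one-base insertion or deletion shifts the reading frame,
reversibly switching the gene off and on again (phase variation).  Whether
a genome carries more long tracts than its base composition predicts, and
whether those tracts cluster near the 5' end of genes (where a frameshift
truncates most of the protein), are therefore questions about selection on
a mutational switch.  `htract` is for microbial genomicists who want to
run that survey on their own gene sets and for experimentalists estimating
tract reversion frequencies from selective-plating assays.

## The model

Under the null, coding sequence is i.i.d. nucleotides at frequencies
*f<sub>i</sub>* estimated from the genes themselves.  The expected number
of maximal runs of base *i* of exact length *k* over *n* genes of total
length *N* is

> E = (N − n(k+1)) · f<sup>k</sup> (1−f)² + 2n · f<sup>k</sup> (1−f)

(interior runs need two non-matching flanks, gene-boundary runs one), and
the observed count O is scored with a binomial normal approximation,
Z = (O − E)/√(Nq(1−q)), q = E/N; Z > 1.64 is the one-sided 5%
over-representation call.  Positional bias uses the relative location
rl = ((first+last)/2)/L of each tract (codon, residue) in its gene:
one-sided Wilcoxon rank-sum "ladder" tests between adjacent tract lengths,
and an odds ratio with one-sided Fisher exact test for falling in the
5'-most 10% of the gene against an equal-size Uniform(0,1) pseudo-dataset.
Reversion frequencies come from plate counts: FR = RD/OCD with
OCD = CFU·DF/VP and RD = TC·(R/CS)·DF/VP (colonies > 8 px are counted as
candidate revertants, a sequenced subset confirming the fraction R/CS).
See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Generate a 400-gene synthetic gene set at 38% GC with one 5'-skewed A7
tract planted per gene, run the census, test positional enrichment, and
estimate a reversion frequency from a simulated plating experiment:

```python
import htract as h

comp = h.CompositionSpec.from_gc(0.38)
genes = h.make_null_geneset(comp, 400, 900, seed=7, genome_id="demo")
genes = h.plant_hts(genes, h.PlantSpec("A", 7, 1.0, ("beta", 1, 9)), seed=8)

df = h.census(genes, k_min=5, k_max=9, bases="A")
print(df[["base", "k", "O", "E", "Z", "call"]].to_string(index=False))

runs = [r for r in h.scan_geneset(genes) if r.base == "A" and r.k == 7]
lengths = {g.gene_id: g.length for g in genes}
rl = [p.rl for p in h.run_relative_locations(runs, lengths, "A", 7)]
enr = h.first_fraction_enrichment(rl, threshold=0.10, seed=9)
print(f"first-10% OR = {enr.odds_ratio:.2f} "
      f"(95% CI {enr.ci95[0]:.2f}-{enr.ci95[1]:.2f}), p = {enr.p:.2e}")

exps = h.simulate_plating(h.PlatingSimSpec(true_freq=5e-7), seed=10)
print(f"mean FR = {h.summarize_replicates(exps):.2e}")
```

prints

```
base  k   O          E         Z call
   A  5 505 520.721881 -0.689471   ns
   A  6 146 163.739041 -1.386605   ns
   A  7 437  51.487062 53.730509 over
   A  8  12  16.189873 -1.041331   ns
   A  9   6   5.090826  0.402955   ns
first-10% OR = 11.76 (95% CI 8.05-17.18), p = 2.72e-49
mean FR = 4.74e-07
```

The planted A7 cell is the only one called over-represented (437 tracts
observed against 51 expected from composition alone; neighbouring lengths
stay within noise of their expectations), the planted tracts are ~12-fold
enriched in the first 10% of genes, and the plating estimator recovers the
simulated true frequency of 5×10⁻⁷ as 4.7×10⁻⁷.

A CLI mirrors the library for shell pipelines:

```sh
htract simulate geneset --gc 0.38 --n-genes 400 --plant A:7:1:beta,1,9 \
    --seed 7 --out demo.fa
htract scan demo.fa --out runs.tsv
htract census demo.fa --out census.tsv
htract position demo.fa --bases A --k-min 6 --k-max 8 --out-dir reports/
```

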