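# rloopmut

Analysis toolkit for reporter-gene mutagenesis assays of DNA binding by
catalytically dead Cas9 (dCas9). When dCas9 binds its ~20-nt target it opens
an R-loop whose displaced single strand is chemically vulnerable; in a
selectable reporter such as yeast *CAN1* this shows up as loss-of-function
mutations clustered at the guide target — cytosine-deamination substitutions
on the non-target strand (C>T, and C>G / C>A from lesion processing),
single-nucleotide slippage indels at homopolymer runs, and complex mutation
clusters produced by translesion synthesis. `rloopmut` turns the raw outputs
of such an experiment — per-isolate mutation lists in compact notation,
guide coordinates, colony counts with dilution factors, and a catalog of
known inactivating substitutions — into the quantitative summaries used to
read them.

## What it computes

* **Mutation records** — parser/formatter for the compact notation
  (`259G>T`, `286–287del`, `290ins(22 bp)`, comma-joined complex isolates),
  TSV tables, and a VCF-style export on the coding sequence.
* **Guide windows and strands** — 1-based coding coordinates, protospacer
  windows with margins, and a configurable strand convention mapping a
  guide's designated strand (NTS/TS) to the physical non-target strand of
  the R-loop.
* **Spectrum summaries** — per-guide counts of isolates/events in the
  target window at several margins, complex-mutation calls (≥2 events
  within 10 nt), the substitution spectrum re-expressed on the non-target
  strand, the fraction of in-target events at non-target-strand cytosines
  (with an exact binomial composition test), homopolymer-indel counts, and
  per-position / per-codon histograms.
* **Mutant frequencies** — per-culture frequency
  `f = (n_sel · d_sel) / (n_nonsel · d_nonsel)`, group medians, fold-changes
  vs. a control group, and a two-tailed Mann–Whitney U test whose p-value is
  **exact** for small samples (dynamic-programming enumeration of the null U
  distribution; exact permutation under ties; recorded fallback otherwise).
* **Guide scoring** — the number of potential inactivating cytosines in each
  guide's non-target strand given a user-supplied catalog, plus Spearman
  rank correlation against measured frequencies.
* **Forward simulator** — seeded generator of isolate tables (mixture of
  target-associated event classes and dispersed background) and Poisson
  plating counts, with `ung1Δ` / `rev3Δ` genotype toggles.

## Worked example

```python
>>> import rloopmut as rm
>>> from rloopmut.datasets import sgrna1_table, SGRNA1
>>> from rloopmut.synthetic_supplement import synthetic_reference
>>> ref = synthetic_reference()
>>> s = rm.summarize(sgrna1_table(), SGRNA1, ref)
>>> s.n_isolates, s.n_in_window[0], s.n_complex_in_target
(19, 9, 3)
```

Of the 19 isolates in the packaged example table, 9 (47%) carry a mutation
inside the guide's 277–296 protospacer and 3 of those 9 are complex
mutations (two events within 10 nt — the pol ζ translesion signature).

```python
>>> res = rm.mann_whitney_exact([7, 8, 9, 10, 11, 12], [1, 2, 3, 4, 5, 6])
>>> res.U, round(res.p, 4), res.method
(36.0, 0.0022, 'exact_dp')
```

With six cultures per group and complete separation, the exact two-tailed
p-value is 2/924 ≈ 0.0022 — the strongest significance a 6-vs-6 rank test
can report, and the value that recurs whenever treated and control cultures
do not overlap.

The same analyses are available from the shell:

```bash
rloopmut spectrum  --reference ref.fasta --guides guides.tsv \
                   --mutations mutations.tsv --out reports/
rloopmut frequency --plating plating.tsv --reference-group no_sgRNA \
                   --out freq.json
rloopmut score-guides --reference ref.fasta --guides guides.tsv \
                   --catalog catalog.tsv --out scores.tsv
rloopmut simulate  --reference ref.fasta --guides guides.tsv \
                   --guide-id sgRNA2 --seed 11 --out sim/
```

The reference coding sequence and the per-guide supplementary-style tables
shipped in `rloopmut.synthetic_supplement` are synthetic stand-ins
constructed to embody the published summary tallies; see
`docs/methods.md` for exactly what they do and do not represent.

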