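# Methods

## Coordinate system and strand bookkeeping

All positions are 1-based inclusive on the reporter **coding sequence**
(position 1 = A of the start codon); no genome-level coordinates are used.
A guide target is the 20-nt protospacer interval plus a strand designation:
`NTS` (non-transcribed = coding strand) or `TS` (transcribed = template
strand). Window arithmetic uses the protospacer interval only, widened by a
margin on each side and clipped to the gene; the PAM side is recorded for
reporting but never enters the arithmetic.

The phrase "the guide targets strand S" is ambiguous. The package's default
convention (`StrandConvention(guide_bears_protospacer=True)`) reads it as
*the protospacer and PAM lie on S*. Since the guide RNA hybridizes to the
complement of its protospacer, the displaced single strand of the R-loop —
the **non-target strand**, where deamination acts — is then S itself. Under
this reading, an NTS guide's non-target-strand bases are simply the coding
bases, which makes reported C>T substitutions at coding-strand cytosines
read directly as non-target-strand C mutations. The opposite reading (guide
anneals to S) is available as a flag and complements every non-target-strand
call; all reports embed the convention in force. Flipping a guide's strand
designation complements the strand-resolved substitution spectrum
(C>T ↔ G>A) but can never change membership or class counts — this is
enforced by a property test.

## Mutation notation

Events are substitutions (`259G>T`, multi-nt allowed), deletions (`292del`,
`286–287del`; en-dash canonical, hyphen accepted), and insertions anchored
3′ of the stated position with the inserted material between `pos` and
`pos+1` (`294ins(T)`; `290ins(22 bp)` when only the length is known).
Anchoring sidedness is not derivable from the notation; 3′ anchoring is
applied uniformly, and interval arithmetic treats an insertion as occupying
its anchor position only. A complex isolate is stored as the comma-joined
list exactly as read — grouping is never inferred. The formatter is the
exact inverse of the parser on valid events (property-tested), so tables
round-trip byte-identically. The VCF-style export left-anchors indels at
`start − 1` per VCF convention, right-anchors the (degenerate) deletion at
position 1, and emits sequence-unknown insertions as symbolic `<INS>` with
`SVLEN`.

## Spectrum summaries

* **Window membership** is per-isolate for headline fractions (an isolate
  with two in-target events counts once), with per-event counts reported
  alongside; membership at several margins (default 0, 2, 10 nt) is always
  non-decreasing in margin.
* **Complex mutations**: ≥2 events whose gap — `later.start − earlier.end`,
  floored at 0 — is ≤ 10 nt. Chains are merged transitively; with a single
  threshold any qualifying chain contains a qualifying pair, so detection
  reduces to a pairwise scan.
* **Deamination fraction**: numerator = in-target substitution events whose
  non-target-strand reference base is C; denominator = *all* in-target
  events including indels, matching how published spectra count their
  totals. A zero denominator is reported as undefined, never 0/0 = 0.
* **Composition test**: the probability that ≥ k of n in-target mutations
  fall at C positions if positions were drawn by base composition alone,
  i.e. an exact one-sided binomial tail at the window's C fraction.
* **Homopolymer indels**: in-target isolates carrying a 1-nt insertion or
  deletion anchored inside, or immediately adjacent to (the 3′-anchoring
  rule makes the left-flank anchor legitimate), a homopolymer run of
  ≥ 6 nt overlapping the window.
* Positional histograms count every covered position of a multi-nt event
  individually; codon index is `ceil(pos / 3)`.

## Frequency estimation and testing

Dilution factors are fold-dilutions of the plated aliquot (≥ 1), so
`colonies × dilution` estimates cells in the undiluted suspension and
`f = (n_sel · d_sel) / (n_nonsel · d_nonsel)` is a dimensionless mutant
frequency — the only reading under which the ratio is a frequency.
Replicate cultures of one strain/guide are pooled into a single group; the
group summary is the **median** (robust to the jackpot skew of fluctuation
data), and effect sizes are ratios of medians. No Luria–Delbrück rate
estimation is attempted: the assay reports frequencies, not rates. Reported
precision: frequencies to 3 significant digits, p-values to 4 decimals.

The Mann–Whitney test is two-tailed with `p = min(1, 2 × smaller one-sided
tail)`. For tie-free pooled samples of ≤ 20 the null distribution of U is
enumerated exactly by dynamic programming over rank subsets
(O(n·m·(n+m)) table); with ties, all C(n+m, n) group assignments are
enumerated exactly (mid-rank U) up to a 2×10⁵ combination budget; beyond
that the tie-corrected normal approximation is used. The method actually
applied is recorded in every result and report. Exactness is verified
against an independent brute-force pair-counting oracle for every sample
size with n+m ≤ 10, and against an independent library implementation on
tie-free cases. Under complete separation of two groups of six the exact
two-tailed p is 2/924 ≈ 0.0022 — the floor for that design.

Guide scoring counts protospacer positions whose non-target-strand base is
C and for which at least one configured deamination outcome, mapped back to
the coding strand through the strand convention, appears in the supplied
catalog of known inactivating substitutions. The default outcome set is
{C>T, C>G, C>A}, since C>G/C>A arise from processing of the uracil lesion;
a {C>T}-only mode mirrors uracil-glycosylase-deficient logic. The catalog
is an input: deriving inactivating status from protein structure is out of
scope, and the packaged catalog is a small synthetic one.

## Synthetic data

### Packaged stand-ins

The real reporter coding sequence and the full per-guide supplementary
isolate lists are external data not shipped here. The package instead ships
`synthetic_supplement`, a deterministic 1773-nt synthetic coding sequence
plus per-guide tables **constructed so that the pipeline's summaries on
them equal the published tallies**: the printed 19-isolate table reproduces
9/19 in-target with 3 complex; the sgRNA2-like table gives 16/21 within
10 nt, 14/21 in-target and a 10/14 deamination fraction with a 6:2:2
C>T:C>G:C>A split inside a window whose non-target strand is 30% C; the
sgRNA4-like table gives 7/20 within 2 nt; the sgRNA6-like table gives 20/25
in-target, 6/20 complex and 10/20 single-nt indels at a 6-nt T run. Tests
on these fixtures validate the *counting machinery end to end* — they do
not re-derive the published numbers from raw data, because the raw
per-isolate lists are not printed. Only sgRNA1's coordinates (277–296) are
published; the other guide placements are synthetic choices consistent with
the described geometry.

### Generator

`simulate_isolates` draws, per isolate, a target-associated event with
probability `p_target` (default 0.76, the strongest observed clustering
fraction) and otherwise a dispersed background substitution (uniform over
the gene, or over a supplied inactivating catalog — reflecting that only
inactivating mutations are selectable). Target events split into four
classes (defaults 0.70 deamination substitution / 0.00 homopolymer 1-nt
indel / 0.15 complex cluster / 0.15 other small indel; the homopolymer
class defaults off because the default target overlaps no long run, and
enabling it without a run is a configuration error, as is deamination with
no non-target-strand C). Deamination outcomes default to 0.6/0.2/0.2 for
C>T/C>G/C>A, echoing the observed 6:2:2 split. Genotype toggles implement
the two mechanistic knockouts: `ung1Δ` collapses outcomes to pure C>T
(uracil never excised, so no error-prone processing) and `rev3Δ` zeroes the
complex class (no pol ζ), redistributing its mass proportionally. Complex
clusters place a secondary substitution at a uniform offset of 1–10 nt from
the primary. Every simulated isolate carries a mutation by construction;
fitness, lethality and jackpot culture dynamics are not modeled.

`simulate_frequency_assay` draws Poisson plating counts:
`n_sel ~ Poisson(N·f/d_sel)`, `n_nonsel ~ Poisson(N/d_nonsel)` for a
culture of `N` cells (default 2×10⁸, d_sel = 10, d_nonsel = 10⁶, giving
~200 colonies per plate at f = 10⁻⁵, the frequency scale of non-transcribed
strand targeting). The background (no-guide) frequency has no published
value and any default used in examples is an arbitrary configuration, not
an estimate.

What the simulator deliberately omits — Luria–Delbrück jackpots, selection
coefficients, R-loop kinetics, position-specific deamination propensity —
bounds what passing tests show: they demonstrate that the estimators and
classifiers recover the parameters of *this* generative structure, not that
the structure is a complete model of the assay.

## Numerical and testing choices

All randomness flows from a single integer seed through one
`numpy.random.Generator`; identical seeds give bit-identical outputs.
Problem sizes in the test suite (500–2000 simulated isolates for mixture
recovery, 1000 Monte-Carlo replicates of 6 cultures for the median
estimator, exhaustive Mann–Whitney enumeration up to n+m = 10, 1000 random
tables for the window/complex oracle) were chosen to make binomial /
Monte-Carlo error small relative to the asserted tolerances while keeping
the suite fast. Stochastic assertions use 95% central intervals around the
analytically expected value (e.g. in-window fraction
`w + (1 − w)·20/L` under the uniform-background mixture). The median-ratio
frequency estimator has O(1/λ) relative bias from the Poisson denominator
(~0.5% at 200 colonies), which is inside the 2% bias band asserted.

## Known limitations

* The strand convention is a modeling choice; if the opposite reading were
  intended, all non-target-strand calls complement (the flag exists for
  exactly this reason, and no biological claim is hard-coded beyond the
  default plus its log entry).
* Margins for "immediately adjacent" clustering are not uniquely defined;
  summaries therefore report several margins (0, 2, 10) rather than
  guessing one.
* No multiple-testing correction is applied to pairwise group tests, and
  no HGVS parsing or read-level variant calling is provided — Sanger
  calling is upstream of this package.
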