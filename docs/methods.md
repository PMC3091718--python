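# Methods

This note documents the models and procedures the package implements, the
defaults it ships, and the choices made where the design was genuinely
open.

## Perfect-repeat detection

A microsatellite locus is a maximal run of exact copies of a primitive
motif (one that is not itself a repetition of a shorter motif). Detection
works per period *p* ∈ [2, 8] on the match profile `s[i] == s[i+p]`: each
maximal run of matches of length *m* defines a perfect tract of length
*m + p*, of which `floor((m+p)/p)` complete units are reported — a trailing
partial copy never counts toward the unit number, and the locus ends at the
last complete copy. Coordinates are 1-based and fully closed.

Rules and their rationale:

- **Thresholds.** ≥ 3 complete units and per-period minimum tract lengths
  12/12/12/15/18/21/24 bp for periods 2–8. The 12 bp floor makes the
  effective minimum 6 units for dinucleotides and 4 for trinucleotides.
  All minima are configurable (`ScanConfig`).
- **Mononucleotides are never reported**: in shotgun assemblies homopolymer
  runs are dominated by sequencing artifacts, and poly-A/T in transcript
  data is confounded with polyadenylation.
- **Period minimality.** A tract whose motif is non-primitive at period *p*
  (e.g. ATAT) is reported only at its true smaller period. By the
  Fine–Wilf periodicity argument a primitive-motif locus of ≥ 3 units can
  never be properly nested inside a smaller-period locus, so this rule
  alone guarantees non-nested output (a containment filter remains as an
  explicit guard).
- **Tie-breaking.** When shifted alignments of the same tract compete
  (…ATATAT**G**TGTGT… admits both TG- and GT-phased candidates), the
  leftmost start wins. Output ordering is (seq_id, start, end).
- **N and case.** Input is upper-cased; any non-ACGT symbol breaks a
  repeat; soft-masking (lowercase) is ignored because no masking policy is
  assumed.
- **Compound SSRs.** Consecutive loci separated by ≤ `compound_max_gap`
  interrupting bases form one compound locus. The threshold is not fixed by
  any published convention we reproduce; 100 bp, the value conventionally
  used by MISA-style miners, is the default and it is configurable. A
  compound is *heterogeneous* when its members differ in canonical motif.

The scanner is validated against a brute-force enumerator (every
(start, period) pair tested for maximal extension by direct string
comparison) on thousands of random and repeat-dense sequences, and against
the generator's truth tables.

## Summary statistics

Density is loci per Mbp of analysed sequence; relative frequency is within
a dataset; the mean repeat number averages complete units only, consistent
with the scanner. Reported tables round percentages and densities to one
decimal while all internal computation is full precision. GC content is
G+C over unambiguous bases only, with a NaN sentinel when none exist.

The genomic-vs-EST density comparison uses a pooled-variance two-sample
Student *t* with df = n₁ + n₂ − 2 and a two-sided p-value. The variant was
chosen because it exactly reproduces the published eight-species
dinucleotide comparison (t = 2.57, p = 0.022) from the printed density
columns; Welch's test does not. The implementation wraps
`scipy.stats.ttest_ind(equal_var=True)` and is cross-checked in the tests
against a hand-computed pooled statistic and a numerically integrated
t-distribution tail.

## Electronic PCR

Primer admissibility is mismatch-only (no indels), with three simultaneous
constraints:

1. mismatches only within the 5′-most `five_prime_window` = 5 positions,
   at most `max_mismatches` = 5 of them;
2. exact match from position 6 through the 3′ terminus — "no mismatches at
   the 3′ end" is thus read as a window constraint that makes the 5′
   allowance literal at the same time;
3. overall identity ≥ 80% of the full primer length (for a 20-mer this
   caps mismatches at 4, and an exactly attained 16/20 is admissible — the
   threshold comparison carries an epsilon against float rounding).

Sites are found on both strands by vectorized profile comparison, which on
the sequence sizes used here is equivalent to (and tested against) an
all-positions sliding-window comparator. Any base outside ACGT counts as a
mismatch.

Products are convergent forward/reverse site combinations on one sequence
with non-overlapping footprints and outer-to-outer length in
[100, 2000] bp. Either primer may provide either side (products are
orientation-symmetric, and e-PCR of the reverse-complemented assembly
yields identical product lengths). A marker is **specific** iff it yields
exactly one product, the product span is ≤ 4 kb (the span rule is applied
to the amplicon's outer coordinates; both caps are configurable), and the
product flanks a perfect SSR whose canonical motif equals the expected one.
More than one product → `multi_product` (discarded by the single-copy
filter); one product with the wrong or no repeat → `motif_mismatch`; none →
`no_amplification`.

## Two-genotype polymorphism

Classification by amplicon-size difference: 0 bp monomorphic, exactly 1 bp
ambiguous (indistinguishable from sizing error; excluded from every
downstream table), ≥ 2 bp polymorphic. Markers unsized in either genotype
are *unresolved* and carried with a missing-size sentinel rather than
dropped, so the partition monomorphic + polymorphic + ambiguous +
unresolved always reconciles with the input panel.

Downstream analyses use the reference genotype's repeat tract:

- **Repeat-length bins** < 30, 30–40 (both ends inclusive), > 40 nt, on
  the reference tract length — markers are designed from the reference
  genotype, so its allele defines the locus. Heterogeneous compound loci
  have no repeat-type class and are excluded from the binned table.
- **Compound repeat units** are summed over uninterrupted member repeats
  when the total reaches 10 units; analyses restricted to dinucleotides
  only admit compounds whose members are all dinucleotides.
- **Expansion/contraction profiles** are computed over polymorphic loci per
  repeat-unit class, with the percentage pair summing to 100 and the
  mean/SD of |Δal|.
- **Correlation** is Pearson's r between |Δal| and the reference
  repeat-unit count (p two-sided via the t transform, n − 2 df). The unit
  count, not the bp length, is the default regressor because the
  dinucleotide-focused analyses are expressed in repeat units; a signed
  option exists but is non-default.
- **Group tests**: one-way ANOVA, then Fisher's LSD — pairwise t on the
  pooled within-group mean square at α = 0.05 — implementing a "95% LSD
  test" literally rather than a studentized-range procedure.

## Synthetic studies

The generator emulates the study design the analysis modules target: one
genome in which markers are designed (reference) and a second genotype
differing only in repeat lengths.

- **Background**: i.i.d. bases at GC = 0.323 by default, matching the
  AT-rich plant genome the defaults are shaped on. Scaffolds are
  rejection-scanned: windows containing any threshold-passing repeat are
  re-sampled, so every detected locus afterwards is an implant. An i.i.d.
  model (no Markov structure) suffices because no downstream quantity
  depends on background composition beyond GC.
- **Implants**: default 240 loci on 4 × 30 kb scaffolds, laid on a spacing
  grid (≥ 450 bp) so flanks stay repeat-free and wide enough for primers.
  Period frequencies mirror a genomic survey (tetra 29.8% > di 26.5% >
  tri 25.6% ≫ penta…octa); motifs are drawn from AT-rich-dominated tables
  (AT; AAT/AAG; AAAT-type); repeat-unit counts are shifted-geometric with
  means ≈ 9.6 units for dinucleotides and ≈ 3.2–4.9 for longer motifs, so
  unit-class analyses are exercised in the regime where dinucleotides carry
  most of the length variation. Strand and phase of each implant are
  randomized within the canonical class. After implantation the two
  flanking bases are forced to break the repeat, and the scaffold is
  re-verified by scanning: recovered loci must equal the truth exactly.
- **Mutation model**: each locus mutates with probability 0.55; the
  direction is a contraction with probability
  logistic(−2.0 + 0.25·units) — ≈ 0.38 at 6 units, 0.88 at 16, 0.98
  at 24 — encoding the observation that long repeats preferentially
  shrink; the step size is geometric (p = 0.55, mean ≈ 1.8 units). Steps
  that would leave fewer than one unit are redrawn; a locus that cannot
  contract expands instead. With these defaults roughly half the marker
  panel is polymorphic.
- **Primers**: windows of 20 bases with GC 30–60% and Wallace-rule Tm
  (2(A+T) + 4(G+C)) in 50–70 °C, searched symmetrically outward from the
  pad that would centre a 250 bp product, accepting products in
  [100, 400] bp. The picker is deliberately crude — the fixture needs
  self-consistent primers, not laboratory-grade ones — and a locus with no
  feasible windows is simply marked primer-less in the truth table.

Every artifact is a pure function of (configuration, seed);
`emit_fixture` writes byte-identical files on re-runs.

What passing the synthetic round-trip shows — and what it does not: the
pipeline recovers implanted truth exactly under a mismatch-free,
indel-free, contamination-free genome model. Real assemblies add imperfect
repeats, N runs, paired-end artifacts, repeat-induced multi-mapping and
assembly errors; of these only N handling and multi-mapping are exercised
here. Agreement metrics are therefore computed over *confound-free*
markers: those specific in both genotypes and whose truth size difference
is not the ambiguous 1 bp (with periods ≥ 2 the generator cannot produce
1-bp differences, so in practice this excludes only e-PCR confounds such
as a contracted allele falling below the scan threshold or outside the
product range).

## Problem sizes and numerical choices

The shipped defaults (4 × 30 kb scaffolds, 240 loci; 5 × 60 kb and 1,000
loci for mutation-model recovery) were chosen so a full study builds and
analyses in seconds while keeping ≥ 200 markers per run, enough for the
binomial checks to be sharp. Percentages and densities round to one
decimal in all emitted tables; orderings are fixed by (seq_id, start) and
(period, canonical motif) so repeated runs produce byte-identical output.
Degenerate inputs are defined rather than accidental: empty sequences scan
to empty locus lists, an all-N record reports a NaN GC sentinel, identical
t-test samples give (t, p) = (0, 1), zero-variance correlations raise, and
LSD on a zero mean-square declares equal means non-significant.

## Known limitations

- Only perfect repeats are modelled; interrupted/imperfect repeat models
  are out of scope.
- Primer annealing is mismatch-only; thermodynamic (Tm/ΔG) models and
  indel-tolerant alignment are not implemented.
- The polymorphism layer compares exactly two genotypes; multi-genotype
  population statistics and mutation-rate estimation are out of scope.
- The synthetic background carries no SNP/indel divergence between
  genotypes, so primer binding is never degraded in the alternate
  genotype — real two-genotype screens lose additional markers to primer
  site variation.
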