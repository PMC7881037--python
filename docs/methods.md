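# Methods

## Guide-site and pair geometry

All coordinates are 0-based and half-open. A guide site requires 20
protospacer bases, none of them N, immediately 5′ of a 3-nt PAM match:

* `+` strand: protospacer `[s, s+20)`, PAM `[s+20, s+23)`, guide 5′ end at
  `s`, nick boundary at `s+17`;
* `−` strand: protospacer footprint `[s, s+20)`, PAM `[s−3, s)`, guide 5′
  end at `s+19`, nick boundary at `s+3`.

The nick is fixed 3 nt 5′ of the PAM (between protospacer bases 17 and 18),
the canonical SpCas9 blunt-cut position. PAM matching against N fails, so N
runs are untargetable by construction.

A valid double-nicking pair is PAM-out only: the minus-strand guide left,
the plus-strand guide right, and the **offset** — defined here as the number
of reference bases strictly between the two facing 5′ ends,
`right.five_prime_end − left.five_prime_end − 1` — within `[offset_min,
offset_max]`, default `[0, 20]` nt. Published offset conventions vary (5′
ends vs nick sites, inclusive vs exclusive counting); this implementation's
formula is deliberately explicit so users comparing against other tools can
translate. Guides may overlap each other, and no off-target or efficiency
scoring is applied: the pair constraint itself is the specificity mechanism
being modelled.

Two edited-window definitions are provided. `overhang` (default) is the
interval between the two nick boundaries — the predicted 5′ overhang of the
staggered break, the most mechanistic reading of "where the edit lands".
`guide_span` extends from the left protospacer start to the right PAM end
and is kept for sensitivity analysis, since genome-wide targetability
percentages depend on the window definition. With homotypic NGG sets and
default offsets the two modes differ by a fixed 3 + 6 bp of flank per pair,
which matters at the percentage level.

## Targetability coverage

A base is targetable under a PAM set when at least one valid pair's window
covers it. Per-contig windows are merged into sorted, disjoint interval
sets; coverage is the summed covered length divided by the total length of
all supplied sequences, **N bases included in the denominator**, so the
denominator of a full-assembly run equals the assembly's total base count.
Combined ("used together") sets pool the guides of all their PAM specs
before pairing, so heterotypic NGG+NGA pairs contribute;
`combine_homotypic_only=True` instead unions the homotypic coverages, which
is never larger. Set differences (|A \ B|) are computed by interval
subtraction per contig and summed.

The whole-genome runner streams contigs one at a time; pairs cannot span
contigs, so the streamed result is provably identical to an in-memory
computation (and is tested to be). Contigs are never sub-chunked. If
sub-chunking were added, chunks would need a 66-bp overlap margin (two
23-bp guide+PAM footprints plus the 20-nt maximum offset).

## Dosage calling

A clone at a locus of copy number *k* with *j* edited copies yields
edited-allele reads at expected fraction *j/k*. Observed counts are
modelled as Binomial(*n*, *p_j*) with

    p_j = (j/k)(1 − ε) + (1 − j/k) ε,

where ε (default 10⁻³) is a symmetric read-misclassification rate. Folding
ε into *p_j* keeps *p_0* > 0 and *p_k* < 1 so every candidate's likelihood
is finite; ε = 0 is accepted and degenerates gracefully (impossible
observations get −∞ log-likelihood). The call is the maximum-likelihood
*j*; exact and floating-point ties (which occur at edited = total/2 for
symmetric *p*) resolve toward smaller *j*, i.e. toward calling fewer edited
copies, using a 10⁻⁹ log-likelihood tolerance. A call is flagged
`ambiguous` when the best-vs-second log-likelihood gap is below 2.0
(~e² ≈ 7.4-fold likelihood ratio); both the gap and ε are arguments. The
observed fraction is reported with a central exact (Clopper–Pearson) 95%
binomial interval.

Reads are classified against a catalogue of known allele sequences by
exact-length, mismatch-bounded matching: a read counts for the allele of
its exact length with the fewest mismatches when that minimum is unique and
≤ `max_mismatch` (default 2); anything else is unclassified. Two
same-length alleles within `max_mismatch` of each other make the model
non-discriminative and are rejected up front. This is intentionally a
minimal classifier — no gapped realignment, no quality weighting — because
the dosage logic consumes only allele fractions.

## Clone-screen predictions

Restriction digestion cuts the top strand at `site_start + cut_offset` for
every recognition occurrence (EcoRI GAATTC, offset 1, is built in; the
enzymes handled are palindromic so a top-strand search suffices). The RFLP
screen declares a pair's edit disruptive when its window overlaps at least
one recognition occurrence; the predicted digestion-resistant band is the
fragment left after cutting at all *surviving* sites, i.e. the merged
wild-type fragments flanking the destroyed site. In-silico PCR is
exact-match only (primers ≥ 15 nt); a long amplicon that fails to amplify
because an edit removed a primer site raises a named error, which is the
computational analogue of excluding large deletions by long-range PCR.

## Simulators and what they do not emulate

`simulate_genome` draws i.i.d. bases at a specified GC fraction (default
0.41, a human-like composition) with exactly placed N runs, seeded and
reproducible. It has no repeats, CpG structure, or chromosome-scale
heterogeneity, so synthetic-genome coverage percentages characterise the
algorithm, not the human genome: real-assembly numbers must come from a
real assembly via `run_genome_coverage`. `simulate_amplicon_reads` draws
each read's allele of origin Bernoulli(j/k) and applies independent
per-base substitutions (uniform over the three other bases) at rate ε; no
sequencing indels, quality scores, chimeras, or PCR amplification bias.
Passing recovery tests therefore demonstrate correctness of the inference
under its own generative model, not robustness to real sequencing
artefacts.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale inputs chosen to make the checks
exact and fast: oracle-equivalence sweeps use 50 seeded 10-kb sequences
compared interval-by-interval against an exhaustive Cartesian pair
enumerator; the whole-genome runner is checked on a 100-kb three-contig
genome; dosage recovery uses 5,000 reads per clone at ε = 10⁻³ across 100
seeded replicates per true dosage (the acceptance script uses 50 replicates
and a 300-kb genome). All randomness flows through
`numpy.random.default_rng` with explicit seeds; CLI outputs are
byte-deterministic for a fixed config and seed.

## Known limitations

* No off-target search, guide-efficiency scoring, or chromatin model; pair
  ranking is purely geometric (target overlap, then centring).
* Coverage percentages depend on the window-mode and offset conventions
  documented above; tools using different conventions will print different
  percentages on the same genome.
* The read classifier requires allele sequences known in advance; it does
  not discover novel indels.
* Non-palindromic restriction enzymes would need a bottom-strand search,
  which is not implemented.
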