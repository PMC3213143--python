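# Methods

## Scope and model

`erisift` analyses collapsed small-RNA libraries from an 18–28-nt
size-selected sequencing protocol, comparing mutant genotypes of an
endogenous siRNA pathway to wild type. The biological model it encodes:
an RdRP synthesises antisense transcripts on a small set of target
mRNAs, and Dicer-dependent processing releases 26-nt 5′G guide siRNAs
whose 5′ ends sit opposite template cytosines and recur at
regular-but-variable 23–29-nt spacings ("phasing"). Each guide derives
from a non-canonical duplex whose ~19-nt sense passenger strand is inset
~3 nt from the guide 3′ end and ~4 nt from its 5′ end (instead of the
2-nt 3′ overhangs of a canonical Dicer product). An Argonaute with
slicer activity removes the passenger; in a slicer mutant the passenger
is stabilised rather than lost. The targets are short, intron-poor,
recently duplicated genes and pseudogenes sharing long stretches of
near-perfect nucleotide identity. Secondary 22-nt 5′G siRNAs from the
same loci dominate post-embryonic stages.

## Coordinate and counting conventions

All intervals are 0-based half-open internally; GFF3 (1-based,
inclusive) is converted at the I/O boundary only. U is normalised to T
on read-in. Mapping is exact and full-length on both strands; a
sequence matching *n* loci carries `count / n` fractional reads at each,
so totals are conserved. RPM uses mapped read copies only — unmapped
reads do not enter the denominator, matching a normalisation "to the
total number of mapped reads". "Antisense to a feature" means the locus
strand is opposite the feature strand with ≥ 1 nt overlap of the exon
set; intron-spanning reads are not modelled (the simulator never emits
them). Class precedence for a locus under multiple annotations is
declared, not inferred: miRNA > piRNA > 26G > 22G > other.

## Thresholds

* Feature-level target call: wild-type antisense ≥ 10 RPM and
  mutant/wt ≤ 1/3 in every required genotype. "Depleted by ≥ 67 %" is
  read inclusively: the default `depletion` parameter is 2/3, so a tie
  at exactly 1/3 passes.
* Single-guide call: the same at 1 RPM, at 26G-sequence resolution.
* Duplex consensus: modal geometry over guides with a passenger found
  (weighted by guide locus weight); median passenger:guide ratio over
  guides ≥ 1 RPM, an absent passenger counting as ratio 0.
* Homology: identity strictly > 82 % over the best local alignment
  (match +1, mismatch −2; a gap of length L costs 5 + 2(L−1); identity =
  matches / aligned columns including gap columns), perfect stretch
  ≥ 27 nt (exact longest common substring via suffix automaton), and — a
  package choice, since "total identity" alone is not meaningful for a
  local alignment — a minimum aligned length of 100 columns. Proximity:
  same chromosome, span gap strictly < 5 kb.
* Windows: width 5000 nt, step 1000 nt; full windows while
  `start + width ≤ L`, plus one truncated terminal window when the
  chromosome end is not flush. The log₂ ratio uses a 1-RPM pseudocount
  on both sides (windows are a screening visual; thresholded calls use
  raw ratios and error on 0/0). A read belongs to a window if its start
  position does.

## Duplex geometry definitions

`inset3` is the distance from the guide's 3′ terminus to the nearest
passenger terminus measured in duplex register — for a minus-strand
guide that is the genomic left end — and `inset5` likewise at the 5′
end. Insets can be negative (protruding passenger) and are recorded
unclamped. The candidate window is the guide interval ± 14 nt (54 nt
for a 26-nt guide); candidates must lie fully inside it on the opposite
strand. Ties on abundance break by |inset3 − 3| ascending, then longer
read, then lexicographic sequence — a deterministic rule that prefers
the canonical 3-nt 3′ inset.

## The synthetic-data generator

The generator's defaults are the package's standard study conditions;
they are fixed, not tuning knobs.

* **Genome.** 3 chromosomes × 50 kb of uniform random sequence. Target
  genes: 8 ERGO-1-class (3 duplication families × 2 copies + 2
  singletons; biotypes mixed coding/pseudogene), 6 ALG-3/4-class, all
  3 exons × 280 nt with 55-nt introns (950-nt span); 8 CSR-1/WAGO
  background genes of 5 × 550-nt exons (~3 kb); 10 miRNA and 10 piRNA
  loci. Family copies are a progenitor mutated at 0.05 substitutions/nt
  (always to a different base, so expected identity is exactly 95 %);
  one family's copies are placed within 5 kb of each other. Neighbouring
  genes are kept > 1.1 kb apart so that two unrelated 0.5-kb-flanked
  sequences never share genomic sequence, which would otherwise fake
  homology.
* **Guides.** Phased within exons at uniform [23, 29]-nt 5′-to-5′
  spacing, restarting at each exon boundary. The template base opposite
  each guide 5′ end is set to C, so guides read 5′ G. Phasing registers
  and passenger jitter are drawn once per family progenitor and
  inherited by copies — the biologically sensible choice given shared
  ancestry, and it keeps the 5′-C patches from adding divergence between
  copies; diverged copies then multi-map a realistic fraction of guides.
* **Passengers.** Sense reads at inset3 = 3, inset5 = 4 (so
  26 = 3 + 19 + 4); with probability 0.3 the inset5 shifts ± 1 nt
  (passenger length 18/20), leaving (19, 3, 4) modal. Per-guide
  passenger:guide ratios are log-normal with population median 0.05
  (σ = 0.5); passenger counts are the rounded product with the guide
  count.
* **Library composition** (wild type): embryo — 26G 5 %,
  ERGO-1-class 22G 1.5 %, ALG-3/4-class 22G 1 %, CSR-1-class 22G 24.5 %,
  miRNA 40 %, piRNA 28 %; adult — ALG-3/4-class 26G 5 %, ERGO-1-class
  22G 4 %, ALG-3/4-class 22G 10 %, CSR-1-class 22G 33 %, miRNA 30 %,
  piRNA 18 %. Per-sequence abundances are log-normal (σ = 0.7) scaled to
  the class budget by largest-remainder rounding; depth 2 × 10⁵ reads
  per library. The 26G class is deliberately a *small* fraction of the
  library: depletion is measured in RPM, so removing a class shrinks the
  normalisation denominator and the measured depletion of a class with
  count factor *f* is `1 − f/T`, where `T` is the mutant's total
  relative mass. Small class shares keep `T ≈ 1`, so measured values sit
  at the factors' own magnitudes and co-regulated classes are not
  spuriously "enriched".
* **Depletion factors** (count space, wild type = 1): embryonic 26G
  0.002 in *eri-6/7/1* and 0.04 in *ergo-1*; embryonic ERGO-1-class 22G
  0.1 in *eri-6/7/1* and 0.5 in *ergo-1*; passenger 0.05 in *eri-6/7/1*
  and 2.0 (stabilisation) in *ergo-1*; adult ERGO-1-class 22G 0.1 in
  *eri-7*; ALG-3/4- and CSR-1-class factors 1.0 throughout. Mutant
  counts are the shared per-stage wild-type draw times the factor with
  stochastic (floor + Bernoulli) rounding — unbiased for any factor, and
  per-library RNG substreams keyed by (genotype, stage) mean adding a
  library never changes another.

### What the simulator does and does not emulate

It reproduces the *structure* the analysis relies on: exact-matching
reads, class-specific lengths and 5′ nucleotides, duplex geometry,
phasing, multi-mapping between duplicated loci, and class-level
depletion. It has no sequencing-error or adapter model, no quality
scores, no expression-level biology (a log-normal abundance assumption
stands in for the unknown true abundance distribution, and tests avoid
depending on its exact shape), no introns under reads, and no
chromatin- or position-dependent siRNA production. Passing tests
therefore demonstrate correct *recovery of known structure*, not
robustness to the noise of real libraries.

## Numerical and degenerate-input choices

Division by a zero wild-type total (class depletion, passenger
fold-change, RPM on an empty library) raises rather than returning a
sentinel. A gene with a single guide yields an empty phasing interval
list and an undefined (None) in-band fraction. An empty duplex record
set and an empty feature set for structure statistics are errors.
Weighted modes break ties toward the smaller value; the weighted median
takes the lower middle element. Report floats are rounded to 6 decimal
places before JSON serialisation so that reruns are byte-identical.

## Problem sizes

Defaults were chosen so a full simulate-to-report run completes in
seconds on a laptop: a 150-kb genome, ~240 distinct guides (~30 per
target gene), ~850 distinct sequences and 2 × 10⁵ read copies per
library. One property test (recovery of the 0.002 depletion factor) uses
depth 10⁶, a pre-run power choice: the expected mutant class count must
be ≳ 100 for its rounding noise to sit inside the ± 15 % tolerance, and
at depth 2 × 10⁵ it would be ~20.

## Known limitations

* Exact matching only; a single sequencing error unmaps a read. Fine
  for the simulator, a real-data pipeline would map with mismatches.
* Percent identity is alignment-derived and therefore depends on the
  declared scoring scheme; BLAST-style tools with other parameters will
  report slightly different identities near the 82 % boundary.
* The background homology rate is computed within each random sample
  (as a matched-size control), not against the full target set.
* miRNA/piRNA classification is annotation-driven; no hairpin-structure
  prediction is attempted.
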