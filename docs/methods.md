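# Methods

## Detection model

A chimeric chromosomal DNA read is operationally defined at two scales.

**Bin scale.** A read of length L is cut into ⌊L / w⌋ non-overlapping
bins of exactly w bases starting at position 0; the sub-w 3′ residue is
discarded. Defaults: w = 200 with a 600 bp minimum read length (long-read
mode); w = 50 with a 150 bp minimum (short-read mode). The minimum is
3 × w because an A-U-B call needs at least one bin on each chromosome
plus the transition bin. Each bin is aligned end-to-end and labelled
`unique` (exactly one genomic locus within the mismatch budget), `multi`
(two or more) or `unmapped` (none). A read is called chimeric only for
the strict pattern A⁺ U B⁺: any multi bin, any additional unmapped bin,
a terminal unmapped bin, a third chromosome, or a direct A→B transition
with no U bin eliminates the read. The direct-transition case is a known
blind spot of the binned definition — a junction falling exactly on a bin
boundary is missed — and is kept deliberately rather than "repaired",
because the single-U-bin requirement is what gives the call its
specificity. Bins are aligned independently with no collinearity or
same-strand requirement between them; chromosome identity alone decides
the pattern.

**Base scale.** For each called event, bin-sized windows are slid one
base at a time across the span from the start of the last A bin to the
end of the first B bin (the minimal region guaranteed to contain the
transition). With s_A the largest window start uniquely aligned to A and
s_B the smallest start > s_A uniquely aligned to B, the signed gap is
s_B − s_A − w: negative gaps are microhomology-mediated (dually aligning)
junctions with homology length −gap, zero is base-to-base, positive gaps
carry inserted bases. Events where no A or B window is found, or where
all B windows precede the last A window (interleaved repeats), are
demoted to eliminated with a reason code.

Refinement windows are matched **exactly** (0 mismatches) by default,
while first-pass bin alignment tolerates substitutions. The asymmetry is
deliberate: if refinement tolerated k mismatches, windows overhanging the
junction by a few bases would still align (each overhang base mismatches
with probability ~3/4), biasing the gap negative by up to ~k bases on
each side. Exact matching makes the recovered gap equal the implanted
truth base-for-base on error-free reads, which is the property the test
suite asserts. On reads with sequencing errors a window containing an
error is simply skipped, which can shift the junction estimate by the
distance to the nearest error; a nonzero refinement tolerance is exposed
for that regime as an explicit trade-off.

## Built-in aligner

Small-genome alignment is done by an exhaustive seed-and-verify
substitution-only aligner: the query is cut into m + 1 disjoint segments
for mismatch budget m, so any end-to-end placement with ≤ m mismatches
contains an error-free segment, whose leading 15-mer is found by exact
k-mer lookup; every candidate offset is then verified by full mismatch
counting on both strands. By this pigeonhole argument the locus set is
provably identical to brute-force scanning of every offset, which a
property test asserts on ≤ 100 kb genomes. Queries too short for the
pigeonhole seeding fall back to a vectorised full scan. The default
budget is ⌈0.02 × query length⌉ (4 mismatches for 200 bp bins, 1 for 50
bp). Uniqueness is defined as exactly one locus within the budget — an
explicit, reproducible criterion; when alignments are ingested from an
external aligner's SAM instead (query names `read_id/bin_index`), the
external aligner's own primary/secondary flags decide the label. N bases
match nothing, in genome or query. The genome is used unmasked; repeat
content is handled by the multi-mapping elimination rule, not by masking.

## Trio phasing and the mutation correction

Informative sites are positions where at least one parent owns an allele
the other parent lacks; alleles shared by both parents are labelled
ambiguous at read time and skipped — they carry no parent-of-origin
signal, and treating them as anything else would manufacture or mask
switches. Only SNVs are used (indels are dropped at VCF parse time), and
only sites present in all three trio VCFs are kept. Reads are classified
maternal / paternal / interallelic chimera (exactly one M↔P transition) /
eliminated-multiswitch / eliminated-mutated (≥ 1 non-parental allele) /
uninformative. The mutation rate is computed per read — a read with one
or more non-parental alleles counts once among all genotype-comparable
reads — and deflates the raw chimera percentage multiplicatively:
corrected% = raw% × (1 − rate). The denominator of raw% is
maternal + paternal + chimera reads. Both choices are forced by the
arithmetic of the published per-sample count tables they reproduce, and
are verified against those tables in the acceptance tests. The
independence model behind the correction fixes p = 0.75 per allele,
0.5625 for both alleles of a diploid locus, and an expected 25%
maternal-consistent fraction for a male offspring's hemizygous X, which
the hemizygous check recovers on simulated observations.

## Synthetic data generator

The generator emulates the study conditions at toy scale and is the
substrate for every end-to-end test:

* **Genome**: by default a few chromosomes of 50–80 kb of i.i.d. uniform
  bases standing in for hg38, with non-overlapping planted repeat
  families — Alu-like 300 bp and L1-like 1 kb units, each copy
  independently diverged from its consensus (default 5–10% per-base
  substitution; 0 divergence produces identical copies, the
  multi-mapping stress case). Divergence i.i.d. per copy creates a
  controllable older/younger subfamily uniqueness gradient.
* **Implants**: one chimeric read per planned junction, junction placed
  at the centre of a bin so the transition bin is genuinely unalignable;
  flanks of at least 2 bins on each side. Dual junctions carry homology
  tracts drawn from 20–60 bp (the published microhomology range); the
  tract is planted into the genome itself (A-side suffix copied over the
  B-side bases upstream of the breakpoint), since a negative gap is only
  recoverable when the donors genuinely share it. Junction-adjacent
  bases are capped (forced to differ from the donor continuations) so
  chance single-base agreement cannot extend the effective homology —
  without the cap the recovered gap would legitimately differ from the
  nominal one by the chance-matching bases, and truth would be fuzzy.
  Implant donor regions are reserved so one implant's genome edits never
  fall inside another's flanks.
* **Background reads**: uniformly placed, either strand, fixed or
  lognormal lengths, i.i.d. substitution errors (default 1%; no indels —
  the detection method aligns fixed-length windows end-to-end, so an
  indel error model would only exercise the external-aligner path).
  Placement and error noise use independent seeded streams, so the same
  seed yields the same placements at any error rate — this is what makes
  the binomial error-rate oracle in the tests exact.
* **Trio**: SNV sites at a configurable density (default 5/kb; 20/kb in
  the rate-recovery tests so every 300 bp read covers several sites), a
  configurable informative fraction, offspring reads sampled from one
  parental haplotype with a fraction s carrying exactly one switch
  placed between two adjacent covered informative sites and a disjoint
  fraction m carrying one non-parental allele. By default informative
  sites use fully diagnostic homozygous parent patterns, so s and m are
  exactly recoverable; a `het_pattern_fraction` mixes in het/hom
  patterns whose shared allele labels as ambiguous, for stress-testing
  the ambiguity handling (at the cost of switch-detection efficiency,
  as in real data).

What the generator does **not** emulate: platform-specific error
profiles (homopolymer indels, quality-correlated errors), CNVs and
structural variants other than the three junction types, chromatin- or
repeat-biased junction placement, non-uniform coverage, and linkage
structure among variant sites. Passing tests therefore demonstrate the
correctness of the curation, refinement and phasing logic under the
stated read model, not platform-level robustness.

## Statistics

Rates are reported as events per billion bases sequenced
(events / bases × 10⁹, 2 decimals). Non-chimeric support counts, for
each event, the non-chimeric reads with a unique bin alignment
overlapping either refined flank footprint padded by one bin (the window
is a package choice, exposed as a parameter). Repeat annotation
intersects the two flank footprints plus a one-bin strand-aware
projection of the unaligned transition region with a repeat BED
(RepeatMasker-style `class/subfamily` names); the max-overlap class is
primary, ties broken lexicographically, `repeat_free` otherwise.
Annotating by BED intersection rather than re-running a repeat masker on
U-bin sequences removes an external tool, is equivalent when the BED is
the masker's own output, and is exactly testable with planted repeats.
Fractions are per event by default (per-base is an option; which one the
published percentages used is not decidable from their description).
Composition: GC% and G/C skew (G−C)/(G+C) exclude N from numerator and
denominator, skew is 0 when G+C = 0; CpG% divides the CG dinucleotide
count by L − 1 positions (a convention choice, configurable at call
sites). The expected X-U-A percentage rescales a sample's observed
percentage by the ratio of X-mapped read fractions (test over
reference) — the direction is fixed by reproducing the published
expected value from the published counts. Gene-body coverage compares
the transcripts hit by a seeded, depth-normalising random subset of
event intervals against the mean over 10 seeded shuffles that place the
same intervals (lengths preserved) uniformly at random genome-wide.

## Numerical and scale choices

All internal coordinates are 0-based half-open; SAM/VCF positions are
shifted only at I/O boundaries. Support SD is the sample SD (ddof 1).
Test and acceptance problem sizes — 4 × 80 kb genomes, 51 implants, 200
background reads, 20,000 trio reads — are chosen so binomial 3-SD bands
are tight enough to be meaningful while the whole suite runs in seconds;
they are package defaults, not statements about the method's scale
limits. Known limitations: junctions on bin boundaries are invisible by
construction; homologous-chromosome fusions cannot be seen by alignment
(that is the trio module's job); telomeric fusions are out of reach
because telomere tracts exceed the bin length; >2-chromosome and
intra-chromosomal rearrangements are out of scope.
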