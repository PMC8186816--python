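# Methods

## The marker model

A CAPS (PCR-RFLP) assay genotypes a sequence variant through differential
restriction digestion of a PCR product. `capsmine` models this as a purely
sequence-level decision: an allele is *digested* by an enzyme if the
enzyme's recognition pattern occurs at least once in the allele's embedded
sequence — the allele's bases placed between the two reference flanks that
surround the variant. A locus × enzyme pair is a marker when, among the
alleles actually observed in at least one non-missing genotype, at least one
is digested and at least one is not.

Because all alleles of a locus share byte-identical flanks, a constitutive
flank site makes *every* allele digested and can never create a marker; a
differential call therefore always involves the allele region itself (for
SNPs/MNPs a site overlapping the changed bases, for indels a site spanning
the junction). This "flank-identity" property is asserted as a test
invariant rather than enforced by an explicit overlap check, which keeps the
mining rule a single scan per allele.

### Embedded sequences and display contexts

Two flank widths serve two purposes:

* **mining flank, default 40 bp** — the scan window. A SNP allele embeds to
  40+1+40 = 81 bp, a 10 bp insertion allele to 40+10+40 = 90 bp. 40 bp per
  side comfortably covers the longest practical recognition patterns
  (~15 bp including N runs), so no junction-spanning site can be missed.
* **display/output flank, default 500 bp** — the primer-design window
  written to marker output and FASTA export (lowercase flanks, uppercase
  allele): 500+1+500 = 1001 bp for a SNP, 500+10+500 = 1010 bp for a 10 bp
  insertion allele. Flanks are clipped at contig ends; callers learn the
  actual widths from the sequence lengths.

Indel alleles are taken literally from the VCF (anchor base included, no
left-normalization): the input caller's representation is trusted, and
coordinates are 1-based inclusive throughout.

### Site scanning

Recognition patterns use the 15 IUPAC codes. A pattern position matches only
a concrete A/C/G/T base within its expansion — an ambiguous reference base
(N) never matches, so uncertain sequence cannot produce a marker. Scanning
runs on both strands by default (a non-palindromic site cuts in either
orientation in a real digest); minus-strand hits are found by matching the
pattern in the reverse complement and mapping positions back, and
palindromic patterns are scanned on the plus strand only so each physical
site is counted once. Overlapping occurrences are all reported (regex
lookahead). Enzymes that cut outside their recognition sequence are scanned
by recognition-site presence only; cut offsets are carried for display.
Isoschizomers — enzymes with identical (pattern, cut offsets) — are merged
into one enzyme group and emitted as one marker line listing all names.

The scanner is verified against an independent brute-force oracle (expand
the pattern into all concrete words, substring-search both strands) on 10⁴
random sequence/pattern pairs, plus strand-symmetry and
generalization-monotonicity property tests.

## Filters

**Segregation prefilter.** Bi-allelic loci are classed hom-ref / het /
hom-alt; a locus is dropped if missing genotypes exceed `max_missing`
(default 5) or the Pearson goodness-of-fit χ² against the expected ratio
(default 1:2:1, df = 2, no continuity correction) has p < α (default 0.05),
with p computed via the χ² survival function (equal to `exp(-χ²/2)` at
df = 2). Multi-allelic loci are retained with a warning: the three-class
test is undefined for them, and silently dropping them would conflate
"untested" with "distorted". The filter precedes mining in the intended
workflow but is an independent operation.

**Single-cut filter.** Over each allele's full display window (both
strands), the marker's enzyme must hit exactly once on every digested allele
and exactly zero times on every undigested allele. The count is recomputed
from the stored contexts, so the filter works on a re-read marker file
without the reference. Output keeps the mining format under a `_scf`
filename suffix.

**Group filter.** Groups are disjoint named sample lists with per-group
thresholds — the tolerated *fraction* of inconsistent individuals relative
to that group's size; comparison is inclusive (1 mismatch in 10 passes a
0.10 threshold) and a missing `?/?` genotype always counts as inconsistent
for the genotype class a group is being matched to. Mode A searches all
injective assignments of the 2–3 groups onto the digestion genotype classes
{`+/+`, `-/+`, `-/-`}; with thresholds 0 and full coverage this is exactly
the co-segregation test. Mode B (two groups) searches both homozygote
classes and both group labelings: one group must be (almost) purely the
chosen homozygote, the other must (almost) lack it — the natural test for a
dominant trait in an F2. The search over assignments means users need not
know which homozygote is recessive; `fixed_assignment` pins it when they
do. Samples outside the declared groups are ignored, which tolerates extra
individuals but means an undeclared third genotype class goes unchecked.
Output carries the `_gf` suffix. No multiple-testing correction is applied
across loci.

## Input handling and caching

The FASTA index is a five-column text file (name, byte offset of first
base, bases per full line, bases in last line, length) headed by
`#<md5-of-source-bytes>`; the V2C intermediate carries the same header for
the VCF. A derived file is reused only while its recorded digest matches
the source, so any one-byte change forces a rebuild. Digests are over raw
file bytes — line-ending normalization is deliberately not performed, and
LF/CRLF FASTA files are both supported by detecting the terminator width at
read time. Sequences must use a uniform line width (except the last line);
ragged widths are rejected with the sequence named. Header names truncate at
the first whitespace, softmasked bases are uppercased on fetch.

VCF parsing (via cyvcf2/htslib) accepts `/` and `|` separators, treats
half-missing calls as fully missing, drops phase (V2C stores unphased sorted
pairs — a documented loss), keeps multi-allelic records with codes 1..k,
skips symbolic/breakend/`*` alleles with a warning, and ignores INFO
entirely so output from any caller works. The REF allele is checked against
the reference bases at the locus to catch a mismatched genome build. The
V2C writer adds an optional `#SAMPLES` header line (absent from the
minimal three-line-per-record format) because sample names are needed by the
marker output and group filter; readers tolerate its absence.

## The synthetic-data generator

`generate_fixture` emulates the *input* side of a small F2 mapping
experiment — one ~1.1 kb contig per locus (variant centered, wide enough
for unclipped 500 bp display flanks), 96 individuals, genotypes drawn
1:2:1 with 2% missing calls. Per enzyme it plants ten site-altering
variants (two each: site-loss SNP, site-gain SNP, site-spanning MNP, 4 bp
deletion, 9 bp insertion giving a 10 bp ALT allele) and two trap loci
(site-loss SNP plus a second constitutive site 70–350 bp away: differential
at the mining flank, two-cut at the display flank), plus 200 decoy SNPs and
a few multi-allelic decoys verified to leave every enzyme's digestion
status unchanged. One planted site-loss SNP is the trait locus — its ALT
allele acts as a dominant restorer splitting the population into
carrier/non-carrier groups computed from the *true* genotypes before
missing-data masking — and two further loci share its gametes with a 5%
recombination fraction.

Every constructed locus is *verified* against the production scanner before
acceptance (flanks are scrubbed of target-enzyme sites, cross-enzyme
neutrality is checked, and the intended hit counts at both flank widths are
confirmed), with rejection-resampling on failure; the recorded truth table
is therefore exact by construction, which is what makes the
exact-recovery and exactly-the-traps tests meaningful. All randomness flows
from a single seed through one generator, and identical seeds yield
byte-identical FASTA/VCF/truth files.

What the generator does **not** emulate: sequencing error, genotype-call
error correlated with depth, the high missingness typical of GBS (~68% in
real reduced-representation data), linkage structure beyond one small
cluster, repetitive flanks, or reference softmasking. Passing the planted
tests therefore demonstrates correctness of the sequence logic and the
filter semantics, not robustness to noisy real-world calls — on real data
the segregation prefilter and threshold choices carry that burden.

## Numerical and design choices

* Deterministic ordering everywhere: markers sort by locus file order then
  enzyme group name; genotype classes by allele-code pair, missing last;
  re-writing a read marker or V2C file is byte-identical.
* Heterozygous digestion genotypes display as `-/+` (minus first);
  homozygotes repeat the flag.
* Threshold comparisons are inclusive (`<=`); χ² test uses no continuity
  correction.
* The trait/phenotype grouping uses true pre-masking genotypes, so a masked
  call at the trait locus shows up as a `?/?` inconsistency — intentional,
  as real phenotypes are observed independently of genotyping success.
* Problem sizes in the test suite (a 60-sample shared fixture; 96 samples
  and 200 decoys in the end-to-end checks; 10⁴ scanner-oracle pairs) were
  chosen so the whole suite exercises every planted variant class in a few
  seconds on one core.

## Known limitations

* Methylation sensitivity, star activity and nicking-enzyme semantics are
  out of scope; an in-silico cut is assumed to be a real cut.
* Fragment sizes / virtual gels are not predicted; cut offsets are carried
  only for display.
* dCAPS (mismatch-primer) design is not attempted: a variant with no
  differential natural site simply yields no marker.
* bgzip-compressed FASTA is not supported by the indexer (plain text only).
* Phase is dropped at V2C conversion.
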