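# Methods

## Matching model

Both the query motif and the genome use the IUPAC ambiguity alphabet.
A motif symbol denotes the set of bases a transcription factor
tolerates at that position; a genome symbol at a masked position
denotes the set of alleles segregating there.  The scanner declares a
match at one position whenever the two sets intersect — i.e. at least
one allele of the SNP is compatible with the motif — and a window is
a hit when every position matches for the forward pattern or for its
reverse complement.  This is exact degenerate-string matching: there
is no mismatch tolerance and no position-weight scoring, because the
question being asked is "could this factor's written consensus occur
here for at least one allele", not "how strong is the site".

Two deliberate rules sharpen the semantics:

* **Genome `N` matches nothing, including the motif wildcard `n`.**
  In SNP-masked FASTA, `N` marks unsequenced assembly gaps, not known
  tetra-allelic SNPs.  Letting it match would flood every gap with
  hits of pure wildcard windows.  (Whether the historical pipelines
  this reimplements made the same choice is undocumented; it is this
  package's documented behaviour.)
* **Palindromic double matches collapse to one hit**, reported with
  strand `±`, so a window matching in both orientations is counted
  once in the motif and SNP statistics.  Its SNP offsets are reported
  in the forward orientation.  Ordinary reverse-strand hits report
  offsets as read 5'→3' on the hit strand.

A genome position is a SNP position iff its symbol is outside
`{A,C,G,T,N}` — exactly the mask alphabet.  Comparisons are
case-insensitive (soft-masked lowercase is uppercased on read);
repeat status is ignored.

The scanner is vectorised with 4-bit base masks (A=1, C=2, G=4, T=8;
a symbol's mask is the OR of its bases; genome `N` encodes to 0), so
a window matches iff the bitwise AND is nonzero at every offset.
Chromosomes are processed one at a time; memory never holds more
than one chromosome.

## Candidate logic

Motif-SNP positions are annotated with rs-numbers from the SNP
catalogue; positions absent from the catalogue are logged and
excluded (density numerators therefore count only rsid-bearing SNPs,
keeping the region, motif and genome densities on the same marker
universe).  Region membership is inclusive on both boundaries after
converting BED's 0-based half-open coordinates to 1-based inclusive.
Set logic is rsid-keyed:

* `AND` — rsids in both lists;
* `OR` — the union;
* `SCORE` — the AND set, plus region SNPs whose best covering
  region's score is **strictly greater** than the threshold ("above"
  is read literally).  A SNP under several regions takes the maximum
  score, on the argument that any single strong region is sufficient
  support.

## Genotype and proxy resolution

A candidate present in the MAP panel is DIRECT.  Otherwise every LD
record on the candidate's chromosome in which it appears as either
pair member and r² ≥ threshold contributes a proxy; the threshold is
inclusive because a cutoff stated as "r²-threshold" conventionally
admits the boundary.  Among *genotyped* proxies the winner is the
highest r²; ties break to the smallest bp distance from the
candidate, then the lexicographically smallest rsid.  The tie-break
beyond "highest r²" is this package's choice — some rule is needed
for the output to be reproducible and independent of LD-file record
order.  Proxies are searched only within the candidate's chromosome
(bulk LD downloads are per-chromosome; inter-chromosomal LD is out of
scope), and a proxy may itself be another candidate; the final
tested-marker list is deduplicated at write time with provenance
concatenated.

## Densities and tests

Densities are SNPs per bp: catalogue SNPs in regions over the summed
region lengths (overlapping regions are **not** merged — the
denominator is "total length of all regions" as given; an opt-in
`--merge-regions` flag merges them first), annotated motif SNPs over
motif length × occurrence count, and total catalogue SNPs over total
FASTA length (gap bases included, since the denominator is defined as
the FASTA length).  Group comparisons use a Pearson chi-square on the
2×2 table SNP/non-SNP × group, 1 df, no Yates correction — at
genome-scale counts the correction is immaterial.  All four cells
must be positive or the comparison is refused.  Per-position SNP
fractions are normalised to the motif's total SNP count and sum to 1
whenever at least one SNP was seen; a per-symbol aggregation pools
positions sharing the same motif symbol.

## Synthetic fixtures

The generator emits all six inputs from one seeded specification and
records a truth table for every planted motif-SNP.  Default
conditions: 3 chromosomes × 50 kb, background SNP rate 0.2 % (the
order of magnitude of genome-wide SNP density), 30 planted motif
occurrences of which half carry exactly one SNP, half of the plants
inside one of 9 scored regions of 1 kb (scores uniform integers
1–10), 90 % of mask positions present in the catalogue, 50 % of
catalogue SNPs genotyped, r² threshold 0.8, combine mode AND,
population label CEU.  The LD policy gives every ungenotyped
candidate 0–3 partners with r² scattered around the threshold —
including exactly at it, so the boundary case is always exercised —
plus occasional tied-r² pairs (for the distance tie-break) and decoy
rows between non-candidate markers.  rsids are sequential `rs%05d`,
so lexicographic and numeric order coincide.

Background sequence is actively scrubbed of accidental motif matches
(both strands, degenerate semantics, mask codes included): accidental
windows are broken by reverting a background SNP inside them or by
mutating a base outside every planted footprint, iterating until the
scan is clean.  Planted windows are kept ≥ L+2 bp apart so no window
can span two plants.  This gives a clean null background: the scanner
must find exactly the planted occurrences.  The expected
DIRECT/PROXY/UNRESOLVED status is recomputed from the *emitted* LD
table with plain loops, and `validate()` cross-checks every truth row
against the files on disk before any test consumes them.

What fixtures do not emulate: coalescent LD structure, allele
frequencies, mutational heterogeneity, repeats, or realistic region
size distributions.  Passing tests therefore demonstrate pipeline
correctness (bookkeeping, set logic, tie-breaks, boundary handling),
not robustness to the statistical texture of real genomes.

With the region SNP rate doubled (density fixtures: 1 chromosome ×
100 kb, 20 × 1 kb regions, no motif), the expected chi-square z is
≈ 4, so the enrichment is detected at α = 0.05 in ≈ 98 % of
replicates; the suite requires ≥ 95 % over 200 seeded replicates.
Note the genome-average density includes the enriched regions
themselves, so the measured region/genome ratio is ≈ 1.67, not 2.

## Numerical and interface choices

* Problem sizes in the test suite (5 kb scan sequences, 6 × 50 kb
  end-to-end fixtures, 200 density replicates) were chosen as the
  smallest sizes at which every property is exercised with clear
  statistical headroom.
* Determinism: a fixed seed yields byte-identical fixture
  directories (gzip mtime pinned to 0); a fixed configuration yields
  byte-identical outputs and log body (the log format carries no
  timestamps).
* Chromosome labels are normalised by stripping a `chr` prefix;
  public catalogues mix the two conventions.
* Duplicate catalogue positions and duplicate MAP rsids keep the
  first occurrence and log a warning.
* The tool cannot verify that FASTA and catalogue share a genome
  build; it logs a prominent warning instead.
* LD files are located by the per-chromosome filename convention
  `ld_chr<label>.txt.gz`; a missing file downgrades that chromosome's
  candidates to unresolved with a warning rather than aborting.
* Output column orders are this package's own (stated in each file's
  `#` header line); the four result filenames are fixed contracts.
* For documentation only: on real human data (CEU), catalogue size is
  on the order of 2.8 million SNPs and genome-wide density just below
  0.1 %, with binding regions near 0.11–0.12 % and motifs 0.15–0.18 %;
  nothing in this package asserts those values, since they depend on
  specific reference downloads.

## Known limitations

One motif per run; no PWM or mismatch-tolerant matching; LD is
consumed, never estimated from genotypes; no VCF input; association
testing downstream of the candidate list (Fisher's exact tests,
multiple-testing correction) is out of scope — the output files are
the hand-off point to PLINK or similar.
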