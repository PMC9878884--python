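# Methods

## The linear pangenome model

`linpan` represents a pangenome as one linear sequence: the primary
reference with novel segments from other assemblies spliced in at their
collinear breakpoints. Construction is iterative. At step *k* the current
reference (ref*k−1*) is compared to the next assembly; every detected
insertion strictly longer than `min_insert` (default 50 bp) is spliced in
immediately before its breakpoint, producing ref*k*. Because each
comparison runs against the *updated* reference, a segment shared by two
assemblies is incorporated only once, at the first iteration that sees it.
Deletions are deliberately never incorporated: sequence missing from an
assembly surfaces later as an absence genotype, which is the representation
the coverage-based genotyper consumes.

Splicing is applied right-to-left within a chromosome so that earlier
coordinates remain valid during the operation. Two distinct insertions at
the same breakpoint in one iteration are rejected as an ambiguous splice
order; byte-identical duplicates are collapsed.

### Coordinates and liftover

All internal coordinates are 0-based, half-open; GFF3 output converts to
1-based inclusive in the writer and back in the reader. Each iteration
yields a `CoordinateMap` — per chromosome, an ordered list of collinear
blocks `(src_start, src_end, dst_start)` plus the inserted destination
intervals that have no source preimage. Maps compose associatively into a
single base-reference → pangenome map, with block refinement wherever a
later iteration split an earlier block. `project(lift(p)) = p` holds for
every base position; projecting a position inside an inserted interval
returns the sentinel `"inserted"` together with the owning segment name.
If a later iteration inserts *inside* an earlier segment, the earlier
annotation interval is widened to the image of its end points (it then
contains the nested insert); annotations are never merged or split.

### Insertion detection

The internal comparison engine finds maximal runs of k-mers
(k = `min_anchor_len`, default 21) that occur exactly once in both
sequences and agree on a diagonal, then chains them per chromosome pair by
a heaviest-increasing-subsequence dynamic program. Between adjacent chain
anchors, a query-side gap exceeding the reference-side gap marks an
insertion of the surplus query bases, placed immediately before the next
anchor's reference start; sentinel anchors pin the chromosome ends so
terminal insertions are found. Reference gaps larger than `max_gap`
(default 500 bp) are treated as unalignable divergence rather than
insertion context. Only forward-strand k-mers are indexed, so inverted
regions produce balanced gaps and never an insertion call — inversions are
handled as genotyped candidates, not as pangenome content. An import path
for Assemblytics-style variant tables (and BLAST outfmt-6 for
translocation hits) lets the package consume output of a full-scale
aligner pipeline instead; the incorporation and genotyping logic is
identical either way. The engine is intended for desk-scale genomes
(hundreds of kb to a few Mb); it is quadratic in the number of chain
anchors and keeps whole sequences in memory.

## Coverage-based PAV genotyping

Per accession, depth over the pangenome is evaluated in non-overlapping
20-bp windows (`window`); a window is *present* when its depth statistic is
at least `min_depth` = 5 reads, else *absent*. The statistic is the mean
per-base depth by default — the rule's source convention does not say mean,
median or minimum, so the choice is exposed (`stat=`); mean matches what
windowed depth tools emit. The terminal partial window is evaluated like
any other so segments always partition the chromosome. Reads count toward
depth only when mapped, primary, and with mapping quality strictly greater
than 20 ("over 20" is read literally); no duplicate-marking beyond those
filters is applied. Maximal runs of same-state windows merge into
segments; the segment boundaries, plus chromosome ends, are the accession's
breakpoints.

Population genotyping takes the sorted union of all accessions'
breakpoints; adjacent union positions delimit PAV regions named
`<chrom>_<left breakpoint>`. Because the union refines every accession's
own partition, each region inherits exactly one state per accession —
re-calling can never produce a mixed region, and the total present length
per accession is conserved. The matrix is filtered by minor-state
frequency > `maf` (0.05) among non-missing entries and missingness <
`missing` (0.15). The window/merge procedure itself yields no missing
state; *missing* arises only for accessions with no depth track over a
chromosome, which is what makes the missingness filter meaningful.
Invariant regions drop out during filtering (they have MAF 0). HapMap
export doubles the alleles (`CC`/`AA`/`NN`) since the target material is
inbred; the HapMap format encodes marker positions but not region ends, so
re-import recovers every genotype and marker name/position, while the last
region's right bound on each chromosome is a sentinel.

## Junction genotyping of translocations and inversions

Translocation candidates are inserted segments longer than 1 kb whose
sequence matches two or more pangenome loci at ≥ 95% identity (the
self-locus counts as one). The internal similarity search takes exact
seeds of length `seed_len` (default 1,000, capped at the segment length) at
every query offset — so a match whose few mismatches sit near the segment
edges is still seeded — anchors a candidate locus at each hit, and scores
the full segment against the locus window by global edit-distance
alignment (identity = 1 − distance / segment length). Near-duplicate locus
placements from seed jitter collapse to the best-scoring one. No e-value
is computed; the length/identity/locus-count rules are the operative
filters at desk scale, and a BLAST tabular import preserves fidelity for
full-scale runs.

Each SV is genotyped per accession from reads spanning a 39-bp window
centred on a breakpoint: a read counts only if a single contiguous matched
block (CIGAR-equivalent) covers at least `flank` = 19 bases on each side —
matched blocks, not re-verified sequence identity, because the screen
exists to reject reads that reach a junction with short mismatching tails.
Fewer than `min_reads` = 5 spanning reads codes absence "A", otherwise
presence "C". An SV with several breakpoints (both ends of an inversion;
both junctions of a translocation placement) is present only if **every**
breakpoint is present; a breakpoint closer than `flank` to a chromosome
end genotypes as missing. The per-breakpoint thresholds are from the
method's definition; the all-breakpoints aggregation is this package's
choice, as the aggregation for multi-junction SVs is otherwise
unspecified. Junction coordinates for a translocation are the boundaries
of the segment's pangenome placement; the matched loci are kept as
metadata.

## Gene PAV and frequency testing

Per gene and accession: horizontal coverage = fraction of CDS bases at
depth ≥ `v_min` (2), vertical coverage = mean CDS depth (the source
convention does not fix the vertical statistic; mean is used and exposed).
A gene is absent iff horizontal < `h_min` (0.95) **and** vertical <
`v_min` — a strict conjunction, read literally from the rule's "and"; a
`rule="disjunction"` switch provides the stricter alternative since the
convention the rule descends from is ambiguous. Group differences use a
two-sided Fisher's exact test (sidedness unspecified in the source;
two-sided is the conservative default) on the per-gene 2×2
present/absent × group table, Bonferroni-adjusted (`min(1, m·p)` over the
m tested genes); significance requires adjusted p < 0.001 and an absolute
between-group frequency difference ≥ 0.10. Genes where a group is
entirely missing are skipped with a warning.

## The synthetic-data generator

`linpan.simulate` emulates exactly the inputs the pipeline contracts need:
a random founder chromosome (default 200 kb), derived genomes differing
from it only by planted events — insertions with log-uniform lengths
(default 51–5,000 bp; the default build plants 10 per genome across 3
genomes), optional duplicated > 1-kb cassettes as translocation bait, and
reverse-complemented segments as inversions — plus per-accession carrier
states, uniform error-free depth tracks (default 10×) and junction read
stubs. Everything derives from a single integer seed.

Three constructions make planted truth *exact* rather than approximate:

- Event anchors are drawn pairwise well-separated (default ≥ 400 bp), so
  the expected pangenome coordinate of each insertion is its founder
  anchor plus the total length of insertions anchored to its left —
  independent of genome incorporation order.
- Inserted sequences are junction-pinned: the first/last base is forced to
  differ from the flanking founder base, so the splice cannot be slid and
  detected breakpoints match planted ones exactly. (Cassette copies differ
  only in these ≤ 2 pinned bases, keeping them > 99% identical.)
- With `window_align` (default 20), anchors and lengths snap to the window
  grid, so coverage-derived segment boundaries coincide exactly with
  planted intervals; with `window_align=None` the recovery guarantee
  relaxes to one window per boundary, which the tests check separately.

What the generator deliberately does **not** model: sequencing error, GC
or mappability bias, repeat-induced multi-mapping, heterozygosity, or real
read placement (depth tracks are written directly; junction evidence is
alignment-record stubs honouring the genotyper's contract). Passing tests
therefore demonstrate the correctness of the incorporation, liftover,
union-re-calling and thresholding logic under clean coverage signals — not
robustness to noisy real-world alignment, which the thresholds (5 reads,
19-bp flanks, 95%/2× gene rule) are designed to absorb but which is only
exercisable with real data.

## Numerical and design notes

- Thresholds are boundary-exact and match their sources: insertion kept iff
  length > 50; mapq kept iff > 20; window present iff depth ≥ 5; read
  spans iff ≥ 19 matched bases per side; presence iff ≥ 5 spanning reads;
  gene absent iff horizontal < 0.95 and vertical < 2; significant iff
  adjusted p < 0.001 and Δfreq ≥ 0.10; region kept iff MAF > 0.05 and
  missing < 0.15.
- Genome incorporation order is an explicit argument (input order by
  default); for disjoint insertions the final content is provably
  order-independent, and the tests assert it.
- Problem sizes in tests and the acceptance script (200-kb founder, 3
  genomes, 30 insertions, 10 accessions; 100-kb cassette simulations) are
  chosen so the full suite runs in well under a minute per stage on one
  core while still exercising every code path at the method's stated
  thresholds.
- Fisher p-values come from `scipy.stats.fisher_exact`; the test suite
  verifies them against an exact integer hypergeometric enumeration over
  all 2×2 tables up to total count 30 (agreement ≲ 1e-15, far inside the
  1e-12 requirement).

## Known limitations

- The anchor-chaining comparator assumes mostly-collinear, repeat-poor
  genomes; heavy repeat content starves it of unique k-mers (it errors,
  advising a smaller k). It is a desk-scale stand-in, not a replacement
  for a genome aligner at chromosome scale.
- Nested insertions widen rather than split earlier annotations (above).
- Translocation junctions are genotyped at the segment placement
  boundaries; the individual matched loci are not genotyped separately.
- The HapMap reader cannot recover the right bound of the final region per
  chromosome (format limitation).
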