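# linpan

Linear pangenome construction and structural-variant genotyping from
short-read coverage.

A single reference genome hides the sequences a species carries only in some
individuals. `linpan` addresses this for inbred crop populations (the design
case is rice): it builds a **linear pangenome** by iteratively comparing
additional genome assemblies against a growing reference and splicing every
novel insertion (> 50 bp) into it at its collinear breakpoint, keeping a
coordinate liftover between the base reference and the pangenome. Because
the result is one plain linear sequence plus a GFF of inserted segments,
standard short-read tooling works on it unchanged.

On that pangenome, `linpan` genotypes — per accession, from read depth alone:

- **PAVs (presence/absence variations):** mean depth in 20-bp windows;
  a window is *present* at ≥ 5 reads, *absent* below; adjacent same-state
  windows merge into segments. Population-wide, all accessions' segment
  boundaries form a **breakpoint union**; each pair of adjacent union
  breakpoints is a PAV region (named `<chrom>_<left breakpoint>`), every
  accession is re-called over those regions, and the rows stack into a
  genotype matrix filtered at MAF > 0.05 and missingness < 15%.
- **Translocations:** inserted segments > 1 kb matching ≥ 2 pangenome loci
  at ≥ 95% identity; **inversions:** imported from genome-vs-pangenome
  comparison. Both are genotyped by counting reads whose contiguous matched
  block spans a 39-bp window centred on each breakpoint (19 bp per side);
  < 5 spanning reads ⇒ absent ("A"), otherwise present ("C").
- **Gene PAVs:** a gene is absent when horizontal CDS coverage
  (fraction of CDS bases at depth ≥ 2) < 95% **and** vertical coverage
  (mean CDS depth) < 2; per-gene group frequency differences are tested by
  a two-sided Fisher's exact test with Bonferroni correction
  (significant: adjusted p < 0.001 and |Δfreq| ≥ 10%).

The PAV matrix exports to HapMap for GWAS, coding present as `CC`, absent
as `AA`, missing as `NN`.

A fully specified synthetic-data module (`linpan.simulate`) generates
founder/derived genomes with planted insertions, duplicated cassettes and
inversions, plus error-free depth tracks and junction reads with known
truth, so every stage is testable end to end without external data.

## Worked example

```sh
linpan run --seed 7 --out demo/
```

runs simulate → build → genotype → matrix → translocation discovery and
prints a report (also written to `demo/run.report.json`):

```json
{
  "seed": 7,
  "pangenome_length": 236360,
  "n_pav_segments": 32,
  "n_accessions": 10,
  "matrix_regions_prefilter": 63,
  "matrix_regions_postfilter": 31,
  "n_translocation_candidates": 2,
  "elapsed_s": 2.09
}
```

Reading it: the 200,000-bp founder grew to 236,360 bp after 32 novel
segments (30 plain insertions across 3 genomes plus one duplicated 1.2-kb
cassette pair) were spliced in; 10 simulated accessions produced 63
breakpoint-union PAV regions, of which 31 are polymorphic at MAF > 0.05;
both cassette copies were recovered as translocation candidates (each
matches the other's locus at > 99% identity). `demo/pav.hmp.txt` holds the
HapMap-coded matrix, e.g.

```
rs#        alleles  chrom  pos    ...  acc1  acc2  acc3  ...
chr1_2700  A/C      chr1   2701   ...  AA    CC    AA    ...
```

— accession `acc2` carries the segment starting at pangenome position
2,700; `acc1` does not.

Individual stages are available as `linpan simulate | build | genotype |
matrix | sv | genepav`; the same operations are importable from the
`linpan` package for programmatic use.

## Layout

| module | role |
|---|---|
| `linpan.align` | unique k-mer anchor chaining; insertion detection; Assemblytics-style import |
| `linpan.build` | iterative incorporation, PAV annotations, coordinate maps, FASTA/GFF3 I/O |
| `linpan.liftover` | piecewise-monotone coordinate maps, composition, lift/project |
| `linpan.coverage` | depth tracks, 20-bp windowing, segment merging, read filters |
| `linpan.popmatrix` | breakpoint union, re-calling, MAF filter, HapMap export |
| `linpan.svgeno` | translocation candidates, junction-spanning-read genotyping, inversion import |
| `linpan.genepav` | CDS coverage, gene PAV calls, Fisher/Bonferroni group tests |
| `linpan.simulate` | seeded synthetic genomes, depth and junction evidence with truth manifests |
| `linpan.cli` | `linpan` command-line entry point |

See `docs/methods.md` for the model, parameter meanings and numerical
choices.
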