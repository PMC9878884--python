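"""Translocation and inversion genotyping from junction-spanning reads.

Translocation candidates are PAV segments longer than 1 kb whose sequence
matches two or more pangenome loci at >= 95% identity (the self-locus counts
as one).  Inversion candidates come from genome-vs-pangenome comparison
(imported from Assemblytics-style tables and lifted onto pangenome
coordinates).  Both are genotyped per accession by counting reads whose
contiguous matched block spans a 39-bp window centred on each breakpoint
(19 bp on each side); fewer than 5 spanning reads codes absence "A",
otherwise presence "C".  An SV with several breakpoints is present only if
every breakpoint is present.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd

from .build import PavSegmentAnnotation, Pangenome
from .coverage import AlignmentRecord, passes_filters
from .liftover import CoordinateMap

CODE_PRESENT = "C"
CODE_ABSENT = "A"
CODE_MISSING = "N"


@dataclass(frozen=True)
class MatchedLocus:
    chrom: str
    start: int
    end: int
    identity: float  # fraction in [0, 1]


@dataclass
class TranslocationCandidate:
    pav_name: str
    chrom: str
    start: int
    end: int
    matched_loci: list[MatchedLocus]

    @property
    def n_loci(self) -> int:
        return len(self.matched_loci)

    def breakpoints(self) -> list[tuple[str, int]]:
        """Junctions of the segment's pangenome placement."""
        return [(self.chrom, self.start), (self.chrom, self.end)]


@dataclass
class InversionCandidate:
    chrom: str
    start: int
    end: int
    source_genome: str = ""

    @property
    def name(self) -> str:
        return f"INV_{self.chrom}_{self.start}_{self.end}"

    def breakpoints(self) -> list[tuple[str, int]]:
        return [(self.chrom, self.start), (self.chrom, self.end)]


@dataclass(frozen=True)
class JunctionEvidence:
    chrom: str
    pos: int
    spanning_read_count: int
    flank: int = 19


@dataclass(frozen=True)
class SvGenotype:
    sv_id: str
    accession: str
    code: str  # "C" presence / "A" absence / "N" missing


def _read_spans_junction(rec: AlignmentRecord, pos: int, flank: int) -> bool:
    """True when one contiguous matched block covers [pos - flank, pos + flank)."""
    return any(s <= pos - flank and pos + flank <= e for s, e in rec.blocks)


def count_spanning_reads(
    records: list[AlignmentRecord],
    chrom: str,
    pos: int,
    flank: int = 19,
    min_mapq: int = 20,
) -> JunctionEvidence:
    n = sum(
        1
        for r in records
        if r.chrom == chrom and passes_filters(r, min_mapq)
        and _read_spans_junction(r, pos, flank)
    )
    return JunctionEvidence(chrom=chrom, pos=pos, spanning_read_count=n, flank=flank)


def genotype_breakpoint(
    records: list[AlignmentRecord],
    chrom: str,
    pos: int,
    chrom_length: int,
    flank: int = 19,
    min_reads: int = 5,
    sv_id: str = "",
    accession: str = "sample",
) -> SvGenotype:
    """Genotype one breakpoint from junction-spanning reads.

    A breakpoint closer than ``flank`` to a chromosome end cannot be spanned
    on both sides and genotypes as missing."""
    if pos - flank < 0 or pos + flank > chrom_length:
        warnings.warn(
            f"breakpoint {chrom}:{pos} within {flank} bp of a chromosome end; "
            "genotype set to missing"
        )
        return SvGenotype(sv_id, accession, CODE_MISSING)
    ev = count_spanning_reads(records, chrom, pos, flank)
    code = CODE_PRESENT if ev.spanning_read_count >= min_reads else CODE_ABSENT
    return SvGenotype(sv_id, accession, code)


def genotype_sv(
    records: list[AlignmentRecord],
    breakpoints: list[tuple[str, int]],
    chrom_lengths: dict[str, int],
    flank: int = 19,
    min_reads: int = 5,
    sv_id: str = "",
    accession: str = "sample",
) -> SvGenotype:
    """All-breakpoints rule: present only if every junction is present."""
    codes = [
        genotype_breakpoint(
            records, c, p, chrom_lengths[c], flank, min_reads, sv_id, accession
        ).code
        for c, p in breakpoints
    ]
    if CODE_ABSENT in codes:
        code = CODE_ABSENT
    elif CODE_MISSING in codes:
        code = CODE_MISSING
    else:
        code = CODE_PRESENT
    return SvGenotype(sv_id, accession, code)


def genotype_sv_population(
    candidates: list[TranslocationCandidate | InversionCandidate],
    accession_records: dict[str, list[AlignmentRecord]],
    chrom_lengths: dict[str, int],
    flank: int = 19,
    min_reads: int = 5,
) -> pd.DataFrame:
    """SV genotype matrix (rows = accessions, columns = SV ids, values A/C/N)."""
    ids = [
        c.pav_name if isinstance(c, TranslocationCandidate) else c.name
        for c in candidates
    ]
    rows = {}
    for acc, records in accession_records.items():
        rows[acc] = [
            genotype_sv(
                records, cand.breakpoints(), chrom_lengths, flank, min_reads,
                sv_id=svid, accession=acc,
            ).code
            for cand, svid in zip(candidates, ids)
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=ids)


# ---------------------------------------------------------------------------
# Translocation candidate discovery
# ---------------------------------------------------------------------------

def _seed_hits(pav_seq: str, target: str, seed_len: int) -> set[int]:
    """Candidate locus starts on ``target`` from exact seed matches.

    Seeds are taken at every query offset (an exact stretch of ``seed_len``
    bases anywhere within a candidate alignment triggers it, so matches whose
    few mismatches sit near the segment edges are still seeded)."""
    starts: set[int] = set()
    for off in range(0, max(len(pav_seq) - seed_len, 0) + 1):
        seed = pav_seq[off : off + seed_len]
        pos = target.find(seed)
        while pos != -1:
            starts.add(pos - off)
            pos = target.find(seed, pos + 1)
    return starts


def find_translocation_candidates(
    pangenome: Pangenome,
    annotations: list[PavSegmentAnnotation] | None = None,
    min_len: int = 1000,
    min_identity: float = 0.95,
    min_loci: int = 2,
    seed_len: int = 1000,
) -> list[TranslocationCandidate]:
    """PAV segments > ``min_len`` whose sequence matches >= ``min_loci``
    pangenome loci at >= ``min_identity``.

    Similarity search: exact seeds of length min(seed_len, segment length)
    anchor candidate loci, which are then scored by global edit-distance
    alignment of the full segment against the locus window; identity =
    1 - dist / segment length.  The self-locus always counts as one match.
    """
    anns = annotations if annotations is not None else pangenome.annotations
    out: list[TranslocationCandidate] = []
    for ann in anns:
        if ann.length <= min_len:
            continue
        seq = pangenome.annotation_sequence(ann)
        slen = min(seed_len, len(seq))
        loci: list[MatchedLocus] = []
        for chrom, target in pangenome.sequence.chromosomes.items():
            for start in sorted(_seed_hits(seq, target, slen)):
                s = max(start, 0)
                e = min(start + len(seq), len(target))
                if e - s < len(seq) * min_identity:
                    continue
                res = edlib.align(seq, target[s:e], mode="NW", task="distance")
                ident = 1 - res["editDistance"] / len(seq)
                if ident >= min_identity:
                    loci.append(MatchedLocus(chrom, s, e, ident))
        loci = _dedup_loci(loci)
        if len(loci) >= min_loci:
            out.append(
                TranslocationCandidate(
                    pav_name=ann.name,
                    chrom=ann.pangenome_chrom,
                    start=ann.start,
                    end=ann.end,
                    matched_loci=loci,
                )
            )
    return out


def _dedup_loci(loci: list[MatchedLocus], min_separation: int = 50) -> list[MatchedLocus]:
    """Collapse near-identical locus placements (seed jitter) keeping the best."""
    kept: list[MatchedLocus] = []
    for loc in sorted(loci, key=lambda l: (l.chrom, l.start, -l.identity)):
        if kept and kept[-1].chrom == loc.chrom and abs(loc.start - kept[-1].start) < min_separation:
            if loc.identity > kept[-1].identity:
                kept[-1] = loc
            continue
        kept.append(loc)
    return kept


# ---------------------------------------------------------------------------
# Imports: BLAST outfmt-6 and Assemblytics inversions
# ---------------------------------------------------------------------------

def read_blast_candidates(
    path: str | Path,
    annotations: list[PavSegmentAnnotation],
    min_len: int = 1000,
    min_identity: float = 0.95,
    min_loci: int = 2,
) -> list[TranslocationCandidate]:
    """Translocation candidates from a BLAST tabular (outfmt 6) file whose
    queries are PAV segment names and subjects are pangenome chromosomes."""
    by_name = {a.name: a for a in annotations}
    hits: dict[str, list[MatchedLocus]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.split("\t")
            qname, schrom, pident = f[0], f[1], float(f[2])
            sstart, send = int(f[8]), int(f[9])
            if qname not in by_name:
                continue
            s, e = min(sstart, send) - 1, max(sstart, send)
            hits.setdefault(qname, []).append(MatchedLocus(schrom, s, e, pident / 100))
    out = []
    for name, loci in hits.items():
        ann = by_name[name]
        if ann.length <= min_len:
            continue
        loci = _dedup_loci([l for l in loci if l.identity >= min_identity])
        if len(loci) >= min_loci:
            out.append(
                TranslocationCandidate(name, ann.pangenome_chrom, ann.start, ann.end, loci)
            )
    return out


def import_inversions(
    path: str | Path,
    coordinate_map: CoordinateMap | None = None,
    source_genome: str = "",
) -> list[InversionCandidate]:
    """Inversion rows from an Assemblytics-style table, lifted onto the
    pangenome via the build module's coordinate map (identity if None)."""
    path = Path(path)
    out: list[InversionCandidate] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        cols = {c.lstrip("#").strip().lower(): c for c in reader.fieldnames}
        for ln, row in enumerate(reader, start=2):
            try:
                vtype = row[cols["type"]]
                if "inversion" not in vtype.lower():
                    continue
                chrom = row[cols.get("reference") or cols["ref_chrom"]]
                start = int(row[cols["ref_start"]])
                stop = int(row[cols.get("ref_stop") or cols["ref_end"]])
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{ln}: malformed inversion row: {exc}") from exc
            if coordinate_map is not None:
                start, stop = coordinate_map.lift_interval(chrom, start, stop)
            out.append(InversionCandidate(chrom, start, stop, source_genome))
    return out
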