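"""Iterative linear-pangenome construction.

Novel sequences detected in each additional genome are spliced into the
growing reference, right to left so earlier coordinates stay valid during
splicing.  Every incorporated segment gets a positional annotation
(``PAV_<sourceGenome>_<ordinal>``) and the per-iteration coordinate maps
compose into a single base-reference -> pangenome liftover.

Only insertions strictly longer than ``min_insert`` (default 50 bp) are
incorporated; deletions are never spliced — missing sequence surfaces later
as absence genotypes during coverage-based PAV calling.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from .align import InsertionCall, detect_insertions
from .genome import GenomeSequence, read_fasta, write_fasta
from .liftover import CoordinateMap

_PAV_NAME = re.compile(r"^PAV_(?P<source>.+)_(?P<ordinal>\d+)$")


@dataclass(frozen=True)
class PavSegmentAnnotation:
    """Positional record of one incorporated novel sequence.

    ``start``/``end`` are 0-based half-open pangenome coordinates (final
    coordinate system after all iterations).
    """

    name: str
    pangenome_chrom: str
    start: int
    end: int
    source_genome: str
    iteration_index: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @staticmethod
    def parse_name(name: str) -> tuple[str, int]:
        m = _PAV_NAME.match(name)
        if m is None:
            raise ValueError(f"not a PAV segment name: {name!r}")
        return m["source"], int(m["ordinal"])


@dataclass
class Pangenome:
    sequence: GenomeSequence
    base_to_final: CoordinateMap
    per_iteration_maps: list[CoordinateMap]
    annotations: list[PavSegmentAnnotation]
    genome_order: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def annotation_sequence(self, ann: PavSegmentAnnotation) -> str:
        return self.sequence.extract(ann.pangenome_chrom, ann.start, ann.end)

    def annotations_by_name(self) -> dict[str, PavSegmentAnnotation]:
        return {a.name: a for a in self.annotations}


def filter_insertions(calls: list[InsertionCall], min_len: int = 50) -> list[InsertionCall]:
    """Keep calls strictly longer than ``min_len`` bp, preserving order."""
    if min_len < 0:
        raise ValueError(f"min_len must be non-negative, got {min_len}")
    return [c for c in calls if c.length > min_len]


def incorporate_insertions(
    reference: GenomeSequence,
    calls: list[InsertionCall],
    iteration_index: int = 1,
    name_counters: dict[str, int] | None = None,
) -> tuple[GenomeSequence, CoordinateMap, list[PavSegmentAnnotation]]:
    """Splice insertion calls into ``reference``.

    Each call's sequence lands immediately before its ``ref_pos``.  Two
    distinct calls at the same point are ambiguous and rejected; identical
    duplicates are silently collapsed.  ``name_counters`` carries per-source
    running ordinals across iterations.
    """
    counters = name_counters if name_counters is not None else {}
    by_chrom: dict[str, list[InsertionCall]] = {}
    for c in calls:
        if c.ref_chrom not in reference.chromosomes:
            raise ValueError(f"insertion on unknown chromosome {c.ref_chrom!r}")
        clen = len(reference.chromosomes[c.ref_chrom])
        if not (0 <= c.ref_pos <= clen):
            raise ValueError(
                f"insertion point {c.ref_pos} outside {c.ref_chrom} (length {clen})"
            )
        by_chrom.setdefault(c.ref_chrom, []).append(c)

    new_chroms: dict[str, str] = {}
    map_insertions: dict[str, list[tuple[int, int, str]]] = {}
    annotations: list[PavSegmentAnnotation] = []

    for chrom, seq in reference.chromosomes.items():
        chrom_calls = sorted(by_chrom.get(chrom, []), key=lambda c: c.ref_pos)
        deduped: list[InsertionCall] = []
        for c in chrom_calls:
            if deduped and deduped[-1].ref_pos == c.ref_pos:
                if deduped[-1].sequence == c.sequence:
                    continue  # exact duplicate: collapse
                raise ValueError(
                    f"two distinct insertions at {chrom}:{c.ref_pos} "
                    f"(lengths {deduped[-1].length} and {c.length}): ambiguous splice order"
                )
            deduped.append(c)

        named: list[tuple[InsertionCall, str]] = []
        for c in deduped:
            counters[c.source_genome] = counters.get(c.source_genome, 0) + 1
            named.append((c, f"PAV_{c.source_genome}_{counters[c.source_genome]}"))

        pieces: list[str] = []
        prev = 0
        offset = 0
        for c, name in named:
            pieces.append(seq[prev : c.ref_pos])
            pieces.append(c.sequence)
            annotations.append(
                PavSegmentAnnotation(
                    name=name,
                    pangenome_chrom=chrom,
                    start=c.ref_pos + offset,
                    end=c.ref_pos + offset + c.length,
                    source_genome=c.source_genome,
                    iteration_index=iteration_index,
                )
            )
            offset += c.length
            prev = c.ref_pos
        pieces.append(seq[prev:])
        new_chroms[chrom] = "".join(pieces)
        map_insertions[chrom] = [(c.ref_pos, c.length, name) for c, name in named]

    new_genome = GenomeSequence(name=reference.name, chromosomes=new_chroms)
    cmap = CoordinateMap.from_insertions(reference.chrom_lengths(), map_insertions)
    return new_genome, cmap, annotations


def build_pangenome(
    primary_reference: GenomeSequence,
    others: list[GenomeSequence],
    min_insert: int = 50,
    min_anchor_len: int = 21,
    max_gap: int = 500,
) -> Pangenome:
    """Iteratively compare each genome to the growing reference and splice in
    its novel sequences.  Genome order is taken as given; a later genome
    sharing an insertion with an earlier one contributes nothing new because
    it is compared against the already-updated reference."""
    current = GenomeSequence(primary_reference.name, dict(primary_reference.chromosomes))
    composed = CoordinateMap.identity(primary_reference.chrom_lengths())
    per_iter: list[CoordinateMap] = []
    annotations: list[PavSegmentAnnotation] = []
    counters: dict[str, int] = {}
    iteration_counts: list[int] = []

    for it, genome in enumerate(others, start=1):
        try:
            calls = detect_insertions(
                current, genome, min_anchor_len=min_anchor_len, max_gap=max_gap
            )
            calls = filter_insertions(calls, min_insert)
            current, cmap, new_anns = incorporate_insertions(
                current, calls, iteration_index=it, name_counters=counters
            )
        except ValueError as exc:
            raise ValueError(f"iteration {it} ({genome.name}): {exc}") from exc
        # earlier annotations live in the previous coordinate system; shift
        # them through this iteration's map
        annotations = [
            replace(a, start=s, end=e)
            for a in annotations
            for s, e in [cmap.lift_interval(a.pangenome_chrom, a.start, a.end)]
        ]
        annotations.extend(new_anns)
        per_iter.append(cmap)
        composed = composed.compose(cmap)
        iteration_counts.append(len(new_anns))

    return Pangenome(
        sequence=current,
        base_to_final=composed,
        per_iteration_maps=per_iter,
        annotations=sorted(annotations, key=lambda a: (a.pangenome_chrom, a.start)),
        genome_order=[primary_reference.name] + [g.name for g in others],
        params={
            "min_insert": min_insert,
            "min_anchor_len": min_anchor_len,
            "max_gap": max_gap,
            "insertions_per_iteration": iteration_counts,
        },
    )


# ---------------------------------------------------------------------------
# Serialization: FASTA + GFF3 + JSON manifest
# ---------------------------------------------------------------------------

def write_pangenome(pan: Pangenome, prefix: str | Path) -> dict[str, Path]:
    """Emit ``<prefix>.fa``, ``<prefix>.pav.gff3`` and ``<prefix>.manifest.json``.

    GFF coordinates are 1-based inclusive (start = 0-based start + 1)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta = prefix.with_suffix(".fa")
    gff = Path(str(prefix) + ".pav.gff3")
    manifest = Path(str(prefix) + ".manifest.json")

    write_fasta(pan.sequence, fasta)
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in pan.sequence.chromosomes.items():
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for a in pan.annotations:
            attrs = (
                f"ID={a.name};source_genome={a.source_genome};iteration={a.iteration_index}"
            )
            fh.write(
                "\t".join(
                    [
                        a.pangenome_chrom,
                        "linpan",
                        "PAV_segment",
                        str(a.start + 1),
                        str(a.end),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
    with open(manifest, "w") as fh:
        json.dump(
            {
                "genome_order": pan.genome_order,
                "params": pan.params,
                "base_to_final": pan.base_to_final.to_dict(),
                "per_iteration_maps": [m.to_dict() for m in pan.per_iteration_maps],
            },
            fh,
            indent=2,
        )
    return {"fasta": fasta, "gff": gff, "manifest": manifest}


def read_pav_gff(path: str | Path) -> list[PavSegmentAnnotation]:
    """Read PAV segment annotations (converting back to 0-based half-open)."""
    anns: list[PavSegmentAnnotation] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "PAV_segment":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            name = attrs["ID"]
            source = attrs.get("source_genome") or PavSegmentAnnotation.parse_name(name)[0]
            anns.append(
                PavSegmentAnnotation(
                    name=name,
                    pangenome_chrom=f[0],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    source_genome=source,
                    iteration_index=int(attrs.get("iteration", 0)),
                )
            )
    return anns


def read_pangenome(prefix: str | Path) -> Pangenome:
    """Rebuild a :class:`Pangenome` from the files ``write_pangenome`` wrote."""
    prefix = Path(prefix)
    fasta = prefix.with_suffix(".fa")
    gff = Path(str(prefix) + ".pav.gff3")
    manifest = Path(str(prefix) + ".manifest.json")
    seq = read_fasta(fasta)
    anns = read_pav_gff(gff)
    with open(manifest) as fh:
        man = json.load(fh)
    seq.name = man["genome_order"][0] if man["genome_order"] else seq.name
    return Pangenome(
        sequence=seq,
        base_to_final=CoordinateMap.from_dict(man["base_to_final"]),
        per_iteration_maps=[CoordinateMap.from_dict(d) for d in man["per_iteration_maps"]],
        annotations=anns,
        genome_order=man["genome_order"],
        params=man["params"],
    )
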