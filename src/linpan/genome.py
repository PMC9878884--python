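"""Genome sequences and FASTA input/output.

A :class:`GenomeSequence` is an ordered collection of named chromosomes over
the alphabet ``{A, C, G, T, N}``.  All coordinates in this package are
0-based, half-open; GFF output converts to 1-based inclusive at the writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")


@dataclass
class GenomeSequence:
    """A named genome: ordered mapping of chromosome name -> sequence string."""

    name: str
    chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {chrom!r} of genome {self.name!r} is empty")
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"chromosome {chrom!r} of genome {self.name!r} contains "
                    f"invalid characters {sorted(bad)}"
                )

    def __len__(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}

    def extract(self, chrom: str, start: int, end: int) -> str:
        """Subsequence at 0-based half-open [start, end)."""
        seq = self.chromosomes[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"interval [{start}, {end}) outside {chrom} (len {len(seq)})")
        return seq[start:end]


def read_fasta(path: str | Path, name: str | None = None) -> GenomeSequence:
    """Load a genome from FASTA; chromosome order follows file order."""
    path = Path(path)
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate chromosome {rec.id!r} in {path}")
        chroms[rec.id] = str(rec.seq).upper()
    if not chroms:
        raise ValueError(f"no sequences found in {path}")
    return GenomeSequence(name=name or path.stem, chromosomes=chroms)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.chromosomes.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
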