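"""Desk-scale collinearity comparison between two genomes.

Detects sequences present in a query genome but absent from the reference:
maximal unique k-mer anchors (k = ``min_anchor_len``, default 21) shared by
both sequences are chained per chromosome pair by a
heaviest-increasing-subsequence dynamic program; wherever the query gap
between adjacent chain anchors exceeds the reference gap, the surplus query
bases are reported as an insertion at the reference breakpoint.

Reverse-strand matches never form anchors here (forward k-mers only), so
inverted regions simply produce balanced gaps and no insertion call;
inversions are handled by the SV genotyping module.  An import path for
Assemblytics-style tabular variant calls is provided as an alternative to
the internal aligner.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path

from .genome import GenomeSequence


@dataclass(frozen=True)
class AlignmentAnchor:
    """Exact match between reference and query (forward strand)."""

    ref_chrom: str
    ref_start: int
    query_chrom: str
    query_start: int
    length: int
    strand: str = "+"

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def query_end(self) -> int:
        return self.query_start + self.length


@dataclass(frozen=True)
class InsertionCall:
    """Query sequence absent from the reference.

    The insertion occurs between reference positions ``ref_pos - 1`` and
    ``ref_pos`` (0-based); ``ref_pos == chromosome length`` appends at the end.
    """

    ref_chrom: str
    ref_pos: int
    sequence: str
    source_genome: str

    @property
    def length(self) -> int:
        return len(self.sequence)


class SparseAnchorsError(ValueError):
    pass


def _unique_kmer_index(seq: str, k: int) -> dict[str, int]:
    """Positions of k-mers occurring exactly once in ``seq``."""
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in seen:
            dup.add(kmer)
        else:
            seen[kmer] = i
    for kmer in dup:
        del seen[kmer]
    return seen


def find_anchors(ref_seq: str, query_seq: str, ref_chrom: str, query_chrom: str,
                 k: int = 21) -> list[AlignmentAnchor]:
    """Maximal runs of doubly-unique shared k-mers on a common diagonal."""
    ref_idx = _unique_kmer_index(ref_seq, k)
    query_idx = _unique_kmer_index(query_seq, k)
    matches = sorted(
        (rpos, query_idx[kmer]) for kmer, rpos in ref_idx.items() if kmer in query_idx
    )
    anchors: list[AlignmentAnchor] = []
    i = 0
    n = len(matches)
    while i < n:
        r0, q0 = matches[i]
        j = i
        while j + 1 < n and matches[j + 1] == (matches[j][0] + 1, matches[j][1] + 1):
            j += 1
        run = j - i + 1
        anchors.append(AlignmentAnchor(ref_chrom, r0, query_chrom, q0, run + k - 1))
        i = j + 1
    return anchors


def chain_anchors(anchors: list[AlignmentAnchor]) -> list[AlignmentAnchor]:
    """Heaviest chain with strictly increasing ref and query coordinates."""
    anchors = sorted(anchors, key=lambda a: (a.ref_start, a.query_start))
    n = len(anchors)
    if n == 0:
        return []
    best = [a.length for a in anchors]
    prev = [-1] * n
    for i in range(n):
        ai = anchors[i]
        for j in range(i):
            aj = anchors[j]
            if aj.ref_start < ai.ref_start and aj.query_start < ai.query_start:
                w = best[j] + ai.length
                if w > best[i]:
                    best[i] = w
                    prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    chain: list[AlignmentAnchor] = []
    while end != -1:
        chain.append(anchors[end])
        end = prev[end]
    return chain[::-1]


def detect_insertions(
    reference: GenomeSequence,
    query: GenomeSequence,
    min_anchor_len: int = 21,
    max_gap: int = 500,
    chrom_pairs: dict[str, str] | None = None,
) -> list[InsertionCall]:
    """Query segments absent from the reference at their collinear breakpoints.

    Parameters
    ----------
    min_anchor_len
        Anchor k-mer length; smaller values rescue sparse anchor sets at the
        cost of specificity.
    max_gap
        Maximum reference-side gap (bp) between adjacent chain anchors across
        which an insertion is still called; larger reference gaps are treated
        as diverged/unalignable regions.
    chrom_pairs
        Optional explicit query->reference chromosome pairing; defaults to
        pairing by identical name.
    """
    if chrom_pairs is None:
        chrom_pairs = {}
        for qc in query.chromosomes:
            if qc not in reference.chromosomes:
                raise ValueError(
                    f"query chromosome {qc!r} has no counterpart in reference "
                    f"{reference.name!r}; supply an explicit chromosome pairing"
                )
            chrom_pairs[qc] = qc

    calls: list[InsertionCall] = []
    for qc, rc in chrom_pairs.items():
        rseq = reference.chromosomes[rc]
        qseq = query.chromosomes[qc]
        anchors = find_anchors(rseq, qseq, rc, qc, k=min_anchor_len)
        chain = chain_anchors(anchors)
        if not chain:
            raise SparseAnchorsError(
                f"no collinear anchors between {rc!r} and {qc!r} at "
                f"k={min_anchor_len}; try a smaller min_anchor_len"
            )
        # sentinels pin the chromosome ends together
        bounded = (
            [AlignmentAnchor(rc, 0, qc, 0, 0)]
            + chain
            + [AlignmentAnchor(rc, len(rseq), qc, len(qseq), 0)]
        )
        for a, b in zip(bounded, bounded[1:]):
            ref_gap = b.ref_start - a.ref_end
            query_gap = b.query_start - a.query_end
            ins_len = query_gap - ref_gap
            if ins_len > 0 and ref_gap <= max_gap:
                seq = qseq[b.query_start - ins_len : b.query_start]
                calls.append(InsertionCall(rc, b.ref_start, seq, query.name))
    calls.sort(key=lambda c: (c.ref_chrom, c.ref_pos))
    return calls


# ---------------------------------------------------------------------------
# Assemblytics-style tabular import
# ---------------------------------------------------------------------------

_QCOORD = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)(?::(?P<strand>[+-]))?$")


def read_assemblytics_insertions(
    path: str | Path,
    query_genome: GenomeSequence | None = None,
    source_genome: str | None = None,
) -> list[InsertionCall]:
    """Insertion calls from an Assemblytics-style variant table.

    Expects a tab-separated header including ``reference``/``ref_chrom``,
    ``ref_start``, ``type``, ``size`` and a ``query_coordinates`` column of the
    form ``chrom:start-end[:strand]``; only rows whose type contains
    "Insertion" are consumed.  The inserted sequence is extracted from
    ``query_genome`` when given, otherwise a placeholder of ``N`` of the
    recorded size is used (sufficient for coordinate work, not for splicing
    real sequence).
    """
    path = Path(path)
    calls: list[InsertionCall] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        cols = {c.lstrip("#").strip().lower(): c for c in reader.fieldnames}

        def col(row, *names):
            for n in names:
                if n in cols:
                    return row[cols[n]]
            raise ValueError(f"missing column (any of {names}) in {path}")

        for ln, row in enumerate(reader, start=2):
            try:
                vtype = col(row, "type")
                if "insertion" not in vtype.lower():
                    continue
                ref_chrom = col(row, "reference", "ref_chrom", "ref")
                ref_start = int(col(row, "ref_start", "reference_start"))
                size = int(col(row, "size", "sv_size"))
                qfield = col(row, "query_coordinates", "query_coords", "query")
                m = _QCOORD.match(qfield.strip())
                if m is None:
                    raise ValueError(f"unparseable query coordinates {qfield!r}")
                if query_genome is not None:
                    qs, qe = int(m["start"]), int(m["end"])
                    seq = query_genome.extract(m["chrom"], qs, qe)
                    if len(seq) != size:
                        seq = seq[:size] if len(seq) > size else seq
                else:
                    seq = "N" * size
                calls.append(
                    InsertionCall(
                        ref_chrom,
                        ref_start,
                        seq,
                        source_genome
                        or (query_genome.name if query_genome else path.stem),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{ln}: malformed row: {exc}") from exc
    calls.sort(key=lambda c: (c.ref_chrom, c.ref_pos))
    return calls
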