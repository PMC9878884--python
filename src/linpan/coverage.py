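"""Per-accession read-depth over the pangenome -> merged presence/absence
segments with recorded breakpoints.

Depth is evaluated in fixed windows (default 20 bp); a window is *present*
when its depth statistic (mean per-base depth by default) is at least 5
reads, otherwise *absent*.  Adjacent windows of equal state merge into
maximal segments; state transitions plus chromosome ends are the breakpoints
consumed by population-level genotyping.

Read filters mirror the standard short-read contract: records count towards
depth only when mapped, not secondary, and with mapping quality strictly
greater than 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

PRESENT = "present"
ABSENT = "absent"


@dataclass
class AlignmentRecord:
    """Minimal alignment-record contract (CIGAR-equivalent match spans).

    ``blocks`` are the contiguously matched reference spans, 0-based
    half-open, as produced by splitting a CIGAR at indels/clips."""

    chrom: str
    mapq: int
    blocks: list[tuple[int, int]]
    is_unmapped: bool = False
    is_secondary: bool = False

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


def passes_filters(rec: AlignmentRecord, min_mapq: int = 20) -> bool:
    """Mapped, primary, and mapping quality strictly over ``min_mapq``."""
    return not rec.is_unmapped and not rec.is_secondary and rec.mapq > min_mapq


@dataclass
class DepthTrack:
    """Per-base depth arrays, one per chromosome, for one accession."""

    accession: str
    depth: dict[str, np.ndarray] = field(default_factory=dict)

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(d) for c, d in self.depth.items()}


@dataclass(frozen=True)
class PresenceWindow:
    chrom: str
    start: int
    end: int
    state: str
    depth: float


@dataclass
class PavCallSet:
    """Merged presence/absence segments for one accession.

    Segments partition each chromosome; breakpoints are the segment
    boundaries including chromosome start and end."""

    accession: str
    segments: list[tuple[str, int, int, str]]
    chrom_lengths: dict[str, int]

    def breakpoints(self) -> dict[str, list[int]]:
        bps: dict[str, set[int]] = {c: {0, n} for c, n in self.chrom_lengths.items()}
        for chrom, start, end, _state in self.segments:
            bps[chrom].add(start)
            bps[chrom].add(end)
        return {c: sorted(v) for c, v in bps.items()}

    def state_at(self, chrom: str, pos: int) -> str:
        for c, s, e, state in self.segments:
            if c == chrom and s <= pos < e:
                return state
        raise KeyError(f"position {chrom}:{pos} not covered by any segment")


def depth_from_alignments(
    records: list[AlignmentRecord],
    chrom_lengths: dict[str, int],
    accession: str = "sample",
    min_mapq: int = 20,
) -> DepthTrack:
    depth = {c: np.zeros(n, dtype=np.int32) for c, n in chrom_lengths.items()}
    for rec in records:
        if rec.chrom not in depth:
            raise ValueError(f"alignment on unknown chromosome {rec.chrom!r}")
        if not passes_filters(rec, min_mapq):
            continue
        arr = depth[rec.chrom]
        for s, e in rec.blocks:
            arr[s:e] += 1
    return DepthTrack(accession=accession, depth=depth)


def records_from_sam(path: str | Path) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Thin adapter from SAM/BAM to the alignment-record contract."""
    import pysam

    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        lengths = dict(zip(af.references, af.lengths))
        for r in af:
            if r.is_unmapped:
                continue
            records.append(
                AlignmentRecord(
                    chrom=r.reference_name,
                    mapq=r.mapping_quality,
                    blocks=[(s, e) for s, e in r.get_blocks()],
                    is_unmapped=r.is_unmapped,
                    is_secondary=r.is_secondary,
                )
            )
    return records, lengths


def read_depth_bed(path: str | Path, accession: str | None = None,
                   chrom_lengths: dict[str, int] | None = None) -> DepthTrack:
    """BED-like depth (chrom, start, end, depth) -> per-base track.

    Accepts per-base rows or constant-depth intervals (e.g. windowed output
    of a depth tool).  Rows must jointly cover each chromosome; the covered
    extent defines the chromosome length unless ``chrom_lengths`` is given.
    """
    path = Path(path)
    rows: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns (chrom,start,end,depth)")
            rows.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
    depth: dict[str, np.ndarray] = {}
    for chrom, ivs in rows.items():
        ivs.sort()
        n = (chrom_lengths or {}).get(chrom, ivs[-1][1])
        arr = np.zeros(n, dtype=np.float64)
        pos = 0
        for s, e, d in ivs:
            if s != pos:
                raise ValueError(
                    f"depth track for {chrom} has a gap/overlap at {pos} (next row starts {s})"
                )
            arr[s:e] = d
            pos = e
        if pos != n:
            raise ValueError(f"depth track for {chrom} covers {pos} of {n} bases")
        depth[chrom] = arr
    return DepthTrack(accession=accession or path.stem, depth=depth)


def write_depth_bed(track: DepthTrack, path: str | Path) -> None:
    """Run-length encoded BED (chrom, start, end, depth)."""
    with open(path, "w") as fh:
        for chrom, arr in track.depth.items():
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


def window_depth(
    track: DepthTrack,
    window: int = 20,
    min_depth: float = 5,
    stat: str = "mean",
) -> list[PresenceWindow]:
    """Tile each chromosome with fixed windows and label presence/absence.

    The terminal partial window is evaluated like any other so that windows
    always partition the chromosome."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if stat not in ("mean", "median", "min"):
        raise ValueError(f"unknown window statistic {stat!r}")
    fn = {"mean": np.mean, "median": np.median, "min": np.min}[stat]
    out: list[PresenceWindow] = []
    for chrom, arr in track.depth.items():
        n = len(arr)
        for s in range(0, n, window):
            e = min(s + window, n)
            d = float(fn(arr[s:e]))
            state = PRESENT if d >= min_depth else ABSENT
            out.append(PresenceWindow(chrom, s, e, state, d))
    return out


def merge_windows(windows: list[PresenceWindow], accession: str = "sample") -> PavCallSet:
    """Run-length merge of same-state adjacent windows into segments."""
    by_chrom: dict[str, list[PresenceWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    segments: list[tuple[str, int, int, str]] = []
    lengths: dict[str, int] = {}
    for chrom, ws in by_chrom.items():
        ws.sort(key=lambda w: w.start)
        pos = 0
        for w in ws:
            if w.start != pos:
                raise ValueError(
                    f"windows on {chrom} are gapped or overlapping at {pos} "
                    f"(next window starts {w.start})"
                )
            pos = w.end
        lengths[chrom] = pos
        cur_start, cur_state = ws[0].start, ws[0].state
        for prev, w in zip(ws, ws[1:]):
            if w.state != cur_state:
                segments.append((chrom, cur_start, prev.end, cur_state))
                cur_start, cur_state = w.start, w.state
        segments.append((chrom, cur_start, ws[-1].end, cur_state))
    return PavCallSet(accession=accession, segments=segments, chrom_lengths=lengths)


def call_accession(
    track: DepthTrack,
    window: int = 20,
    min_depth: float = 5,
    stat: str = "mean",
) -> PavCallSet:
    """Convenience: window + merge in one step."""
    return merge_windows(window_depth(track, window, min_depth, stat), track.accession)


def write_segment_bed(callset: PavCallSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, state in callset.segments:
            fh.write(f"{chrom}\t{s}\t{e}\t{state}\n")


def read_segment_bed(path: str | Path, accession: str | None = None) -> PavCallSet:
    path = Path(path)
    segments: list[tuple[str, int, int, str]] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e, state = line.split("\t")[:4]
            state = state.strip()
            if state not in (PRESENT, ABSENT):
                raise ValueError(f"bad segment state {state!r} in {path}")
            segments.append((chrom, int(s), int(e), state))
            lengths[chrom] = max(lengths.get(chrom, 0), int(e))
    return PavCallSet(accession=accession or path.stem, segments=segments,
                      chrom_lengths=lengths)
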