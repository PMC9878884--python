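"""Piecewise-monotone coordinate maps between a source genome and a
pangenome that extends it by spliced-in insertions.

A :class:`CoordinateMap` stores, per chromosome, an ordered list of
collinear blocks ``(src_start, src_end, dst_start)`` covering the whole
source axis, plus the inserted destination intervals that have no source
preimage.  ``lift`` goes source -> destination, ``project`` goes back and
returns the sentinel :data:`INSERTED` (with the owning segment name) for
positions inside an inserted interval.  Maps from successive construction
iterations compose into a single base->final map.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

INSERTED = "inserted"


@dataclass(frozen=True)
class Block:
    src_start: int
    src_end: int
    dst_start: int

    @property
    def length(self) -> int:
        return self.src_end - self.src_start

    @property
    def dst_end(self) -> int:
        return self.dst_start + self.length


@dataclass(frozen=True)
class InsertedInterval:
    """Destination interval with no source preimage."""

    dst_start: int
    dst_end: int
    name: str


@dataclass
class ChromMap:
    src_len: int
    blocks: list[Block]
    inserted: list[InsertedInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks, key=lambda b: b.src_start)
        self.inserted = sorted(self.inserted, key=lambda i: i.dst_start)
        self._block_src_starts = [b.src_start for b in self.blocks]
        self.validate()

    @property
    def dst_len(self) -> int:
        return self.src_len + sum(i.dst_end - i.dst_start for i in self.inserted)

    def validate(self) -> None:
        pos = 0
        for b in self.blocks:
            if b.src_start != pos:
                raise ValueError(f"blocks do not tile source axis at {pos}")
            if b.src_end < b.src_start:
                raise ValueError("negative block length")
            pos = b.src_end
        if pos != self.src_len:
            raise ValueError(f"blocks cover {pos} of {self.src_len} source bases")
        # destination axis must be tiled by block images and inserted intervals
        pieces = [(b.dst_start, b.dst_end) for b in self.blocks if b.length > 0]
        pieces += [(i.dst_start, i.dst_end) for i in self.inserted]
        pieces.sort()
        pos = 0
        for s, e in pieces:
            if s != pos or e < s:
                raise ValueError(f"destination axis not tiled at {pos} (piece [{s},{e}))")
            pos = e
        if pos != self.dst_len:
            raise ValueError("destination tiling does not reach dst_len")

    def lift(self, pos: int) -> int:
        if not (0 <= pos < self.src_len):
            raise ValueError(f"source position {pos} outside [0, {self.src_len})")
        i = bisect_right(self._block_src_starts, pos) - 1
        b = self.blocks[i]
        # zero-length blocks can share a src_start with the following block
        while b.src_end <= pos:
            i += 1
            b = self.blocks[i]
        return b.dst_start + (pos - b.src_start)

    def project(self, pos: int) -> int | tuple[str, str]:
        if not (0 <= pos < self.dst_len):
            raise ValueError(f"destination position {pos} outside [0, {self.dst_len})")
        for iv in self.inserted:
            if iv.dst_start <= pos < iv.dst_end:
                return (INSERTED, iv.name)
        for b in self.blocks:
            if b.dst_start <= pos < b.dst_end:
                return b.src_start + (pos - b.dst_start)
        raise AssertionError("destination position not covered by any piece")


class CoordinateMap:
    """Mapping src genome -> dst genome for a set of chromosomes."""

    def __init__(self, chrom_maps: dict[str, ChromMap]):
        self.chrom_maps = chrom_maps

    @classmethod
    def identity(cls, chrom_lengths: dict[str, int]) -> "CoordinateMap":
        return cls(
            {c: ChromMap(n, [Block(0, n, 0)]) for c, n in chrom_lengths.items()}
        )

    @classmethod
    def from_insertions(
        cls,
        chrom_lengths: dict[str, int],
        insertions: dict[str, list[tuple[int, int, str]]],
    ) -> "CoordinateMap":
        """Build the map induced by splicing insertions into a source genome.

        ``insertions[chrom]`` is a list of ``(src_pos, length, name)``; the
        inserted sequence lands immediately before ``src_pos``.
        """
        maps: dict[str, ChromMap] = {}
        for chrom, src_len in chrom_lengths.items():
            calls = sorted(insertions.get(chrom, []))
            blocks: list[Block] = []
            inserted: list[InsertedInterval] = []
            prev = 0
            offset = 0
            for pos, length, name in calls:
                if not (0 <= pos <= src_len):
                    raise ValueError(f"insertion point {pos} outside {chrom}")
                blocks.append(Block(prev, pos, prev + offset))
                inserted.append(InsertedInterval(pos + offset, pos + offset + length, name))
                offset += length
                prev = pos
            blocks.append(Block(prev, src_len, prev + offset))
            blocks = [b for b in blocks if b.length > 0] or [Block(0, src_len, offset)]
            maps[chrom] = ChromMap(src_len, blocks, inserted)
        return cls(maps)

    def lift(self, chrom: str, pos: int) -> int:
        return self._cm(chrom).lift(pos)

    def project(self, chrom: str, pos: int) -> int | tuple[str, str]:
        return self._cm(chrom).project(pos)

    def lift_interval(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Image of a half-open source interval; grows if later insertions landed inside."""
        if end <= start:
            raise ValueError("empty interval")
        return self.lift(chrom, start), self.lift(chrom, end - 1) + 1

    def _cm(self, chrom: str) -> ChromMap:
        if chrom not in self.chrom_maps:
            raise KeyError(f"no coordinate map for chromosome {chrom!r}")
        return self.chrom_maps[chrom]

    def src_lengths(self) -> dict[str, int]:
        return {c: m.src_len for c, m in self.chrom_maps.items()}

    def dst_lengths(self) -> dict[str, int]:
        return {c: m.dst_len for c, m in self.chrom_maps.items()}

    def compose(self, other: "CoordinateMap") -> "CoordinateMap":
        """Return the map (self then other): src(self) -> dst(other).

        ``self`` maps A->B, ``other`` maps B->C.  Blocks of the composite are
        the A-blocks refined wherever ``other`` splits their B-image; inserted
        intervals are ``other``'s own insertions plus the C-images of
        ``self``'s insertions (split if ``other`` inserted inside them).
        """
        out: dict[str, ChromMap] = {}
        for chrom, m1 in self.chrom_maps.items():
            m2 = other.chrom_maps[chrom]
            if m2.src_len != m1.dst_len:
                raise ValueError(
                    f"cannot compose maps for {chrom}: intermediate lengths "
                    f"{m1.dst_len} != {m2.src_len}"
                )
            blocks: list[Block] = []
            for b in m1.blocks:
                if b.length == 0:
                    continue
                for s, e, c0 in _map_through(m2, b.dst_start, b.dst_end):
                    blocks.append(Block(b.src_start + (s - b.dst_start),
                                        b.src_start + (e - b.dst_start), c0))
            inserted: list[InsertedInterval] = list(m2.inserted)
            for iv in m1.inserted:
                for s, e, c0 in _map_through(m2, iv.dst_start, iv.dst_end):
                    inserted.append(InsertedInterval(c0, c0 + (e - s), iv.name))
            out[chrom] = ChromMap(m1.src_len, blocks, inserted)
        return CoordinateMap(out)

    # -- JSON round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            chrom: {
                "src_len": m.src_len,
                "blocks": [[b.src_start, b.src_end, b.dst_start] for b in m.blocks],
                "inserted": [[i.dst_start, i.dst_end, i.name] for i in m.inserted],
            }
            for chrom, m in self.chrom_maps.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoordinateMap":
        return cls(
            {
                chrom: ChromMap(
                    v["src_len"],
                    [Block(*b) for b in v["blocks"]],
                    [InsertedInterval(s, e, n) for s, e, n in v["inserted"]],
                )
                for chrom, v in d.items()
            }
        )


def _map_through(m: ChromMap, start: int, end: int):
    """Yield (b_start, b_end, c_start) pieces: the image under ``m`` of the
    half-open B-interval [start, end), split at m's block boundaries."""
    for b in m.blocks:
        s = max(start, b.src_start)
        e = min(end, b.src_end)
        if s < e:
            yield s, e, b.dst_start + (s - b.src_start)
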