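"""Synthetic truth sets for every pipeline stage.

Generates a random founder genome, derived genomes that differ from it only
by planted events (insertions, duplicated "TE cassette" insertions that
mimic translocations, inversions), per-accession carrier states, error-free
uniform-coverage depth tracks, and junction-spanning read stubs — together
with a :class:`TruthManifest` recording where everything is and what every
downstream matrix should contain.

Planted insertion anchors are pairwise well-separated on the founder, so the
expected pangenome coordinate of each insertion is its anchor plus the total
length of insertions anchored to its left — independent of the genome order
used for construction.  With ``window_align`` set (default 20), anchors and
lengths snap to the window grid so coverage-derived segment boundaries
coincide exactly with the planted intervals.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import ABSENT, PRESENT, AlignmentRecord, DepthTrack
from .genome import GenomeSequence, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_length: int = 200_000
    chrom_name: str = "chr1"
    n_genomes: int = 3
    insertions_per_genome: int = 10
    insertion_len_range: tuple[int, int] = (51, 5_000)  # log-uniform draw
    n_cassette_pairs: int = 0          # duplicated >1 kb insertions (translocation bait)
    cassette_length: int = 1_200
    n_inversions: int = 0
    inversion_len_range: tuple[int, int] = (1_500, 4_000)
    n_accessions: int = 10
    coverage_depth: float = 10.0
    read_length: int = 100
    carrier_prob: float = 0.5
    window_align: int | None = 20      # snap anchors/lengths to this grid (None = off)
    min_event_separation: int = 400
    depth_jitter: float = 0.0          # sd of per-base noise, 0 = error-free

    def __post_init__(self) -> None:
        if self.insertion_len_range[0] < 1:
            raise ValueError("insertion lengths must be positive")
        for name in ("n_genomes", "insertions_per_genome", "n_accessions",
                     "n_cassette_pairs", "n_inversions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PlantedInsertion:
    event_id: str
    chrom: str
    base_pos: int            # founder anchor: insertion lands before this position
    sequence: str
    carrier_genomes: list[str]
    pan_start: int = -1      # expected pangenome interval (filled by the manifest)
    pan_end: int = -1

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PlantedInversion:
    event_id: str
    chrom: str
    base_start: int
    base_end: int
    carrier_genomes: list[str]
    pan_start: int = -1
    pan_end: int = -1


@dataclass
class TruthManifest:
    config: SimulationConfig
    chrom_name: str
    founder_length: int
    insertions: list[PlantedInsertion]
    inversions: list[PlantedInversion]
    accession_carriers: dict[str, list[str]] = field(default_factory=dict)
    # accession -> list of carried insertion event_ids

    def __post_init__(self) -> None:
        self._fill_pangenome_coords()

    @property
    def pangenome_length(self) -> int:
        return self.founder_length + sum(i.length for i in self.insertions)

    def _fill_pangenome_coords(self) -> None:
        offset = 0
        for ins in sorted(self.insertions, key=lambda i: i.base_pos):
            ins.pan_start = ins.base_pos + offset
            ins.pan_end = ins.pan_start + ins.length
            offset += ins.length
        ins_sorted = sorted(self.insertions, key=lambda i: i.base_pos)
        anchors = [i.base_pos for i in ins_sorted]
        shifts = np.cumsum([0] + [i.length for i in ins_sorted])
        for inv in self.inversions:
            # inversions never overlap insertion anchors by construction
            k = int(np.searchsorted(anchors, inv.base_start, side="right"))
            inv.pan_start = inv.base_start + int(shifts[k])
            k = int(np.searchsorted(anchors, inv.base_end, side="right"))
            inv.pan_end = inv.base_end + int(shifts[k])

    # -- expected downstream results ------------------------------------
    def absent_intervals(self, accession: str) -> list[tuple[int, int]]:
        carried = set(self.accession_carriers[accession])
        return sorted(
            (i.pan_start, i.pan_end)
            for i in self.insertions
            if i.event_id not in carried
        )

    def expected_pav_matrix(self) -> pd.DataFrame:
        """Accession x union-region truth matrix (1 present / 0 absent),
        regions named ``<chrom>_<left breakpoint>`` as the pipeline names
        them."""
        L = self.pangenome_length
        bps: set[int] = {0, L}
        for acc in self.accession_carriers:
            for s, e in self.absent_intervals(acc):
                bps.update((s, e))
        pos = sorted(bps)
        regions = list(zip(pos, pos[1:]))
        names = [f"{self.chrom_name}_{s}" for s, _ in regions]
        rows = {}
        for acc in self.accession_carriers:
            absent = self.absent_intervals(acc)
            row = []
            for s, e in regions:
                inside = any(a <= s and e <= b for a, b in absent)
                row.append(0 if inside else 1)
            rows[acc] = row
        return pd.DataFrame.from_dict(rows, orient="index", columns=names).astype(np.int8)

    def expected_sv_genotypes(self, sv_carriers: dict[str, list[str]]) -> pd.DataFrame:
        """sv_carriers: sv_id -> carrier accessions; returns A/C matrix."""
        accs = list(self.accession_carriers)
        return pd.DataFrame(
            {
                sv: ["C" if a in carriers else "A" for a in accs]
                for sv, carriers in sv_carriers.items()
            },
            index=accs,
        )

    def to_json(self, path: str | Path) -> None:
        d = {
            "config": asdict(self.config),
            "chrom_name": self.chrom_name,
            "founder_length": self.founder_length,
            "insertions": [asdict(i) for i in self.insertions],
            "inversions": [asdict(i) for i in self.inversions],
            "accession_carriers": self.accession_carriers,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _pin_junctions(seq: str, left_base: str, right_base: str) -> str:
    """Make an inserted sequence's breakpoint unambiguous: its last base must
    differ from the base left of the insertion point and its first base from
    the base at the insertion point, so the splice cannot be slid."""
    subst = {"A": "C", "C": "G", "G": "T", "T": "A"}
    first = subst[seq[0]] if seq[0] == right_base else seq[0]
    last = subst[seq[-1]] if seq[-1] == left_base else seq[-1]
    if len(seq) == 1:
        return first if first != left_base else subst[first]
    return first + seq[1:-1] + last


def _draw_positions(
    rng: np.random.Generator,
    n: int,
    length: int,
    min_sep: int,
    align: int | None,
    margin: int = 2_000,
    max_tries: int = 10_000,
) -> list[int]:
    taken: list[int] = []
    tries = 0
    while len(taken) < n:
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} events with separation {min_sep} "
                f"on a {length}-bp chromosome"
            )
        tries += 1
        p = int(rng.integers(margin, length - margin))
        if align:
            p -= p % align
        if all(abs(p - q) >= min_sep for q in taken):
            taken.append(p)
    return sorted(taken)


def _draw_length(rng: np.random.Generator, lo: int, hi: int, align: int | None) -> int:
    n = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    n = min(max(n, lo), hi)
    if align:
        n = -(-n // align) * align  # round up: snapping must not undershoot lo
        if n > hi and n - align >= lo:
            n -= align
    return n


def simulate_pangenome_inputs(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GenomeSequence], TruthManifest]:
    """Founder genome, derived genomes with planted events, truth manifest."""
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom_name
    founder_seq = _random_seq(rng, config.chrom_length)
    founder = GenomeSequence("founder", {chrom: founder_seq})

    genome_names = [f"genome{i + 1}" for i in range(config.n_genomes)]
    n_plain = config.n_genomes * config.insertions_per_genome
    n_cassette = 2 * config.n_cassette_pairs
    n_events = n_plain + n_cassette + config.n_inversions
    # inversions need room: reserve max inversion length around their anchor
    inv_len_max = config.inversion_len_range[1] if config.n_inversions else 0
    sep = config.min_event_separation + inv_len_max
    positions = _draw_positions(
        rng, n_events, config.chrom_length, sep, config.window_align
    )
    rng.shuffle(positions)
    pos_iter = iter(positions)

    insertions: list[PlantedInsertion] = []
    eid = 0
    for gname in genome_names:
        for _ in range(config.insertions_per_genome):
            eid += 1
            L = _draw_length(rng, *config.insertion_len_range, config.window_align)
            pos = next(pos_iter)
            seq = _pin_junctions(
                _random_seq(rng, L), founder_seq[pos - 1], founder_seq[pos]
            )
            insertions.append(
                PlantedInsertion(
                    event_id=f"ins{eid}",
                    chrom=chrom,
                    base_pos=pos,
                    sequence=seq,
                    carrier_genomes=[gname],
                )
            )
    # duplicated cassettes: two copies of (nearly) the same >1 kb sequence,
    # planted in the first genome at two distant anchors
    for k in range(config.n_cassette_pairs):
        L = config.cassette_length
        if config.window_align:
            L = max(config.window_align, L - L % config.window_align)
        cassette = _random_seq(rng, L)
        for copy in range(2):
            eid += 1
            pos = next(pos_iter)
            # pinning alters at most 2 of >1000 bases: copies stay >99% identical
            seq = _pin_junctions(cassette, founder_seq[pos - 1], founder_seq[pos])
            insertions.append(
                PlantedInsertion(
                    event_id=f"cas{k + 1}_{copy + 1}",
                    chrom=chrom,
                    base_pos=pos,
                    sequence=seq,
                    carrier_genomes=[genome_names[0]] if genome_names else [],
                )
            )
    inversions: list[PlantedInversion] = []
    for k in range(config.n_inversions):
        L = _draw_length(rng, *config.inversion_len_range, config.window_align)
        s = next(pos_iter)
        carrier = genome_names[int(rng.integers(0, len(genome_names)))] if genome_names else ""
        inversions.append(
            PlantedInversion(
                event_id=f"inv{k + 1}",
                chrom=chrom,
                base_start=s,
                base_end=s + L,
                carrier_genomes=[carrier] if carrier else [],
            )
        )

    derived: list[GenomeSequence] = []
    for gname in genome_names:
        seq = founder_seq
        events = sorted(
            [i for i in insertions if gname in i.carrier_genomes],
            key=lambda i: i.base_pos,
            reverse=True,
        )
        for ins in events:  # right-to-left so anchors stay valid
            seq = seq[: ins.base_pos] + ins.sequence + seq[ins.base_pos :]
        offsets = sorted(
            (i.base_pos, i.length) for i in insertions if gname in i.carrier_genomes
        )
        for inv in inversions:
            if gname not in inv.carrier_genomes:
                continue
            shift = sum(l for p, l in offsets if p <= inv.base_start)
            s, e = inv.base_start + shift, inv.base_end + shift
            seq = seq[:s] + revcomp(seq[s:e]) + seq[e:]
        derived.append(GenomeSequence(gname, {chrom: seq}))

    accessions = [f"acc{i + 1}" for i in range(config.n_accessions)]
    carriers: dict[str, list[str]] = {}
    for acc in accessions:
        carried = [
            ins.event_id
            for ins in insertions
            if rng.random() < config.carrier_prob
        ]
        carriers[acc] = carried

    manifest = TruthManifest(
        config=config,
        chrom_name=chrom,
        founder_length=config.chrom_length,
        insertions=insertions,
        inversions=inversions,
        accession_carriers=carriers,
    )
    return founder, derived, manifest


def simulate_accession_evidence(
    manifest: TruthManifest,
    accession: str,
) -> DepthTrack:
    """Error-free uniform depth over the pangenome for one accession: the
    configured coverage everywhere except zero over segments the accession
    does not carry."""
    cfg = manifest.config
    rng = np.random.default_rng((cfg.seed, zlib.crc32(accession.encode())))
    arr = np.full(manifest.pangenome_length, cfg.coverage_depth, dtype=np.float64)
    if cfg.depth_jitter > 0:
        arr += rng.normal(0, cfg.depth_jitter, arr.shape)
        np.clip(arr, 0, None, out=arr)
    for s, e in manifest.absent_intervals(accession):
        arr[s:e] = 0
    return DepthTrack(accession=accession, depth={manifest.chrom_name: arr})


def simulate_junction_reads(
    manifest: TruthManifest,
    breakpoint_pos: int,
    carrier: bool,
    n_reads: int | None = None,
    mapq: int = 60,
) -> list[AlignmentRecord]:
    """Alignment-record stubs around one junction.

    Carriers get reads whose single matched block spans the junction with at
    least 19 bp on each side; non-carriers get the same number of reads that
    stop exactly at the junction (clipped there), so no read spans."""
    cfg = manifest.config
    n = int(n_reads if n_reads is not None else round(cfg.coverage_depth))
    rl = cfg.read_length
    chrom = manifest.chrom_name
    records: list[AlignmentRecord] = []
    rng = np.random.default_rng((cfg.seed, breakpoint_pos, int(carrier)))
    for _ in range(n):
        if carrier:
            left = int(rng.integers(19, rl - 19))  # >=19 matched on each side
            block = (breakpoint_pos - left, breakpoint_pos - left + rl)
        else:
            side = rng.random() < 0.5
            if side:
                block = (breakpoint_pos - rl, breakpoint_pos)
            else:
                block = (breakpoint_pos, breakpoint_pos + rl)
        s = max(block[0], 0)
        e = min(block[1], manifest.pangenome_length)
        records.append(AlignmentRecord(chrom=chrom, mapq=mapq, blocks=[(s, e)]))
    return records


def simulate_sv_evidence(
    manifest: TruthManifest,
    breakpoints: list[tuple[str, int]],
    sv_carriers: dict[str, bool],
) -> dict[str, list[AlignmentRecord]]:
    """Per-accession junction reads for one SV's breakpoints."""
    out: dict[str, list[AlignmentRecord]] = {}
    for acc, is_carrier in sv_carriers.items():
        recs: list[AlignmentRecord] = []
        for _chrom, pos in breakpoints:
            recs.extend(simulate_junction_reads(manifest, pos, is_carrier))
        out[acc] = recs
    return out
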