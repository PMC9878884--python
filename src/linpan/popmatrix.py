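"""Population-level PAV genotyping via the breakpoint-union scheme.

Every accession's segment boundaries are pooled into a per-chromosome sorted
union; adjacent union breakpoints define the PAV regions (named
``<chrom>_<left breakpoint>``), each accession's calls are re-expressed over
those regions, and the rows combine into a genotype matrix.  Columns are
filtered by minor-state frequency (> 0.05 by default) and missingness
(< 0.15) before export to HapMap, where presence codes ``CC`` and absence
``AA`` (inbred material: homozygous doubled alleles).

Matrix entries are int8: 1 = present, 0 = absent, -1 = missing.  A missing
entry arises only when an accession has no depth track for a chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import ABSENT, PRESENT, PavCallSet

PRESENT_CODE = 1
ABSENT_CODE = 0
MISSING_CODE = -1

_HAPMAP_COLS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


@dataclass(frozen=True)
class PavRegion:
    chrom: str
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"{self.chrom}_{self.start}"


@dataclass
class BreakpointUnion:
    """Sorted unique breakpoint positions per chromosome (incl. 0 and end)."""

    positions: dict[str, list[int]]
    chrom_lengths: dict[str, int]

    def regions(self) -> list[PavRegion]:
        out: list[PavRegion] = []
        for chrom in self.positions:
            pos = self.positions[chrom]
            out.extend(PavRegion(chrom, a, b) for a, b in zip(pos, pos[1:]))
        return out


@dataclass
class PavMatrix:
    """Accessions (rows) x PAV regions (columns, genome order)."""

    data: pd.DataFrame  # int8 codes
    regions: list[PavRegion]

    def __post_init__(self) -> None:
        if list(self.data.columns) != [r.name for r in self.regions]:
            raise ValueError("matrix columns do not match region list")

    @property
    def accessions(self) -> list[str]:
        return list(self.data.index)


def union_breakpoints(callsets: list[PavCallSet]) -> BreakpointUnion:
    if not callsets:
        raise ValueError("no callsets supplied")
    lengths: dict[str, int] = {}
    for cs in callsets:
        for chrom, n in cs.chrom_lengths.items():
            if lengths.setdefault(chrom, n) != n:
                raise ValueError(
                    f"chromosome {chrom!r} length differs between accessions "
                    f"({lengths[chrom]} vs {n} in {cs.accession})"
                )
    pooled: dict[str, set[int]] = {c: {0, n} for c, n in lengths.items()}
    for cs in callsets:
        for chrom, bps in cs.breakpoints().items():
            pooled[chrom].update(bps)
    return BreakpointUnion(
        positions={c: sorted(v) for c, v in pooled.items()}, chrom_lengths=lengths
    )


def recall_genotypes(callset: PavCallSet, union: BreakpointUnion) -> pd.Series:
    """Re-express one accession's segments over the union regions.

    Each region lies inside exactly one original segment (the union refines
    every accession's own partition), so it simply inherits that state.
    Chromosomes with no track for this accession genotype as missing."""
    regions = union.regions()
    seg_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, s, e, state in callset.segments:
        seg_by_chrom.setdefault(chrom, []).append((s, e, state))
    for segs in seg_by_chrom.values():
        segs.sort()

    codes = np.full(len(regions), MISSING_CODE, dtype=np.int8)
    for i, r in enumerate(regions):
        segs = seg_by_chrom.get(r.chrom)
        if segs is None:
            continue
        starts = [s for s, _, _ in segs]
        j = np.searchsorted(starts, r.start, side="right") - 1
        s, e, state = segs[j]
        assert s <= r.start and r.end <= e, (
            f"union region {r.name} crosses a segment boundary of {callset.accession}"
        )
        codes[i] = PRESENT_CODE if state == PRESENT else ABSENT_CODE
    return pd.Series(codes, index=[r.name for r in regions], name=callset.accession)


def build_matrix(callsets: list[PavCallSet]) -> PavMatrix:
    union = union_breakpoints(callsets)
    rows = [recall_genotypes(cs, union) for cs in callsets]
    df = pd.DataFrame(rows).astype(np.int8)
    if df.index.duplicated().any():
        raise ValueError("duplicate accession names")
    return PavMatrix(data=df, regions=union.regions())


def filter_maf(matrix: PavMatrix, maf_min: float = 0.05,
               max_missing: float = 0.15) -> PavMatrix:
    """Keep columns with minor-state frequency > maf_min (among non-missing
    calls) and missing fraction < max_missing; invariant columns drop out."""
    if matrix.data.empty:
        raise ValueError("cannot filter an empty matrix")
    df = matrix.data
    n = len(df)
    missing_frac = (df == MISSING_CODE).sum(axis=0) / n
    non_missing = (df != MISSING_CODE).sum(axis=0)
    n_present = (df == PRESENT_CODE).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = n_present / non_missing.replace(0, np.nan)
    maf = np.minimum(freq, 1 - freq)
    keep = (maf > maf_min) & (missing_frac < max_missing)
    keep = keep.fillna(False)
    kept_names = set(df.columns[keep])
    regions = [r for r in matrix.regions if r.name in kept_names]
    return PavMatrix(data=df.loc[:, keep].copy(), regions=regions)


def export_hapmap(matrix: PavMatrix, path: str | Path) -> None:
    """HapMap genotype table: one marker row per PAV region.

    Genotypes: present -> "CC", absent -> "AA", missing -> "NN"; marker
    position is the 1-based left breakpoint."""
    path = Path(path)
    if matrix.data.empty or not matrix.regions:
        warnings.warn("exporting an empty PAV matrix: header-only HapMap file")
        with open(path, "w") as fh:
            fh.write("\t".join(_HAPMAP_COLS + matrix.accessions) + "\n")
        return
    code_map = {PRESENT_CODE: "CC", ABSENT_CODE: "AA", MISSING_CODE: "NN"}
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_COLS + matrix.accessions) + "\n")
        for r in matrix.regions:
            col = matrix.data[r.name]
            fields = [
                r.name, "A/C", r.chrom, str(r.start + 1), "+", "NA",
                "NA", "NA", "NA", "NA", "NA",
            ] + [code_map[int(v)] for v in col]
            fh.write("\t".join(fields) + "\n")


def read_hapmap(path: str | Path) -> PavMatrix:
    """Inverse of :func:`export_hapmap` (region ends inferred from the next
    marker's start on the same chromosome; the final region on each
    chromosome gets a zero-length sentinel end equal to its start unless a
    following marker bounds it)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        return PavMatrix(data=pd.DataFrame(), regions=[])
    accessions = [c for c in df.columns if c not in _HAPMAP_COLS]
    geno_map = {"CC": PRESENT_CODE, "AA": ABSENT_CODE, "NN": MISSING_CODE}
    regions: list[PavRegion] = []
    starts = df["pos"].astype(int) - 1
    chroms = df["chrom"]
    for i in range(len(df)):
        if i + 1 < len(df) and chroms[i + 1] == chroms[i]:
            end = int(starts[i + 1])
        else:
            end = int(starts[i])  # unknown right bound: sentinel
        regions.append(PavRegion(str(chroms[i]), int(starts[i]), end))
    data = pd.DataFrame(
        {
            df["rs#"][i]: [geno_map[df[a][i]] for a in accessions]
            for i in range(len(df))
        },
        index=accessions,
        dtype=np.int8,
    )
    # marker names are authoritative; rebuild regions so names align
    regions = [PavRegion(r.chrom, r.start, r.end) for r in regions]
    return PavMatrix(data=data, regions=regions)


def write_matrix_tsv(matrix: PavMatrix, path: str | Path) -> None:
    sym = {PRESENT_CODE: PRESENT, ABSENT_CODE: ABSENT, MISSING_CODE: "missing"}
    matrix.data.replace(sym).to_csv(path, sep="\t", index_label="accession")


def write_region_bed(matrix: PavMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in matrix.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")
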