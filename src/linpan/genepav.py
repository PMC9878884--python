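"""Gene-level presence/absence from CDS coverage, with subpopulation
frequency tests.

A gene is called *absent* for an accession when, jointly, the horizontal
coverage of its CDS (fraction of CDS bases at depth >= 2) is below 95% AND
the vertical coverage (mean CDS depth) is below 2; otherwise present.  The
rule is a strict conjunction by default but can be switched to a
disjunction.  Group frequency differences are tested per gene with a
two-sided Fisher's exact test on the 2x2 present/absent x group table,
Bonferroni-adjusted over all tested genes; significant genes must reach
adjusted p < 0.001 and an absolute frequency difference >= 10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .coverage import DepthTrack

PRESENT = "present"
ABSENT = "absent"


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    cds: list[tuple[int, int]]  # 0-based half-open, sorted, non-overlapping

    def __post_init__(self) -> None:
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.cds, self.cds[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")
        if self.cds_length() == 0:
            raise ValueError(f"gene {self.gene_id} has zero-length CDS")

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass(frozen=True)
class GeneCoverage:
    gene_id: str
    accession: str
    horizontal: float  # fraction of CDS bases with depth >= vertical_min
    vertical: float    # mean depth over the CDS


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """CDS features from GFF3, grouped by gene (via gene_id/Parent chain).

    GFF coordinates are 1-based inclusive and converted here to 0-based
    half-open."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, GeneModel] = {}
    order: list[str] = []
    for cds in db.features_of_type("CDS"):
        gid = None
        for parent in db.parents(cds):
            if parent.featuretype == "gene":
                gid = parent.id
        if gid is None:
            gid = cds.attributes.get("gene_id", [cds.id or "gene"])[0]
        iv = (cds.start - 1, cds.end)
        if gid not in genes:
            genes[gid] = GeneModel(gene_id=gid, chrom=cds.seqid, cds=[iv])
            order.append(gid)
        else:
            g = genes[gid]
            if g.chrom != cds.seqid:
                raise ValueError(f"gene {gid} has CDS on multiple chromosomes")
            merged = sorted(g.cds + [iv])
            genes[gid] = GeneModel(gene_id=gid, chrom=g.chrom, cds=merged)
    return [genes[g] for g in order]


def gene_coverage(depth: DepthTrack, model: GeneModel, vertical_min: float = 2) -> GeneCoverage:
    if model.chrom not in depth.depth:
        raise ValueError(
            f"no depth for chromosome {model.chrom!r} (gene {model.gene_id})"
        )
    arr = depth.depth[model.chrom]
    parts = [arr[s:e] for s, e in model.cds]
    cds_depth = np.concatenate(parts)
    horizontal = float(np.mean(cds_depth >= vertical_min))
    vertical = float(np.mean(cds_depth))
    return GeneCoverage(model.gene_id, depth.accession, horizontal, vertical)


def call_gene_pav(
    cov: GeneCoverage,
    h_min: float = 0.95,
    v_min: float = 2,
    rule: str = "conjunction",
) -> str:
    """Absent iff horizontal < h_min AND vertical < v_min (conjunction, the
    default); the disjunction variant calls absent when either fails."""
    low_h = cov.horizontal < h_min
    low_v = cov.vertical < v_min
    if rule == "conjunction":
        return ABSENT if (low_h and low_v) else PRESENT
    if rule == "disjunction":
        return ABSENT if (low_h or low_v) else PRESENT
    raise ValueError(f"unknown rule {rule!r}")


def build_gene_matrix(
    tracks: list[DepthTrack],
    models: list[GeneModel],
    h_min: float = 0.95,
    v_min: float = 2,
    rule: str = "conjunction",
) -> pd.DataFrame:
    """Genes (rows) x accessions (columns), entries 1 present / 0 absent."""
    data = {}
    for track in tracks:
        calls = []
        for m in models:
            cov = gene_coverage(track, m, vertical_min=v_min)
            calls.append(1 if call_gene_pav(cov, h_min, v_min, rule) == PRESENT else 0)
        data[track.accession] = calls
    return pd.DataFrame(data, index=[m.gene_id for m in models], dtype=np.int8)


def bonferroni(pvals: np.ndarray) -> np.ndarray:
    """adjusted p = min(1, m * p), m = number of tests."""
    p = np.asarray(pvals, dtype=float)
    return np.minimum(1.0, p * len(p))


@dataclass
class GeneFrequencyResult:
    table: pd.DataFrame
    significant: list[str] = field(default_factory=list)


def gene_frequency_test(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    p_adj_max: float = 0.001,
    min_diff: float = 0.10,
) -> GeneFrequencyResult:
    """Per-gene two-sided Fisher's exact test of presence frequency between
    two disjoint accession groups, Bonferroni-corrected over tested genes.

    ``matrix`` entries may be 1 (present), 0 (absent) or -1 (missing);
    genes with a group that is all-missing are skipped with a warning.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    for g, label in ((group_a, "A"), (group_b, "B")):
        if len(g) < 2:
            raise ValueError(f"group {label} needs at least 2 accessions")

    rows = []
    for gene in matrix.index:
        a = matrix.loc[gene, group_a]
        b = matrix.loc[gene, group_b]
        a = a[a >= 0]
        b = b[b >= 0]
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"gene {gene}: a group is all-missing; skipped")
            continue
        pa, pb = int(a.sum()), int(b.sum())
        aa, ab = len(a) - pa, len(b) - pb
        _, p = fisher_exact([[pa, pb], [aa, ab]], alternative="two-sided")
        rows.append(
            {
                "gene": gene,
                "freq_a": pa / len(a),
                "freq_b": pb / len(b),
                "present_a": pa, "absent_a": aa,
                "present_b": pb, "absent_b": ab,
                "p": float(p),
            }
        )
    if not rows:
        return GeneFrequencyResult(table=pd.DataFrame(), significant=[])
    table = pd.DataFrame(rows).set_index("gene")
    table["p_adj"] = bonferroni(table["p"].to_numpy())
    table["freq_diff"] = (table["freq_a"] - table["freq_b"]).abs()
    table["significant"] = (table["p_adj"] < p_adj_max) & (table["freq_diff"] >= min_diff)
    sig = list(table.index[table["significant"]])
    return GeneFrequencyResult(table=table, significant=sig)
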