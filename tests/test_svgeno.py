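"""Junction-spanning-read SV genotyping and translocation candidates."""

import numpy as np
import pytest

from linpan.build import PavSegmentAnnotation, Pangenome, build_pangenome
from linpan.coverage import AlignmentRecord
from linpan.genome import GenomeSequence
from linpan.liftover import CoordinateMap
from linpan.svgeno import (
    CODE_ABSENT,
    CODE_MISSING,
    CODE_PRESENT,
    count_spanning_reads,
    find_translocation_candidates,
    genotype_breakpoint,
    genotype_sv,
    genotype_sv_population,
    import_inversions,
)

CHROM_LEN = 100_000
BP = 5_000


def _spanning(pos, left, right, mapq=60):
    return AlignmentRecord("chr1", mapq, [(pos - left, pos + right)])


class TestJunctionCounting:
    @pytest.mark.parametrize("n,code", [(5, CODE_PRESENT), (4, CODE_ABSENT)])
    def test_read_count_threshold(self, n, code):
        recs = [_spanning(BP, 50, 50) for _ in range(n)]
        g = genotype_breakpoint(recs, "chr1", BP, CHROM_LEN)
        assert g.code == code

    def test_reads_ending_at_breakpoint_do_not_span(self):
        recs = [AlignmentRecord("chr1", 60, [(BP - 100, BP)]) for _ in range(100)]
        g = genotype_breakpoint(recs, "chr1", BP, CHROM_LEN)
        assert g.code == CODE_ABSENT

    @pytest.mark.parametrize(
        "left,right,counted",
        [(18, 30, False), (19, 19, True), (30, 18, False), (19, 30, True)],
    )
    def test_flank_boundary_19bp_per_side(self, left, right, counted):
        ev = count_spanning_reads([_spanning(BP, left, right)], "chr1", BP)
        assert ev.spanning_read_count == (1 if counted else 0)

    def test_split_blocks_do_not_span(self):
        # two match blocks abutting the junction: no contiguous 39-bp span
        rec = AlignmentRecord("chr1", 60, [(BP - 50, BP), (BP, BP + 50)])
        assert count_spanning_reads([rec], "chr1", BP).spanning_read_count == 0

    def test_low_mapq_reads_not_counted(self):
        recs = [_spanning(BP, 50, 50, mapq=20) for _ in range(10)]
        assert count_spanning_reads(recs, "chr1", BP).spanning_read_count == 0

    def test_breakpoint_near_chromosome_end_is_missing(self):
        with pytest.warns(UserWarning):
            g = genotype_breakpoint([], "chr1", 10, CHROM_LEN)
        assert g.code == CODE_MISSING


class TestAllBreakpointsRule:
    def test_both_junctions_present(self):
        recs = [_spanning(p, 50, 50) for p in (BP, BP + 900) for _ in range(5)]
        g = genotype_sv(recs, [("chr1", BP), ("chr1", BP + 900)], {"chr1": CHROM_LEN})
        assert g.code == CODE_PRESENT

    def test_one_junction_at_zero_reads_is_absent(self):
        recs = [_spanning(BP, 50, 50) for _ in range(10)]
        g = genotype_sv(recs, [("chr1", BP), ("chr1", BP + 900)], {"chr1": CHROM_LEN})
        assert g.code == CODE_ABSENT


class TestPopulationGenotyping:
    def test_simulated_carriers_recovered(self, cassette_sim, cassette_pangenome):
        from linpan.simulate import simulate_sv_evidence

        _f, _d, manifest = cassette_sim
        pan = cassette_pangenome
        cands = find_translocation_candidates(pan)
        assert cands, "cassette pair should yield candidates"
        cand = cands[0]
        carriers = {acc: i % 2 == 0
                    for i, acc in enumerate(manifest.accession_carriers)}
        evidence = simulate_sv_evidence(manifest, cand.breakpoints(), carriers)
        mat = genotype_sv_population(
            [cand], evidence, pan.sequence.chrom_lengths()
        )
        for acc, is_carrier in carriers.items():
            expected = CODE_PRESENT if is_carrier else CODE_ABSENT
            assert mat.loc[acc, cand.pav_name] == expected


def _brute_force_candidates(pan: Pangenome, min_len=1000, min_identity=0.95,
                            min_loci=2):
    """Oracle: exhaustive sliding-window Hamming scan for every PAV sequence
    (the planted duplicated cassettes differ only by substitutions, so
    substitution-only identity is exact for them)."""
    names = set()
    for ann in pan.annotations:
        if ann.length <= min_len:
            continue
        seq = np.frombuffer(
            pan.sequence.extract(ann.pangenome_chrom, ann.start, ann.end).encode(),
            dtype=np.uint8,
        )
        m = len(seq)
        max_mm = int(m * (1 - min_identity))
        n_loci = 0
        for _chrom, target in pan.sequence.chromosomes.items():
            t = np.frombuffer(target.encode(), dtype=np.uint8)
            n_pos = len(t) - m + 1
            if n_pos <= 0:
                continue
            mismatches = np.zeros(n_pos, dtype=np.int32)
            for j in range(m):
                mismatches += t[j : j + n_pos] != seq[j]
            hit_starts = np.flatnonzero(mismatches <= max_mm)
            last = -(10 ** 9)
            for s in hit_starts:
                if s - last >= min_len // 2:
                    n_loci += 1
                    last = s
        if n_loci >= min_loci:
            names.add(ann.name)
    return names


class TestCandidateDiscovery:
    def test_duplicated_cassette_found_with_two_loci(self, cassette_pangenome):
        cands = find_translocation_candidates(cassette_pangenome)
        cassette_names = {
            a.name for a in cassette_pangenome.annotations if a.length > 1000
        }
        assert {c.pav_name for c in cands} == cassette_names
        for c in cands:
            assert c.n_loci == 2
            assert all(l.identity >= 0.95 for l in c.matched_loci)

    def test_short_duplicate_not_a_candidate(self, rng):
        # 900-bp sequence present at 3 loci: below the >1 kb length rule
        base = "".join(rng.choice(list("ACGT"), 30_000))
        dup = "".join(rng.choice(list("ACGT"), 900))
        seq = base[:5000] + dup + base[5000:15000] + dup + base[15000:25000] + dup + base[25000:]
        pan = Pangenome(
            sequence=GenomeSequence("pan", {"chr1": seq}),
            base_to_final=CoordinateMap.identity({"chr1": len(seq)}),
            per_iteration_maps=[],
            annotations=[PavSegmentAnnotation("PAV_g_1", "chr1", 5000, 5900, "g", 1)],
        )
        assert find_translocation_candidates(pan) == []

    def test_unique_long_segment_not_a_candidate(self, rng):
        base = "".join(rng.choice(list("ACGT"), 30_000))
        pan = Pangenome(
            sequence=GenomeSequence("pan", {"chr1": base}),
            base_to_final=CoordinateMap.identity({"chr1": len(base)}),
            per_iteration_maps=[],
            annotations=[PavSegmentAnnotation("PAV_g_1", "chr1", 5000, 7000, "g", 1)],
        )
        assert find_translocation_candidates(pan) == []

    def test_matches_brute_force_oracle(self, cassette_pangenome):
        got = {c.pav_name for c in find_translocation_candidates(cassette_pangenome)}
        assert got == _brute_force_candidates(cassette_pangenome)


class TestInversionImport:
    HEADER = "reference\tref_start\tref_stop\tID\tsize\tstrand\ttype\n"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "inv.tsv"
        p.write_text(self.HEADER)
        assert import_inversions(p) == []

    def test_identity_map_keeps_coordinates(self, tmp_path):
        p = tmp_path / "inv.tsv"
        p.write_text(self.HEADER + "chr1\t10000\t12000\tv1\t2000\t+\tInversion\n")
        m = CoordinateMap.identity({"chr1": 50_000})
        (cand,) = import_inversions(p, m)
        assert (cand.start, cand.end) == (10_000, 12_000)

    def test_liftover_shifts_past_insertion(self, tmp_path):
        p = tmp_path / "inv.tsv"
        p.write_text(self.HEADER + "chr1\t10000\t12000\tv1\t2000\t+\tInversion\n")
        m = CoordinateMap.from_insertions(
            {"chr1": 50_000}, {"chr1": [(5_000, 100, "PAV_x_1")]}
        )
        (cand,) = import_inversions(p, m)
        assert (cand.start, cand.end) == (10_100, 12_100)

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "inv.tsv"
        p.write_text(self.HEADER + "chr1\tBAD\t12000\tv1\t2000\t+\tInversion\n")
        with pytest.raises(ValueError, match=":2"):
            import_inversions(p)
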