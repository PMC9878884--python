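"""Pangenome construction: filtering, incorporation, iteration, liftover,
annotation fidelity and file round-trips."""

import numpy as np
import pytest

from linpan.align import InsertionCall, detect_insertions
from linpan.build import (
    PavSegmentAnnotation,
    build_pangenome,
    filter_insertions,
    incorporate_insertions,
    read_pangenome,
    write_pangenome,
)
from linpan.genome import GenomeSequence
from linpan.liftover import INSERTED
from linpan.simulate import SimulationConfig, simulate_pangenome_inputs


def _call(pos, seq, chrom="chr1", source="g"):
    return InsertionCall(chrom, pos, seq, source)


class TestFilterInsertions:
    def test_strictly_greater_than_threshold(self):
        # "larger than 50 bp": 50 is dropped, 51 kept
        calls = [_call(10, "A" * 50), _call(20, "A" * 51)]
        kept = filter_insertions(calls, 50)
        assert [c.length for c in kept] == [51]

    def test_empty_input(self):
        assert filter_insertions([], 50) == []

    def test_mixed_lengths(self):
        calls = [_call(p, "A" * n) for p, n in [(1, 10), (2, 50), (3, 51), (4, 5000)]]
        assert [c.length for c in filter_insertions(calls, 50)] == [51, 5000]

    def test_order_preserved(self):
        calls = [_call(30, "A" * 100), _call(10, "C" * 200)]
        assert [c.ref_pos for c in filter_insertions(calls, 50)] == [30, 10]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_insertions([], -1)


class TestIncorporate:
    def test_length_and_shift(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        ref = GenomeSequence("ref", {"chr1": seq})
        new, cmap, anns = incorporate_insertions(ref, [_call(4000, "G" * 100)])
        assert len(new.chromosomes["chr1"]) == 10_100
        assert cmap.lift("chr1", 4500) == 4600
        assert len(anns) == 1 and anns[0].length == 100

    def test_no_calls_identity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1_000))
        ref = GenomeSequence("ref", {"chr1": seq})
        new, cmap, anns = incorporate_insertions(ref, [])
        assert new.chromosomes == ref.chromosomes
        assert anns == []
        assert cmap.lift("chr1", 999) == 999

    def test_spliced_sequences_extract_back(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        ref = GenomeSequence("ref", {"chr1": seq})
        planted = {
            1_000: "".join(rng.choice(list("ACGT"), 60)),
            4_000: "".join(rng.choice(list("ACGT"), 500)),
            8_000: "".join(rng.choice(list("ACGT"), 2_000)),
        }
        calls = [_call(p, s) for p, s in planted.items()]
        new, _cmap, anns = incorporate_insertions(ref, calls)
        assert len(new.chromosomes["chr1"]) == 10_000 + 2_560
        for a in anns:
            src_pos = a.start  # map anns back to their planted sequence by length
        for a, (p, s) in zip(sorted(anns, key=lambda a: a.start), sorted(planted.items())):
            assert new.extract("chr1", a.start, a.end) == s

    def test_duplicate_identical_calls_collapse(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1_000))
        ref = GenomeSequence("ref", {"chr1": seq})
        c = _call(500, "T" * 80)
        new, _m, anns = incorporate_insertions(ref, [c, c])
        assert len(anns) == 1
        assert len(new.chromosomes["chr1"]) == 1_080

    def test_distinct_calls_at_same_point_error(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1_000))
        ref = GenomeSequence("ref", {"chr1": seq})
        with pytest.raises(ValueError, match="ambiguous"):
            incorporate_insertions(ref, [_call(500, "T" * 80), _call(500, "G" * 80)])

    def test_out_of_bounds_call_error(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1_000))
        ref = GenomeSequence("ref", {"chr1": seq})
        with pytest.raises(ValueError, match="outside"):
            incorporate_insertions(ref, [_call(1_001, "T" * 80)])

    def test_name_ordinals_run_per_source_genome(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 2_000))
        ref = GenomeSequence("ref", {"chr1": seq})
        calls = [
            _call(100, "A" * 60, source="Lemont"),
            _call(500, "C" * 60, source="Tumba"),
            _call(900, "G" * 60, source="Lemont"),
        ]
        _new, _m, anns = incorporate_insertions(ref, calls)
        names = sorted(a.name for a in anns)
        assert names == ["PAV_Lemont_1", "PAV_Lemont_2", "PAV_Tumba_1"]


class TestBuildPangenome:
    def test_no_other_genomes_returns_reference(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 5_000))
        ref = GenomeSequence("ref", {"chr1": seq})
        pan = build_pangenome(ref, [])
        assert pan.sequence.chromosomes == ref.chromosomes
        assert pan.annotations == []

    def test_length_conservation_and_truth_recovery(self, small_sim, small_pangenome):
        founder, _derived, manifest = small_sim
        pan = small_pangenome
        assert len(pan.sequence) == len(founder) + sum(
            a.length for a in pan.annotations
        )
        assert len(pan.sequence) == manifest.pangenome_length
        got = {(a.start, a.end) for a in pan.annotations}
        expected = {(i.pan_start, i.pan_end) for i in manifest.insertions}
        assert got == expected
        for ins in manifest.insertions:
            assert (
                pan.sequence.extract(manifest.chrom_name, ins.pan_start, ins.pan_end)
                == ins.sequence
            )

    def test_shared_insertion_incorporated_once(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 20_000))
        shared = "".join(rng.choice(list("ACGT"), 400))
        own = "".join(rng.choice(list("ACGT"), 300))
        g1 = GenomeSequence("g1", {"chr1": seq[:8000] + shared + seq[8000:]})
        g2 = GenomeSequence(
            "g2", {"chr1": seq[:8000] + shared + seq[8000:14000] + own + seq[14000:]}
        )
        pan = build_pangenome(GenomeSequence("ref", {"chr1": seq}), [g1, g2])
        # shared segment annotated once, at iteration 1
        shared_anns = [a for a in pan.annotations if a.length == 400]
        assert len(shared_anns) == 1
        assert shared_anns[0].iteration_index == 1
        assert shared_anns[0].source_genome == "g1"
        assert len(pan.annotations) == 2

    def test_order_insensitive_content_for_disjoint_insertions(self, small_sim):
        founder, derived, _m = small_sim
        pan_fwd = build_pangenome(founder, derived)
        pan_rev = build_pangenome(founder, derived[::-1])
        assert pan_fwd.sequence.chromosomes == pan_rev.sequence.chromosomes
        assert {(a.start, a.end) for a in pan_fwd.annotations} == {
            (a.start, a.end) for a in pan_rev.annotations
        }

    def test_idempotence_against_finished_pangenome(self, small_sim, small_pangenome):
        _founder, derived, _m = small_sim
        for g in derived:
            calls = filter_insertions(
                detect_insertions(small_pangenome.sequence, g), 50
            )
            assert calls == []

    def test_liftover_round_trip_on_random_positions(self, small_sim, small_pangenome):
        founder, _d, manifest = small_sim
        cmap = small_pangenome.base_to_final
        rng = np.random.default_rng(7)
        chrom = manifest.chrom_name
        for pos in rng.integers(0, len(founder), 1_000):
            lifted = cmap.lift(chrom, int(pos))
            assert cmap.project(chrom, lifted) == int(pos)

    def test_project_inside_segment_names_owner(self, small_pangenome):
        ann = small_pangenome.annotations[0]
        res = small_pangenome.base_to_final.project(
            ann.pangenome_chrom, (ann.start + ann.end) // 2
        )
        assert res == (INSERTED, ann.name)


class TestSerialization:
    def test_gff_is_one_based_inclusive(self, tmp_path, rng):
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        ref = GenomeSequence("ref", {"chr1": seq})
        qry = GenomeSequence(
            "qry", {"chr1": seq[:4000] + "".join(rng.choice(list("ACGT"), 60)) + seq[4000:]}
        )
        pan = build_pangenome(ref, [qry])
        paths = write_pangenome(pan, tmp_path / "pan")
        gff_lines = [
            l for l in paths["gff"].read_text().splitlines() if not l.startswith("#")
        ]
        assert len(gff_lines) == 1
        f = gff_lines[0].split("\t")
        assert (int(f[3]), int(f[4])) == (4001, 4060)

    def test_fasta_gff_manifest_round_trip(self, tmp_path, cassette_pangenome):
        pan = cassette_pangenome
        write_pangenome(pan, tmp_path / "pan")
        back = read_pangenome(tmp_path / "pan")
        assert back.sequence.chromosomes == pan.sequence.chromosomes
        assert back.annotations == pan.annotations
        assert back.genome_order == pan.genome_order
        assert back.base_to_final.to_dict() == pan.base_to_final.to_dict()

    def test_pav_name_parses(self):
        assert PavSegmentAnnotation.parse_name("PAV_Lemont_570") == ("Lemont", 570)
        assert PavSegmentAnnotation.parse_name("PAV_Tumba_552") == ("Tumba", 552)
        with pytest.raises(ValueError):
            PavSegmentAnnotation.parse_name("not_a_pav")
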