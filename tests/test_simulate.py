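"""Synthetic genome / trio / read generators."""

import numpy as np
import pytest

import chlorotrace as ct
from chlorotrace.genome import revcomp


class TestBuildGenome:
    def test_construction_layout(self):
        g = ct.build_genome(1000, 300, 200, seed=7)
        assert g.length == 1800
        assert (g.lsc_end, g.ira_end, g.ssc_end) == (1000, 1300, 1500)
        assert g.irb == revcomp(g.ira)
        assert set(g.sequence) <= set("ACGT")

    def test_deterministic(self):
        a = ct.build_genome(1000, 300, 200, seed=7)
        b = ct.build_genome(1000, 300, 200, seed=7)
        c = ct.build_genome(1000, 300, 200, seed=8)
        assert a.sequence == b.sequence
        assert a.sequence != c.sequence

    def test_region_gc_content(self):
        g = ct.build_genome(20000, 6000, 4000, seed=1)
        gc = lambda s: (s.count("G") + s.count("C")) / len(s)
        assert gc(g.lsc) == pytest.approx(0.3447, abs=0.02)
        assert gc(g.ira) == pytest.approx(0.4197, abs=0.02)
        assert gc(g.ssc) == pytest.approx(0.3054, abs=0.02)

    def test_invalid_lengths_rejected(self):
        with pytest.raises(ValueError):
            ct.build_genome(0, 300, 200)
        with pytest.raises(ValueError):
            ct.build_genome(1000, -1, 200)

    def test_short_ir_warns(self):
        with pytest.warns(UserWarning, match="undetectable"):
            ct.build_genome(1000, 40, 200, seed=0)

    def test_region_lookup_and_mirror(self):
        g = ct.build_genome(1000, 300, 200, seed=7)
        assert g.region_of(1) == "LSC"
        assert g.region_of(1001) == "IRa"
        assert g.region_of(1400) == "SSC"
        assert g.region_of(1501) == "IRb"
        # first IRa base mirrors to the last IRb base
        assert g.mirror_ir_position(1001) == 1800
        assert g.mirror_ir_position(1800) == 1001


class TestMakeTrio:
    def test_zero_de_novo_offspring_equals_mother(self, toy_genome):
        spec = ct.TrioSpec(3, 2, 2, 0, seed=1)
        m, f, o, _ = ct.make_trio(toy_genome, spec)
        assert o.sequence == m.sequence

    def test_carrier_structure(self, toy_genome):
        spec = ct.TrioSpec(5, 3, 4, 2, seed=2)
        m, f, o, truth = ct.make_trio(toy_genome, spec)
        assert len(truth) == 14  # single-copy only: no mirrored rows
        by_class = truth.groupby("var_class").size().to_dict()
        assert by_class == {"shared": 5, "mother_private": 3,
                            "father_private": 4, "de_novo": 2}
        for r in truth.itertuples():
            carriers = set(r.carriers.split(","))
            expected = {
                "shared": {"mother", "father", "offspring"},
                "mother_private": {"mother", "offspring"},
                "father_private": {"father"},
                "de_novo": {"offspring"},
            }[r.var_class]
            assert carriers == expected

    def test_truth_alleles_match_reference(self, toy_genome, toy_trio):
        _, _, _, truth = toy_trio
        for r in truth.itertuples():
            ref = toy_genome.sequence[r.pos - 1 : r.pos - 1 + len(r.ref)]
            assert ref == r.ref

    def test_ir_snp_mirrored_and_symmetry_kept(self, toy_genome):
        spec = ct.TrioSpec(2, 0, 0, 0, snp_indel_ratio=1.0,
                           region_weights={"single_copy": 0.0, "ir": 1.0},
                           seed=5)
        m, f, o, truth = ct.make_trio(toy_genome, spec)
        assert set(truth.region) == {"IRa", "IRb"}
        assert len(truth) == 4  # 2 planted, each mirrored
        for g in (m, f, o):
            assert g.ir_symmetric()
        # mirrored alt is the complement at the mirrored position
        ira_rows = truth[truth.region == "IRa"]
        for r in ira_rows.itertuples():
            mirror = truth[truth.pos == toy_genome.mirror_ir_position(r.pos)]
            assert len(mirror) == 1
            assert mirror.iloc[0].alt == revcomp(r.alt)

    def test_deterministic(self, toy_genome):
        spec = ct.TrioSpec(4, 2, 2, 1, seed=9)
        a = ct.make_trio(toy_genome, spec)
        b = ct.make_trio(toy_genome, spec)
        assert a[0].sequence == b[0].sequence
        assert a[3].equals(b[3])

    def test_overflow_rejected(self, toy_genome):
        spec = ct.TrioSpec(500, 0, 0, 0, seed=0)
        with pytest.raises(ValueError, match="non-overlapping"):
            ct.make_trio(toy_genome, spec)

    def test_spacing_and_homopolymer_exclusion(self, toy_genome):
        spec = ct.TrioSpec(10, 5, 5, 2, seed=13)
        *_, truth = ct.make_trio(toy_genome, spec)
        pos = sorted(truth.pos)
        assert min(b - a for a, b in zip(pos, pos[1:])) >= 20


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self, toy_genome):
        ds = ct.simulate_reads(toy_genome, 200, read_length=100, seed=3)
        doubled = toy_genome.sequence * 2
        for _, seq, _ in ds.reads():
            assert seq in doubled or revcomp(seq) in doubled

    def test_error_rate_binomial(self, toy_genome):
        ds = ct.simulate_reads(toy_genome, 2000, read_length=100,
                               error_rate=0.01, seed=4)
        doubled = toy_genome.sequence * 2
        mismatches = bases = 0
        idx = ct.build_index(toy_genome)
        for _, seq, _ in ds.reads():
            aln = ct.map_read(seq, idx, min_identity=0.8)
            if aln.mapped:
                mismatches += aln.edit_distance
                bases += len(seq)
        p = mismatches / bases
        se = (0.01 * 0.99 / bases) ** 0.5
        assert abs(p - 0.01) < 3 * se

    def test_quality_encoding_and_lengths(self, toy_reads):
        for p in toy_reads.pairs:
            assert len(p.seq1) == len(p.qual1) == 100
            assert set(p.qual1) == {chr(35 + 33)}

    def test_empty_dataset_valid(self, toy_genome):
        ds = ct.simulate_reads(toy_genome, 0, seed=0)
        assert ds.n_pairs == 0

    def test_read_longer_than_insert_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            ct.simulate_reads(toy_genome, 10, read_length=400,
                              insert_mean=300)

    def test_duplicate_rate(self, toy_genome):
        ds = ct.simulate_reads(toy_genome, 1000, duplicate_rate=0.3, seed=6)
        assert ds.n_pairs == 1300
        _, frac = ct.dedup_pairs(ds)
        # expected removed fraction d/(1+d)
        assert frac == pytest.approx(0.3 / 1.3, abs=0.02)

    def test_deterministic(self, toy_genome):
        a = ct.simulate_reads(toy_genome, 50, seed=11)
        b = ct.simulate_reads(toy_genome, 50, seed=11)
        assert a.pairs == b.pairs


class TestSplitReads:
    def test_linear_count(self):
        g = ct.build_genome(1000, 300, 200, seed=7)
        frags = ct.split_reads(g.sequence, window=100, step=1)
        assert len(frags) == 1800 - 100 + 1

    def test_window_equals_length(self):
        seq = "ACGT" * 25
        assert ct.split_reads(seq, window=100) == [seq]

    def test_circular_count_and_wrap(self, toy_genome):
        frags = ct.split_reads(toy_genome, window=100, step=1)
        assert len(frags) == toy_genome.length
        wrap = frags[-1]
        assert wrap == (toy_genome.sequence[-1:]
                        + toy_genome.sequence[:99])

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError):
            ct.split_reads("ACGT", window=10)

    def test_fragments_are_exact_substrings(self, toy_genome):
        doubled = toy_genome.sequence * 2
        for fr in ct.split_reads(toy_genome, window=80, step=37):
            assert fr in doubled
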