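import numpy as np
import pandas as pd
import pytest

from oracles import naive_hits, oracle_fractional_counts
from repquant.alignment import (
    AlignmentHit,
    ReadAssignmentClass,
    align_and_classify,
    build_indexes,
)
from repquant.repeat_annotation_io import (
    GenomeSequence,
    RepeatCatalog,
    RepeatInstance,
    reverse_complement,
)
from repquant.repenrich_core import (
    FractionalAssignment,
    SubfamilyCountMatrix,
    aggregate_counts,
    assign_multimap,
    build_pseudogenomes,
    count_unique_overlaps,
    quantify_sample,
)


def inst(start, end, subfam="S", iid=0, contig="chr", strand="+"):
    return RepeatInstance(contig, start, end, strand, subfam, subfam, subfam, iid)


def unique_read(read_id, pos, length=50, contig="chr"):
    return ReadAssignmentClass(
        read_id, "unique", [AlignmentHit(contig, pos, "+", 0)], "A" * length
    )


class TestBuildPseudogenomes:
    def test_length_arithmetic(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        genome = {"chr": seq}
        cat = RepeatCatalog([inst(10, 110, iid=0), inst(200, 350, iid=1)])
        pg = build_pseudogenomes(genome, cat, spacer_length=50)["S"]
        assert len(pg.sequence) == 100 + 50 + 150
        assert pg.sequence[100:150] == "N" * 50
        assert pg.offsets == {0: (0, 100), 1: (150, 150)}

    def test_single_instance_equals_its_sequence(self):
        genome = {"chr": "ACGTACGTACGTACGTACGT"}
        cat = RepeatCatalog([inst(4, 12)])
        pg = build_pseudogenomes(genome, cat, 10)["S"]
        assert pg.sequence == genome["chr"][4:12]

    def test_minus_strand_not_reverse_complemented_by_default(self):
        genome = {"chr": "AAAACGTTTTGGGGCCCCAA"}
        cat = RepeatCatalog([inst(2, 10, strand="-")])
        pg = build_pseudogenomes(genome, cat, 10)["S"]
        assert pg.sequence == genome["chr"][2:10]
        pg_rc = build_pseudogenomes(
            genome, cat, 10, reverse_complement_minus=True
        )["S"]
        assert pg_rc.sequence == reverse_complement(genome["chr"][2:10])

    def test_flank_toggle(self):
        genome = {"chr": "AAAACGTTTTGGGGCCCCAA"}
        cat = RepeatCatalog([inst(5, 10)])
        pg = build_pseudogenomes(genome, cat, 10, flank=3)["S"]
        assert pg.sequence == genome["chr"][2:13]

    def test_out_of_bounds_instance_errors(self):
        genome = {"chr": "ACGTACGT"}
        cat = RepeatCatalog([inst(4, 100)])
        with pytest.raises(ValueError, match="outside contig"):
            build_pseudogenomes(genome, cat, 10)

    def test_simulated_reads_align_to_own_pseudogenome(self, tiny_world):
        genome, catalog, truth, design = tiny_world
        from repquant.synthetic_data import simulate_sample

        noiseless = type(design)(**{**design.__dict__, "error_rate": 0.0,
                                    "reads_per_sample": 400})
        reads, rt = simulate_sample(
            genome, catalog, truth, noiseless, "young", 3
        )
        pgs = build_pseudogenomes(
            {genome.name: genome.sequence}, catalog, design.read_length
        )
        idx = {s: build_indexes({s: pg.sequence}) for s, pg in pgs.items()}
        from repquant.alignment import align_all

        for read, origin in zip(reads, rt["origin_subfamily"]):
            if origin == "background":
                continue
            hits = align_all(read.sequence, idx[origin], 2)
            assert hits, f"read from {origin} missed its pseudo-genome"


class TestCountUniqueOverlaps:
    def test_read_inside_instance(self):
        cat = RepeatCatalog([inst(100, 300)])
        counts, attr = count_unique_overlaps([unique_read("r", 150)], cat)
        assert counts == {"S": 1}
        assert attr == {"r": ("S", 0)}

    def test_background_read_not_counted(self):
        cat = RepeatCatalog([inst(100, 300)])
        counts, attr = count_unique_overlaps([unique_read("r", 500)], cat)
        assert counts == {}
        assert attr == {}

    def test_one_bp_overlap_counts(self):
        cat = RepeatCatalog([inst(100, 300)])
        counts, _ = count_unique_overlaps([unique_read("r", 51)], cat)
        assert counts == {"S": 1}  # read [51,101) overlaps 1 bp
        counts, _ = count_unique_overlaps([unique_read("r", 50)], cat)
        assert counts == {}

    def test_straddle_tiebreak_larger_overlap(self):
        # read [80,130): 30 bp in A=[0,110), 20 bp in B=[110,400)
        cat = RepeatCatalog(
            [inst(0, 110, "A", 0), inst(110, 400, "B", 1)]
        )
        counts, attr = count_unique_overlaps([unique_read("r", 80)], cat)
        assert counts == {"A": 1}
        # oracle: enumerate all overlaps explicitly
        overlaps = {"A": min(110, 130) - max(0, 80), "B": min(400, 130) - 110}
        assert overlaps == {"A": 30, "B": 20}

    def test_equal_overlap_lexicographic_tiebreak(self):
        # read [85,135): 25 bp in each → lexicographically smaller name wins
        cat = RepeatCatalog(
            [inst(0, 110, "ZB", 0), inst(110, 400, "AX", 1)]
        )
        counts, _ = count_unique_overlaps([unique_read("r", 85)], cat)
        assert counts == {"AX": 1}

    def test_rejects_non_unique_read(self):
        cat = RepeatCatalog([inst(0, 100)])
        multi = ReadAssignmentClass(
            "r", "multi",
            [AlignmentHit("chr", 0, "+", 0), AlignmentHit("chr", 50, "+", 0)],
            "A" * 50,
        )
        with pytest.raises(ValueError, match="not uniquely"):
            count_unique_overlaps([multi], cat)

    def test_random_reads_match_linear_scan_oracle(self, rng):
        instances = []
        for i in range(60):
            s = int(rng.integers(0, 20_000))
            e = s + int(rng.integers(30, 500))
            instances.append(inst(s, e, f"S{i % 9}", i))
        # catalog construction permits overlaps; counting must still be exact
        cat = RepeatCatalog(instances)
        oracle_rows = [
            (i.contig, i.start, i.end, i.subfamily, i.instance_id)
            for i in instances
        ]
        from oracles import oracle_unique_subfamily

        for j in range(500):
            pos = int(rng.integers(0, 20_400))
            counts, attr = count_unique_overlaps(
                [unique_read(f"r{j}", pos)], cat
            )
            expected = oracle_unique_subfamily("chr", pos, 50, oracle_rows)
            if expected is None:
                assert counts == {}
            else:
                assert counts == {expected[0]: 1}
                assert attr[f"r{j}"] == expected


class TestAssignMultimap:
    def mk_multi(self, read_id, seq):
        return ReadAssignmentClass(
            read_id, "multi",
            [AlignmentHit("chr", 0, "+", 0), AlignmentHit("chr", 9, "+", 0)],
            seq,
        )

    def test_single_pseudogenome_weight_one(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=60))
        pgs = {"A": core, "B": "".join(rng.choice(list("ACGT"), size=60))}
        idx = build_indexes(pgs)
        assignments, unassigned = assign_multimap(
            [self.mk_multi("r", core[5:35])], idx
        )
        assert unassigned == []
        assert assignments[0].subfamilies == frozenset({"A"})
        assert assignments[0].weight == 1.0

    def test_four_pseudogenomes_quarter_each(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=60))
        pgs = {name: core for name in "ABCD"}
        idx = build_indexes(pgs)
        assignments, _ = assign_multimap([self.mk_multi("r", core[5:35])], idx)
        assert assignments[0].subfamilies == frozenset("ABCD")
        assert assignments[0].weight == pytest.approx(0.25)

    def test_five_hits_in_one_pseudogenome_count_once(self, rng):
        unit = "".join(rng.choice(list("ACGT"), size=40))
        pgs = {"A": unit * 5}
        idx = build_indexes(pgs)
        assignments, _ = assign_multimap([self.mk_multi("r", unit[:30])], idx)
        assert assignments[0].subfamilies == frozenset({"A"})
        assert assignments[0].weight == 1.0

    def test_no_hits_unassigned(self, rng):
        pgs = {"A": "".join(rng.choice(list("ACGT"), size=80))}
        idx = build_indexes(pgs)
        read = "".join(rng.choice(list("ACGT"), size=30))
        assignments, unassigned = assign_multimap([self.mk_multi("r", read)], idx)
        assert assignments == []
        assert unassigned == ["r"]

    def test_weights_sum_to_one_property(self, rng):
        core = "".join(rng.choice(list("ACGT"), size=50))
        pgs = {"A": core, "B": core, "C": "".join(rng.choice(list("ACGT"),
                                                             size=50))}
        idx = build_indexes(pgs)
        assignments, _ = assign_multimap(
            [self.mk_multi(f"r{i}", core[i : i + 30]) for i in range(10)], idx
        )
        for a in assignments:
            assert len(a.subfamilies) * a.weight == pytest.approx(1.0)


class TestAggregateCounts:
    def cat2(self):
        return RepeatCatalog([inst(0, 100, "A", 0), inst(200, 300, "B", 1)])

    def test_half_up_rounding(self):
        cat = self.cat2()
        unique = {"s1": {"A": 10}}
        fracs = {"s1": [
            FractionalAssignment(f"m{i}", frozenset({"A", "B"}))
            for i in range(5)
        ]}
        mat = aggregate_counts(unique, fracs, cat, {"s1": 100})
        assert mat.counts.loc["A", "s1"] == pytest.approx(12.5)
        rounded = mat.rounded()
        assert rounded.counts.loc["A", "s1"] == 13  # half-up
        assert rounded.counts.loc["B", "s1"] == 3  # 2.5 → 3

    def test_round_down_below_half(self):
        cat = self.cat2()
        fracs = {"s1": [
            FractionalAssignment(f"m{i}", frozenset({"A", "B", "C"}))
            for i in range(1)
        ]}
        cat3 = RepeatCatalog(
            [inst(0, 100, "A", 0), inst(200, 300, "B", 1), inst(400, 500, "C", 2)]
        )
        mat = aggregate_counts({"s1": {"A": 12}}, fracs, cat3, {"s1": 50})
        assert mat.counts.loc["A", "s1"] == pytest.approx(12 + 1 / 3)
        assert mat.rounded().counts.loc["A", "s1"] == 12

    def test_zero_fill_full_subfamily_set(self):
        cat = self.cat2()
        mat = aggregate_counts({"s1": {}}, {"s1": []}, cat, {"s1": 10})
        assert list(mat.counts.index) == ["A", "B"]
        assert (mat.counts.values == 0).all()

    def test_sample_mismatch_errors(self):
        cat = self.cat2()
        with pytest.raises(ValueError, match="sample sets differ"):
            aggregate_counts({"s1": {}}, {"s2": []}, cat, {"s1": 1})

    def test_fractional_sum_conservation(self):
        cat = self.cat2()
        unique = {"s1": {"A": 7, "B": 3}}
        fracs = {"s1": [
            FractionalAssignment("m1", frozenset({"A"})),
            FractionalAssignment("m2", frozenset({"A", "B"})),
        ]}
        mat = aggregate_counts(unique, fracs, cat, {"s1": 20})
        total = mat.counts["s1"].sum()
        assert total == pytest.approx(10 + 2)  # unique reads + assigned multi

    def test_tsv_roundtrip(self, tmp_path):
        cat = self.cat2()
        unique = {"s1": {"A": 3}, "s2": {"B": 2}}
        fracs = {
            "s1": [FractionalAssignment("m", frozenset({"A", "B"}))],
            "s2": [],
        }
        mat = aggregate_counts(unique, fracs, cat, {"s1": 10, "s2": 20})
        p = tmp_path / "counts.tsv"
        mat.to_tsv(p, header_lines=["test"])
        back = SubfamilyCountMatrix.from_tsv(p)
        assert back.stage == "fractional"
        pd.testing.assert_frame_equal(back.counts, mat.counts)
        assert back.library_sizes == mat.library_sizes
        assert back.lineage == mat.lineage
        rp = tmp_path / "rounded.tsv"
        mat.rounded().to_tsv(rp)
        back_r = SubfamilyCountMatrix.from_tsv(rp)
        assert back_r.stage == "rounded"
        pd.testing.assert_frame_equal(
            back_r.counts, mat.rounded().counts, check_dtype=False
        )


class TestQuantifySampleConservation:
    def test_ledger_identity_on_simulation(self, tiny_world, tiny_sample):
        genome, catalog, truth, design = tiny_world
        reads, _ = tiny_sample
        refs = {genome.name: genome.sequence}
        classes = align_and_classify(reads, refs, 2)
        pgs = build_pseudogenomes(refs, catalog, design.read_length)
        pidx = build_indexes({s: pg.sequence for s, pg in pgs.items()})
        ucounts, fracs, ledger = quantify_sample("s", classes, catalog, pidx)
        assert ledger.total_reads == len(reads)
        ledger.check()
        # per-sample fractional total = unique-overlap + assigned multi
        total = sum(ucounts.values()) + sum(1.0 for _ in fracs)
        frac_total = sum(ucounts.values()) + sum(
            a.weight * len(a.subfamilies) for a in fracs
        )
        assert frac_total == pytest.approx(total)

    def test_monotonicity_adding_reads(self, tiny_world):
        # appending one more unique read from subfamily never decreases it
        genome, catalog, truth, design = tiny_world
        target = catalog.instances_of("BetaSINE")[0]
        read1 = unique_read("extra", target.start + 5, contig=genome.name)
        counts0, _ = count_unique_overlaps([], catalog)
        counts1, _ = count_unique_overlaps([read1], catalog)
        assert counts1.get("BetaSINE", 0) >= counts0.get("BetaSINE", 0)


class TestEndToEndOracle:
    def test_small_pipeline_equals_bruteforce(self, tiny_world):
        from repquant.synthetic_data import simulate_sample

        genome, catalog, truth, design = tiny_world
        small = type(design)(**{**design.__dict__, "reads_per_sample": 400})
        reads, _ = simulate_sample(genome, catalog, truth, small, "mid", 2)
        refs = {genome.name: genome.sequence}
        classes = align_and_classify(reads, refs, 2)
        pgs = build_pseudogenomes(refs, catalog, design.read_length)
        pidx = build_indexes({s: pg.sequence for s, pg in pgs.items()})
        ucounts, fracs, ledger = quantify_sample("s", classes, catalog, pidx)
        mat = aggregate_counts(
            {"s": ucounts}, {"s": fracs}, catalog, {"s": ledger.library_size}
        )
        oracle_counts, oracle_ledger = oracle_fractional_counts(
            {r.name: r.sequence for r in reads},
            refs,
            [(i.contig, i.start, i.end, i.subfamily, i.instance_id)
             for i in catalog],
            {s: pg.sequence for s, pg in pgs.items()},
            v=2,
            use_matmul=False,
        )
        for subfam in catalog.subfamilies:
            assert mat.counts.loc[subfam, "s"] == pytest.approx(
                oracle_counts.get(subfam, 0.0), abs=1e-9
            )
        for key in ("unique_overlap", "unique_non_overlap", "multi_assigned",
                    "multi_unassigned", "unmapped"):
            assert getattr(ledger, key) == oracle_ledger[key]
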