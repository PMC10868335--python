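import numpy as np
import pytest

from knotmotif.bpp_engine import (
    BppMatrix,
    FoldConstraints,
    FoldError,
    alignment_bpp,
    constrained_level_bpps,
    enumerate_structures,
    fold_bpp,
    sum_pseudo_bpp,
)
from knotmotif.motif_catalog import Alignment
from knotmotif.structure_core import (
    BasePair,
    LayeredStructure,
    RnaSequence,
    SecondaryStructure,
    StructureError,
)

from conftest import oracle_bpp, random_rna


class TestFoldConstraints:
    def test_crossing_forced_pairs_rejected(self):
        with pytest.raises(StructureError, match="cross"):
            FoldConstraints(frozenset({BasePair(0, 9), BasePair(4, 13)}))

    def test_forced_pair_on_forbidden_position_rejected(self):
        with pytest.raises(StructureError, match="forbidden"):
            FoldConstraints(frozenset({BasePair(0, 9)}), frozenset({9}))

    def test_overlapping_forced_pairs_rejected(self):
        with pytest.raises(StructureError, match="overlap"):
            FoldConstraints(frozenset({BasePair(0, 9), BasePair(5, 9)}))


class TestFoldBpp:
    def test_unpairable_sequence_gives_zero_matrix(self):
        m = fold_bpp(RnaSequence("AAAAAAAA"))
        assert np.all(m.p == 0)

    def test_forced_pair_has_probability_one(self):
        m = fold_bpp(
            RnaSequence("GGGAAAUCCC"),
            FoldConstraints(frozenset({BasePair(0, 9)})),
        )
        assert m[0, 9] == 1.0

    def test_forbidden_position_has_zero_row_and_column(self):
        m = fold_bpp(
            RnaSequence("GGGAAAUCCC"), FoldConstraints(frozenset(), frozenset({0}))
        )
        assert np.all(m.p[0] == 0) and np.all(m.p[:, 0] == 0)

    def test_matches_enumeration_oracle_on_fixed_sequence(self):
        seq = RnaSequence("GCGAAAGC")
        m = fold_bpp(seq)
        expected = oracle_bpp(seq)
        assert np.abs(m.p - expected).max() < 1e-9

    def test_overconstrained_raises(self):
        # forcing a non-admissible pair (A-A) must fail
        with pytest.raises(FoldError):
            fold_bpp(
                RnaSequence("AAAAAAAA"), FoldConstraints(frozenset({BasePair(0, 7)}))
            )

    def test_unknown_backend(self):
        with pytest.raises(FoldError, match="backend"):
            fold_bpp(RnaSequence("GGGAAAUCCC"), backend="nonexistent")

    def test_row_sums_bounded_by_one(self, rng):
        for _ in range(10):
            m = fold_bpp(random_rna(rng, int(rng.integers(10, 25))))
            assert m.row_sums().max() <= 1 + 1e-9

    def test_symmetry_and_short_range_zeros(self, rng):
        m = fold_bpp(random_rna(rng, 20))
        assert np.allclose(m.p, m.p.T)
        for i in range(20):
            for j in range(i, min(i + 4, 20)):
                assert m[i, j] == 0


class TestEnumerate:
    def test_single_possible_pair(self):
        structs = enumerate_structures(RnaSequence("GAAAC"))
        assert sorted(s.as_tuples() for s in structs) == [[], [(0, 4)]]

    def test_no_pairs(self):
        structs = enumerate_structures(RnaSequence("AAAA"))
        assert [s.as_tuples() for s in structs] == [[]]

    def test_cap_enforced(self):
        with pytest.raises(FoldError, match="cap"):
            enumerate_structures(RnaSequence("A" * 30))

    def test_count_matches_independent_recursion(self):
        seq = RnaSequence("GAAACGAAAC")

        # independent count: case analysis on the pairing of position 0
        def count(i, j, allowed):
            if i >= j:
                return 1
            total = count(i + 1, j, allowed)  # i unpaired
            for k in range(i + 4, j + 1):
                if allowed(i, k):
                    total += count(i + 1, k - 1, allowed) * count(k + 1, j, allowed)
            return total

        canon = {"GC", "CG", "AU", "UA", "GU", "UG"}
        allowed = lambda i, j: seq[i] + seq[j] in canon
        assert len(enumerate_structures(seq)) == count(0, seq.n - 1, allowed)

    def test_forced_pair_removes_empty_structure(self):
        structs = enumerate_structures(
            RnaSequence("GAAAC"), FoldConstraints(frozenset({BasePair(0, 4)}))
        )
        assert [s.as_tuples() for s in structs] == [[(0, 4)]]


class TestOracleEquivalence:
    def test_random_sequences_and_constraints(self, rng):
        """DP probabilities equal Boltzmann frequencies from enumeration."""
        for trial in range(25):
            seq = random_rna(rng, int(rng.integers(8, 19)))
            constraints = None
            m0 = fold_bpp(seq)
            candidates = np.argwhere(m0.p > 0.05)
            if trial % 2 and len(candidates):
                u, v = candidates[rng.integers(0, len(candidates))]
                u, v = int(min(u, v)), int(max(u, v))
                pos = int(rng.integers(0, seq.n))
                forbid = frozenset({pos}) if pos not in (u, v) else frozenset()
                constraints = FoldConstraints(frozenset({BasePair(u, v)}), forbid)
            try:
                m = fold_bpp(seq, constraints)
            except FoldError:
                continue  # over-constrained draw
            expected = oracle_bpp(seq, constraints)
            assert np.abs(m.p - expected).max() < 1e-9


class TestConstrainedLevelBpps:
    def test_empty_structure_gives_single_unconstrained_matrix(self):
        seq = RnaSequence("GGGAAAUCCC")
        out = constrained_level_bpps(seq, None)
        assert len(out) == 1
        assert np.allclose(out[0].p, fold_bpp(seq).p)

    def test_single_level_forces_its_pairs(self):
        seq = RnaSequence("GGGAAAUCCC")
        layered = LayeredStructure([SecondaryStructure([(0, 9)], 10)])
        out = constrained_level_bpps(seq, layered)
        assert len(out) == 1 and out[0][0, 9] == 1.0

    def test_two_levels_forbid_each_other(self):
        seq = RnaSequence("GGAAGGAACCAACCAAAAAA")
        layered = LayeredStructure(
            [
                SecondaryStructure([(0, 9), (1, 8)], 20),
                SecondaryStructure([(4, 13), (5, 12)], 20),
            ]
        )
        m1, m2 = constrained_level_bpps(seq, layered)
        for pos in (4, 5, 12, 13):
            assert np.all(m1.p[pos] == 0)
        for pos in (0, 1, 8, 9):
            assert np.all(m2.p[pos] == 0)
        assert m1[0, 9] == m1[1, 8] == 1.0
        assert m2[4, 13] == m2[5, 12] == 1.0


class TestSumPseudoBpp:
    def test_single_matrix_identity(self):
        m = fold_bpp(RnaSequence("GGGAAAUCCC"))
        s = sum_pseudo_bpp([m])
        assert np.array_equal(s.p, m.p)

    def test_entrywise_sum(self):
        a = BppMatrix(np.zeros((12, 12)))
        b = BppMatrix(np.zeros((12, 12)))
        a.p[2, 9] = a.p[9, 2] = 0.4
        b.p[2, 9] = b.p[9, 2] = 0.3
        s = sum_pseudo_bpp([a, b])
        assert s[2, 9] == pytest.approx(0.7)

    def test_empty_list_is_an_error(self):
        with pytest.raises(StructureError):
            sum_pseudo_bpp([])

    def test_dimension_mismatch(self):
        with pytest.raises(StructureError):
            sum_pseudo_bpp([BppMatrix(np.zeros((4, 4))), BppMatrix(np.zeros((5, 5)))])


class TestBppTriplets:
    def test_roundtrip(self, rng):
        m = fold_bpp(random_rna(rng, 15))
        back = BppMatrix.from_triplets(m.to_triplets(), 15)
        assert np.abs(back.p - m.p).max() < 1e-12


class TestAlignmentBpp:
    def test_identical_rows_equal_single_sequence(self):
        seq = "GCCGAAAGGC"
        aln = Alignment([seq, seq, seq])
        assert np.array_equal(alignment_bpp(aln).p, fold_bpp(RnaSequence(seq)).p)

    def test_single_row_equals_fold(self):
        seq = "GGGAAAUCCC"
        assert np.array_equal(
            alignment_bpp(Alignment([seq])).p, fold_bpp(RnaSequence(seq)).p
        )

    def test_compensatory_substitution_raises_probability(self):
        seq = "GCCGAAAGGC"
        # G-C at columns (2, 7) replaced by A-U in one row
        comp = "GCAGAAAUGC"
        single = fold_bpp(RnaSequence(seq))
        consensus = alignment_bpp(Alignment([seq, comp, seq]))
        assert consensus[2, 7] > single[2, 7]

    def test_gap_projection(self):
        # target row has a gap; probabilities are on ungapped coordinates
        aln = Alignment(["GCCGAAA-GGC", "GCCGAAAAGGC"], target_row=0)
        m = alignment_bpp(aln)
        assert m.n == 10
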