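import numpy as np
import pytest

from knotmotif.bpp_engine import PseudoBpp, fold_bpp, sum_pseudo_bpp
from knotmotif.ip_optimizer import (
    CandidatePair,
    CandidatePairSet,
    IpError,
    IpModelSpec,
    IpSolution,
    brute_force_optimize,
    build_model,
    collect_candidate_pairs,
    solve_ip,
    validate_solution,
)
from knotmotif.motif_catalog import CandidatePlacement, Motif
from knotmotif.structure_core import (
    LayeredStructure,
    RnaSequence,
    SecondaryStructure,
)

from conftest import random_rna


def _pbpp(n, entries):
    p = np.zeros((n, n))
    for (i, j, v) in entries:
        p[i, j] = p[j, i] = v
    return PseudoBpp(p)


def _random_instance(rng, with_placements=True):
    """A small random instance shared by the optimality cross-checks."""
    n = int(rng.integers(10, 15))
    seq = random_rna(rng, n)
    from knotmotif.structure_core import BasePair, is_canonical_or_wobble

    cands = []
    for u in range(n):
        for v in range(u + 4, n):
            if is_canonical_or_wobble(seq, BasePair(u, v)) and rng.random() < 0.7:
                cands.append((u, v, float(np.round(rng.random(), 3))))
    cands = cands[:12]
    placements = []
    if with_placements:
        for k in range(int(rng.integers(0, 5))):
            a = int(rng.integers(0, n - 3))
            b = min(n - 1, a + int(rng.integers(1, 4)))
            pat = seq.residues[a : b + 1]
            placements.append(CandidatePlacement(Motif(f"M{k}", "cls", (pat,)), 1, a, b))
    spec = IpModelSpec(
        n=n,
        m=int(rng.choice([1, 2])),
        B=CandidatePairSet(cands),
        placements=placements,
        alpha=float(rng.choice([0.0, 0.1, 0.5])),
        min_paired_fraction=float(rng.choice([0.0, 0.25])),
    )
    return seq, spec


class TestCollectCandidatePairs:
    def test_zero_matrix_gives_empty_set(self):
        B = collect_candidate_pairs(_pbpp(10, []), RnaSequence("GGGAAAUCCC"), 0.1)
        assert len(B) == 0

    def test_pair_above_threshold_kept(self):
        B = collect_candidate_pairs(
            _pbpp(10, [(0, 9, 0.8)]), RnaSequence("GGGAAAUCCC"), 0.1
        )
        assert list(B) == [CandidatePair(0, 9, 0.8)]

    def test_noncanonical_pair_excluded(self):
        B = collect_candidate_pairs(
            _pbpp(10, [(0, 4, 0.9)]), RnaSequence("AAAACAAAAA"), 0.1
        )
        assert len(B) == 0

    def test_short_range_excluded(self):
        B = collect_candidate_pairs(
            _pbpp(10, [(0, 3, 0.9)]), RnaSequence("GAACAAAAAA"), 0.1
        )
        assert len(B) == 0


class TestBuildModel:
    def test_alpha_zero_fixes_insertions_off(self):
        motif = Motif("HP", "c", ("AAAA",))
        spec = IpModelSpec(
            n=12,
            m=1,
            B=CandidatePairSet([(0, 11, 0.9), (1, 10, 0.8)]),
            placements=[CandidatePlacement(motif, 1, 4, 7)],
            alpha=0.0,
            min_paired_fraction=0.0,
        )
        model = build_model(spec)
        assert all(model.objective[k] == 0 for k in model.c_index.values())
        sol = solve_ip(model)
        assert sol.insertions == []

    def test_objective_coefficient_scale_beta(self):
        spec = IpModelSpec(
            n=12, m=1, B=CandidatePairSet([(0, 11, 0.6)]), min_paired_fraction=0.0
        )
        model = build_model(spec)
        (k,) = model.d_index.values()
        assert model.objective[k] == pytest.approx(10 * 0.5 * 0.6)

    def test_two_strand_motif_gets_linkage_constraints(self):
        motif = Motif("IL", "c", ("GA", "UC"))
        spec = IpModelSpec(
            n=14,
            m=1,
            B=CandidatePairSet([(0, 13, 0.9)]),
            placements=[
                CandidatePlacement(motif, 1, 1, 2),
                CandidatePlacement(motif, 2, 10, 11),
            ],
            alpha=0.5,
            min_paired_fraction=0.0,
        )
        model = build_model(spec)
        names = [c[0] for c in model.constraints]
        assert any(name.startswith("match_out_IL") for name in names)
        assert any(name.startswith("match_in_IL") for name in names)
        # one forward junction (strand 1 -> 2) and one cyclic closure (2 -> 1)
        assert len(model.y_index) == 2

    def test_beta_table_bounds_m(self):
        with pytest.raises(IpError):
            IpModelSpec(n=10, m=5, B=CandidatePairSet([]))

    def test_lp_export_contains_variables(self):
        spec = IpModelSpec(
            n=12, m=1, B=CandidatePairSet([(0, 11, 0.6)]), min_paired_fraction=0.0
        )
        lp = build_model(spec).to_lp()
        assert "Maximize" in lp and "D_0_11_1" in lp and "Binary" in lp


class TestSolveIp:
    def test_all_a_sequence_with_bound_is_infeasible(self):
        spec = IpModelSpec(n=12, m=1, B=CandidatePairSet([]), min_paired_fraction=0.25)
        sol = solve_ip(build_model(spec))
        assert sol.status == "infeasible"

    def test_unknown_backend(self):
        spec = IpModelSpec(n=12, m=1, B=CandidatePairSet([]), min_paired_fraction=0.0)
        with pytest.raises(IpError, match="backend"):
            solve_ip(build_model(spec), backend="cplex")

    def test_objective_recomputable_from_assignment(self, rng):
        from knotmotif.ip_optimizer import recompute_objective

        for _ in range(10):
            _, spec = _random_instance(rng)
            sol = solve_ip(build_model(spec))
            if sol.status == "optimal":
                assert abs(recompute_objective(spec, sol) - sol.objective) < 1e-6

    def test_matches_exhaustive_on_simple_hairpin(self):
        seq = RnaSequence("GGGGAAAACCCC")
        pbpp = sum_pseudo_bpp([fold_bpp(seq)])
        B = collect_candidate_pairs(pbpp, seq, 0.01)
        spec = IpModelSpec(n=seq.n, m=1, B=B, alpha=0.0)
        sol = solve_ip(build_model(spec))
        bf = brute_force_optimize(spec)
        assert sol.objective == pytest.approx(bf.objective, abs=1e-6)


class TestValidateSolution:
    def _spec(self, n=20, pairs=(), placements=(), m=2, frac=0.0):
        return IpModelSpec(
            n=n,
            m=m,
            B=CandidatePairSet(list(pairs)),
            placements=list(placements),
            min_paired_fraction=frac,
        )

    def test_crossing_within_level(self):
        sol = IpSolution(
            LayeredStructure(
                [SecondaryStructure([], 20), SecondaryStructure([], 20)], 20
            ),
            [],
            0.0,
            "optimal",
        )
        # build an intentionally broken layered structure via direct surgery
        from knotmotif.structure_core import BasePair

        bad = SecondaryStructure([(0, 9), (1, 8)], 20)
        bad.pairs = frozenset({BasePair(0, 9), BasePair(4, 13)})
        sol.pairs_by_level.levels[0] = bad
        report = validate_solution(sol, self._spec())
        assert any("crossing within level" in v for v in report)

    def test_uncrossed_upper_level_pair(self):
        sol = IpSolution(
            LayeredStructure(
                [
                    SecondaryStructure([(0, 9), (1, 8)], 20),
                    SecondaryStructure([(11, 18), (12, 17)], 20),
                ],
                20,
            ),
            [],
            0.0,
            "optimal",
        )
        report = validate_solution(
            sol, self._spec(pairs=[(0, 9, 1), (1, 8, 1), (11, 18, 1), (12, 17, 1)])
        )
        assert any("uncrossed upper-level pair" in v for v in report)

    def test_lonely_pair(self):
        sol = IpSolution(
            LayeredStructure([SecondaryStructure([(0, 9)], 20)], 20),
            [],
            0.0,
            "optimal",
        )
        report = validate_solution(sol, self._spec(pairs=[(0, 9, 1)], m=1))
        assert any("lonely pair" in v for v in report)

    def test_unanchored_hairpin_strand(self):
        motif = Motif("HP", "c", ("AAAAA",))
        sol = IpSolution(
            LayeredStructure([SecondaryStructure([], 20)], 20),
            [CandidatePlacement(motif, 1, 4, 8)],
            0.0,
            "optimal",
        )
        report = validate_solution(sol, self._spec(m=1))
        assert any("unanchored" in v for v in report)

    def test_anchored_hairpin_passes(self):
        motif = Motif("HP", "c", ("AAAAA",))
        sol = IpSolution(
            LayeredStructure(
                [SecondaryStructure([(3, 9), (2, 10)], 20)], 20
            ),
            [CandidatePlacement(motif, 1, 4, 8)],
            0.0,
            "optimal",
        )
        report = validate_solution(
            sol, self._spec(pairs=[(3, 9, 1), (2, 10, 1)], m=1)
        )
        assert report == []

    def test_pair_inside_inserted_strand(self):
        motif = Motif("HP", "c", ("A" * 10,))
        sol = IpSolution(
            LayeredStructure(
                [SecondaryStructure([(4, 13), (5, 12), (3, 14), (2, 15)], 20)], 20
            ),
            [CandidatePlacement(motif, 1, 3, 12)],
            0.0,
            "optimal",
        )
        report = validate_solution(
            sol,
            self._spec(pairs=[(4, 13, 1), (5, 12, 1), (3, 14, 1), (2, 15, 1)], m=1),
        )
        assert any("inside inserted strand" in v for v in report)


class TestBruteForce:
    def test_empty_instance(self):
        spec = IpModelSpec(n=10, m=1, B=CandidatePairSet([]), min_paired_fraction=0.0)
        sol = brute_force_optimize(spec)
        assert sol.objective == 0.0 and sol.insertions == []

    def test_two_stacked_pairs_arithmetic(self):
        spec = IpModelSpec(
            n=10,
            m=1,
            B=CandidatePairSet([(0, 9, 0.8), (1, 8, 0.7)]),
            alpha=0.0,
            min_paired_fraction=0.0,
        )
        sol = brute_force_optimize(spec)
        assert sol.objective == pytest.approx(10 * 0.5 * 1.5)

    def test_bound_enforced(self):
        B = CandidatePairSet([(i, i + 5, 0.5) for i in range(0, 40, 2)])
        with pytest.raises(IpError, match="bound"):
            brute_force_optimize(IpModelSpec(n=50, m=1, B=B))

    def test_agrees_with_solver_on_random_instances(self, rng):
        for _ in range(30):
            _, spec = _random_instance(rng)
            bf = brute_force_optimize(spec)
            sol = solve_ip(build_model(spec))
            if bf.status == "infeasible":
                assert sol.status == "infeasible"
            else:
                assert sol.objective == pytest.approx(bf.objective, abs=1e-6)


class TestObjectiveMonotonicity:
    def test_adding_a_placement_never_decreases_optimum(self, rng):
        for _ in range(10):
            _, spec = _random_instance(rng, with_placements=False)
            spec.alpha = 0.3
            base = brute_force_optimize(spec).objective
            seq_len = spec.n
            motif = Motif("EXTRA", "c", ("**",))
            spec2 = IpModelSpec(
                n=spec.n,
                m=spec.m,
                B=spec.B,
                placements=[CandidatePlacement(motif, 1, 0, 1)],
                alpha=0.3,
                min_paired_fraction=spec.min_paired_fraction,
            )
            richer = brute_force_optimize(spec2).objective
            assert richer >= base - 1e-9

    def test_alpha_zero_never_inserts(self, rng):
        for _ in range(10):
            _, spec = _random_instance(rng)
            spec.alpha = 0.0
            sol = solve_ip(build_model(spec))
            assert sol.insertions == []

    def test_increasing_alpha_never_shrinks_inserted_size(self):
        motif = Motif("HP", "c", ("AAAA",))
        B = CandidatePairSet([(3, 8, 0.9), (2, 9, 0.8)])
        sizes = []
        for alpha in (0.0, 0.1, 0.5, 2.0):
            spec = IpModelSpec(
                n=12,
                m=1,
                B=B,
                placements=[CandidatePlacement(motif, 1, 4, 7)],
                alpha=alpha,
                min_paired_fraction=0.0,
            )
            sol = brute_force_optimize(spec)
            sizes.append(sum(p.motif.size for p in sol.insertions))
        assert sizes == sorted(sizes)
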