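"""Integer program for joint base-pair / motif-insertion optimization.

Variables
---------
``D[u,v,q]``
    binary, 1 iff positions ``u < v`` pair at level ``q`` (level 1 holds the
    dominant knot-free structure, higher levels hold pairs crossing all
    lower levels).  One variable per candidate pair (pseudo-probability
    above threshold, canonical/Wobble, ``v - u > 3``) and level.
``C[x,i,k,l]``
    binary, 1 iff strand ``i`` of motif ``x`` is inserted over the closed
    interval ``[k, l]``.
``Y[p -> p']``
    auxiliary binaries pairing consecutive-strand placements of the same
    motif into occurrences (junction matching); order-preservation
    constraints force the r-th selected occurrence of each strand to be
    matched in sequence order.

Objective (maximized)::

    10 * sum_q beta_q * sum_(u,v) p(u,v) * D[u,v,q]
       + alpha * sum_(strand-1 placements) weight * |x|^2 * C[x,1,k,l]

with beta = (0.5, 0.25, 0.125, 0.0625).  The factor 10 normalizes the scale
between pairing probabilities and motif bonuses so that alpha is easy to
calibrate; the squared motif size |x|^2 favors few large motifs over many
small ones.  At alpha = 0 the insertion variables are fixed to zero and the
model reduces to the IPknot-style pure base-pair program.

Constraints: (a) each position in at most one pair; (b) no crossing within
a level; (c) each level-q pair crosses at least one selected pair in every
lower level; (d) no lonely pairs — a pair needs a stacked neighbor
(i-1,j+1) or (i+1,j-1) at its own level; (f) at least ``min_paired_fraction``
of positions paired; (g) motif strand linkage via the Y matching; (h) each
junction between consecutive strands (cyclically) anchored by a level-1
pair, stacked or overlapping by one; (i) no pair endpoint strictly inside
an inserted strand, and inserted intervals pairwise disjoint.

The default solver backend is HiGHS through :func:`scipy.optimize.milp`
(deterministic); every returned solution is re-checked by the independent
:func:`validate_solution` before being reported.  A brute-force optimizer
over tiny instances serves as an exactness oracle in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .bpp_engine import PseudoBpp
from .motif_catalog import CandidatePlacement
from .structure_core import (
    MIN_LOOP_SEP,
    BasePair,
    LayeredStructure,
    RnaSequence,
    SecondaryStructure,
    StructureError,
    is_canonical_or_wobble,
)

__all__ = [
    "CandidatePair",
    "CandidatePairSet",
    "IpModelSpec",
    "IpModel",
    "IpSolution",
    "IpError",
    "DEFAULT_BETA",
    "DEFAULT_SCALE",
    "collect_candidate_pairs",
    "build_model",
    "solve_ip",
    "validate_solution",
    "brute_force_optimize",
]

DEFAULT_BETA: tuple[float, ...] = (0.5, 0.25, 0.125, 0.0625)
DEFAULT_SCALE = 10.0


class IpError(StructureError):
    """Ill-formed IP specification or solver failure."""


@dataclass(frozen=True, order=True)
class CandidatePair:
    u: int
    v: int
    p: float


class CandidatePairSet:
    """The set B of scored candidate pairs, deterministically ordered."""

    def __init__(self, pairs: Sequence[CandidatePair | tuple[int, int, float]]):
        items = [p if isinstance(p, CandidatePair) else CandidatePair(*p) for p in pairs]
        self.pairs: list[CandidatePair] = sorted(items, key=lambda c: (c.u, c.v))
        seen = {(c.u, c.v) for c in self.pairs}
        if len(seen) != len(self.pairs):
            raise IpError("duplicate candidate pair")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def index_of(self) -> dict[tuple[int, int], int]:
        return {(c.u, c.v): k for k, c in enumerate(self.pairs)}


def collect_candidate_pairs(
    pbpp: PseudoBpp, seq: RnaSequence, threshold: float = 0.01
) -> CandidatePairSet:
    """Candidate pairs: pseudo-probability >= threshold, canonical, v-u > 3."""
    if threshold < 0:
        raise IpError("threshold must be >= 0")
    out = []
    for u in range(seq.n):
        for v in range(u + MIN_LOOP_SEP + 1, seq.n):
            p = float(pbpp[u, v])
            if p >= threshold and p > 0 and is_canonical_or_wobble(seq, BasePair(u, v)):
                out.append(CandidatePair(u, v, p))
    return CandidatePairSet(out)


@dataclass
class IpModelSpec:
    """Everything needed to instantiate the integer program."""

    n: int
    m: int
    B: CandidatePairSet
    placements: list[CandidatePlacement] = field(default_factory=list)
    alpha: float = 0.1
    beta: tuple[float, ...] = DEFAULT_BETA
    scale: float = DEFAULT_SCALE
    min_paired_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.m < 1 or self.m > len(self.beta):
            raise IpError(f"m={self.m} outside 1..{len(self.beta)} supported levels")
        if any(b2 >= b1 for b1, b2 in zip(self.beta, self.beta[1:])):
            raise IpError("beta weights must be strictly decreasing")
        if self.alpha < 0:
            raise IpError("alpha must be >= 0")
        self.placements = sorted(self.placements, key=CandidatePlacement.sort_key)


# ---------------------------------------------------------------------------
# Model assembly


@dataclass
class IpModel:
    """Solver-agnostic model: binary variables, linear objective/constraints."""

    spec: IpModelSpec
    var_names: list[str]
    objective: np.ndarray  # maximization coefficients
    constraints: list[tuple[str, dict[int, float], float, float]]  # name, coefs, lb, ub
    d_index: dict[tuple[int, int, int], int]  # (u, v, q) -> column
    c_index: dict[int, int]  # placement position in spec.placements -> column
    y_index: dict[tuple[int, int], int]  # (placement idx, placement idx) -> column

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    def to_lp(self) -> str:
        """Export in CPLEX LP format for debugging."""
        terms = [
            f"{'+' if c >= 0 else '-'} {abs(c):.12g} {self.var_names[k]}"
            for k, c in enumerate(self.objective)
            if c != 0
        ]
        lines = ["Maximize", " obj: " + " ".join(terms) if terms else " obj: 0 x0"]
        lines.append("Subject To")
        for name, coefs, lb, ub in self.constraints:
            expr = " ".join(
                f"{'+' if c >= 0 else '-'} {abs(c):.12g} {self.var_names[k]}"
                for k, c in sorted(coefs.items())
            )
            if ub < np.inf:
                lines.append(f" {name}_ub: {expr} <= {ub:.12g}")
            if lb > -np.inf:
                lines.append(f" {name}_lb: {expr} >= {lb:.12g}")
        lines.append("Binary")
        lines.append(" " + " ".join(self.var_names))
        lines.append("End")
        return "\n".join(lines) + "\n"


def _junction_anchor_pairs(
    a: int, b: int, n: int
) -> list[tuple[int, int]]:
    """Level-1 anchor candidates for a junction with 3' end a and 5' end b.

    For consecutive strands (a = end of strand s, b = start of strand s+1,
    a < b) the anchors are the stacked pair (a+1, b-1) and the one-position
    overlap pair (a, b).  For the cyclic closure (a = start of strand 1,
    b = end of the last strand, enclosing) the caller passes the enclosing
    orientation directly.
    """
    out = []
    for (i, j) in ((a + 1, b - 1), (a, b)):
        if 0 <= i < j < n and j - i > MIN_LOOP_SEP:
            out.append((i, j))
    return out


def _enclosing_anchor_pairs(k: int, l: int, n: int) -> list[tuple[int, int]]:
    """Anchors enclosing an occurrence spanning [k, l]: (k-1, l+1) or (k, l)."""
    out = []
    for (i, j) in ((k - 1, l + 1), (k, l)):
        if 0 <= i < j < n and j - i > MIN_LOOP_SEP:
            out.append((i, j))
    return out


def build_model(spec: IpModelSpec) -> IpModel:
    """Assemble variables, objective and constraints (deterministic order)."""
    n, m = spec.n, spec.m
    pairs = spec.B.pairs
    pair_idx = spec.B.index_of()

    var_names: list[str] = []
    d_index: dict[tuple[int, int, int], int] = {}
    for q in range(1, m + 1):
        for c in pairs:
            d_index[(c.u, c.v, q)] = len(var_names)
            var_names.append(f"D_{c.u}_{c.v}_{q}")
    c_index: dict[int, int] = {}
    for pi, pl in enumerate(spec.placements):
        c_index[pi] = len(var_names)
        var_names.append(f"C_{pl.motif.id}_{pl.strand_index}_{pl.start}_{pl.end}")

    # junction matching variables between consecutive strands (cyclic)
    by_motif: dict[str, dict[int, list[int]]] = {}
    motif_of: dict[str, CandidatePlacement] = {}
    for pi, pl in enumerate(spec.placements):
        by_motif.setdefault(pl.motif.id, {}).setdefault(pl.strand_index, []).append(pi)
        motif_of[pl.motif.id] = pl
    y_index: dict[tuple[int, int], int] = {}
    junctions: list[tuple[str, int, int, list[tuple[int, int]]]] = []
    # (motif id, strand s, strand s', [(pi, pj), ...]) for each junction
    for mid in sorted(by_motif):
        strands = motif_of[mid].motif.n_strands
        if strands == 1:
            continue
        for s in range(1, strands + 1):
            s2 = s + 1 if s < strands else 1
            compat: list[tuple[int, int]] = []
            for pi in by_motif[mid].get(s, []):
                for pj in by_motif[mid].get(s2, []):
                    a, b = spec.placements[pi], spec.placements[pj]
                    if s < strands:
                        ok = a.end < b.start
                    else:  # cyclic closure: strand 1 of the occurrence precedes strand J
                        ok = b.end < a.start
                    if ok:
                        compat.append((pi, pj))
            for (pi, pj) in sorted(compat):
                y_index[(pi, pj)] = len(var_names)
                var_names.append(f"Y_{mid}_{s}to{s2}_{pi}_{pj}")
            junctions.append((mid, s, s2, sorted(compat)))

    nv = len(var_names)
    obj = np.zeros(nv)
    for q in range(1, m + 1):
        bq = spec.beta[q - 1]
        for c in pairs:
            obj[d_index[(c.u, c.v, q)]] = spec.scale * bq * c.p
    if spec.alpha > 0:
        for pi, pl in enumerate(spec.placements):
            if pl.strand_index == 1:
                obj[c_index[pi]] = spec.alpha * pl.weight * pl.motif.size**2

    cons: list[tuple[str, dict[int, float], float, float]] = []

    def add(name: str, coefs: dict[int, float], lb: float, ub: float) -> None:
        if coefs:
            cons.append((name, coefs, lb, ub))

    # (a) each position in at most one pair, across all levels
    for t in range(n):
        coefs = {
            d_index[(c.u, c.v, q)]: 1.0
            for c in pairs
            if t in (c.u, c.v)
            for q in range(1, m + 1)
        }
        add(f"pos{t}", coefs, -np.inf, 1.0)

    # (b) no crossing within a level
    for ci in range(len(pairs)):
        for cj in range(ci + 1, len(pairs)):
            a, b = pairs[ci], pairs[cj]
            if BasePair(a.u, a.v).crosses(BasePair(b.u, b.v)):
                for q in range(1, m + 1):
                    add(
                        f"cross_{a.u}_{a.v}_{b.u}_{b.v}_q{q}",
                        {d_index[(a.u, a.v, q)]: 1.0, d_index[(b.u, b.v, q)]: 1.0},
                        -np.inf,
                        1.0,
                    )

    # (c) a level-q pair must cross >= 1 selected pair in every lower level
    for q in range(2, m + 1):
        for c in pairs:
            bp = BasePair(c.u, c.v)
            crossers = [d for d in pairs if bp.crosses(BasePair(d.u, d.v))]
            for ql in range(1, q):
                coefs = {d_index[(c.u, c.v, q)]: 1.0}
                for d in crossers:
                    coefs[d_index[(d.u, d.v, ql)]] = -1.0
                add(f"hier_{c.u}_{c.v}_q{q}_l{ql}", coefs, -np.inf, 0.0)

    # (d) no lonely pairs: a selected pair needs a stacked neighbor at its level
    for q in range(1, m + 1):
        for c in pairs:
            coefs = {d_index[(c.u, c.v, q)]: 1.0}
            for (nu, nv) in ((c.u - 1, c.v + 1), (c.u + 1, c.v - 1)):
                if (nu, nv) in pair_idx:
                    coefs[d_index[(nu, nv, q)]] = -1.0
            add(f"stack_{c.u}_{c.v}_q{q}", coefs, -np.inf, 0.0)

    # (f) at least min_paired_fraction of positions in a base pair
    if spec.min_paired_fraction > 0:
        coefs = {k: 2.0 for k in d_index.values()}
        # an empty candidate set leaves the bound unsatisfiable; keep the
        # (infeasible) constraint representable via an impossible empty model
        cons.append(
            ("min_paired", coefs, spec.min_paired_fraction * n, np.inf)
        )

    # (g, h) junction matching: every selected strand placement is matched
    # exactly once per junction it participates in, matches are anchored by
    # a level-1 pair, and the matching is order-preserving.
    for (mid, s, s2, compat) in junctions:
        outgoing: dict[int, list[int]] = {}
        incoming: dict[int, list[int]] = {}
        for (pi, pj) in compat:
            outgoing.setdefault(pi, []).append(y_index[(pi, pj)])
            incoming.setdefault(pj, []).append(y_index[(pi, pj)])
        for pi in by_motif[mid].get(s, []):
            coefs = {y: 1.0 for y in outgoing.get(pi, [])}
            coefs[c_index[pi]] = coefs.get(c_index[pi], 0.0) - 1.0
            add(f"match_out_{mid}_{s}_{pi}", coefs, 0.0, 0.0)
        for pj in by_motif[mid].get(s2, []):
            coefs = {y: 1.0 for y in incoming.get(pj, [])}
            coefs[c_index[pj]] = coefs.get(c_index[pj], 0.0) - 1.0
            add(f"match_in_{mid}_{s}_{pj}", coefs, 0.0, 0.0)
        # order preservation: no two selected matches may cross
        for (p1, p2), (q1, q2) in itertools.combinations(compat, 2):
            s1a, s1b = spec.placements[p1].start, spec.placements[q1].start
            s2a, s2b = spec.placements[p2].start, spec.placements[q2].start
            if (s1a - s1b) * (s2a - s2b) < 0:
                add(
                    f"order_{mid}_{s}_{p1}_{p2}_{q1}_{q2}",
                    {y_index[(p1, p2)]: 1.0, y_index[(q1, q2)]: 1.0},
                    -np.inf,
                    1.0,
                )
        # anchoring: a match requires one of its level-1 anchor pairs
        for (pi, pj) in compat:
            a, b = spec.placements[pi], spec.placements[pj]
            if s < motif_of[mid].motif.n_strands:
                anchors = _junction_anchor_pairs(a.end, b.start, n)
            else:
                anchors = _enclosing_anchor_pairs(b.start, a.end, n)
            coefs = {y_index[(pi, pj)]: 1.0}
            found = False
            for (i, j) in anchors:
                if (i, j) in pair_idx:
                    coefs[d_index[(i, j, 1)]] = -1.0
                    found = True
            if not found:
                add(f"anchor_{mid}_{s}_{pi}_{pj}", {y_index[(pi, pj)]: 1.0}, -np.inf, 0.0)
            else:
                add(f"anchor_{mid}_{s}_{pi}_{pj}", coefs, -np.inf, 0.0)

    # (h) hairpins anchor directly on their own interval
    for pi, pl in enumerate(spec.placements):
        if pl.motif.n_strands == 1:
            anchors = _enclosing_anchor_pairs(pl.start, pl.end, n)
            coefs = {c_index[pi]: 1.0}
            found = False
            for (i, j) in anchors:
                if (i, j) in pair_idx:
                    coefs[d_index[(i, j, 1)]] = -1.0
                    found = True
            if found:
                add(f"hairpin_anchor_{pi}", coefs, -np.inf, 0.0)
            else:
                add(f"hairpin_anchor_{pi}", {c_index[pi]: 1.0}, -np.inf, 0.0)

    # (i) clash: no pair endpoint strictly inside a selected strand interval
    for pi, pl in enumerate(spec.placements):
        inside = [
            d_index[(c.u, c.v, q)]
            for c in pairs
            if pl.start < c.u < pl.end or pl.start < c.v < pl.end
            for q in range(1, m + 1)
        ]
        if inside:
            big = float(len(inside))
            coefs = {k: 1.0 for k in inside}
            coefs[c_index[pi]] = big
            add(f"clash_{pi}", coefs, -np.inf, big)

    # (i) inserted intervals pairwise disjoint
    for pi, pj in itertools.combinations(range(len(spec.placements)), 2):
        a, b = spec.placements[pi], spec.placements[pj]
        if a.start <= b.end and b.start <= a.end:
            add(
                f"disjoint_{pi}_{pj}",
                {c_index[pi]: 1.0, c_index[pj]: 1.0},
                -np.inf,
                1.0,
            )

    # alpha = 0 reduction: insertion machinery fixed off
    if spec.alpha == 0:
        for pi in c_index:
            add(f"alpha0_C_{pi}", {c_index[pi]: 1.0}, -np.inf, 0.0)

    return IpModel(spec, var_names, obj, cons, d_index, c_index, y_index)


# ---------------------------------------------------------------------------
# Solving


@dataclass
class IpSolution:
    pairs_by_level: LayeredStructure
    insertions: list[CandidatePlacement]
    objective: float
    status: str  # optimal | feasible | infeasible | timeout
    trace: dict = field(default_factory=dict)

    def canonical_key(self) -> tuple:
        """Floating-point-free identity used for iteration convergence."""
        return (
            tuple(tuple(lvl.as_tuples()) for lvl in self.pairs_by_level.levels),
            tuple(
                (p.motif.id, p.strand_index, p.start, p.end) for p in
                sorted(self.insertions, key=CandidatePlacement.sort_key)
            ),
        )


def recompute_objective(spec: IpModelSpec, solution: IpSolution) -> float:
    """Objective value implied by a solution's selected variables."""
    score = {(c.u, c.v): c.p for c in spec.B}
    total = 0.0
    for q, lvl in enumerate(solution.pairs_by_level.levels, start=1):
        for p in lvl.pairs:
            total += spec.scale * spec.beta[q - 1] * score[(p.i, p.j)]
    if spec.alpha > 0:
        for pl in solution.insertions:
            if pl.strand_index == 1:
                total += spec.alpha * pl.weight * pl.motif.size**2
    return total


def _empty_solution(spec: IpModelSpec, status: str) -> IpSolution:
    levels = [SecondaryStructure([], spec.n) for _ in range(spec.m)]
    return IpSolution(LayeredStructure(levels, spec.n), [], 0.0, status)


def solve_ip(
    model: IpModel,
    backend: str = "highs",
    time_limit_s: float = 10000.0,
    seed: int = 0,
) -> IpSolution:
    """Solve through the selected backend and verify the result.

    The returned assignment is re-checked against the independent validator
    before being reported; a first-found optimal solution is returned (the
    HiGHS backend is deterministic for a fixed model).
    """
    if backend != "highs":
        raise IpError(f"unknown solver backend {backend!r}")
    spec = model.spec
    if model.n_vars == 0:
        if spec.min_paired_fraction > 0 and spec.n > 0:
            return _empty_solution(spec, "infeasible")
        return _empty_solution(spec, "optimal")

    rows, cols, vals, lbs, ubs = [], [], [], [], []
    for r, (_, coefs, lb, ub) in enumerate(model.constraints):
        for k, c in coefs.items():
            rows.append(r)
            cols.append(k)
            vals.append(c)
        lbs.append(lb)
        ubs.append(ub)
    constraints = []
    if model.constraints:
        A = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(model.constraints), model.n_vars)
        )
        constraints = [LinearConstraint(A, np.array(lbs), np.array(ubs))]

    res = milp(
        c=-model.objective,
        constraints=constraints,
        integrality=np.ones(model.n_vars),
        bounds=Bounds(0, 1),
        options={"time_limit": max(time_limit_s, 0.01)},
    )
    if res.status == 2 or (res.x is None and res.status != 0):
        status = "timeout" if res.status == 1 else "infeasible"
        return _empty_solution(spec, status)
    x = np.round(res.x).astype(int)
    status = "optimal" if res.status == 0 else "feasible"

    level_pairs: list[list[tuple[int, int]]] = [[] for _ in range(spec.m)]
    for (u, v, q), k in model.d_index.items():
        if x[k] == 1:
            level_pairs[q - 1].append((u, v))
    insertions = [
        spec.placements[pi] for pi, k in sorted(model.c_index.items()) if x[k] == 1
    ]
    layered = LayeredStructure(
        [SecondaryStructure(lp, spec.n) for lp in level_pairs], spec.n
    )
    sol = IpSolution(layered, insertions, 0.0, status)
    sol.objective = recompute_objective(spec, sol)
    if abs(sol.objective - float(-res.fun)) > 1e-6:
        raise IpError(
            f"objective mismatch: solver {-res.fun:.9g} vs recomputed {sol.objective:.9g}"
        )
    violations = validate_solution(sol, spec)
    if violations:
        raise IpError(f"solver returned an invalid assignment: {violations}")
    return sol


# ---------------------------------------------------------------------------
# Independent validation


def _occurrence_groups(
    insertions: list[CandidatePlacement],
) -> dict[str, dict[int, list[CandidatePlacement]]]:
    groups: dict[str, dict[int, list[CandidatePlacement]]] = {}
    for pl in insertions:
        groups.setdefault(pl.motif.id, {}).setdefault(pl.strand_index, []).append(pl)
    for strands in groups.values():
        for lst in strands.values():
            lst.sort(key=lambda p: p.start)
    return groups


def validate_solution(
    solution: IpSolution, spec: IpModelSpec, seq: Optional[RnaSequence] = None
) -> list[str]:
    """Independent semantic check of a solution; empty list iff valid.

    Re-implements the feasibility rules directly on the assignment (no
    reference to the solver or the model matrices).
    """
    out: list[str] = []
    layered = solution.pairs_by_level
    n = spec.n

    seen: dict[int, int] = {}
    for q, lvl in enumerate(layered.levels, start=1):
        for p in lvl.pairs:
            for pos in (p.i, p.j):
                if pos in seen:
                    out.append(f"position {pos} paired more than once")
                seen[pos] = q
            if seq is not None and not is_canonical_or_wobble(seq, p):
                out.append(f"pair ({p.i}, {p.j}) not canonical/Wobble")

    for q, lvl in enumerate(layered.levels, start=1):
        ps = sorted(lvl.pairs)
        for x_i, a in enumerate(ps):
            for b in ps[x_i + 1 :]:
                if a.crosses(b):
                    out.append(f"crossing within level {q}: {a.as_tuple()} x {b.as_tuple()}")

    for q in range(2, len(layered.levels) + 1):
        for p in layered.levels[q - 1].pairs:
            for ql in range(1, q):
                if not any(p.crosses(o) for o in layered.levels[ql - 1].pairs):
                    out.append(
                        f"uncrossed upper-level pair {p.as_tuple()} at level {q} "
                        f"(no crossing pair at level {ql})"
                    )

    for q, lvl in enumerate(layered.levels, start=1):
        tuples = {p.as_tuple() for p in lvl.pairs}
        for (i, j) in tuples:
            if (i - 1, j + 1) not in tuples and (i + 1, j - 1) not in tuples:
                out.append(f"lonely pair ({i}, {j}) at level {q}")

    n_paired = sum(2 * len(lvl) for lvl in layered.levels)
    if spec.min_paired_fraction > 0 and n_paired < spec.min_paired_fraction * n - 1e-9:
        out.append(
            f"only {n_paired}/{n} positions paired "
            f"(< {spec.min_paired_fraction:.0%} bound)"
        )

    # motif rules
    level1 = {p.as_tuple() for p in layered.levels[0].pairs} if layered.levels else set()
    ins = sorted(solution.insertions, key=CandidatePlacement.sort_key)
    for a, b in itertools.combinations(ins, 2):
        if a.start <= b.end and b.start <= a.end:
            out.append(
                f"overlapping inserted strands {a.motif.id}/{a.strand_index} "
                f"and {b.motif.id}/{b.strand_index}"
            )
    all_pairs = [p for lvl in layered.levels for p in lvl.pairs]
    for pl in ins:
        for p in all_pairs:
            if pl.start < p.i < pl.end or pl.start < p.j < pl.end:
                out.append(
                    f"pair {p.as_tuple()} has an endpoint inside inserted strand "
                    f"{pl.motif.id}/{pl.strand_index} [{pl.start}, {pl.end}]"
                )

    for mid, strands in _occurrence_groups(ins).items():
        motif = strands[next(iter(strands))][0].motif
        counts = {s: len(strands.get(s, [])) for s in range(1, motif.n_strands + 1)}
        if len(set(counts.values())) != 1:
            out.append(f"motif {mid}: unequal strand selection counts {counts}")
            continue
        reps = counts[1]
        for r in range(reps):
            occ = [strands[s][r] for s in range(1, motif.n_strands + 1)]
            for s in range(len(occ) - 1):
                if not occ[s].end < occ[s + 1].start:
                    out.append(
                        f"motif {mid} occurrence {r + 1}: strands out of 5'->3' order"
                    )
            # junctions between consecutive strands, then the cyclic closure
            junctions = [
                (occ[s].end, occ[s + 1].start, False) for s in range(len(occ) - 1)
            ]
            junctions.append((occ[0].start, occ[-1].end, True))
            for (a, b, enclosing) in junctions:
                if enclosing:
                    cands = _enclosing_anchor_pairs(a, b, n)
                else:
                    cands = _junction_anchor_pairs(a, b, n)
                if not any(c in level1 for c in cands):
                    where = "enclosing" if enclosing else f"junction ({a}, {b})"
                    out.append(f"motif {mid} occurrence {r + 1}: unanchored strand ({where})")
    return out


# ---------------------------------------------------------------------------
# Brute-force oracle


def brute_force_optimize(
    spec: IpModelSpec, max_pairs: int = 18, max_placements: int = 8
) -> IpSolution:
    """Exact optimum by enumeration; feasibility rules as validate_solution.

    Bounded to tiny instances (|B| <= 18, <= 8 placements by default).
    """
    if len(spec.B) > max_pairs:
        raise IpError(f"|B|={len(spec.B)} exceeds enumeration bound {max_pairs}")
    if len(spec.placements) > max_placements:
        raise IpError(
            f"{len(spec.placements)} placements exceed enumeration bound {max_placements}"
        )
    pairs = spec.B.pairs
    bp = [BasePair(c.u, c.v) for c in pairs]
    best: Optional[IpSolution] = None

    assignments: list[list[int]] = []  # level (0 = unselected) per pair

    def dfs(idx: int, levels: list[int], used: set[int]) -> None:
        if idx == len(pairs):
            assignments.append(list(levels))
            return
        dfs(idx + 1, levels + [0], used)
        c = pairs[idx]
        if c.u in used or c.v in used:
            return
        for q in range(1, spec.m + 1):
            if any(
                levels[k] == q and bp[idx].crosses(bp[k]) for k in range(idx)
            ):
                continue
            dfs(idx + 1, levels + [q], used | {c.u, c.v})

    dfs(0, [], set())

    placement_subsets = list(
        itertools.chain.from_iterable(
            itertools.combinations(range(len(spec.placements)), r)
            for r in range(len(spec.placements) + 1)
        )
    )

    for levels in assignments:
        level_sets: list[list[tuple[int, int]]] = [[] for _ in range(spec.m)]
        for k, q in enumerate(levels):
            if q > 0:
                level_sets[q - 1].append((pairs[k].u, pairs[k].v))
        layered = LayeredStructure(
            [SecondaryStructure(ls, spec.n) for ls in level_sets], spec.n
        )
        for subset in placement_subsets:
            sol = IpSolution(
                layered, [spec.placements[i] for i in subset], 0.0, "optimal"
            )
            if validate_solution(sol, spec):
                continue
            sol.objective = recompute_objective(spec, sol)
            if best is None or sol.objective > best.objective + 1e-12:
                best = sol
    if best is None:
        return _empty_solution(spec, "infeasible")
    return best
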