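"""Base-pair probability matrices under hard structural constraints.

The default backend is a self-contained McCaskill-style partition-function
implementation over a stacking-only nearest-neighbor energy model: every
stacked pair of pairs ``(i,j)/(i+1,j-1)`` contributes a sequence-dependent
stacking free energy from an embedded table; isolated pairs are permitted at
this stage (the integer program forbids them later); temperature is fixed at
37 degC.  This keeps the recursion exhaustively verifiable against explicit
structure enumeration while preserving the matrix semantics the rest of the
pipeline expects.  The ViennaRNA command-line programs (RNAfold/RNAalifold)
are available as an optional external backend for full Turner-model
fidelity.

Hard constraints: forced pairs are conditioned on (their probability is
exactly 1 in the output) and forbidden positions are excluded from pairing
(all-zero row/column).

The per-level matrices of a layered structure are summed into a
*pseudo-probability* matrix p(i,j) = p^1_{i,j} + ... + p^m_{i,j}; no
renormalization is applied, entries may exceed 1.
"""

from __future__ import annotations

import math
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .structure_core import (
    MIN_LOOP_SEP,
    BasePair,
    LayeredStructure,
    RnaSequence,
    SecondaryStructure,
    StructureError,
)

__all__ = [
    "BppMatrix",
    "PseudoBpp",
    "FoldConstraints",
    "FoldError",
    "fold_bpp",
    "enumerate_structures",
    "constrained_level_bpps",
    "sum_pseudo_bpp",
    "alignment_bpp",
    "structure_energy",
    "boltzmann_weight",
    "STACKING_ENERGY",
    "RT_37C",
]

#: Gas constant times temperature at 37 degC, kcal/mol.
RT_37C = 0.0019872 * 310.15

#: Probabilities below this are truncated to zero (numerical hygiene).
PROB_FLOOR = 1e-12

# Approximate Watson-Crick / Wobble nearest-neighbor stacking free energies
# (kcal/mol, 37 degC), keyed by (outer pair nucleotides, inner pair
# nucleotides) for the stack (i,j) on (i+1,j-1).
STACKING_ENERGY: dict[tuple[str, str], float] = {
    ("AU", "AU"): -0.9, ("AU", "UA"): -1.1, ("AU", "GC"): -2.1,
    ("AU", "CG"): -2.2, ("AU", "GU"): -0.6, ("AU", "UG"): -1.4,
    ("UA", "AU"): -1.3, ("UA", "UA"): -0.9, ("UA", "GC"): -2.4,
    ("UA", "CG"): -2.1, ("UA", "GU"): -1.0, ("UA", "UG"): -1.3,
    ("GC", "AU"): -2.2, ("GC", "UA"): -2.4, ("GC", "GC"): -3.3,
    ("GC", "CG"): -3.4, ("GC", "GU"): -1.5, ("GC", "UG"): -2.5,
    ("CG", "AU"): -2.1, ("CG", "UA"): -2.1, ("CG", "GC"): -2.4,
    ("CG", "CG"): -3.3, ("CG", "GU"): -1.4, ("CG", "UG"): -2.1,
    ("GU", "AU"): -1.4, ("GU", "UA"): -1.3, ("GU", "GC"): -2.5,
    ("GU", "CG"): -2.1, ("GU", "GU"): -0.5, ("GU", "UG"): -0.6,
    ("UG", "AU"): -0.6, ("UG", "UA"): -1.0, ("UG", "GC"): -1.5,
    ("UG", "CG"): -1.4, ("UG", "GU"): -0.3, ("UG", "UG"): -0.5,
}

_PAIRABLE = {"AU", "UA", "GC", "CG", "GU", "UG"}

#: Helix-initiation / loop-entropy proxy: every pair costs this much
#: (kcal/mol), suppressing spurious short helices the way loop penalties do
#: in the full nearest-neighbor model.
PAIR_PENALTY = 1.0


class FoldError(StructureError):
    """Folding failed (over-constrained input or backend problem)."""


@dataclass(frozen=True)
class FoldConstraints:
    """Hard constraints for a constrained partition function.

    ``forced_pairs`` must be mutually compatible (non-crossing, disjoint
    positions) and must not involve a forbidden position.
    """

    forced_pairs: frozenset[BasePair] = frozenset()
    forbidden_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        forced = frozenset(
            p if isinstance(p, BasePair) else BasePair(*p) for p in self.forced_pairs
        )
        object.__setattr__(self, "forced_pairs", forced)
        object.__setattr__(self, "forbidden_positions", frozenset(self.forbidden_positions))
        seen: set[int] = set()
        for p in forced:
            for pos in (p.i, p.j):
                if pos in seen:
                    raise StructureError(f"forced pairs overlap at position {pos}")
                if pos in self.forbidden_positions:
                    raise StructureError(f"forced pair uses forbidden position {pos}")
                seen.add(pos)
        fp = sorted(forced)
        for a_idx, a in enumerate(fp):
            for b in fp[a_idx + 1 :]:
                if a.crosses(b):
                    raise StructureError(f"forced pairs {a} and {b} cross")

    @classmethod
    def none(cls) -> "FoldConstraints":
        return cls()


class BppMatrix:
    """Symmetric matrix of pairing probabilities in [0, 1]."""

    def __init__(self, p: np.ndarray):
        p = np.asarray(p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise StructureError("BppMatrix requires a square matrix")
        self.p = p
        self.n = p.shape[0]

    def __getitem__(self, idx):
        return self.p[idx]

    def row_sums(self) -> np.ndarray:
        return self.p.sum(axis=1)

    def to_triplets(self) -> str:
        """Export as tab-separated '<i> <j> <p>' triplets, 1-based, i < j."""
        lines = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.p[i, j] > 0:
                    lines.append(f"{i + 1}\t{j + 1}\t{self.p[i, j]:.12g}")
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_triplets(cls, text: str, n: int) -> "BppMatrix":
        p = np.zeros((n, n))
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise StructureError(f"malformed triplet line {lineno}: {line!r}")
            i, j, v = int(parts[0]) - 1, int(parts[1]) - 1, float(parts[2])
            p[i, j] = p[j, i] = v
        return cls(p)


class PseudoBpp(BppMatrix):
    """Entrywise sum of per-level BPP matrices; entries may exceed 1."""


def _pair_symbol(seq: RnaSequence, i: int, j: int) -> str:
    return seq[i] + seq[j]


def _allowed_matrix(seq: RnaSequence, constraints: FoldConstraints) -> np.ndarray:
    """Boolean matrix of admissible pairs under sequence + constraints."""
    n = seq.n
    allowed = np.zeros((n, n), dtype=bool)
    partner = {p.i: p.j for p in constraints.forced_pairs}
    partner.update({p.j: p.i for p in constraints.forced_pairs})
    for i in range(n):
        for j in range(i + MIN_LOOP_SEP + 1, n):
            if _pair_symbol(seq, i, j) not in _PAIRABLE:
                continue
            if i in constraints.forbidden_positions or j in constraints.forbidden_positions:
                continue
            if i in partner and partner[i] != j:
                continue
            if j in partner and partner[j] != i:
                continue
            allowed[i, j] = allowed[j, i] = True
    return allowed


def _stack_weight_matrix(seq: RnaSequence, allowed: np.ndarray) -> np.ndarray:
    """s[i, j] = Boltzmann factor of stacking (i,j) on (i+1,j-1)."""
    n = seq.n
    s = np.ones((n, n))
    for i in range(n):
        for j in range(i + MIN_LOOP_SEP + 3, n):
            if allowed[i, j] and allowed[i + 1, j - 1]:
                e = STACKING_ENERGY.get(
                    (_pair_symbol(seq, i, j), _pair_symbol(seq, i + 1, j - 1)), 0.0
                )
                s[i, j] = math.exp(-e / RT_37C)
    return s


def _mccaskill(
    n: int,
    allowed: np.ndarray,
    stack_w: np.ndarray,
    pair_w: np.ndarray,
    must_pair: frozenset[int],
) -> np.ndarray:
    """Inside-outside recursion; returns the pairing-probability matrix.

    Q[i, j]  : partition function of interval [i, j] (1 on empty intervals).
    Qp[i, j] : partition function given (i, j) paired, including the factor
               pair_w[i, j] and stacking with the directly enclosed pair.
    Qh[i, j] : outside ("hat") partition function of the exterior of (i, j).
    """
    # Q is indexed with a +1 offset on the first axis so Q[i, i-1] == 1
    # (empty interval) is representable as Qo[i, i-1+1].
    Qo = np.zeros((n + 1, n + 1))  # Qo[i, j+1] = Q(i, j); Q(i, i-1) = 1
    Qp = np.zeros((n, n))
    for i in range(n + 1):
        Qo[i, i] = 1.0
    Q = lambda i, j: 1.0 if i > j else Qo[i, j + 1]

    for span in range(0, n):
        for i in range(0, n - span):
            j = i + span
            # pair (i..k paired with j) terms
            total = 0.0
            if j not in must_pair:
                total += Q(i, j - 1)
            for k in range(i, j - MIN_LOOP_SEP):
                if not allowed[k, j]:
                    continue
                inner = Q(k + 1, j - 1)
                if k + 1 <= j - 1 - (MIN_LOOP_SEP + 1) and allowed[k + 1, j - 1]:
                    inner += (stack_w[k, j] - 1.0) * Qp[k + 1, j - 1]
                qp = pair_w[k, j] * inner
                Qp[k, j] = qp
                total += qp * Q(i, k - 1)
            Qo[i, j + 1] = total
    # Note: the k-sum above recomputes Qp[k, j] for every i; the value only
    # depends on (k, j) so repeated assignment is idempotent.

    Ztot = Q(0, n - 1)
    if Ztot <= 0.0:
        raise FoldError("no structure is compatible with the constraints")

    # Outside pass, by decreasing span.  A[k, l] accumulates
    # Qh[k, l] * pair_w-free outer weight for reuse by enclosed pairs.
    Qh = np.zeros((n, n))
    A = np.zeros((n, n))
    spans = sorted(
        ((i, j) for i in range(n) for j in range(i + MIN_LOOP_SEP + 1, n) if allowed[i, j]),
        key=lambda ij: ij[1] - ij[0],
        reverse=True,
    )
    for i, j in spans:
        val = Q(0, i - 1) * Q(j + 1, n - 1)
        if i >= 1 and j <= n - 2:
            # sum over innermost enclosing pair (k, l), k < i, l > j
            left = np.array([Q(k + 1, i - 1) for k in range(0, i)])
            right = np.array([Q(j + 1, l - 1) for l in range(j + 1, n)])
            block = A[0:i, j + 1 : n]
            if block.size:
                val += float(left @ block @ right)
            if allowed[i - 1, j + 1]:
                val += A[i - 1, j + 1] * (stack_w[i - 1, j + 1] - 1.0)
        Qh[i, j] = val
        A[i, j] = val * pair_w[i, j]

    p = np.zeros((n, n))
    for i, j in spans:
        v = Qp[i, j] * Qh[i, j] / Ztot
        if v < PROB_FLOOR:
            v = 0.0
        p[i, j] = p[j, i] = min(v, 1.0)
    return p


def _single_sequence_inputs(seq: RnaSequence, constraints: FoldConstraints):
    allowed = _allowed_matrix(seq, constraints)
    stack_w = _stack_weight_matrix(seq, allowed)
    pair_w = np.full((seq.n, seq.n), math.exp(-PAIR_PENALTY / RT_37C))
    must_pair = frozenset(
        pos for p in constraints.forced_pairs for pos in (p.i, p.j)
    )
    return allowed, stack_w, pair_w, must_pair


def fold_bpp(
    seq: RnaSequence,
    constraints: Optional[FoldConstraints] = None,
    backend: str = "internal",
    params: Optional[dict] = None,
) -> BppMatrix:
    """Boltzmann pairing probabilities under hard constraints.

    Every forced pair has probability exactly 1; forbidden positions have
    all-zero rows.  ``backend`` is ``"internal"`` (default) or ``"vienna"``
    (requires the RNAfold executable).
    """
    constraints = constraints or FoldConstraints.none()
    if backend == "internal":
        allowed, stack_w, pair_w, must_pair = _single_sequence_inputs(seq, constraints)
        for p in constraints.forced_pairs:
            if not allowed[p.i, p.j]:
                raise FoldError(
                    f"forced pair ({p.i + 1}, {p.j + 1}) is not admissible for this sequence"
                )
        p = _mccaskill(seq.n, allowed, stack_w, pair_w, must_pair)
        for fp in constraints.forced_pairs:
            p[fp.i, fp.j] = p[fp.j, fp.i] = 1.0
        return BppMatrix(p)
    if backend == "vienna":
        return _vienna_fold_bpp(seq, constraints)
    raise FoldError(f"unknown folding backend {backend!r}")


# ---------------------------------------------------------------------------
# Enumeration oracle


def structure_energy(
    seq: RnaSequence, pairs: Iterable[tuple[int, int]], pair_energy: Optional[dict] = None
) -> float:
    """Stacking-only free energy of a pseudoknot-free structure (kcal/mol)."""
    ps = set(tuple(p) for p in pairs)
    e = 0.0
    for (i, j) in ps:
        e += PAIR_PENALTY
        if (i + 1, j - 1) in ps:
            e += STACKING_ENERGY.get(
                (_pair_symbol(seq, i, j), _pair_symbol(seq, i + 1, j - 1)), 0.0
            )
        if pair_energy:
            e += pair_energy.get((i, j), 0.0)
    return e


def boltzmann_weight(seq: RnaSequence, pairs: Iterable[tuple[int, int]]) -> float:
    return math.exp(-structure_energy(seq, pairs) / RT_37C)


def enumerate_structures(
    seq: RnaSequence,
    constraints: Optional[FoldConstraints] = None,
    max_n: int = 25,
) -> list[SecondaryStructure]:
    """All pseudoknot-free, constraint-compatible structures (test oracle).

    Exponential; refuses sequences longer than ``max_n``.
    """
    if seq.n > max_n:
        raise FoldError(f"sequence length {seq.n} exceeds enumeration cap {max_n}")
    constraints = constraints or FoldConstraints.none()
    allowed, _, _, must_pair = _single_sequence_inputs(seq, constraints)

    def rec(i: int, j: int) -> list[frozenset]:
        if i > j:
            return [frozenset()]
        if i == j:
            # a single position cannot satisfy a forced pair
            return [] if i in must_pair else [frozenset()]
        out: list[frozenset] = []
        if j not in must_pair:
            out.extend(rec(i, j - 1))
        for k in range(i, j - MIN_LOOP_SEP):
            if not allowed[k, j]:
                continue
            for inner in rec(k + 1, j - 1):
                for outer in rec(i, k - 1):
                    out.append(inner | outer | {(k, j)})
        return out

    raw = rec(0, seq.n - 1)
    return [SecondaryStructure(fs, seq.n) for fs in sorted(raw, key=sorted)]


# ---------------------------------------------------------------------------
# Level-constrained matrices and the pseudo-probability sum


def constrained_level_bpps(
    seq: RnaSequence,
    layered: Optional[LayeredStructure],
    backend: str = "internal",
    params: Optional[dict] = None,
) -> list[BppMatrix]:
    """One hard-constrained matrix per level of a layered structure.

    Level q's pairs are forced and every position paired in any *other*
    level is forbidden.  An empty input structure yields exactly one
    unconstrained matrix.
    """
    if layered is None or layered.nonempty_level_count() == 0:
        return [fold_bpp(seq, None, backend, params)]
    out = []
    levels = [lvl for lvl in layered.levels if len(lvl) > 0]
    for q, lvl in enumerate(levels):
        others = {
            pos
            for r, other in enumerate(levels)
            if r != q
            for pos in other.paired_positions()
        }
        fc = FoldConstraints(frozenset(lvl.pairs), frozenset(others))
        out.append(fold_bpp(seq, fc, backend, params))
    return out


def sum_pseudo_bpp(matrices: Sequence[BppMatrix]) -> PseudoBpp:
    """Entrywise sum of per-level matrices (no renormalization)."""
    if not matrices:
        raise StructureError("cannot sum an empty list of BPP matrices")
    n = matrices[0].n
    if any(m.n != n for m in matrices):
        raise StructureError("BPP matrices have mismatched dimensions")
    total = np.zeros((n, n))
    for m in matrices:
        total += m.p
    return PseudoBpp(total)


# ---------------------------------------------------------------------------
# Alignment consensus model

#: Covariance bonus per distinct additional canonical combination (kcal/mol).
COVARIANCE_BONUS = 1.0
#: Penalty per fully non-canonical/gapped row fraction (kcal/mol).
NONCANONICAL_PENALTY = 1.0


def alignment_bpp(
    alignment,
    backend: str = "internal",
    params: Optional[dict] = None,
    constraints: Optional[FoldConstraints] = None,
) -> BppMatrix:
    """Consensus pairing probabilities projected onto the target sequence.

    Internal model: the target sequence is folded with stacking energies
    averaged over the alignment rows in which the stack is canonical, plus a
    covariance bonus per column pair rewarding compensatory substitutions
    (distinct canonical nucleotide combinations beyond the first) and a
    penalty proportional to the fraction of rows that cannot form the pair.
    On an alignment of identical rows both corrections vanish and the result
    equals single-sequence folding exactly.  The external backend delegates
    to RNAalifold.
    """
    constraints = constraints or FoldConstraints.none()
    if backend == "vienna":
        return _vienna_alignment_bpp(alignment, constraints)
    if backend != "internal":
        raise FoldError(f"unknown folding backend {backend!r}")

    seq = alignment.target_sequence()
    if all(row == alignment.rows[alignment.target_row] for row in alignment.rows):
        # degenerate alignment: consensus model reduces to the single
        # sequence bit-for-bit
        return fold_bpp(seq, constraints, "internal")
    n = seq.n
    rows = alignment.rows
    cols = [alignment.column_map[i] for i in range(n)]

    def row_sym(r: str, i: int, j: int) -> str:
        return r[cols[i]].upper().replace("T", "U") + r[cols[j]].upper().replace("T", "U")

    allowed = _allowed_matrix(seq, constraints)
    canon_frac = np.zeros((n, n))
    distinct = np.zeros((n, n))
    for i in range(n):
        for j in range(i + MIN_LOOP_SEP + 1, n):
            if not allowed[i, j]:
                continue
            combos = set()
            ok = 0
            for r in rows:
                sym = row_sym(r, i, j)
                if sym in _PAIRABLE:
                    ok += 1
                    combos.add(sym)
            canon_frac[i, j] = ok / len(rows)
            # saturating covariance evidence: more than two extra
            # compensatory combinations add no further bonus
            distinct[i, j] = min(max(len(combos) - 1, 0), 2)
            if canon_frac[i, j] < 0.5:
                allowed[i, j] = allowed[j, i] = False
    for p in constraints.forced_pairs:
        allowed[p.i, p.j] = allowed[p.j, p.i] = True

    # Stacking energies averaged over rows where the stack is canonical.
    stack_w = np.ones((n, n))
    for i in range(n):
        for j in range(i + MIN_LOOP_SEP + 3, n):
            if allowed[i, j] and allowed[i + 1, j - 1]:
                es = [
                    STACKING_ENERGY.get((row_sym(r, i, j), row_sym(r, i + 1, j - 1)), 0.0)
                    for r in rows
                    if row_sym(r, i, j) in _PAIRABLE and row_sym(r, i + 1, j - 1) in _PAIRABLE
                ]
                mean_e = sum(es) / len(rows) if es else 0.0
                stack_w[i, j] = math.exp(-mean_e / RT_37C)

    pair_w = np.ones((n, n))
    for i in range(n):
        for j in range(i + MIN_LOOP_SEP + 1, n):
            if allowed[i, j]:
                e = PAIR_PENALTY - COVARIANCE_BONUS * distinct[i, j] + NONCANONICAL_PENALTY * (
                    1.0 - canon_frac[i, j]
                )
                pair_w[i, j] = math.exp(-e / RT_37C)

    must_pair = frozenset(pos for p in constraints.forced_pairs for pos in (p.i, p.j))
    p = _mccaskill(n, allowed, stack_w, pair_w, must_pair)
    for fp in constraints.forced_pairs:
        p[fp.i, fp.j] = p[fp.j, fp.i] = 1.0
    return BppMatrix(p)


# ---------------------------------------------------------------------------
# ViennaRNA external backend (optional)


def _constraint_string(n: int, constraints: FoldConstraints) -> str:
    cs = ["."] * n
    for pos in constraints.forbidden_positions:
        cs[pos] = "x"
    for p in constraints.forced_pairs:
        cs[p.i] = "("
        cs[p.j] = ")"
    return "".join(cs)


def _parse_dotplot(ps_text: str, n: int) -> np.ndarray:
    p = np.zeros((n, n))
    in_data = False
    for line in ps_text.splitlines():
        if "%start of base pair probability data" in line:
            in_data = True
            continue
        if in_data:
            parts = line.split()
            if len(parts) == 4 and parts[3] == "ubox":
                i, j, sq = int(parts[0]) - 1, int(parts[1]) - 1, float(parts[2])
                p[i, j] = p[j, i] = sq * sq
            elif line.startswith("showpage"):
                break
    return p


def _vienna_fold_bpp(seq: RnaSequence, constraints: FoldConstraints) -> BppMatrix:
    with tempfile.TemporaryDirectory() as tmp:
        inp = f">target\n{seq.residues}\n{_constraint_string(seq.n, constraints)}\n"
        cmd = ["RNAfold", "-p", "--noPS", "-C", "--enforceConstraint"]
        try:
            subprocess.run(
                cmd, input=inp, cwd=tmp, capture_output=True, text=True, check=True
            )
        except FileNotFoundError as exc:
            raise FoldError("RNAfold executable not found") from exc
        except subprocess.CalledProcessError as exc:
            raise FoldError(f"RNAfold failed: {exc.stderr.strip()}") from exc
        dp = Path(tmp) / "target_dp.ps"
        if not dp.exists():
            raise FoldError("RNAfold produced no dot-plot output")
        p = _parse_dotplot(dp.read_text(), seq.n)
    p[p < PROB_FLOOR] = 0.0
    for fp in constraints.forced_pairs:
        p[fp.i, fp.j] = p[fp.j, fp.i] = 1.0
    return BppMatrix(p)


def _vienna_alignment_bpp(alignment, constraints: FoldConstraints) -> BppMatrix:
    seq = alignment.target_sequence()
    ncol = len(alignment.rows[0])
    with tempfile.TemporaryDirectory() as tmp:
        aln = Path(tmp) / "aln.fa"
        aln.write_text(
            "".join(f">row{r}\n{row}\n" for r, row in enumerate(alignment.rows))
        )
        cmd = ["RNAalifold", "-p", "--noPS", str(aln)]
        try:
            res = subprocess.run(cmd, cwd=tmp, capture_output=True, text=True, check=True)
        except FileNotFoundError as exc:
            raise FoldError("RNAalifold executable not found") from exc
        except subprocess.CalledProcessError as exc:
            raise FoldError(f"RNAalifold failed: {exc.stderr.strip()}") from exc
        dp = Path(tmp) / "alidot.ps"
        if not dp.exists():
            cands = list(Path(tmp).glob("*_dp.ps")) + list(Path(tmp).glob("*dp.ps"))
            if not cands:
                raise FoldError("RNAalifold produced no dot-plot output")
            dp = cands[0]
        pc = _parse_dotplot(dp.read_text(), ncol)
    # project alignment columns onto target coordinates
    n = seq.n
    p = np.zeros((n, n))
    colmap = alignment.column_map
    for i in range(n):
        for j in range(i + 1, n):
            p[i, j] = p[j, i] = pc[colmap[i], colmap[j]]
    p[p < PROB_FLOOR] = 0.0
    return BppMatrix(p)
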