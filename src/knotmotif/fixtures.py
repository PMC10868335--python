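"""Deterministic fixture generation: sequences with planted structures,
toy motif catalogs, and toy alignments.

Every generator draws from its own pseudorandom stream seeded by
``(global seed, generator id)``, so adding a generator never shifts the
output of another.  Same spec, same bytes.

The planted-structure generator assigns each planted pair a Watson-Crick
nucleotide combination (helices energy-balanced against each other) and
draws unpaired positions from a purine-rich distribution; whole draws are
rejection-sampled until the planted structure dominates the Boltzmann
ensemble — these fixtures exist to test *recovery of a recoverable
structure*, not to mimic arbitrary sequences.  The toy catalog reads
hairpin and interior loops directly off the planted structure, so their
strands literally occur in the sequence and insertions are achievable;
decoy motifs that match nowhere are added as negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .motif_catalog import Alignment, Motif
from .structure_core import (
    MIN_LOOP_SEP,
    LayeredStructure,
    RnaSequence,
    SecondaryStructure,
    StructureError,
)

__all__ = [
    "FixtureSpec",
    "generate_sequence_with_structure",
    "generate_toy_catalog",
    "generate_alignment",
    "planted_pseudoknot_template",
    "planted_hairpin_template",
    "compensatory_demo_fixture",
]

#: Watson-Crick combinations used for planted pairs, G-C enriched.
_PAIR_COMBOS = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]
_PAIR_WEIGHTS = [0.35, 0.35, 0.15, 0.15]

_CANONICAL_COMBOS = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")]

_GENERATOR_IDS = {"sequence": 1, "catalog": 2, "alignment": 3}


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible recipe for one synthetic test case."""

    seed: int
    n: int
    planted: Optional[LayeredStructure] = None
    mutation_rate: float = 0.1
    rows: int = 3

    def rng(self, generator: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _GENERATOR_IDS[generator]])


def _helix(i: int, j: int, length: int) -> list[tuple[int, int]]:
    """Stacked pairs (i, j), (i+1, j-1), ..."""
    return [(i + k, j - k) for k in range(length)]


def planted_hairpin_template(n: int = 20, stem: int = 5) -> LayeredStructure:
    """A single hairpin: stem of ``stem`` pairs opening at position 0."""
    pairs = _helix(0, 2 * stem + MIN_LOOP_SEP, stem)
    if pairs[-1][1] - pairs[-1][0] <= MIN_LOOP_SEP or pairs[0][1] >= n:
        raise StructureError("hairpin template infeasible for this n")
    return LayeredStructure([SecondaryStructure(pairs, n)], n)


def planted_pseudoknot_template(
    stem1: int = 5, stem2: int = 5, tail_hairpin: int = 4, n: Optional[int] = None
) -> LayeredStructure:
    """An H-type pseudoknot, optionally followed by a nested hairpin.

    Layout (0-based): stem1 5' | loop1 | stem2 5' | stem1 3' | loop2 |
    stem2 3' [| linker | hairpin stem | GNRA-size loop | hairpin stem].
    The two stems cross, giving a two-level structure; the trailing hairpin
    is knot-free (level 1) and provides a loop to insert motifs into.
    """
    loop = MIN_LOOP_SEP + 1
    s1_5 = 0
    loop1 = s1_5 + stem1
    s2_5 = loop1 + loop
    s1_3 = s2_5 + stem2
    loop2 = s1_3 + stem1
    s2_3 = loop2 + loop
    core_end = s2_3 + stem2
    level1 = _helix(s1_5, s1_3 + stem1 - 1, stem1)
    level2 = _helix(s2_5, s2_3 + stem2 - 1, stem2)
    total = core_end
    if tail_hairpin:
        hp_start = core_end + 2
        hp_loop = 4
        level1 = level1 + _helix(hp_start, hp_start + 2 * tail_hairpin + hp_loop - 1, tail_hairpin)
        total = hp_start + 2 * tail_hairpin + hp_loop
    if n is None:
        n = total
    if n < total:
        raise StructureError(f"template needs n >= {total}, got {n}")
    return LayeredStructure(
        [SecondaryStructure(level1, n), SecondaryStructure(level2, n)], n
    )


def generate_sequence_with_structure(
    spec: FixtureSpec,
) -> tuple[RnaSequence, LayeredStructure]:
    """A random sequence in which the planted structure is dominant.

    Every planted pair receives a Watson-Crick nucleotide combination;
    unpaired positions are purine-rich; draws are rejected until every
    planted pair is prominent in the unconstrained Boltzmann ensemble.
    Deterministic under the fixture seed.
    """
    planted = spec.planted
    if planted is None:
        planted = LayeredStructure([SecondaryStructure([], spec.n)], spec.n)
    if planted.length > spec.n:
        raise StructureError(
            f"planted template length {planted.length} exceeds n={spec.n}"
        )
    rng = spec.rng("sequence")
    from .bpp_engine import STACKING_ENERGY, fold_bpp
    from .structure_core import _helices

    helices = [h for lvl in planted.levels for h in _helices(lvl.pairs)]
    planted_tuples = [p.as_tuple() for lvl in planted.levels for p in lvl.pairs]

    def draw() -> list[str]:
        """One candidate assignment: balanced-energy stems, A-biased loops.

        Combos are redrawn until planted helices have comparable stacking
        energy (spread <= 2 kcal/mol): a helix much weaker than its planted
        partners would vanish from the Boltzmann ensemble.  Unpaired
        positions are purine-rich (as in GNRA-type loops), limiting
        spurious complementarity with the stems.
        """
        best_combos: Optional[list] = None
        best_spread = float("inf")
        for _ in range(100):
            combos = [[rng.integers(0, len(_PAIR_COMBOS)) for _ in h] for h in helices]
            energies = []
            for h, cs in zip(helices, combos):
                if len(h) < 2:
                    continue
                syms = ["".join(_PAIR_COMBOS[c]) for c in cs]
                energies.append(
                    sum(STACKING_ENERGY[(syms[t], syms[t + 1])] for t in range(len(syms) - 1))
                )
            spread = max(energies) - min(energies) if len(energies) > 1 else 0.0
            if spread < best_spread:
                best_spread, best_combos = spread, combos
            if best_spread <= 2.0:
                break
        chars = [""] * spec.n
        for h, cs in zip(helices, best_combos):
            for p, c in zip(h, cs):
                chars[p.i], chars[p.j] = _PAIR_COMBOS[c]
        for k in range(spec.n):
            if not chars[k]:
                chars[k] = "ACGU"[rng.choice(4, p=[0.7, 0.1, 0.1, 0.1])]
        # block single-pair extensions of planted helices: the unpaired
        # positions flanking a helix end must not be mutually pairable
        canon = {"AU", "UA", "GC", "CG", "GU", "UG"}
        paired_pos = {pos for (i, j) in planted_tuples for pos in (i, j)}
        for h in helices:
            for (a, b) in ((h[0].i - 1, h[0].j + 1), (h[-1].i + 1, h[-1].j - 1)):
                if 0 <= a < b < spec.n and a not in paired_pos and b not in paired_pos:
                    if chars[a] + chars[b] in canon:
                        chars[a] = chars[b] = "A"
        return chars

    # Accept a draw only if every planted pair is visible in the
    # unconstrained Boltzmann ensemble (probability >= 0.1) and no spurious
    # pair is prominent (probability <= 0.2): chance complementarity between
    # stems and loops can otherwise bury a planted helix under chimeric
    # alternatives that no optimizer could reject.
    chars = draw()
    if planted_tuples:
        planted_set = set(planted_tuples)
        best_chars, best_score = None, -np.inf
        for _ in range(40):
            m = fold_bpp(RnaSequence("".join(chars)))
            lo = min(m[i, j] for (i, j) in planted_set)
            hi = max(
                (
                    m[i, j]
                    for i in range(spec.n)
                    for j in range(i + 1, spec.n)
                    if (i, j) not in planted_set
                ),
                default=0.0,
            )
            score = lo - hi
            if score > best_score:
                best_chars, best_score = chars, score
            if lo >= 0.1 and hi <= 0.2:
                break
            chars = draw()
        chars = best_chars
    if planted.length < spec.n:
        planted = LayeredStructure(
            [SecondaryStructure(lvl.as_tuples(), spec.n) for lvl in planted.levels],
            spec.n,
        )
    return RnaSequence("".join(chars), name=f"fixture_seed{spec.seed}"), planted


def _planted_loops(structure: LayeredStructure) -> tuple[list[tuple[int, int]], list[tuple[tuple[int, int], tuple[int, int]]]]:
    """Hairpin loop intervals and interior-loop strand interval pairs.

    Loops are regions unpaired in the *entire* planted structure (all
    levels), delimited by level-1 pairs — a motif extracted here can be
    inserted without clashing with any planted pair.
    """
    level1 = {p.as_tuple() for p in structure.levels[0].pairs} if structure.levels else set()
    paired = {pos for lvl in structure.levels for pos in lvl.paired_positions()}
    unpaired = lambda a, b: all(pos not in paired for pos in range(a, b + 1))
    hairpins = []
    interiors = []
    for (i, j) in sorted(level1):
        if j - i >= 2 and unpaired(i + 1, j - 1):
            hairpins.append((i + 1, j - 1))
            continue
        inner = [
            (k, l) for (k, l) in level1 if i < k < l < j
        ]
        if inner:
            k, l = min(inner)
            if not any(i < a < k and l < b < j for (a, b) in level1 if (a, b) != (k, l)):
                if k - i > 1 and j - l > 1 and unpaired(i + 1, k - 1) and unpaired(l + 1, j - 1):
                    interiors.append(((i + 1, k - 1), (l + 1, j - 1)))
    return hairpins, interiors


def generate_toy_catalog(
    spec: FixtureSpec, seq: RnaSequence, structure: LayeredStructure
) -> list[Motif]:
    """Motifs whose strands literally occur in the planted loops, plus decoys."""
    hairpins, interiors = _planted_loops(structure)
    if not hairpins:
        raise StructureError("toy catalog needs at least one hairpin loop")
    rng = spec.rng("catalog")
    motifs: list[Motif] = []
    for k, (a, b) in enumerate(hairpins, 1):
        motifs.append(
            Motif(f"HP{k}", f"fixture_hp{k}", (seq.residues[a : b + 1],))
        )
    for k, ((a1, b1), (a2, b2)) in enumerate(interiors, 1):
        motifs.append(
            Motif(
                f"IL{k}",
                f"fixture_il{k}",
                (seq.residues[a1 : b1 + 1], seq.residues[a2 : b2 + 1]),
            )
        )
    # decoys: random patterns re-drawn until they match nowhere
    for k in range(2):
        for _ in range(50):
            size = int(rng.integers(6, 10))
            pat = "".join("ACGU"[c] for c in rng.integers(0, 4, size))
            if pat not in seq.residues:
                motifs.append(Motif(f"DECOY{k + 1}", "fixture_decoy", (pat,)))
                break
    return motifs


def generate_alignment(
    seq: RnaSequence, structure: LayeredStructure, spec: FixtureSpec
) -> Alignment:
    """Rows mutated from ``seq``; paired-position mutations are compensatory
    with probability 0.9, preserving alignment support for the plant."""
    if spec.rows < 1:
        raise StructureError("alignment needs at least one row")
    rng = spec.rng("alignment")
    partner: dict[int, int] = {}
    for lvl in structure.levels:
        for p in lvl.pairs:
            partner[p.i] = p.j
            partner[p.j] = p.i
    rows = [seq.residues]
    for _ in range(spec.rows - 1):
        chars = list(seq.residues)
        visited: set[int] = set()
        for pos in range(seq.n):
            if pos in visited or rng.random() >= spec.mutation_rate:
                continue
            if pos in partner and partner[pos] > pos:
                j = partner[pos]
                if rng.random() < 0.9:
                    cur = (chars[pos], chars[j])
                    options = [c for c in _CANONICAL_COMBOS if c != cur]
                    a, b = options[rng.integers(0, len(options))]
                    chars[pos], chars[j] = a, b
                    visited.add(j)
                else:
                    chars[pos] = "ACGU"[rng.integers(0, 4)]
            elif pos in partner:
                continue  # handled from the 5' partner
            else:
                chars[pos] = "ACGU"[rng.integers(0, 4)]
        rows.append("".join(chars))
    return Alignment(rows, target_row=0)


def compensatory_demo_fixture() -> tuple[RnaSequence, LayeredStructure, Alignment, list[Motif]]:
    """A deterministic fixture where only evolutionary covariation can
    rescue the pseudoknot.

    The H-type pseudoknot has a strong all-G-C level-1 stem and a weak
    all-A-U level-2 stem: in the single-sequence Boltzmann ensemble the
    weak stem is buried (its pair probabilities fall below any sensible
    candidate threshold), so single-sequence prediction recovers only the
    level-1 stem and the trailing hairpin.  The alignment rows rotate the
    level-2 stem through alternative canonical combinations — classic
    compensatory substitution — leaving everything else untouched; the
    covariance bonus then lifts the weak stem back into the candidate set.
    """
    planted = planted_pseudoknot_template(stem1=5, stem2=5)
    n = planted.length
    chars = ["A"] * n
    stem1 = sorted(planted.levels[0].pairs)[:5]
    hairpin = sorted(planted.levels[0].pairs)[5:]
    stem2 = sorted(planted.levels[1].pairs)
    # level-1 stem of moderate (mixed) strength, level-2 stem weak all-A-U:
    # the gap (~4 kcal/mol) buries the weak stem in the single-sequence
    # ensemble, while one compensatory combination (~1 kcal/mol bonus per
    # pair) lifts it back without burying the level-1 stem in turn
    stem1_combos = [("G", "C"), ("A", "U"), ("G", "C"), ("A", "U"), ("G", "C")]
    hairpin_combos = [("G", "C"), ("C", "G"), ("G", "C"), ("U", "A")]
    stem2_target = [("A", "U"), ("U", "A"), ("A", "U"), ("U", "A"), ("A", "U")]
    for p, (a, b) in zip(stem1, stem1_combos):
        chars[p.i], chars[p.j] = a, b
    for p, (a, b) in zip(hairpin, hairpin_combos):
        chars[p.i], chars[p.j] = a, b
    for p, (a, b) in zip(stem2, stem2_target):
        chars[p.i], chars[p.j] = a, b
    # hairpin loop distinct from the A-rich background so the toy motif is
    # anchored where intended
    loop_start = hairpin[-1].i + 1
    for off, ch in enumerate("GAAA"):
        chars[loop_start + off] = ch
    target = "".join(chars)

    # compensatory rows swap every level-2 stem pair A-U -> U-A: the double
    # substitution preserves both pairing and stacking strength, so the
    # alignment adds pure covariance evidence for the weak stem
    swap = {"A": "U", "U": "A"}
    rows = [target]
    for _ in range(2):
        rchars = list(target)
        for p in stem2:
            rchars[p.i] = swap[rchars[p.i]]
            rchars[p.j] = swap[rchars[p.j]]
        rows.append("".join(rchars))
    alignment = Alignment(rows + [target], target_row=0)

    seq = RnaSequence(target, name="compensatory_demo")
    catalog = generate_toy_catalog(
        FixtureSpec(seed=0, n=n, planted=planted), seq, planted
    )
    return seq, planted, alignment, catalog
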