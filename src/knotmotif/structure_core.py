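"""Sequences, base pairs and layered (pseudoknotted) secondary structures.

A secondary structure is a set of base pairs ``(i, j)`` over a sequence of
nucleotides; pairs may cross (``i < k < j < l``), in which case the structure
contains a pseudoknot.  Any such structure can be decomposed into an ordered
list of *levels* (pages), each of which is pseudoknot-free on its own.

Coordinates are 0-based, closed intervals internally; user-facing output is
1-based.  A base pair must satisfy ``j - i > 3`` (at least three unpaired
positions in a hairpin loop) and, when checked against a sequence, must be
canonical (G-C, A-U) or Wobble (G-U).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "RnaSequence",
    "BasePair",
    "SecondaryStructure",
    "LayeredStructure",
    "StructureError",
    "DotBracketError",
    "BRACKET_ALPHABETS",
    "parse_dotbracket",
    "write_dotbracket",
    "decompose_layers",
    "is_canonical_or_wobble",
    "read_fasta",
]

#: Bracket alphabets in priority order; index = suggested level annotation.
BRACKET_ALPHABETS: list[tuple[str, str]] = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")] + [
    (chr(ord("A") + k), chr(ord("a") + k)) for k in range(26)
]

_CANONICAL = {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}
_VALID_NT = set("ACGU")

#: Minimum loop size: a pair (i, j) requires j - i > MIN_LOOP_SEP.
MIN_LOOP_SEP = 3


class StructureError(ValueError):
    """Invalid sequence or structure data."""


class DotBracketError(StructureError):
    """Malformed dot-bracket text."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over the alphabet {A, C, G, U}.

    Input is normalized: lowercase is uppercased and T becomes U.  Any other
    character is rejected.
    """

    residues: str
    name: str = ""

    def __post_init__(self) -> None:
        norm = self.residues.strip().upper().replace("T", "U")
        bad = set(norm) - _VALID_NT
        if bad:
            raise StructureError(
                f"invalid nucleotide(s) {sorted(bad)!r} in sequence {self.name!r}"
            )
        if not norm:
            raise StructureError("empty sequence")
        object.__setattr__(self, "residues", norm)

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True, order=True)
class BasePair:
    """A base pair (i, j), 0-based, i < j, with j - i > 3."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if not (0 <= self.i < self.j):
            raise StructureError(f"base pair requires 0 <= i < j, got ({self.i}, {self.j})")
        if self.j - self.i <= MIN_LOOP_SEP:
            raise StructureError(
                f"base pair ({self.i}, {self.j}) violates minimum loop size j - i > {MIN_LOOP_SEP}"
            )

    def crosses(self, other: "BasePair") -> bool:
        """True iff the two pairs cross (i < k < j < l in either order)."""
        i, j, k, l = self.i, self.j, other.i, other.j
        return (i < k < j < l) or (k < i < l < j)

    def as_tuple(self) -> tuple[int, int]:
        return (self.i, self.j)


def is_canonical_or_wobble(seq: RnaSequence, pair: BasePair) -> bool:
    """True iff the paired nucleotides form G-C, A-U or G-U (either order)."""
    if pair.j >= seq.n:
        raise StructureError(f"pair ({pair.i}, {pair.j}) out of bounds for n={seq.n}")
    return (seq[pair.i], seq[pair.j]) in _CANONICAL


class SecondaryStructure:
    """A set of base pairs in which no position is paired twice."""

    def __init__(self, pairs: Iterable[BasePair | tuple[int, int]], length: int):
        bps = frozenset(p if isinstance(p, BasePair) else BasePair(*p) for p in pairs)
        seen: set[int] = set()
        for p in bps:
            if p.j >= length:
                raise StructureError(f"pair ({p.i}, {p.j}) out of bounds for n={length}")
            for pos in (p.i, p.j):
                if pos in seen:
                    raise StructureError(f"position {pos} appears in more than one pair")
                seen.add(pos)
        self.pairs: frozenset[BasePair] = bps
        self.length = int(length)

    def __iter__(self) -> Iterator[BasePair]:
        return iter(sorted(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SecondaryStructure)
            and self.pairs == other.pairs
            and self.length == other.length
        )

    def __hash__(self) -> int:
        return hash((self.pairs, self.length))

    def __repr__(self) -> str:
        return f"SecondaryStructure({sorted(p.as_tuple() for p in self.pairs)}, n={self.length})"

    def as_tuples(self) -> list[tuple[int, int]]:
        return sorted(p.as_tuple() for p in self.pairs)

    def paired_positions(self) -> set[int]:
        return {pos for p in self.pairs for pos in (p.i, p.j)}

    def is_pseudoknot_free(self) -> bool:
        ps = sorted(self.pairs)
        return not any(a.crosses(b) for x, a in enumerate(ps) for b in ps[x + 1 :])


class LayeredStructure:
    """An ordered list of pseudoknot-free levels with disjoint positions.

    Level 1 (index 0) conventionally holds the dominant, knot-free part of
    the structure; higher levels hold pairs crossing everything below.
    """

    def __init__(self, levels: Sequence[SecondaryStructure], length: Optional[int] = None):
        levels = list(levels)
        if length is None:
            if not levels:
                raise StructureError("LayeredStructure with no levels requires explicit length")
            length = levels[0].length
        for q, lvl in enumerate(levels):
            if lvl.length != length:
                raise StructureError("all levels must share the same sequence length")
            if not lvl.is_pseudoknot_free():
                raise StructureError(f"level {q + 1} contains crossing pairs")
        seen: set[int] = set()
        for lvl in levels:
            for pos in lvl.paired_positions():
                if pos in seen:
                    raise StructureError(f"position {pos} paired in more than one level")
                seen.add(pos)
        self.levels: list[SecondaryStructure] = levels
        self.length = int(length)

    @property
    def m(self) -> int:
        return len(self.levels)

    def nonempty_level_count(self) -> int:
        return sum(1 for lvl in self.levels if len(lvl) > 0)

    def all_pairs(self) -> SecondaryStructure:
        return SecondaryStructure([p for lvl in self.levels for p in lvl.pairs], self.length)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LayeredStructure)
            and self.length == other.length
            and [l.pairs for l in self.levels] == [l.pairs for l in other.levels]
        )

    def __repr__(self) -> str:
        return f"LayeredStructure({[l.as_tuples() for l in self.levels]}, n={self.length})"


def parse_dotbracket(
    text: str, length: Optional[int] = None, min_sep: int = MIN_LOOP_SEP
) -> SecondaryStructure:
    """Parse dot-bracket text, supporting pseudoknot bracket alphabets.

    Brackets pair within their own alphabet; ``.`` (also ``-`` and ``_``) is
    unpaired.  The alphabet index of each pair is retained as a suggested
    level annotation on the returned structure (attribute ``alphabet_of``).

    Raises :class:`DotBracketError` on unbalanced brackets (naming the
    position) and on a length mismatch.
    """
    text = text.strip()
    if length is not None and len(text) != length:
        raise DotBracketError(f"structure length {len(text)} != expected {length}")
    open_of = {o: k for k, (o, c) in enumerate(BRACKET_ALPHABETS)}
    close_of = {c: k for k, (o, c) in enumerate(BRACKET_ALPHABETS)}
    stacks: dict[int, list[int]] = {}
    pairs: list[tuple[int, int]] = []
    alphabet_of: dict[tuple[int, int], int] = {}
    for pos, ch in enumerate(text):
        if ch in ".-_":
            continue
        if ch in open_of:
            stacks.setdefault(open_of[ch], []).append(pos)
        elif ch in close_of:
            k = close_of[ch]
            if not stacks.get(k):
                raise DotBracketError(f"unmatched {ch!r} at position {pos + 1}")
            i = stacks[k].pop()
            if pos - i <= min_sep:
                raise DotBracketError(
                    f"pair ({i + 1}, {pos + 1}) violates minimum loop size j - i > {min_sep}"
                )
            pairs.append((i, pos))
            alphabet_of[(i, pos)] = k
        else:
            raise DotBracketError(f"unrecognized character {ch!r} at position {pos + 1}")
    for k, st in stacks.items():
        if st:
            o = BRACKET_ALPHABETS[k][0]
            raise DotBracketError(f"unclosed {o!r} opened at position {st[-1] + 1}")
    ss = SecondaryStructure(pairs, len(text))
    ss.alphabet_of = {BasePair(i, j): k for (i, j), k in alphabet_of.items()}  # type: ignore[attr-defined]
    return ss


def write_dotbracket(structure: LayeredStructure) -> str:
    """Render a layered structure, level q using the q-th bracket alphabet."""
    if structure.m > len(BRACKET_ALPHABETS):
        raise StructureError(
            f"{structure.m} levels exceed the {len(BRACKET_ALPHABETS)} available bracket alphabets"
        )
    out = ["."] * structure.length
    for q, lvl in enumerate(structure.levels):
        o, c = BRACKET_ALPHABETS[q]
        for p in lvl.pairs:
            out[p.i] = o
            out[p.j] = c
    return "".join(out)


def _helices(pairs: Iterable[BasePair]) -> list[list[BasePair]]:
    """Group pairs into maximal stacked runs ((i,j),(i+1,j-1),...)."""
    remaining = set(pairs)
    helices = []
    for p in sorted(remaining):
        if p not in remaining:
            continue
        run = [p]
        remaining.discard(p)
        while True:
            nxt = BasePair(run[-1].i + 1, run[-1].j - 1) if run[-1].j - run[-1].i > MIN_LOOP_SEP + 2 else None
            if nxt is not None and nxt in remaining:
                run.append(nxt)
                remaining.discard(nxt)
            else:
                break
        helices.append(run)
    return helices


def decompose_layers(structure: SecondaryStructure, max_levels: int = 4) -> LayeredStructure:
    """Decompose a crossing structure into the fewest pseudoknot-free levels.

    Pairs are ordered by helix (maximal stacks, descending length, then 5'
    start) and colored by deterministic backtracking with the minimum number
    of crossing-free classes; classes are then ranked by size (descending,
    ties 5'-first) so level 1 holds the dominant structure.  Exact and
    deterministic; the IP re-optimizes level assignment downstream anyway.
    """
    if max_levels < 1:
        raise StructureError("max_levels must be >= 1")
    ordered: list[BasePair] = []
    for h in sorted(_helices(structure.pairs), key=lambda h: (-len(h), h[0].i)):
        ordered.extend(h)
    if not ordered:
        return LayeredStructure([SecondaryStructure([], structure.length)], structure.length)

    crosses = [
        [a.crosses(b) for b in ordered] for a in ordered
    ]
    colors = [-1] * len(ordered)

    def backtrack(idx: int, k: int) -> bool:
        if idx == len(ordered):
            return True
        for c in range(k):
            if all(colors[o] != c or not crosses[idx][o] for o in range(idx)):
                colors[idx] = c
                if backtrack(idx + 1, k):
                    return True
        colors[idx] = -1
        return False

    n_levels = None
    for k in range(1, max_levels + 1):
        if backtrack(0, k):
            n_levels = k
            break
    if n_levels is None:
        residual = [p.as_tuple() for p in ordered]
        raise StructureError(
            f"pairs not colorable within {max_levels} levels: {sorted(residual)}"
        )
    groups: dict[int, list[BasePair]] = {}
    for p, c in zip(ordered, colors):
        groups.setdefault(c, []).append(p)
    ranked = sorted(
        groups.values(), key=lambda g: (-len(g), min(p.i for p in g))
    )
    levels = [SecondaryStructure(g, structure.length) for g in ranked]
    return LayeredStructure(levels, structure.length)


def read_fasta(handle) -> RnaSequence:
    """Read a single sequence from FASTA (path, file object, or raw text).

    The first record is taken; a warning is emitted if there are more.
    Raw (non-FASTA) text consisting of nucleotides is accepted as-is.
    """
    import warnings

    from Bio import SeqIO

    if isinstance(handle, str) and "\n" not in handle and not handle.lstrip().startswith(">"):
        try:
            with open(handle) as fh:
                return read_fasta(fh.read())
        except OSError:
            return RnaSequence(handle)
    text = handle if isinstance(handle, str) else handle.read()
    text = text.strip()
    if not text.startswith(">"):
        return RnaSequence("".join(text.split()))
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise StructureError("no FASTA records found")
    if len(records) > 1:
        warnings.warn(f"multiple FASTA records; using the first ({records[0].id})")
    return RnaSequence(str(records[0].seq), name=records[0].id)
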