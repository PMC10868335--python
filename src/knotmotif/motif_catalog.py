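"""Strand-based structural-motif catalogs and their placement on a sequence.

A motif is an ordered list of strands (5'->3'), each a pattern over
``{A, C, G, U, *}`` where ``*`` matches any nucleotide.  Hairpins have one
strand, interior loops and bulges two, k-way junctions k.  Matching a motif
against a sequence yields one candidate placement per (strand, interval)
occurrence; a motif contributes placements only if *every* strand matches
somewhere.  Geometric consistency (ordering, disjointness, anchoring) is the
integer program's job, not the matcher's.

Catalog file format (tab-separated, one motif per line, '#' comments)::

    <id> <TAB> <source_class> <TAB> <strand>,<strand>,...

``source_class`` is a provenance class used for blacklisting (e.g. removing
every motif that originates from the same nonredundant structure class as a
benchmark target).

In alignment mode a placement is eligible if its strand (i) literally
matches the target sequence there — always true for placements produced by
:func:`enumerate_placements` — and additionally has alignment support:
either a perfect target match (clause i) or at most Hamming distance 1 from
at least 50% of the alignment rows at those columns (clause ii).  Its weight
is the fraction of rows within Hamming distance 1, floored at a small
epsilon so clause-(i)-eligible motifs keep a positive objective weight.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .structure_core import RnaSequence, StructureError

__all__ = [
    "MotifStrand",
    "Motif",
    "CandidatePlacement",
    "Alignment",
    "CatalogError",
    "load_motif_catalog",
    "parse_motif_catalog",
    "write_motif_catalog",
    "match_strand",
    "enumerate_placements",
    "alignment_eligibility",
    "read_alignment",
    "MIN_ALIGNMENT_WEIGHT",
]

_STRAND_CHARS = set("ACGU*")

#: Weight floor for eligible placements with no row support (clause i only).
MIN_ALIGNMENT_WEIGHT = 0.05

GAP_CHARS = set("-.")


class CatalogError(StructureError):
    """Malformed motif catalog."""


@dataclass(frozen=True)
class MotifStrand:
    """One contiguous strand pattern over {A, C, G, U, *}."""

    pattern: str

    def __post_init__(self) -> None:
        pat = self.pattern.strip().upper().replace("T", "U")
        if not pat:
            raise CatalogError("empty strand pattern")
        bad = set(pat) - _STRAND_CHARS
        if bad:
            raise CatalogError(f"invalid strand character(s) {sorted(bad)!r} in {pat!r}")
        object.__setattr__(self, "pattern", pat)

    @property
    def k(self) -> int:
        return len(self.pattern)

    def matches_at(self, seq: str, a: int) -> bool:
        if a < 0 or a + self.k > len(seq):
            return False
        return all(pc == "*" or pc == seq[a + off] for off, pc in enumerate(self.pattern))


@dataclass(frozen=True)
class Motif:
    """An ordered multi-strand motif with an id and a provenance class."""

    id: str
    source_class: str
    strands: tuple[MotifStrand, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise CatalogError("motif id must be non-empty")
        strands = tuple(
            s if isinstance(s, MotifStrand) else MotifStrand(s) for s in self.strands
        )
        if not strands:
            raise CatalogError(f"motif {self.id!r} has no strands")
        object.__setattr__(self, "strands", strands)

    @property
    def n_strands(self) -> int:
        return len(self.strands)

    @property
    def size(self) -> int:
        """Total nucleotide count |x| over all strands."""
        return sum(s.k for s in self.strands)


@dataclass(frozen=True)
class CandidatePlacement:
    """Strand ``strand_index`` (1-based) of ``motif`` matched at [start, end].

    The interval is 0-based closed; ``weight`` defaults to 1.0 and is
    replaced by the alignment support weight in alignment mode.
    """

    motif: Motif
    strand_index: int
    start: int
    end: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        k = self.motif.strands[self.strand_index - 1].k
        if self.end - self.start + 1 != k:
            raise CatalogError(
                f"interval ({self.start}, {self.end}) does not fit strand length {k}"
            )
        if not (0.0 <= self.weight <= 1.0):
            raise CatalogError(f"weight {self.weight} outside [0, 1]")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def sort_key(self) -> tuple:
        return (self.motif.id, self.strand_index, self.start)

    def replace_weight(self, w: float) -> "CandidatePlacement":
        return CandidatePlacement(self.motif, self.strand_index, self.start, self.end, w)


# ---------------------------------------------------------------------------
# Catalog I/O


def parse_motif_catalog(text: str) -> list[Motif]:
    motifs: list[Motif] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise CatalogError(
                f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        mid, klass, strands = (p.strip() for p in parts)
        if mid in seen:
            raise CatalogError(f"line {lineno}: duplicate motif id {mid!r}")
        seen.add(mid)
        try:
            motifs.append(Motif(mid, klass, tuple(strands.split(","))))
        except CatalogError as exc:
            raise CatalogError(f"line {lineno}: {exc}") from exc
    if not motifs:
        warnings.warn("motif catalog is empty")
    return motifs


def load_motif_catalog(path) -> list[Motif]:
    """Load a catalog from a file path or file-like object."""
    if hasattr(path, "read"):
        return parse_motif_catalog(path.read())
    with open(path) as fh:
        return parse_motif_catalog(fh.read())


def write_motif_catalog(motifs: Iterable[Motif]) -> str:
    lines = [
        "\t".join((m.id, m.source_class, ",".join(s.pattern for s in m.strands)))
        for m in motifs
    ]
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Matching


def match_strand(strand: MotifStrand, seq: RnaSequence) -> list[tuple[int, int]]:
    """All closed intervals [a, a+k-1] where the pattern matches, 5' first.

    Overlapping occurrences are all reported.
    """
    s = seq.residues
    return [
        (a, a + strand.k - 1) for a in range(seq.n - strand.k + 1) if strand.matches_at(s, a)
    ]


def enumerate_placements(
    catalog: Sequence[Motif],
    seq: RnaSequence,
    blacklist: Optional[set[str]] = None,
) -> list[CandidatePlacement]:
    """All candidate placements of non-blacklisted motifs.

    A motif yields placements only if every one of its strands matches at
    least once (all-strands-matchable rule).  Output is deterministically
    sorted by (motif id, strand index, start).
    """
    blacklist = blacklist or set()
    out: list[CandidatePlacement] = []
    for motif in catalog:
        if motif.source_class in blacklist:
            continue
        per_strand = [match_strand(s, seq) for s in motif.strands]
        if any(not hits for hits in per_strand):
            continue
        for idx, hits in enumerate(per_strand, start=1):
            for (a, b) in hits:
                out.append(CandidatePlacement(motif, idx, a, b))
    out.sort(key=CandidatePlacement.sort_key)
    return out


# ---------------------------------------------------------------------------
# Alignments


class Alignment:
    """A gapped multiple sequence alignment with a designated target row.

    ``column_map`` maps each ungapped target position to its alignment
    column; removing gaps from the target row reproduces the input sequence.
    """

    def __init__(self, rows: Sequence[str], target_row: int = 0):
        rows = [r.strip().upper().replace("T", "U") for r in rows]
        if not rows:
            raise StructureError("alignment has no rows")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise StructureError("alignment rows have unequal lengths")
        if not (0 <= target_row < len(rows)):
            raise StructureError(f"target row {target_row} out of range")
        self.rows = rows
        self.target_row = target_row
        self.column_map: dict[int, int] = {}
        k = 0
        for c, ch in enumerate(rows[target_row]):
            if ch not in GAP_CHARS:
                self.column_map[k] = c
                k += 1

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def target_sequence(self) -> RnaSequence:
        ungapped = "".join(
            ch for ch in self.rows[self.target_row] if ch not in GAP_CHARS
        )
        return RnaSequence(ungapped)

    @classmethod
    def from_sequences_with_target(cls, rows: Sequence[str], target: RnaSequence) -> "Alignment":
        """Locate the row whose ungapped form equals ``target``."""
        for r, row in enumerate(rows):
            ungapped = "".join(ch for ch in row.upper().replace("T", "U") if ch not in GAP_CHARS)
            if ungapped == target.residues:
                return cls(rows, target_row=r)
        raise StructureError("target sequence not found among alignment rows")


def read_alignment(handle, fmt: Optional[str] = None, target_row: int = 0) -> Alignment:
    """Read Stockholm / Clustal / aligned-FASTA via Biopython AlignIO."""
    from Bio import AlignIO

    if isinstance(handle, str) and "\n" not in handle:
        with open(handle) as fh:
            text = fh.read()
    else:
        text = handle if isinstance(handle, str) else handle.read()
    formats = [fmt] if fmt else ["stockholm", "clustal", "fasta"]
    last_exc: Optional[Exception] = None
    for f in formats:
        try:
            aln = AlignIO.read(io.StringIO(text), f)
            return Alignment([str(rec.seq) for rec in aln], target_row=target_row)
        except Exception as exc:  # Biopython raises bare ValueError on format mismatch
            last_exc = exc
    raise StructureError(f"could not parse alignment: {last_exc}")


def _row_segment(alignment: Alignment, row: str, start: int, end: int) -> str:
    cols = [alignment.column_map[i] for i in range(start, end + 1)]
    return "".join(row[c] for c in cols)


def _hamming_to_pattern(pattern: str, segment: str) -> int:
    """Wildcards count as distance 0; any gap character is a mismatch."""
    d = 0
    for pc, sc in zip(pattern, segment):
        if sc in GAP_CHARS or (pc != "*" and pc != sc):
            d += 1
    return d


def alignment_eligibility(
    placement: CandidatePlacement, alignment: Alignment
) -> tuple[bool, float]:
    """Eligibility and support weight of a placement under an alignment.

    Eligible iff the strand perfectly matches the target sequence at the
    placement (clause i — always true for matcher output, wildcards count
    as matches) or at least 50% of rows are within Hamming distance 1 of
    the strand pattern over those columns (clause ii).  The weight is the
    fraction of rows within distance 1, floored at
    :data:`MIN_ALIGNMENT_WEIGHT` for eligible placements.
    """
    if any(i not in alignment.column_map for i in (placement.start, placement.end)):
        raise StructureError(
            f"placement interval ({placement.start}, {placement.end}) maps outside the alignment"
        )
    pattern = placement.motif.strands[placement.strand_index - 1].pattern
    target = alignment.rows[alignment.target_row]
    target_seg = _row_segment(alignment, target, placement.start, placement.end)
    clause_i = _hamming_to_pattern(pattern, target_seg) == 0

    within = sum(
        1
        for row in alignment.rows
        if _hamming_to_pattern(pattern, _row_segment(alignment, row, placement.start, placement.end)) <= 1
    )
    frac = within / alignment.n_rows
    eligible = clause_i or frac >= 0.5
    if not eligible:
        return False, 0.0
    return True, max(frac, MIN_ALIGNMENT_WEIGHT)
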