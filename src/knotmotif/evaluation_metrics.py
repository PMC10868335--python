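"""Scoring predictions against reference structures and interaction annotations.

PPV = TP/(TP+FP), STY (sensitivity) = TP/(TP+FN) and their harmonic mean F1
over exact base-pair identity; any metric with a zero denominator is 0 by
convention.  Optionally, base pairs falling entirely inside an inserted
motif's positions can be counted as true positives (a relaxation used when
judging how much structure the motifs themselves account for; off by
default — the strict metric is the comparable one).

Pseudoknot-level correctness compares the number of nonempty levels of the
predicted and reference layered structures.  Motif-interaction scoring
restricts Leontis-Westhof-annotated reference interactions to the inserted
positions, split into canonical/Wobble cWW pairs versus everything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from .motif_catalog import CandidatePlacement
from .structure_core import BasePair, LayeredStructure, RnaSequence, StructureError

__all__ = [
    "LW_FAMILIES",
    "InteractionAnnotation",
    "MetricReport",
    "score_pairs",
    "score_pk_level",
    "score_motif_interactions",
    "read_annotations",
]

#: The 12 Leontis-Westhof base-pair geometry families (cis/trans x
#: Watson-Crick/Hoogsteen/Sugar edge combinations, unordered).
LW_FAMILIES = frozenset(
    {
        "cWW", "tWW", "cWH", "tWH", "cWS", "tWS",
        "cHH", "tHH", "cHS", "tHS", "cSS", "tSS",
    }
)

_EDGE_ORDER = {"W": 0, "H": 1, "S": 2}
_CANONICAL_NT = {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}


def _normalize_lw(lw: str) -> str:
    """Normalize edge order (cHW -> cWH); validate against the 12 families."""
    if len(lw) != 3 or lw[0] not in "ct":
        raise StructureError(f"invalid Leontis-Westhof type {lw!r}")
    a, b = lw[1].upper(), lw[2].upper()
    if a not in _EDGE_ORDER or b not in _EDGE_ORDER:
        raise StructureError(f"invalid Leontis-Westhof type {lw!r}")
    if _EDGE_ORDER[a] > _EDGE_ORDER[b]:
        a, b = b, a
    norm = lw[0] + a + b
    if norm not in LW_FAMILIES:
        raise StructureError(f"invalid Leontis-Westhof type {lw!r}")
    return norm


class InteractionAnnotation:
    """Typed reference interactions: (i, j, lw_family), 0-based, i < j."""

    def __init__(self, pairs: Iterable[tuple[int, int, str]]):
        norm = []
        for (i, j, lw) in pairs:
            if not (0 <= i < j):
                raise StructureError(f"annotation requires 0 <= i < j, got ({i}, {j})")
            norm.append((i, j, _normalize_lw(lw)))
        self.pairs: list[tuple[int, int, str]] = sorted(norm)

    def __len__(self) -> int:
        return len(self.pairs)


def read_annotations(text: str) -> InteractionAnnotation:
    """Parse tab-separated 'i<TAB>j<TAB>lw_type' lines (1-based)."""
    pairs = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise StructureError(f"annotation line {lineno}: expected 'i j lw_type'")
        i, j = int(parts[0]) - 1, int(parts[1]) - 1
        pairs.append((min(i, j), max(i, j), parts[2]))
    return InteractionAnnotation(pairs)


@dataclass(frozen=True)
class MetricReport:
    TP: int
    FP: int
    FN: int
    motif_tp_relaxation: bool = False

    @property
    def PPV(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 0.0

    @property
    def STY(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def F1(self) -> float:
        p, s = self.PPV, self.STY
        return 2 * p * s / (p + s) if p + s else 0.0

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "FN": self.FN,
            "PPV": self.PPV, "STY": self.STY, "F1": self.F1,
        }


def _as_tuple_set(pairs) -> set[tuple[int, int]]:
    out = set()
    for p in pairs:
        if isinstance(p, BasePair):
            out.add(p.as_tuple())
        else:
            i, j = p
            out.add((min(i, j), max(i, j)))
    return out


def score_pairs(
    predicted,
    reference,
    motif_positions: Optional[Sequence[Iterable[int]]] = None,
    motif_as_tp: bool = False,
) -> MetricReport:
    """Exact-identity base-pair contingency counts and PPV/STY/F1.

    With ``motif_as_tp`` and ``motif_positions`` (one position set per
    inserted motif), any predicted-or-reference pair whose endpoints both
    fall inside a single motif's combined positions is counted as a true
    positive rather than FP/FN.
    """
    pred = _as_tuple_set(predicted)
    ref = _as_tuple_set(reference)
    tp = len(pred & ref)
    fp_set = pred - ref
    fn_set = ref - pred
    if motif_as_tp and motif_positions:
        pos_sets = [set(ps) for ps in motif_positions]

        def inside_one_motif(pair: tuple[int, int]) -> bool:
            return any(pair[0] in ps and pair[1] in ps for ps in pos_sets)

        promoted_fp = {p for p in fp_set if inside_one_motif(p)}
        promoted_fn = {p for p in fn_set if inside_one_motif(p)}
        tp += len(promoted_fp) + len(promoted_fn)
        fp_set -= promoted_fp
        fn_set -= promoted_fn
    return MetricReport(tp, len(fp_set), len(fn_set), motif_tp_relaxation=motif_as_tp)


def score_pk_level(
    predicted: LayeredStructure, reference: LayeredStructure
) -> Literal["too_low", "correct", "too_high"]:
    """Compare nonempty-level counts of prediction and reference."""
    p, r = predicted.nonempty_level_count(), reference.nonempty_level_count()
    if p < r:
        return "too_low"
    if p > r:
        return "too_high"
    return "correct"


def score_motif_interactions(
    insertions: Sequence[CandidatePlacement],
    annotations: InteractionAnnotation,
    mode: Literal["canonical_wobble", "noncanonical"],
    seq: RnaSequence,
    predicted_pairs: Iterable = (),
) -> MetricReport:
    """Score annotated interactions at inserted-motif positions.

    Positives are the annotated interactions of the selected mode with both
    endpoints among inserted positions: ``canonical_wobble`` keeps cWW
    pairs whose nucleotides are G-C/A-U/G-U; ``noncanonical`` keeps
    everything else.  Predictions are the supplied pairs (typically the
    solution's own base pairs) restricted to the same positions.
    """
    if mode not in ("canonical_wobble", "noncanonical"):
        raise StructureError(f"unknown scoring mode {mode!r}")
    inserted: set[int] = set()
    for pl in insertions:
        inserted.update(range(pl.start, pl.end + 1))
    for (i, j, _) in annotations.pairs:
        if j >= seq.n:
            raise StructureError(f"annotation ({i + 1}, {j + 1}) out of range for n={seq.n}")

    def is_canonical_cww(i: int, j: int, lw: str) -> bool:
        return lw == "cWW" and (seq[i], seq[j]) in _CANONICAL_NT

    positives = set()
    for (i, j, lw) in annotations.pairs:
        if i in inserted and j in inserted:
            canon = is_canonical_cww(i, j, lw)
            if (mode == "canonical_wobble") == canon:
                positives.add((i, j))

    preds = {
        (i, j)
        for (i, j) in _as_tuple_set(predicted_pairs)
        if i in inserted and j in inserted
    }
    tp = len(preds & positives)
    return MetricReport(tp, len(preds - positives), len(positives - preds))
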