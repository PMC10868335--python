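"""Iterative prediction loop: fold -> sum -> match -> optimize -> repeat.

Each iteration decomposes the current structure into pseudoknot-free
levels, computes one hard-constrained base-pair probability matrix per
level, sums them into the pseudo-probability matrix, matches the motif
catalog against the sequence, and solves the integer program.  The loop
stops when two consecutive iterations return the identical solution (pair
sets and insertion sets; objective values are not compared), when the
iteration cap is reached, or when the global time budget is exhausted.

In alignment mode the probabilities come from the consensus model
(:func:`knotmotif.bpp_engine.alignment_bpp`) and placements are filtered
and weighted by their alignment support.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .bpp_engine import (
    FoldConstraints,
    alignment_bpp,
    constrained_level_bpps,
    sum_pseudo_bpp,
)
from .ip_optimizer import (
    IpModelSpec,
    IpSolution,
    build_model,
    collect_candidate_pairs,
    solve_ip,
)
from .motif_catalog import (
    Alignment,
    CandidatePlacement,
    Motif,
    alignment_eligibility,
    enumerate_placements,
)
from .structure_core import (
    LayeredStructure,
    RnaSequence,
    SecondaryStructure,
    StructureError,
    decompose_layers,
    write_dotbracket,
)

__all__ = [
    "PipelineConfig",
    "PredictionResult",
    "PipelineError",
    "predict",
    "predict_with_alignment",
    "serialize_result",
    "parse_result",
]


class PipelineError(StructureError):
    """Prediction failed (infeasible model on the first iteration, etc.)."""

    def __init__(self, message: str, status: str = "error"):
        super().__init__(message)
        self.status = status


@dataclass
class PipelineConfig:
    """Tunable parameters of the prediction loop.

    ``alpha`` balances pairing probabilities against motif-insertion
    bonuses (0 disables insertions entirely); ``m`` is the maximum number
    of crossing levels; ``threshold`` is the minimum pseudo-probability for
    a candidate pair; the time limit is a global budget in seconds shared
    by all iterations.
    """

    alpha: float = 0.1
    m: int = 3
    threshold: float = 0.01
    max_iterations: int = 3
    time_limit_s: float = 10000.0
    fold_backend: str = "internal"
    solver_backend: str = "highs"
    seed: int = 0
    min_paired_fraction: float = 0.25
    blacklist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise PipelineError("max_iterations must be >= 1")
        if self.time_limit_s <= 0:
            raise PipelineError("time_limit_s must be positive")


@dataclass
class PredictionResult:
    sequence: RnaSequence
    structure: LayeredStructure
    insertions: list[CandidatePlacement]
    objective: float
    status: str
    iterations_run: int
    trace: list[dict] = field(default_factory=list)
    config: Optional[PipelineConfig] = None

    def dotbracket(self) -> str:
        return write_dotbracket(self.structure)


def _weighted_placements(
    placements: Sequence[CandidatePlacement], alignment: Alignment
) -> list[CandidatePlacement]:
    """Filter by alignment eligibility; weight strand-1 variables.

    The insertion bonus is attached to strand-1 variables, so each
    strand-1 placement carries the motif-level weight: the mean over
    strands of the best support weight among that strand's eligible
    placements (its own weight for strand 1).
    """
    eligible: list[tuple[CandidatePlacement, float]] = []
    for pl in placements:
        ok, w = alignment_eligibility(pl, alignment)
        if ok:
            eligible.append((pl, w))
    best_by_strand: dict[tuple[str, int], float] = {}
    strands_present: dict[str, set[int]] = {}
    for pl, w in eligible:
        key = (pl.motif.id, pl.strand_index)
        best_by_strand[key] = max(best_by_strand.get(key, 0.0), w)
        strands_present.setdefault(pl.motif.id, set()).add(pl.strand_index)
    out: list[CandidatePlacement] = []
    for pl, w in eligible:
        need = set(range(1, pl.motif.n_strands + 1))
        if strands_present.get(pl.motif.id, set()) != need:
            continue  # a strand lost all eligible placements
        if pl.strand_index == 1:
            per_strand = [w] + [
                best_by_strand[(pl.motif.id, s)] for s in range(2, pl.motif.n_strands + 1)
            ]
            w = sum(per_strand) / len(per_strand)
        out.append(pl.replace_weight(w))
    return out


def _run_loop(
    seq: RnaSequence,
    initial: Optional[LayeredStructure],
    catalog: Sequence[Motif],
    config: PipelineConfig,
    bpp_fn,
    placements: list[CandidatePlacement],
) -> PredictionResult:
    deadline = time.monotonic() + config.time_limit_s
    layered = initial
    prev_key = None
    last: Optional[IpSolution] = None
    trace: list[dict] = []
    iterations = 0

    for it in range(1, config.max_iterations + 1):
        iterations = it
        matrices = bpp_fn(layered)
        pbpp = sum_pseudo_bpp(matrices)
        B = collect_candidate_pairs(pbpp, seq, config.threshold)
        spec = IpModelSpec(
            n=seq.n,
            m=config.m,
            B=B,
            placements=list(placements),
            alpha=config.alpha,
            min_paired_fraction=config.min_paired_fraction,
        )
        remaining = max(deadline - time.monotonic(), 0.01)
        sol = solve_ip(
            build_model(spec), config.solver_backend, remaining, config.seed
        )
        entry = {
            "iteration": it,
            "status": sol.status,
            "objective": sol.objective,
            "n_candidate_pairs": len(B),
            "n_pairs": sum(len(l) for l in sol.pairs_by_level.levels),
            "n_insertions": len(sol.insertions),
            "timed_out_incumbent": sol.status == "feasible",
        }
        trace.append(entry)
        if sol.status in ("infeasible", "timeout"):
            if last is None:
                raise PipelineError(
                    f"iteration 1 produced no solution (status: {sol.status})",
                    status=sol.status,
                )
            iterations = it
            break
        key = sol.canonical_key()
        last = sol
        if key == prev_key:
            entry["converged"] = True
            break
        prev_key = key
        layered = sol.pairs_by_level
        if time.monotonic() >= deadline:
            break

    assert last is not None
    return PredictionResult(
        sequence=seq,
        structure=last.pairs_by_level,
        insertions=last.insertions,
        objective=last.objective,
        status=last.status,
        iterations_run=iterations,
        trace=trace,
        config=config,
    )


def predict(
    seq: RnaSequence,
    initial: Optional[SecondaryStructure | LayeredStructure] = None,
    catalog: Sequence[Motif] = (),
    config: Optional[PipelineConfig] = None,
) -> PredictionResult:
    """Predict a pseudoknotted structure with motif insertions."""
    config = config or PipelineConfig()
    layered = None
    if initial is not None:
        if isinstance(initial, SecondaryStructure):
            layered = decompose_layers(initial, config.m)
        else:
            layered = initial
    placements = enumerate_placements(list(catalog), seq, set(config.blacklist))

    def bpp_fn(layered_now):
        return constrained_level_bpps(seq, layered_now, config.fold_backend)

    return _run_loop(seq, layered, catalog, config, bpp_fn, placements)


def predict_with_alignment(
    alignment: Alignment,
    initial: Optional[SecondaryStructure | LayeredStructure] = None,
    catalog: Sequence[Motif] = (),
    config: Optional[PipelineConfig] = None,
) -> PredictionResult:
    """As :func:`predict`, with consensus probabilities and weighted motifs."""
    config = config or PipelineConfig()
    seq = alignment.target_sequence()
    layered = None
    if initial is not None:
        if isinstance(initial, SecondaryStructure):
            layered = decompose_layers(initial, config.m)
        else:
            layered = initial
    placements = _weighted_placements(
        enumerate_placements(list(catalog), seq, set(config.blacklist)), alignment
    )

    def bpp_fn(layered_now):
        if layered_now is None or layered_now.nonempty_level_count() == 0:
            return [alignment_bpp(alignment, config.fold_backend)]
        levels = [lvl for lvl in layered_now.levels if len(lvl) > 0]
        out = []
        for q, lvl in enumerate(levels):
            others = {
                pos
                for r, other in enumerate(levels)
                if r != q
                for pos in other.paired_positions()
            }
            fc = FoldConstraints(frozenset(lvl.pairs), frozenset(others))
            out.append(
                alignment_bpp(alignment, config.fold_backend, constraints=fc)
            )
        return out

    return _run_loop(seq, layered, catalog, config, bpp_fn, placements)


# ---------------------------------------------------------------------------
# Result document


def serialize_result(result: PredictionResult) -> str:
    """Canonical JSON result document (1-based coordinates; round-trips)."""
    from . import __version__

    doc = {
        "format": "knotmotif-result",
        "version": __version__,
        "sequence": result.sequence.residues,
        "name": result.sequence.name,
        "dotbracket": result.dotbracket(),
        "levels": [
            [[i + 1, j + 1] for (i, j) in lvl.as_tuples()]
            for lvl in result.structure.levels
        ],
        "insertions": [
            {
                "motif": p.motif.id,
                "source_class": p.motif.source_class,
                "strand": p.strand_index,
                "interval": [p.start + 1, p.end + 1],
                "pattern": p.motif.strands[p.strand_index - 1].pattern,
                "all_strands": [s.pattern for s in p.motif.strands],
                "weight": p.weight,
            }
            for p in sorted(result.insertions, key=CandidatePlacement.sort_key)
        ],
        "objective": result.objective,
        "status": result.status,
        "iterations_run": result.iterations_run,
        "trace": result.trace,
        "config": (
            {
                "alpha": result.config.alpha,
                "m": result.config.m,
                "threshold": result.config.threshold,
                "max_iterations": result.config.max_iterations,
                "time_limit_s": result.config.time_limit_s,
                "fold_backend": result.config.fold_backend,
                "solver_backend": result.config.solver_backend,
                "seed": result.config.seed,
                "min_paired_fraction": result.config.min_paired_fraction,
            }
            if result.config
            else None
        ),
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def parse_result(text: str) -> PredictionResult:
    """Reload a serialized result document."""
    doc = json.loads(text)
    if doc.get("format") != "knotmotif-result":
        raise PipelineError("not a knotmotif result document")
    seq = RnaSequence(doc["sequence"], name=doc.get("name", ""))
    levels = [
        SecondaryStructure([(i - 1, j - 1) for (i, j) in lvl], seq.n)
        for lvl in doc["levels"]
    ]
    insertions = []
    for rec in doc["insertions"]:
        motif = Motif(rec["motif"], rec["source_class"], tuple(rec["all_strands"]))
        insertions.append(
            CandidatePlacement(
                motif,
                rec["strand"],
                rec["interval"][0] - 1,
                rec["interval"][1] - 1,
                rec["weight"],
            )
        )
    cfg = None
    if doc.get("config"):
        cfg = PipelineConfig(**doc["config"])
    return PredictionResult(
        sequence=seq,
        structure=LayeredStructure(levels, seq.n),
        insertions=insertions,
        objective=doc["objective"],
        status=doc["status"],
        iterations_run=doc["iterations_run"],
        trace=doc.get("trace", []),
        config=cfg,
    )
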