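"""Greedy coordinate ascent over a mixed parameter space.

Starting from the default parameter vector, the search repeatedly cycles
through the parameters in declaration order and, for each coordinate,
proposes the single-step moves that kind allows: one step down/up for
numeric parameters (clamped to the bounds; multiplied/divided for
scale-like parameters), the flip for booleans, and every alternative for
categoricals.  A proposal is accepted only on a strict improvement of the
scaled AUC, so the final vector never scores below the start and the
procedure terminates — a full pass with no acceptance is the stopping
condition.  The objective is memoized: no vector is ever evaluated twice.

This is deliberately a single deterministic run from the default, with no
restarts: the assembler parameter landscapes this targets have very few
local maxima, so one greedy pass schedule recovers (near-)optimal vectors
at a predictable objective-call budget.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Sequence

from . import evaluation
from .advisor_core import (
    AdvisorSet,
    ParameterSpec,
    ParameterVector,
    default_vector,
    validate_vector,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class AscentConfig:
    """Knobs of the greedy search.

    ``direction_policy`` — "best-of-both" evaluates every proposal for a
    coordinate and takes the best; "first-improvement" accepts the first
    proposal that improves.  ``min_improvement`` is the strict margin on
    scaled AUC a proposal must exceed; 0 still demands a strictly larger
    value.  ``seed`` only shuffles the order in which a coordinate's
    proposals are evaluated, for reproducible tie handling; 0 keeps the
    natural down/up (or declaration) order.
    """

    max_passes: int = 20
    direction_policy: str = "best-of-both"
    min_improvement: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_passes < 1:
            raise ValidationError("max_passes must be >= 1")
        if self.direction_policy not in ("best-of-both", "first-improvement"):
            raise ValidationError(f"unknown direction_policy {self.direction_policy!r}")
        if self.min_improvement < 0:
            raise ValidationError("min_improvement must be non-negative")


@dataclass
class AscentTrace:
    """Accepted steps and bookkeeping of one ascent run."""

    steps: list[tuple[str, Any, Any, float]] = field(default_factory=list)
    evaluations: int = 0
    start_auc: float = 0.0
    final_auc: float = 0.0


def _proposals(p: ParameterSpec, current: Any) -> list[Any]:
    """Single-step moves for one coordinate, excluding the current value."""
    if p.kind in ("integer", "real"):
        if p.multiplicative:
            down, up = current / p.step, current * p.step
        else:
            down, up = current - p.step, current + p.step
        cast = (lambda x: int(round(x))) if p.kind == "integer" else float
        moves = []
        for x in (down, up):
            x = cast(min(max(x, p.lower), p.upper))
            if x != current and x not in moves:
                moves.append(x)
        return moves
    if p.kind == "boolean":
        return [not current]
    return [c for c in p.choices if c != current]


def coordinate_ascent(
    start: ParameterVector,
    spec: Sequence[ParameterSpec],
    objective: Callable[[ParameterVector], float],
    config: AscentConfig | None = None,
) -> tuple[ParameterVector, AscentTrace]:
    """Greedy coordinate ascent of ``objective`` from ``start``.

    Returns the incumbent vector and the full trace.  The objective must
    evaluate on ``start`` (errors there propagate); elsewhere a raising
    objective is treated as scoring 0 with a warning, mirroring a failed
    assembler run.
    """
    config = config or AscentConfig()
    violations = validate_vector(spec, start)
    if violations:
        raise ValidationError("invalid start vector: " + "; ".join(violations))

    trace = AscentTrace()
    memo: dict[tuple, float] = {}

    def evaluate(v: ParameterVector, is_start: bool = False) -> float:
        k = v.key()
        if k in memo:
            return memo[k]
        trace.evaluations += 1
        try:
            val = float(objective(v))
        except Exception:
            if is_start:
                raise
            logger.warning("objective failed on %s; scored 0", dict(v.values))
            val = 0.0
        memo[k] = val
        return val

    rng = random.Random(config.seed) if config.seed else None
    incumbent = ParameterVector(dict(start.values), provenance=start.provenance)
    f_inc = evaluate(incumbent, is_start=True)
    trace.start_auc = f_inc

    for _pass in range(config.max_passes):
        accepted_any = False
        for p in spec:
            current = incumbent.values[p.name]
            moves = _proposals(p, current)
            if rng is not None:
                rng.shuffle(moves)
            best_move, best_val = None, f_inc
            for m in moves:
                cand = ParameterVector({**incumbent.values, p.name: m})
                val = evaluate(cand)
                if val <= f_inc + config.min_improvement:
                    continue
                if best_move is None or val > best_val:
                    best_move, best_val = m, val
                if config.direction_policy == "first-improvement":
                    break
            if best_move is not None:
                incumbent = ParameterVector(
                    {**incumbent.values, p.name: best_move},
                    provenance=incumbent.provenance,
                )
                trace.steps.append((p.name, current, best_move, best_val))
                f_inc = best_val
                accepted_any = True
        if not accepted_any:
            break

    trace.final_auc = f_inc
    incumbent.provenance = start.provenance or "CA"
    return incumbent, trace


def build_advisor_set(
    samples: Sequence[str | Path],
    spec: Sequence[ParameterSpec],
    adapter: "AssemblerAdapter",
    ref_gtf: str | Path,
    config: AscentConfig | None = None,
    include_default: bool = True,
    workdir: str | Path | None = None,
    single_exon_overlap: float = evaluation.DEFAULT_SINGLE_EXON_OVERLAP,
) -> AdvisorSet:
    """Run coordinate ascent per training sample; collect the distinct optima.

    Each sample's objective is the scaled AUC of the assembly the adapter
    produces under a candidate vector, scored against ``ref_gtf``.  The
    resulting vectors are deduplicated and tagged with their source
    sample; with ``include_default`` the default vector is prepended, so
    advising with the returned set can never score below the default.
    """
    import tempfile

    from .gtf_io import read_gtf

    if not samples:
        raise ValidationError("need at least one training sample")
    workdir = Path(workdir) if workdir is not None else Path(tempfile.mkdtemp(prefix="ascent_"))
    workdir.mkdir(parents=True, exist_ok=True)
    ref = read_gtf(ref_gtf)

    vectors: list[ParameterVector] = []
    if include_default:
        vectors.append(default_vector(spec))
    seen = {v.key() for v in vectors}

    for sample in samples:
        sample = Path(sample)
        out_dir = workdir / sample.stem
        out_dir.mkdir(exist_ok=True)

        def objective(v: ParameterVector) -> float:
            path = adapter.run(sample, v, out_dir)
            return evaluation.auc(path, ref, single_exon_overlap=single_exon_overlap)

        best, trace = coordinate_ascent(default_vector(spec), spec, objective, config)
        logger.info(
            "sample %s: AUC %.2f -> %.2f in %d evaluations",
            sample.name, trace.start_auc, trace.final_auc, trace.evaluations,
        )
        best = ParameterVector(dict(best.values), provenance=f"CA:{sample.stem}")
        if best.key() not in seen:
            vectors.append(best)
            seen.add(best.key())

    return AdvisorSet(vectors=vectors, includes_default=include_default)
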