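"""Segmentation round planning: coarse tiling and branch-and-bound refinement.

The workflow starts with a coarse partition of the repeat protein into a
few overlapping segments (overlap hedges against misfolding of repeats at
non-native cap junctions). Binding calls on those segments then drive a
pruning step: units in the *trusted core* of a non-binding segment (the
segment minus an edge-distrust margin at each end) cannot belong to a
paratope and are removed from the positive regions. Each surviving
candidate region is refined with a stride-1 tiling whose sub-segment
length is chosen from the entropy-admissible set — by default the largest
admissible length, trading a little information for better-folding
constructs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .entropy_design import entropy_profile
from .repeat_model import ConstructDesign, RepeatProtein, UnitWindow

logger = logging.getLogger(__name__)


class Verdict(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class BindingCall:
    """Per-construct binding verdict, optionally backed by a ΔCq statistic."""

    construct_id: str
    verdict: Verdict
    evidence: float | None = None


@dataclass(frozen=True)
class PlanParams:
    """Design parameters that produced a round's construct set."""

    n: int | None = None  # window length within the round (refinement rounds)
    overlaps: tuple[int, ...] = ()  # junction overlaps (initial partition)
    tolerance: float = 0.9
    edge_margin: int = 2


@dataclass
class SegmentationPlan:
    """One round's full set of constructs plus its design parameters."""

    round_id: str
    protein: RepeatProtein
    constructs: list[ConstructDesign]
    params: PlanParams = field(default_factory=PlanParams)

    def windows(self) -> list[UnitWindow]:
        return [c.window for c in self.constructs]

    def construct(self, construct_id: str) -> ConstructDesign:
        for c in self.constructs:
            if c.construct_id == construct_id:
                return c
        raise KeyError(f"no construct {construct_id!r} in round {self.round_id}")


def _make_construct(protein: RepeatProtein, window: UnitWindow) -> ConstructDesign:
    return ConstructDesign(
        construct_id=f"LRR{window.label}", window=window, protein=protein
    )


def initial_partition(
    protein: RepeatProtein,
    k: int,
    segment_length: int,
    *,
    tolerance: float = 0.9,
    edge_margin: int = 2,
    round_id: str = "initial",
) -> SegmentationPlan:
    """Partition the repeats into ``k`` segments of ``segment_length`` each.

    Segments cover every repeat; the total excess ``k*s - R`` is spread
    over the ``k - 1`` junctions as evenly as possible, with larger
    overlaps assigned to earlier junctions on ties. Segment bounds are
    repeat indices; a loopout lying inside a segment rides along in
    assembly and unit accounting.

    Raises
    ------
    ValueError
        If ``k * segment_length < n_repeats`` (cannot cover) or the
        required overlaps are infeasible.
    """
    R = protein.n_repeats
    s = segment_length
    if s < 1 or s > R:
        raise ValueError(f"segment length {s} outside [1, {R}]")
    excess = k * s - R
    if excess < 0:
        raise ValueError(
            f"cannot cover {R} units with {k} segments of length {s} "
            f"({k}*{s} = {k * s} < {R})"
        )
    if k == 1:
        overlaps: list[int] = []
        starts = [1]
    else:
        base, rem = divmod(excess, k - 1)
        overlaps = [base + 1 if j < rem else base for j in range(k - 1)]
        if any(o > s - 1 for o in overlaps):
            raise ValueError(
                f"required junction overlaps {overlaps} exceed segment span {s}"
            )
        starts = [1]
        for o in overlaps:
            starts.append(starts[-1] + s - o)
    constructs = [
        _make_construct(protein, protein.window(a, a + s - 1)) for a in starts
    ]
    return SegmentationPlan(
        round_id=round_id,
        protein=protein,
        constructs=constructs,
        params=PlanParams(
            n=s, overlaps=tuple(overlaps), tolerance=tolerance, edge_margin=edge_margin
        ),
    )


def prune_candidates(
    protein: RepeatProtein,
    positives: Sequence[UnitWindow],
    negatives: Sequence[UnitWindow],
    edge_margin: int = 2,
) -> list[UnitWindow]:
    """Subtract trusted cores of negative windows from positive windows.

    The trusted core of a negative window is the window minus
    ``edge_margin`` units at each end — edge units are distrusted because
    repeats abutting a non-native cap junction may simply have misfolded.
    Units remaining after subtraction are returned as maximal contiguous
    windows in protein order; the result may be empty.
    """
    if edge_margin < 0:
        raise ValueError(f"edge_margin must be >= 0, got {edge_margin}")
    covered: set[int] = set()
    for w in positives:
        covered.update(protein.window_ordinals(w))
    for w in negatives:
        a, b = min(protein.window_ordinals(w)), max(protein.window_ordinals(w))
        core_a, core_b = a + edge_margin, b - edge_margin
        if core_a <= core_b:
            covered.difference_update(range(core_a, core_b + 1))
    return _ordinals_to_windows(protein, covered)


def _ordinals_to_windows(protein: RepeatProtein, ordinals: set[int]) -> list[UnitWindow]:
    """Maximal contiguous runs of ordinals as sorted windows."""
    windows: list[UnitWindow] = []
    run_start = prev = None
    for p in sorted(ordinals):
        if run_start is None:
            run_start = prev = p
        elif p == prev + 1:
            prev = p
        else:
            windows.append(protein.window_from_ordinals(run_start, prev))
            run_start = prev = p
    if run_start is not None:
        windows.append(protein.window_from_ordinals(run_start, prev))
    return windows


def plan_refinement(
    protein: RepeatProtein,
    region: UnitWindow,
    *,
    tolerance: float = 0.9,
    selection: str = "largest",
    n: int | None = None,
    edge_margin: int = 2,
    round_id: str | None = None,
) -> SegmentationPlan:
    """Stride-1 tiling of a candidate region at an admissible length.

    Parameters
    ----------
    selection:
        ``"largest"`` (default) takes the largest entropy-admissible
        length; ``"max_entropy"`` takes the entropy-maximal one. An
        explicit ``n`` overrides both; if it exceeds the region length it
        falls back to the full region with a warning.
    """
    L = protein.window_length(region)
    profile = entropy_profile(L)
    if n is None:
        admissible = profile.admissible(tolerance)
        chosen = max(admissible) if selection == "largest" else profile.argmax_n
    else:
        chosen = n
    if chosen > L:
        logger.warning(
            "requested sub-segment length %d exceeds region %s (L=%d); using n=L",
            chosen,
            region.label,
            L,
        )
        chosen = L
    start0 = protein.ordinal(region.start_unit)
    constructs = [
        _make_construct(protein, protein.window_from_ordinals(a, a + chosen - 1))
        for a in range(start0, start0 + L - chosen + 1)
    ]
    return SegmentationPlan(
        round_id=round_id or f"refine-{region.label}",
        protein=protein,
        constructs=constructs,
        params=PlanParams(n=chosen, tolerance=tolerance, edge_margin=edge_margin),
    )


def branch_step(
    plan: SegmentationPlan,
    calls: Sequence[BindingCall],
    next_n: int | None = None,
    *,
    tolerance: float | None = None,
    edge_margin: int | None = None,
) -> list[SegmentationPlan]:
    """One branch-and-bound step: prune on the calls, plan refinements.

    Every construct in the plan must have a call. Positive windows seed
    candidate regions; negative windows prune via their trusted cores;
    inconclusive calls contribute no evidence either way (a weak signal
    cannot distinguish non-binding from misfolding). Returns one
    refinement plan per surviving disjoint region, or an empty list when
    nothing bound.
    """
    by_id = {c.construct_id: c for c in plan.constructs}
    call_ids = {c.construct_id for c in calls}
    missing = sorted(set(by_id) - call_ids)
    if missing:
        raise ValueError(f"constructs without binding calls: {missing}")
    unknown = sorted(call_ids - set(by_id))
    if unknown:
        raise ValueError(f"calls for unknown constructs: {unknown}")

    positives = [by_id[c.construct_id].window for c in calls if c.verdict == Verdict.POSITIVE]
    negatives = [by_id[c.construct_id].window for c in calls if c.verdict == Verdict.NEGATIVE]
    if not positives:
        logger.info("no binding detected in round %s; nothing to refine", plan.round_id)
        return []

    tol = plan.params.tolerance if tolerance is None else tolerance
    margin = plan.params.edge_margin if edge_margin is None else edge_margin
    regions = prune_candidates(plan.protein, positives, negatives, margin)
    return [
        plan_refinement(
            plan.protein,
            region,
            tolerance=tol,
            n=next_n,
            edge_margin=margin,
            round_id=f"{plan.round_id}/refine-{region.label}",
        )
        for region in regions
    ]
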