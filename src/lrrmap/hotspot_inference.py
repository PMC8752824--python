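"""Hotspot calling: per-unit support from significant constructs.

A construct is called *significant* when its mean ΔCq is positive and it
is Tukey-significantly greater than at least one other construct in the
round — i.e. it separates from the round's own low-signal constructs,
which serve as the internal non-binder baseline. (With a single construct
there is no baseline; a configurable ΔCq floor is used instead.)

Per-unit support counts, for every design unit, how many significant and
how many tested constructs contain it. Hotspots are the maximal
contiguous runs of units with support at or above ``min_support``, each
annotated with its best construct. Resolution is the repeat unit: the
method cannot localize below one repeat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .panning_planner import SegmentationPlan
from .qpcr_stats import ComparisonReport, DeltaCqResult
from .repeat_model import ConstructDesign, RepeatProtein, Unit, UnitWindow


@dataclass(frozen=True)
class UnitSupport:
    unit: Unit
    n_significant: int
    n_tested: int
    mean_delta_cq: float  # mean ΔCq of non-excluded constructs containing the unit


@dataclass(frozen=True)
class HotspotCall:
    """Inferred paratope intervals with the support map behind them."""

    intervals: tuple[UnitWindow, ...]
    per_unit_support: dict[Unit, UnitSupport]
    top_constructs: tuple[str, ...]  # best construct per interval, aligned


def significant_constructs(
    report: ComparisonReport,
    results: Sequence[DeltaCqResult],
    *,
    min_delta_floor: float = 1.0,
) -> set[str]:
    """Construct ids passing the significance rule (see module docstring)."""
    usable = {r.construct_id: r for r in results if not r.excluded}
    if len(usable) == 1:
        (only,) = usable.values()
        return {only.construct_id} if only.delta_cq_mean > min_delta_floor else set()
    means = {cid: r.delta_cq_mean for cid, r in usable.items()}
    sig: set[str] = set()
    for pair in report.pairwise:
        if not pair.significant:
            continue
        if pair.mean_diff > 0:
            winner = pair.construct_b
        elif pair.mean_diff < 0:
            winner = pair.construct_a
        else:
            continue
        if winner in means and means[winner] > 0:
            sig.add(winner)
    return sig


def unit_support(
    plans: SegmentationPlan | Sequence[SegmentationPlan],
    report: ComparisonReport,
    results: Sequence[DeltaCqResult],
    *,
    min_delta_floor: float = 1.0,
) -> dict[Unit, UnitSupport]:
    """Per-unit support map over every unit of the protein.

    Raises if the results and the plans' construct ids do not match.
    """
    if isinstance(plans, SegmentationPlan):
        plans = [plans]
    constructs = [c for p in plans for c in p.constructs]
    protein = plans[0].protein
    plan_ids = {c.construct_id for c in constructs}
    result_ids = {r.construct_id for r in results}
    if plan_ids != result_ids:
        raise ValueError(
            f"construct id mismatch between plans and results: "
            f"only in plans {sorted(plan_ids - result_ids)}, "
            f"only in results {sorted(result_ids - plan_ids)}"
        )
    sig = significant_constructs(report, results, min_delta_floor=min_delta_floor)
    means = {r.construct_id: r.delta_cq_mean for r in results if not r.excluded}

    membership: dict[Unit, list[ConstructDesign]] = {
        u: [] for u in protein.unit_order()
    }
    for c in constructs:
        for u in protein.window_units(c.window):
            membership[u].append(c)

    support: dict[Unit, UnitSupport] = {}
    for u, containing in membership.items():
        scored = [means[c.construct_id] for c in containing if c.construct_id in means]
        support[u] = UnitSupport(
            unit=u,
            n_significant=sum(1 for c in containing if c.construct_id in sig),
            n_tested=len(containing),
            mean_delta_cq=sum(scored) / len(scored) if scored else float("nan"),
        )
    return support


def call_hotspots(
    protein: RepeatProtein,
    support: dict[Unit, UnitSupport],
    *,
    candidates: Sequence[tuple[str, UnitWindow, float]] = (),
    min_support: int = 1,
) -> HotspotCall:
    """Maximal contiguous unit runs with support >= ``min_support``.

    ``candidates`` are (construct_id, window, mean ΔCq) triples of the
    significant constructs, used to annotate each interval with its top
    construct: largest ΔCq mean, then smallest span, then lowest start.
    """
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    hot = {
        protein.ordinal(u): s
        for u, s in support.items()
        if s.n_significant >= min_support
    }
    intervals: list[UnitWindow] = []
    run_start = prev = None
    for p in sorted(hot):
        if run_start is None:
            run_start = prev = p
        elif p == prev + 1:
            prev = p
        else:
            intervals.append(protein.window_from_ordinals(run_start, prev))
            run_start = prev = p
    if run_start is not None:
        intervals.append(protein.window_from_ordinals(run_start, prev))

    tops = tuple(_top_construct(protein, iv, candidates) for iv in intervals)
    return HotspotCall(
        intervals=tuple(intervals), per_unit_support=dict(support), top_constructs=tops
    )


def _top_construct(
    protein: RepeatProtein,
    interval: UnitWindow,
    candidates: Sequence[tuple[str, UnitWindow, float]],
) -> str:
    iv = set(protein.window_ordinals(interval))
    overlapping = [
        (cid, w, m)
        for cid, w, m in candidates
        if iv & set(protein.window_ordinals(w))
    ]
    if not overlapping:
        return ""
    return min(
        overlapping,
        key=lambda t: (-t[2], protein.window_length(t[1]), protein.ordinal(t[1].start_unit)),
    )[0]


def infer_hotspots(
    plans: SegmentationPlan | Sequence[SegmentationPlan],
    report: ComparisonReport,
    results: Sequence[DeltaCqResult],
    *,
    min_support: int = 1,
    min_delta_floor: float = 1.0,
) -> HotspotCall:
    """Full chain: significance -> unit support -> interval calls."""
    if isinstance(plans, SegmentationPlan):
        plans = [plans]
    protein = plans[0].protein
    support = unit_support(
        plans, report, results, min_delta_floor=min_delta_floor
    )
    sig = significant_constructs(report, results, min_delta_floor=min_delta_floor)
    means = {r.construct_id: r.delta_cq_mean for r in results}
    candidates = [
        (c.construct_id, c.window, means[c.construct_id])
        for p in plans
        for c in p.constructs
        if c.construct_id in sig
    ]
    return call_hotspots(
        protein, support, candidates=candidates, min_support=min_support
    )
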