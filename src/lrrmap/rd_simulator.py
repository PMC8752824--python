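"""Synthetic ribosome-display qPCR data with a planted ground-truth paratope.

The generative model is deliberately simple — the real assay's readout is
qualitative (competable signal vs background) — but it reproduces the
structure of the data the analysis pipeline must handle:

* a construct's specific binding ``s`` is the best fractional contiguous
  overlap between its window and any planted paratope, zeroed below a
  minimum contiguous overlap (too small an interface gives no detectable
  binding);
* uncompeted wells bind ``s + b`` (``b`` = nonspecific background),
  competed wells bind ``leak*s + b`` (a small fraction of specific
  binding survives excess soluble competitor);
* qPCR quantification cycles assume perfect doubling:
  ``Cq = c0 - log2(bound)``, plus an additive per-batch offset (day
  effects) and Gaussian cycle noise.

Under zero noise this gives the closed form
``ΔCq = log2((s + b) / (leak*s + b))``, which is zero iff ``s = 0`` and
strictly increasing in ``s`` — the invariants the statistics tests lean on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panning_planner import SegmentationPlan
from .repeat_model import RepeatProtein, UnitWindow

#: Exact column order of the Cq table.
CQ_COLUMNS = ["construct_id", "condition", "replicate", "batch", "cq"]

UNCOMPETED = "uncompeted"
COMPETED = "competed"


@dataclass(frozen=True)
class GroundTruth:
    """Planted paratope(s) and binding-model parameters.

    ``paratopes`` are disjoint unit windows; ``signal_scale`` (β) sets the
    specific-binding strength of a full-overlap construct, ``leak`` the
    fraction of specific binding surviving competition, ``background`` (b)
    the nonspecific binding common to all wells, and ``min_contig`` the
    smallest contiguous overlap (units) that still yields detectable
    binding.
    """

    paratopes: tuple[UnitWindow, ...] = ()
    min_contig: int = 3
    signal_scale: float = 1.0
    leak: float = 0.05
    background: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.leak < 1:
            raise ValueError(f"leak must be in [0, 1), got {self.leak}")
        if self.background <= 0:
            raise ValueError(f"background must be > 0, got {self.background}")
        if self.min_contig < 1:
            raise ValueError(f"min_contig must be >= 1, got {self.min_contig}")
        object.__setattr__(self, "paratopes", tuple(self.paratopes))


@dataclass(frozen=True)
class SimConfig:
    """Assay noise model: cycle noise sd, baseline Cq, batch offsets,
    replicates per condition per batch, and the RNG seed."""

    noise_sd: float = 0.25
    cq_baseline: float = 20.0
    batch_offsets: tuple[float, ...] = (0.0,)
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        object.__setattr__(self, "batch_offsets", tuple(self.batch_offsets))


def _contiguous_overlap(
    protein: RepeatProtein, a: UnitWindow, b: UnitWindow
) -> int:
    # both windows are contiguous in ordinal space, so the intersection is too
    lo = max(protein.ordinal(a.start_unit), protein.ordinal(b.start_unit))
    hi = min(protein.ordinal(a.end_unit), protein.ordinal(b.end_unit))
    return max(0, hi - lo + 1)


def specific_signal(
    protein: RepeatProtein, construct_window: UnitWindow, truth: GroundTruth
) -> float:
    """Specific binding of a construct: β × best fractional paratope overlap,
    zero when no contiguous overlap reaches ``min_contig`` units."""
    best = 0.0
    for p in truth.paratopes:
        ov = _contiguous_overlap(protein, construct_window, p)
        if ov >= truth.min_contig:
            best = max(best, ov / protein.window_length(p))
    return truth.signal_scale * best


def _bound_to_cq(bound: float, c0: float) -> float:
    return c0 - math.log2(bound)


def simulate_cq(
    plans: SegmentationPlan | Sequence[SegmentationPlan],
    truth: GroundTruth,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Simulate a full Cq table for one or more rounds' constructs.

    Rows cover every (construct, condition, replicate, batch) cell;
    regeneration with the same config is bit-identical.
    """
    if isinstance(plans, SegmentationPlan):
        plans = [plans]
    rng = np.random.default_rng(cfg.seed)
    rows: list[tuple] = []
    for plan in plans:
        protein = plan.protein
        for construct in plan.constructs:
            s = specific_signal(protein, construct.window, truth)
            for ib, offset in enumerate(cfg.batch_offsets, start=1):
                batch = f"b{ib}"
                for rep in range(1, cfg.n_replicates + 1):
                    for condition, bound in (
                        (UNCOMPETED, s + truth.background),
                        (COMPETED, truth.leak * s + truth.background),
                    ):
                        cq = _bound_to_cq(bound, cfg.cq_baseline) + offset
                        if cfg.noise_sd > 0:
                            cq += rng.normal(0.0, cfg.noise_sd)
                        rows.append(
                            (construct.construct_id, condition, rep, batch, cq)
                        )
    return pd.DataFrame(rows, columns=CQ_COLUMNS)


def simulate_dose_response(
    construct_window: UnitWindow,
    protein: RepeatProtein,
    truth: GroundTruth,
    competitor_levels: Iterable[float],
    cfg: SimConfig,
) -> pd.DataFrame:
    """Cq across a competitor titration for one construct.

    ``competitor_levels`` are fractions in [0, 1] of the specific binding
    competed away: level 0 reproduces the uncompeted condition, level 1
    the fully competed one. Bound quantity is
    ``(1 - level*(1 - leak))*s + b``, so Cq is monotone non-decreasing in
    the level when noise is off.
    """
    levels = list(competitor_levels)
    if any(not 0 <= x <= 1 for x in levels):
        raise ValueError("competitor levels must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    s = specific_signal(protein, construct_window, truth)
    cid = f"LRR{construct_window.label}"
    rows = []
    for ib, offset in enumerate(cfg.batch_offsets, start=1):
        batch = f"b{ib}"
        for rep in range(1, cfg.n_replicates + 1):
            for level in levels:
                bound = (1 - level * (1 - truth.leak)) * s + truth.background
                cq = _bound_to_cq(bound, cfg.cq_baseline) + offset
                if cfg.noise_sd > 0:
                    cq += rng.normal(0.0, cfg.noise_sd)
                rows.append((cid, level, rep, batch, cq))
    return pd.DataFrame(
        rows, columns=["construct_id", "competitor_level", "replicate", "batch", "cq"]
    )


def band_intensities(table: pd.DataFrame) -> pd.DataFrame:
    """Add a gel-band-like ``intensity`` column proportional to 2^(-Cq),
    scaled so the strongest band is 1."""
    out = table.copy()
    out["intensity"] = 2.0 ** (out["cq"].min() - out["cq"])
    return out
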