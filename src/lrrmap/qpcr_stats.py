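"""Statistics for competed/uncompeted qPCR binding data.

Pipeline: (1) normalize each batch to the global average Cq so replicates
measured on different days are comparable; (2) compute per-construct ΔCq
(competed − uncompeted, paired by replicate and batch) with uncertainty
propagated from the per-condition Cq standard deviations; (3) exclude
constructs whose ΔCq standard deviation is an outlier by the Tukey fence
(high side only — low variance is not a defect); (4) single-factor ANOVA
on the replicate-level ΔCq values followed by Tukey HSD pairwise
comparisons, significant at alpha (default 0.1).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .rd_simulator import COMPETED, CQ_COLUMNS, UNCOMPETED

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeltaCqResult:
    """Per-construct ΔCq summary.

    ``delta_cq_sd`` is the propagated uncertainty
    ``sqrt(sd_competed**2 + sd_uncompeted**2)`` of the per-condition Cq
    spreads, not the sd of the paired differences.
    """

    construct_id: str
    delta_cq_mean: float
    delta_cq_sd: float
    n_pairs: int
    replicate_deltas: tuple[float, ...]
    excluded: bool = False
    exclude_reason: str | None = None


@dataclass(frozen=True)
class PairwiseComparison:
    construct_a: str
    construct_b: str
    mean_diff: float  # mean(b) - mean(a)
    adjusted_p: float
    significant: bool


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    p_value: float
    df_between: int
    df_within: int


@dataclass(frozen=True)
class ComparisonReport:
    anova: AnovaResult
    pairwise: tuple[PairwiseComparison, ...]
    alpha: float = 0.1


def normalize_batches(table: pd.DataFrame) -> pd.DataFrame:
    """Shift every batch to the global average Cq.

    ``Cq' = Cq - mean(batch) + mean(all)``: the grand mean and all
    within-batch differences are preserved exactly, while additive
    between-day offsets cancel.
    """
    if table.empty:
        raise ValueError("cannot normalize an empty Cq table")
    out = table.copy()
    grand = out["cq"].mean()
    out["cq"] = out["cq"] - out.groupby("batch")["cq"].transform("mean") + grand
    return out


def delta_cq(table: pd.DataFrame) -> list[DeltaCqResult]:
    """Per-construct ΔCq = Cq(competed) − Cq(uncompeted), paired by
    (replicate, batch).

    A construct missing either condition entirely is returned with
    ``excluded=True`` and reason "incomplete conditions" rather than
    dropped, so downstream reports stay aligned with the plan.
    """
    results: list[DeltaCqResult] = []
    for cid in pd.unique(table["construct_id"]):
        sub = table[table["construct_id"] == cid]
        wide = sub.pivot_table(
            index=["replicate", "batch"], columns="condition", values="cq"
        )
        if COMPETED not in wide.columns or UNCOMPETED not in wide.columns:
            results.append(
                DeltaCqResult(
                    construct_id=cid,
                    delta_cq_mean=math.nan,
                    delta_cq_sd=math.nan,
                    n_pairs=0,
                    replicate_deltas=(),
                    excluded=True,
                    exclude_reason="incomplete conditions",
                )
            )
            continue
        paired = wide.dropna(subset=[COMPETED, UNCOMPETED])
        deltas = (paired[COMPETED] - paired[UNCOMPETED]).to_numpy()
        sd_c = _sd(sub.loc[sub["condition"] == COMPETED, "cq"])
        sd_u = _sd(sub.loc[sub["condition"] == UNCOMPETED, "cq"])
        results.append(
            DeltaCqResult(
                construct_id=cid,
                delta_cq_mean=float(np.mean(deltas)),
                delta_cq_sd=math.hypot(sd_c, sd_u),
                n_pairs=len(deltas),
                replicate_deltas=tuple(float(d) for d in deltas),
            )
        )
    return results


def _sd(values: pd.Series) -> float:
    return float(values.std(ddof=1)) if len(values) > 1 else 0.0


def flag_sd_outliers(
    results: list[DeltaCqResult], k: float = 1.5
) -> list[DeltaCqResult]:
    """Exclude constructs whose propagated ΔCq sd exceeds Q3 + k·IQR.

    The fence is one-sided (high variance only). With fewer than 4
    usable results quartiles are meaningless and nothing is flagged.
    """
    active = [r for r in results if not r.excluded and math.isfinite(r.delta_cq_sd)]
    if len(active) < 4:
        logger.warning("only %d usable results; skipping sd outlier fence", len(active))
        return list(results)
    sds = np.array([r.delta_cq_sd for r in active])
    q1, q3 = np.percentile(sds, [25, 75])
    fence = q3 + k * (q3 - q1)
    out = []
    for r in results:
        if not r.excluded and r.delta_cq_sd > fence:
            out.append(
                dataclasses.replace(
                    r,
                    excluded=True,
                    exclude_reason=(
                        f"outlying ΔCq standard deviation "
                        f"({r.delta_cq_sd:.3g} > Tukey fence {fence:.3g})"
                    ),
                )
            )
        else:
            out.append(r)
    return out


def compare_constructs(
    results: list[DeltaCqResult], alpha: float = 0.1
) -> ComparisonReport:
    """One-way ANOVA on replicate ΔCq values + Tukey HSD pairwise tests.

    Only non-excluded constructs enter; each needs at least two replicate
    deltas. Tukey HSD uses the studentized range with the Tukey-Kramer
    adjustment for unequal group sizes. Degenerate data (all values
    identical) yields no significant pairs.
    """
    usable = [r for r in results if not r.excluded]
    if len(usable) < 2:
        raise ValueError("need at least 2 non-excluded constructs to compare")
    thin = [r.construct_id for r in usable if len(r.replicate_deltas) < 2]
    if thin:
        raise ValueError(f"constructs with <2 replicate ΔCq values: {thin}")

    groups = [np.asarray(r.replicate_deltas, dtype=float) for r in usable]
    values = np.concatenate(groups)
    labels = np.concatenate(
        [[r.construct_id] * len(r.replicate_deltas) for r in usable]
    )
    k = len(groups)
    df_between, df_within = k - 1, len(values) - k

    if np.ptp(values) == 0:
        # all observations identical: F is 0/0; report nothing significant
        pairwise = tuple(
            PairwiseComparison(a.construct_id, b.construct_id, 0.0, 1.0, False)
            for a, b in itertools.combinations(usable, 2)
        )
        return ComparisonReport(
            anova=AnovaResult(math.nan, 1.0, df_between, df_within),
            pairwise=pairwise,
            alpha=alpha,
        )

    if all(np.ptp(g) == 0 for g in groups):
        # distinct constant groups: zero within-group variance, F -> inf;
        # any nonzero mean difference is unambiguous
        means = {r.construct_id: float(np.mean(r.replicate_deltas)) for r in usable}
        pairwise = tuple(
            PairwiseComparison(
                a.construct_id,
                b.construct_id,
                means[b.construct_id] - means[a.construct_id],
                0.0 if means[a.construct_id] != means[b.construct_id] else 1.0,
                means[a.construct_id] != means[b.construct_id],
            )
            for a, b in itertools.combinations(usable, 2)
        )
        return ComparisonReport(
            anova=AnovaResult(math.inf, 0.0, df_between, df_within),
            pairwise=pairwise,
            alpha=alpha,
        )

    f_stat, p_value = stats.f_oneway(*groups)
    hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairs = list(itertools.combinations(hsd.groupsunique, 2))
    pairwise = tuple(
        PairwiseComparison(
            construct_a=str(a),
            construct_b=str(b),
            mean_diff=float(diff),
            adjusted_p=float(p),
            significant=bool(p <= alpha),
        )
        for (a, b), diff, p in zip(pairs, hsd.meandiffs, hsd.pvalues)
    )
    return ComparisonReport(
        anova=AnovaResult(float(f_stat), float(p_value), df_between, df_within),
        pairwise=pairwise,
        alpha=alpha,
    )


def read_cq_tsv(path) -> pd.DataFrame:
    """Read a Cq table TSV with the canonical column set."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in CQ_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Cq table missing columns: {missing}")
    return table[CQ_COLUMNS]


def write_cq_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
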