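"""qPCR statistics: normalization, ΔCq, outlier fence, ANOVA + Tukey HSD."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from lrrmap.panning_planner import plan_refinement
from lrrmap.qpcr_stats import (
    DeltaCqResult,
    compare_constructs,
    delta_cq,
    flag_sd_outliers,
    normalize_batches,
)
from lrrmap.rd_simulator import GroundTruth, SimConfig, simulate_cq
from lrrmap.repeat_model import RepeatProtein, UnitWindow

P11 = RepeatProtein("p", 11)
TRUTH = GroundTruth(paratopes=(UnitWindow(6, 10),))


def _table(rows):
    return pd.DataFrame(
        rows, columns=["construct_id", "condition", "replicate", "batch", "cq"]
    )


class TestNormalizeBatches:
    def test_single_batch_unchanged(self):
        t = _table([("a", "uncompeted", 1, "b1", 20.0), ("a", "competed", 1, "b1", 23.0)])
        pd.testing.assert_frame_equal(normalize_batches(t), t)

    def test_two_batches_pulled_to_grand_mean(self):
        t = _table(
            [
                ("a", "uncompeted", 1, "b1", 19.0),
                ("a", "competed", 1, "b1", 21.0),
                ("a", "uncompeted", 1, "b2", 21.0),
                ("a", "competed", 1, "b2", 23.0),
            ]
        )
        out = normalize_batches(t)
        assert out["cq"].tolist() == [20.0, 22.0, 20.0, 22.0]
        assert out["cq"].mean() == t["cq"].mean()

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=6),
        st.floats(-3, 3, allow_nan=False),
    )
    def test_within_batch_differences_preserved(self, cqs, offset):
        rows = [("c", "uncompeted", i, "b1", 20 + x) for i, x in enumerate(cqs)]
        rows += [("c", "competed", i, "b2", 20 + x + offset) for i, x in enumerate(cqs)]
        out = normalize_batches(_table(rows))
        for batch in ("b1", "b2"):
            before = _table(rows).loc[lambda d: d.batch == batch, "cq"].to_numpy()
            after = out.loc[out.batch == batch, "cq"].to_numpy()
            assert np.allclose(np.diff(before), np.diff(after), atol=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            normalize_batches(_table([]))


class TestDeltaCq:
    def test_constant_replicates(self):
        t = _table(
            [("a", "competed", r, "b1", 24.0) for r in (1, 2)]
            + [("a", "uncompeted", r, "b1", 20.0) for r in (1, 2)]
        )
        (res,) = delta_cq(t)
        assert res.delta_cq_mean == 4.0
        assert res.delta_cq_sd == 0.0
        assert res.n_pairs == 2
        assert res.replicate_deltas == (4.0, 4.0)

    def test_propagated_sd_three_four_five(self):
        t = _table(
            [("a", "uncompeted", r, "b1", cq) for r, cq in enumerate([19.6, 20.0, 20.4])]
            + [("a", "competed", r, "b1", cq) for r, cq in enumerate([23.7, 24.0, 24.3])]
        )
        (res,) = delta_cq(t)
        assert res.delta_cq_mean == pytest.approx(4.0)
        assert res.delta_cq_sd == pytest.approx(0.5)

    def test_matches_simulator_closed_form(self):
        plan = plan_refinement(P11, P11.full_window(), n=5)
        table = simulate_cq(plan, TRUTH, SimConfig(noise_sd=0.0, n_replicates=2))
        by_id = {r.construct_id: r for r in delta_cq(table)}
        assert by_id["LRR6-10"].delta_cq_mean == pytest.approx(
            math.log2(1.05 / 0.10), abs=1e-12
        )
        assert by_id["LRR1-5"].delta_cq_mean == 0.0

    def test_batch_offsets_cancel_in_normalized_paired_deltas(self):
        plan = plan_refinement(P11, P11.full_window(), n=5)
        offset_free = simulate_cq(
            plan, TRUTH, SimConfig(noise_sd=0.0, n_replicates=2, batch_offsets=(0.0, 0.0))
        )
        shifted = simulate_cq(
            plan, TRUTH, SimConfig(noise_sd=0.0, n_replicates=2, batch_offsets=(0.7, -0.7))
        )
        ref = {r.construct_id: r.delta_cq_mean for r in delta_cq(offset_free)}
        for r in delta_cq(normalize_batches(shifted)):
            assert r.delta_cq_mean == pytest.approx(ref[r.construct_id], abs=1e-12)

    def test_missing_condition_marks_excluded(self):
        t = _table([("a", "uncompeted", 1, "b1", 20.0)])
        (res,) = delta_cq(t)
        assert res.excluded
        assert res.exclude_reason == "incomplete conditions"


def _result(cid, sd, mean=2.0, deltas=(2.0, 2.0)):
    return DeltaCqResult(cid, mean, sd, len(deltas), tuple(deltas))


class TestOutlierFence:
    def test_single_high_sd_flagged(self):
        results = [
            _result(c, sd)
            for c, sd in zip("abcde", [0.2, 0.25, 0.3, 0.28, 2.0])
        ]
        out = flag_sd_outliers(results)
        assert [r.excluded for r in out] == [False, False, False, False, True]
        assert "Tukey fence" in out[-1].exclude_reason

    def test_equal_sds_none_flagged(self):
        out = flag_sd_outliers([_result(c, 0.3) for c in "abcd"])
        assert not any(r.excluded for r in out)

    def test_monotone_sds_without_gap_none_flagged(self):
        out = flag_sd_outliers([_result(c, sd) for c, sd in zip("abcde", [0.1, 0.2, 0.3, 0.4, 0.5])])
        assert not any(r.excluded for r in out)

    def test_fewer_than_four_skips_with_warning(self, caplog):
        results = [_result(c, sd) for c, sd in zip("abc", [0.1, 0.2, 9.9])]
        with caplog.at_level("WARNING"):
            out = flag_sd_outliers(results)
        assert not any(r.excluded for r in out)
        assert "skipping" in caplog.text


class TestCompareConstructs:
    def test_two_group_f_equals_t_squared(self):
        a, b = (0.0, 0.0, 0.1), (4.0, 4.1, 3.9)
        report = compare_constructs([_result("a", 0.1, np.mean(a), a), _result("b", 0.1, np.mean(b), b)])
        t_stat, t_p = sps.ttest_ind(a, b)
        assert report.anova.f_stat == pytest.approx(t_stat**2, rel=1e-10)
        assert report.anova.p_value == pytest.approx(t_p, rel=1e-10)
        assert report.anova.p_value < 0.1
        (pair,) = report.pairwise
        assert pair.significant
        assert pair.mean_diff == pytest.approx(np.mean(b) - np.mean(a))

    def test_identical_constant_groups_report_nothing_significant(self):
        report = compare_constructs(
            [_result(c, 0.0, 2.0, (2.0, 2.0)) for c in "abc"]
        )
        assert math.isnan(report.anova.f_stat)
        assert not any(p.significant for p in report.pairwise)

    def test_distinct_constant_groups_fully_separate(self):
        report = compare_constructs(
            [_result("a", 0.0, 0.0, (0.0, 0.0)), _result("b", 0.0, 3.0, (3.0, 3.0))]
        )
        assert math.isinf(report.anova.f_stat)
        (pair,) = report.pairwise
        assert pair.significant and pair.adjusted_p == 0.0

    def test_insufficient_replication_names_construct(self):
        results = [_result("a", 0.1), _result("thin", 0.1, deltas=(1.0,))]
        with pytest.raises(ValueError, match="thin"):
            compare_constructs(results)

    def test_excluded_constructs_stay_out_of_pairs(self):
        results = [
            _result("a", 0.1, 0.0, (0.0, 0.1, -0.1)),
            _result("b", 0.1, 4.0, (4.0, 4.1, 3.9)),
            DeltaCqResult("x", 4.0, 9.0, 3, (1.0, 9.0, -3.0), excluded=True, exclude_reason="outlier"),
        ]
        report = compare_constructs(results)
        named = {p.construct_a for p in report.pairwise} | {
            p.construct_b for p in report.pairwise
        }
        assert named == {"a", "b"}

    def test_binders_separate_from_non_overlapping_constructs(self):
        """Fixed-seed simulated round: paratope-covering constructs separate
        from zero-overlap ones; ANOVA p cross-checked by permutation."""
        plan = plan_refinement(P11, P11.window(1, 11))
        table = simulate_cq(plan, TRUTH, SimConfig(noise_sd=0.25, n_replicates=3, seed=11))
        results = delta_cq(normalize_batches(table))
        report = compare_constructs(results, alpha=0.1)
        sig_pairs = {
            frozenset((p.construct_a, p.construct_b))
            for p in report.pairwise
            if p.significant
        }
        assert frozenset(("LRR1-5", "LRR6-10")) in sig_pairs

        # permutation oracle for the ANOVA p-value
        groups = [np.array(r.replicate_deltas) for r in results]
        values = np.concatenate(groups)
        labels = np.repeat(np.arange(len(groups)), [len(g) for g in groups])
        f_obs = sps.f_oneway(*groups).statistic
        rng = np.random.default_rng(0)
        perm_f = []
        for _ in range(2000):
            lab = rng.permutation(labels)
            perm_f.append(
                sps.f_oneway(*(values[lab == g] for g in range(len(groups)))).statistic
            )
        p_perm = np.mean(np.array(perm_f) >= f_obs)
        assert report.anova.p_value < 0.01
        assert p_perm < 0.01
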