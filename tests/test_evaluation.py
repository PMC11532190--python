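"""ISO-style agreement statistics: ICC, pair selection, Accuracy/Stability/
Change, Bland-Altman, within-subject change and the criteria report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuffless_bp import evaluation as ev


def pairs_df(diffs, subjects=None, day=1):
    diffs = np.asarray(diffs, float)
    ref = np.full(diffs.size, 120.0)
    return pd.DataFrame(
        {
            "subject_id": subjects if subjects is not None else "S1",
            "day": day,
            "reference": ref,
            "device": ref + diffs,
        }
    )


class TestICC:
    def test_no_between_subject_variance_gives_near_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 5, 200)
        subs = np.repeat(np.arange(10), 20)
        res = ev.icc(vals, subs)
        assert abs(res.icc) < 0.15

    def test_dominant_between_subject_variance_approaches_one(self):
        rng = np.random.default_rng(1)
        subs = np.repeat(np.arange(10), 20)
        vals = subs * 50.0 + rng.normal(0, 0.5, 200)
        assert ev.icc(vals, subs).icc > 0.95

    def test_toy_table_matches_anova_oracle(self):
        # 4 subjects x 3 repeats, hand-computed one-way ANOVA
        vals = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12])
        subs = np.repeat(["a", "b", "c", "d"], 3)
        grand = vals.mean()
        gm = vals.reshape(4, 3).mean(axis=1)
        ssb = 3 * np.sum((gm - grand) ** 2)
        ssw = np.sum((vals.reshape(4, 3) - gm[:, None]) ** 2)
        msb, msw = ssb / 3, ssw / 8
        expected = (msb - msw) / (msb + 2 * msw)
        assert ev.icc(vals, subs).icc == pytest.approx(expected, rel=1e-12)

    def test_insufficient_repeats_rejected(self):
        with pytest.raises(ValueError):
            ev.icc(np.array([1.0, 2.0]), np.array(["a", "b"]))

    def test_negative_estimate_reported_as_is(self):
        vals = np.array([1.0, 9.0, 9.0, 1.0, 1.0, 9.0, 9.0, 1.0])
        subs = np.repeat(["a", "b"], 4)
        res = ev.icc(vals, subs)
        assert res.icc < 0
        assert "negative" in res.note


class TestSelectPairs:
    def _pool(self, n_subjects, per_subject, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "subject_id": np.repeat(
                    [f"S{i:02d}" for i in range(n_subjects)], per_subject
                ),
                "day": 1,
                "reference": rng.normal(120, 10, n_subjects * per_subject),
                "device": rng.normal(120, 10, n_subjects * per_subject),
            }
        )

    def test_accuracy_selection_count_38x22(self):
        sel = ev.select_pairs(self._pool(38, 60), 22, seed=1)
        assert len(sel) == 836
        assert (sel.groupby("subject_id").size() == 22).all()

    def test_stability_selection_count_11x44(self):
        sel = ev.select_pairs(self._pool(11, 90), 44, seed=1)
        assert len(sel) == 484

    def test_selecting_all_available_is_identity(self):
        pool = self._pool(3, 10)
        sel = ev.select_pairs(pool, 10, seed=5)
        assert len(sel) == 30
        pd.testing.assert_frame_equal(
            sel.sort_values(["subject_id", "reference"]).reset_index(drop=True),
            pool.sort_values(["subject_id", "reference"]).reset_index(drop=True),
        )

    def test_short_subject_named_in_error(self):
        pool = self._pool(2, 10)
        with pytest.raises(ValueError, match="S01"):
            ev.select_pairs(pool[:-5], 10)

    def test_fixed_seed_reproducible(self):
        pool = self._pool(5, 40)
        a = ev.select_pairs(pool, 10, seed=9)
        b = ev.select_pairs(pool, 10, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestAccuracyStatistic:
    def test_two_symmetric_differences(self):
        res = ev.accuracy_statistic(pairs_df([2.0, -2.0]))
        assert res.mean == 0.0
        assert res.sd == pytest.approx(2 * np.sqrt(2), rel=1e-12)

    def test_constant_differences(self):
        res = ev.accuracy_statistic(pairs_df([3.0, 3.0, 3.0]))
        assert (res.mean, res.sd) == (3.0, 0.0)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            ev.accuracy_statistic(pairs_df([1.0]))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(-30, 30), min_size=2, max_size=200))
    def test_matches_two_pass_oracle(self, diffs):
        res = ev.accuracy_statistic(pairs_df(diffs))
        n = len(diffs)
        mean = sum(diffs) / n
        var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
        assert res.mean == pytest.approx(mean, abs=1e-9)
        assert res.sd == pytest.approx(np.sqrt(var), abs=1e-9)


class TestStability:
    def test_day2_drift_shifts_mean_by_pair_fraction(self):
        """With day-1 differences 0 and day-2 differences d, the pooled mean
        equals d times the selected day-2 pair fraction exactly."""
        d = 6.0
        day1 = pairs_df(np.zeros(60), subjects=np.repeat(["A", "B"], 30))
        day2 = pairs_df(np.full(40, d), subjects=np.repeat(["A", "B"], 20),
                        day=2)
        res = ev.stability_statistic(day1, day2, n_per_subject=44, seed=3)
        sel = ev.select_pairs(pd.concat([day1, day2]), 44, seed=3)
        frac2 = (sel["day"] == 2).mean()
        assert res.mean == pytest.approx(d * frac2, abs=1e-9)

    def test_no_day2_subjects_rejected(self):
        day1 = pairs_df(np.zeros(10), subjects=["A"] * 10)
        with pytest.raises(ValueError):
            ev.stability_statistic(day1, day1.iloc[:0], 5)


def segments_table(ref, dev, param="sbp", subject="S1", session="handgrip"):
    n = len(ref)
    df = pd.DataFrame(
        {
            "subject_id": subject,
            "day": 1,
            "session": session,
            "window_start_s": np.arange(n) * 15.0,
        }
    )
    for p in ("sbp", "dbp", "map"):
        df[f"ref_{p}"] = np.nan
        df[f"dev_{p}"] = np.nan
    df[f"ref_{param}"] = np.asarray(ref, float)
    df[f"dev_{param}"] = np.asarray(dev, float)
    return df


class TestChange:
    def test_error_rate_arithmetic(self):
        tab = segments_table([100.0, 120.0], [100.0, 115.0])
        cp = ev.change_pairs(tab, params=("sbp",))
        assert len(cp) == 1
        assert cp.loc[0, "delta_ref"] == 20.0
        assert cp.loc[0, "error_rate"] == pytest.approx(25.0)

    def test_perfect_tracking_zero_rate(self):
        tab = segments_table([100.0, 120.0], [90.0, 110.0])
        cp = ev.change_pairs(tab, params=("sbp",))
        assert cp.loc[0, "error_rate"] == 0.0

    @pytest.mark.parametrize(
        "param,delta,kept",
        [
            ("sbp", 12.0, False), ("sbp", 15.0, True),
            ("dbp", 9.0, False), ("dbp", 10.0, True),
            ("map", 11.0, False), ("map", 12.0, True),
        ],
    )
    def test_minimum_change_thresholds(self, param, delta, kept):
        tab = segments_table([100.0, 100.0 + delta], [100.0, 100.0 + delta],
                             param=param)
        cp = ev.change_pairs(tab, params=(param,))
        assert (len(cp) == 1) is kept

    def test_cross_activity_pairs_never_formed(self):
        a = segments_table([100.0] * 3, [100.0] * 3, session="handgrip")
        b = segments_table([160.0] * 3, [160.0] * 3, session="cold_pressor")
        cp = ev.change_pairs(pd.concat([a, b], ignore_index=True),
                             params=("sbp",))
        assert len(cp) == 0  # the 60 mmHg jump spans two activities

    def test_capping_bounds_candidates_per_subject(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(130, 20, 60)
        tab = segments_table(ref, ref)
        cp = ev.change_pairs(tab, params=("sbp",), cap_per_subject=50, seed=1)
        assert len(cp) == 50

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.floats(0.1, 10.0))
    def test_error_rate_scale_invariance(self, scale):
        dref, ddev = 20.0, 14.0
        base = abs(ddev - dref) / abs(dref) * 100
        scaled = abs(ddev * scale - dref * scale) / abs(dref * scale) * 100
        assert scaled == pytest.approx(base, rel=1e-9)


class TestChangePercentiles:
    def test_linear_interpolation_order_statistics(self):
        res = ev.change_percentiles([10.0, 20.0, 30.0, 40.0])
        assert res.p50 == pytest.approx(25.0)
        assert res.p85 == pytest.approx(35.5)

    def test_constant_rates(self):
        res = ev.change_percentiles([7.0] * 5)
        assert res.p50 == res.p85 == 7.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.change_percentiles([])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0, 200), min_size=1, max_size=500))
    def test_matches_full_sort_oracle(self, rates):
        res = ev.change_percentiles(rates)
        x = np.sort(np.asarray(rates))
        for q, got in [(0.5, res.p50), (0.85, res.p85)]:
            pos = q * (x.size - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, x.size - 1)
            expect = x[lo] + (pos - lo) * (x[hi] - x[lo])
            assert got == pytest.approx(expect, abs=1e-9)
        assert res.p50 <= res.p85 + 1e-12


class TestBlandAltman:
    def test_all_zero_differences(self):
        res = ev.bland_altman(pairs_df(np.zeros(10)))
        assert res.bias == res.loa_lower == res.loa_upper == 0.0

    def test_loa_formula(self):
        rng = np.random.default_rng(2)
        d = rng.normal(1.5, 4.0, 500)
        res = ev.bland_altman(pairs_df(d))
        assert res.bias == pytest.approx(d.mean())
        assert res.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_clamping_affects_plotting_only(self, tmp_path):
        d = np.array([0.0, 1.0, -2.0, 35.0])
        res = ev.bland_altman(pairs_df(d))
        # the +35 difference enters the statistics unclamped
        assert res.bias == pytest.approx(d.mean())
        fig = ev.bland_altman_plot(pairs_df(d), "sbp",
                                   tmp_path / "ba.png")
        ys = fig.axes[0].collections[0].get_offsets()[:, 1]
        assert ys.max() == pytest.approx(30.0)  # plotted at the bound
        assert (tmp_path / "ba.png").exists()


class TestWithinSubjectChange:
    def test_max_minus_min(self):
        tab = segments_table([110.0, 150.0, 120.0], [0, 0, 0])
        res = ev.within_subject_change(tab, "ref_sbp")
        assert res["overall"] == 40.0

    def test_constant_series_zero(self):
        tab = segments_table([120.0] * 4, [0] * 4)
        assert ev.within_subject_change(tab, "ref_sbp")["overall"] == 0.0

    def test_matches_direct_scan_oracle(self, default_cohort_small):
        from cuffless_bp import beats as bt

        subj = default_cohort_small[0]
        frames = []
        for sess in subj.day_sessions(1):
            seg = bt.aggregate_segments(sess.truth, sess.spec.total_duration)
            seg["session"] = sess.activity
            seg["day"] = 1
            seg["subject_id"] = subj.subject_id
            seg = seg.rename(columns={"sbp": "ref_sbp"})
            frames.append(seg)
        tab = pd.concat(frames, ignore_index=True)
        res = ev.within_subject_change(tab, "ref_sbp")
        vals = tab["ref_sbp"].dropna().to_numpy()
        assert res["overall"] == pytest.approx(vals.max() - vals.min())


class TestCriteriaReport:
    def _from_stats(self, stats):
        return {
            p: ev.AgreementResult(836, m, s) for p, (m, s) in stats.items()
        }

    def test_published_statistics_reproduce_verdicts(self):
        """Feeding the reported device statistics directly through the
        criteria logic yields: Accuracy and Stability pass everywhere, the
        50th percentile fails all parameters, the 85th fails SBP only."""
        accuracy = self._from_stats(
            {"sbp": (0.3, 8.7), "dbp": (0.04, 6.6), "map": (0.8, 7.9)}
        )
        stability = self._from_stats(
            {"sbp": (1.9, 9.2), "dbp": (2.9, 8.1), "map": (2.5, 9.5)}
        )
        change = {
            "sbp": ev.ChangeResult(3549, 39.0, 56.0),
            "dbp": ev.ChangeResult(3142, 32.0, 48.0),
            "map": ev.ChangeResult(3510, 33.0, 47.0),
        }
        rep = ev.criteria_report(accuracy, stability, change)
        assert all(r.passed for r in rep.accuracy.values())
        assert all(r.passed for r in rep.stability.values())
        assert all(not r.pass_p50 for r in rep.change.values())
        assert not rep.change["sbp"].pass_p85
        assert rep.change["dbp"].pass_p85 and rep.change["map"].pass_p85
        assert not rep.passed()
        d = rep.to_dict()
        assert d["accuracy"]["sbp"]["passed"] is True

    def test_boundary_mean_six_is_inclusive_pass(self):
        assert ev.AgreementResult(10, 6.0, 10.0).passed
        assert not ev.AgreementResult(10, 6.01, 10.0).passed
        assert not ev.AgreementResult(10, 0.0, 10.01).passed

    def test_change_percentile_ordering_enforced(self):
        with pytest.raises(ValueError):
            ev.ChangeResult(5, 30.0, 20.0)
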