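"""Mission-statistics tests: percentages, diel profiles, ANOVA, encounters."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gliderpam import (
    count_encounters,
    day_night_anova,
    detector_performance,
    diel_profile,
    dive_summaries,
    encounter_rate,
    one_way_anova,
    percent_with_class,
)


def make_flags(n_files=240, n_dives=10, start="2009-10-27T00:00:00+00:00",
               positives=None, cls="delphinid", minutes_per_file=60):
    """Synthetic per-file flag table: consecutive minute files split
    evenly over dives."""
    times = pd.date_range(start, periods=n_files, freq=f"{minutes_per_file}min")
    df = pd.DataFrame({
        "file_id": [f"f{i:04d}" for i in range(n_files)],
        "dive_id": np.repeat(np.arange(n_dives), n_files // n_dives),
        "start_utc": times,
        cls: False,
    })
    if positives is not None:
        df.loc[positives, cls] = True
    return df


class TestPercent:
    def test_survey_scale_arithmetic(self):
        """109 beaked-whale files out of 11,615 -> 0.94 % ~ 1 %."""
        flags = pd.DataFrame({"beaked_whale": [True] * 109 + [False] * (11_615 - 109)})
        pct = percent_with_class(flags, "beaked_whale")
        assert pct == pytest.approx(100 * 109 / 11_615)
        assert round(pct) == 1

    def test_zero_and_all(self):
        flags = pd.DataFrame({"c": [False] * 10})
        assert percent_with_class(flags, "c") == 0.0
        flags["c"] = True
        assert percent_with_class(flags, "c") == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_with_class(pd.DataFrame({"c": []}), "c")


class TestDielProfile:
    def test_night_only_daytime_zero(self):
        flags = make_flags(n_files=48, n_dives=4, minutes_per_file=60)
        hours_local = ((flags["start_utc"].dt.hour - 10) % 24)
        flags.loc[hours_local.isin(range(20, 24)), "delphinid"] = True
        prof = diel_profile(flags, "delphinid", utc_offset_h=-10)
        day = prof[prof["hour"].between(7, 18)]
        assert (day["percentage"].dropna() == 0).all()
        night = prof[prof["hour"].isin([20, 21, 22, 23])]
        assert (night["percentage"] == 100).all()

    def test_time_shift_equivariance(self):
        """Shifting all timestamps by k hours rotates the profile by k."""
        rng = np.random.default_rng(1)
        flags = make_flags(n_files=480, n_dives=10)
        flags.loc[rng.random(480) < 0.3, "delphinid"] = True
        base = diel_profile(flags, "delphinid", utc_offset_h=-10)
        k = 5
        shifted = flags.copy()
        shifted["start_utc"] = shifted["start_utc"] + pd.Timedelta(hours=k)
        rot = diel_profile(shifted, "delphinid", utc_offset_h=-10)
        np.testing.assert_allclose(
            np.roll(base["positive_minutes"].to_numpy(), k),
            rot["positive_minutes"].to_numpy(),
        )

    def test_uniform_prevalence_flat_within_binomial_error(self):
        rng = np.random.default_rng(2)
        p = 0.4
        flags = make_flags(n_files=2400, n_dives=10)
        flags.loc[rng.random(2400) < p, "delphinid"] = True
        prof = diel_profile(flags, "delphinid", utc_offset_h=0)
        for _, row in prof.iterrows():
            n = row["observation_minutes"]
            if n == 0:
                continue
            sd = 100 * math.sqrt(p * (1 - p) / n)
            assert abs(row["percentage"] - 100 * p) < 4 * sd
        assert prof["observation_minutes"].sum() == 2400


class TestAnova:
    def test_identical_groups(self):
        f, p = one_way_anova([np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        a = np.array([0.0, 0.001, -0.001])
        b = np.array([1.0, 1.001, 0.999])
        f, p = one_way_anova([a, b])
        assert p < 0.01

    def test_t_squared_equals_f(self):
        """For 2 groups the ANOVA F equals the squared pooled t statistic."""
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1, 15)
        f, p = one_way_anova([a, b])
        t, pt = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t**2, abs=1e-10)
        assert p == pytest.approx(pt, abs=1e-10)

    def test_three_group_matches_reference(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(m, 1, 10) for m in (0.0, 0.5, 1.0)]
        f, p = one_way_anova(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_returns_nan(self):
        f, p = one_way_anova([np.array([1.0]), np.array([1.0])])
        assert math.isnan(f) and math.isnan(p)

    def test_day_night_wrapper(self):
        flags = make_flags(n_files=480, n_dives=10)
        hours_local = ((flags["start_utc"].dt.hour - 10) % 24)
        night = ~hours_local.between(7, 18)
        rng = np.random.default_rng(6)
        flags.loc[night & (rng.random(480) < 0.8), "delphinid"] = True
        flags.loc[~night & (rng.random(480) < 0.1), "delphinid"] = True
        res = day_night_anova(flags, "delphinid", utc_offset_h=-10)
        assert res["p"] < 0.01
        assert res["night_mean_pct"] > res["day_mean_pct"]


class TestEncounters:
    def test_well_separated_dives(self):
        """Positives scattered over 7 well-separated dives -> 7 encounters."""
        flags = make_flags(n_files=850, n_dives=85)
        pos_dives = [3, 10, 20, 33, 47, 60, 79]
        for d in pos_dives:
            flags.loc[flags["dive_id"] == d, "delphinid"] = True
        enc = count_encounters(flags, "delphinid", max_gap_s=3600.0)
        assert len(enc) == 7
        assert sorted(e.dive_ids[0] for e in enc) == pos_dives

    def test_no_positives(self):
        assert count_encounters(make_flags(), "delphinid") == []

    def test_consecutive_files_one_encounter(self):
        flags = make_flags(n_files=60, n_dives=1, positives=range(10, 20))
        enc = count_encounters(flags, "delphinid")
        assert len(enc) == 1 and enc[0].n_files == 10

    def test_encounter_rate(self):
        assert encounter_rate(194.0, 7) == pytest.approx(27.7, abs=0.05)
        assert encounter_rate(10.0, 10) == 1.0
        assert encounter_rate(26.8, 1) == pytest.approx(26.8)
        assert math.isinf(encounter_rate(5.0, 0))


class TestDetectorPerformance:
    def _series(self, n, idx_true, idx_det, dives=None):
        index = pd.Index([f"f{i}" for i in range(n)], name="file_id")
        truth = pd.Series(False, index=index)
        truth.iloc[list(idx_true)] = True
        det = pd.Series(False, index=index)
        det.iloc[list(idx_det)] = True
        dv = None
        if dives is not None:
            dv = pd.Series(dives, index=index)
        return truth, det, dv

    def test_survey_recall_accounting(self):
        """79 of 109 truth-positive files detected -> 72 % recall."""
        truth, det, _ = self._series(200, range(109), range(79))
        res = detector_performance(truth, det)
        assert round(res["file_recall_pct"]) == 72

    def test_perfect_detector(self):
        truth, det, dv = self._series(50, range(10), range(10), dives=[i // 5 for i in range(50)])
        res = detector_performance(truth, det, dv)
        assert res["file_recall_pct"] == 100.0
        assert res["dive_false_detections"] == 0

    def test_false_positive_dives(self):
        """Detector fires on 10 dives, 7 of them truth-positive -> 3 false."""
        dives = [i for i in range(85) for _ in range(2)]
        n = len(dives)
        truth_idx = [2 * d for d in range(7)]
        det_idx = [2 * d for d in range(10)]
        truth, det, dv = self._series(n, truth_idx, det_idx, dives=dives)
        res = detector_performance(truth, det, dv)
        assert res["dive_detections"] == 10
        assert res["dive_true_detections"] == 7
        assert res["dive_false_detections"] == 3

    def test_universe_mismatch_rejected(self):
        truth, det, _ = self._series(10, [0], [0])
        with pytest.raises(ValueError):
            detector_performance(truth, det.iloc[:5])


class TestDiveSummaries:
    def test_counts_and_conservation(self):
        flags = make_flags(n_files=100, n_dives=10, positives=range(0, 30))
        dives = dive_summaries(flags, ["delphinid"])
        assert dives["n_minute_files"].sum() == 100
        assert dives["delphinid_files"].sum() == 30
        assert (dives["delphinid_pct"] <= 100).all()

    def test_write_report_outputs(self, tmp_path):
        import json

        from gliderpam.mission import write_report

        flags = make_flags(n_files=100, n_dives=10, positives=range(0, 50))
        flags["lat"] = 19.7
        flags["lon"] = -156.3
        rep = write_report(flags, tmp_path)
        assert rep["percent_by_class"]["delphinid"] == 50.0
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "dive_summaries.csv").exists()
        assert (tmp_path / "diel_delphinid.csv").exists()
        gj = json.loads((tmp_path / "dives.geojson").read_text())
        assert len(gj["features"]) == 10
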