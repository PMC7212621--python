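"""First-half filtering, entry classification, Table-style summary
features, the Poisson mixed model, and outcome labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diarycal import (
    FEATURE_NAMES,
    ValidationError,
    build_feature_matrix,
    classify_entry,
    define_outcomes,
    first_half_filter,
    fit_poisson_trajectory,
    summarize_features,
)
from diarycal.features import audit_zone

from conftest import make_entries, make_participants


class TestFirstHalfFilter:
    def test_strict_half_boundary(self):
        participants = make_participants(1, duration=70)
        entries = make_entries([("p1", 34, 2), ("p1", 35, 3)])
        out = first_half_filter(entries, participants)
        days = (out["date"] - pd.Timestamp("2020-01-01")).dt.days.tolist()
        assert days == [34]

    def test_late_followup_participant_excluded(self):
        participants = make_participants(2, duration=70)
        participants.loc[1, "followup_date"] = participants.loc[1, "baseline_date"] + pd.Timedelta(days=106)
        entries = make_entries([("p1", 10, 2), ("p2", 10, 2)])
        out = first_half_filter(entries, participants)
        assert set(out["participant_id"]) == {"p1"}

    def test_exactly_35_extra_days_retained(self):
        participants = make_participants(1, duration=105)
        out = first_half_filter(make_entries([("p1", 10, 2)]), participants)
        assert len(out) == 1

    def test_norm_time_in_first_half(self, small_cohort):
        _, participants, diary, _ = small_cohort
        out = first_half_filter(diary, participants)
        assert (out["norm_time"] >= 0).all() and (out["norm_time"] < 0.5).all()


class TestClassifyEntry:
    @pytest.mark.parametrize(
        "drinks,sex,expected",
        [
            (7, "female", "binge"),
            (8, "male", "heavy"),
            (9, "male", "binge"),
            (0, "female", "light"),
            (0, "male", "light"),
            (3, "female", "light"),
            (4, "female", "heavy"),
            (6, "female", "heavy"),
            (4, "male", "light"),
            (5, "male", "heavy"),
        ],
    )
    def test_threshold_table(self, drinks, sex, expected):
        assert classify_entry(drinks, sex) == expected

    @pytest.mark.parametrize("sex", ["female", "male"])
    def test_integer_partition_is_exhaustive(self, sex):
        for d in range(0, 30):
            assert classify_entry(d, sex) in {"light", "heavy", "binge"}

    def test_gap_value_resolved_by_precedence(self):
        # woman at 3.5 drinks falls in the printed-threshold gap; heavy wins over light
        assert classify_entry(3.5, "female") == "heavy"

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            classify_entry(-1, "female")
        with pytest.raises(ValidationError):
            classify_entry(2, "other")


class TestSummarizeFeatures:
    def test_three_entry_hand_computation(self):
        entries = make_entries([("p1", 0, 2), ("p1", 1, 0), ("p1", 2, 9)])
        f = summarize_features(entries, "female")
        assert f["Entries"] == 3
        assert f["Sum.drinks"] == 11
        assert f["Avg.drinks"] == pytest.approx(11 / 3)
        assert f["Max.drinks"] == 9
        assert f["Min.drinks"] == 0
        assert f["Range.drinks"] == 9
        assert f["Median.drinks"] == 2
        assert f["Abs.diff"] == 7  # signed last - first
        assert f["Rel.diff"] == pytest.approx(7 / 2)

    def test_singleton_entry(self):
        f = summarize_features(make_entries([("p1", 3, 5)]), "male")
        assert f["Abs.diff"] == 0
        assert f["Rel.diff"] == 0
        assert f["Range.drinks"] == 0
        assert f["Median.drinks"] == f["Avg.drinks"] == f["Max.drinks"] == f["Min.drinks"] == 5

    def test_zero_first_entry_rel_diff_zero(self):
        f = summarize_features(make_entries([("p1", 0, 0), ("p1", 1, 4)]), "male")
        assert f["Rel.diff"] == 0.0
        assert f["Abs.diff"] == 4.0

    def test_category_counts_one_each(self):
        f = summarize_features(make_entries([("p1", 0, 2), ("p1", 1, 5), ("p1", 2, 7)]), "female")
        assert (f["n.light"], f["n.heavy"], f["n.binge"]) == (1, 1, 1)
        for key in ("Perc.light", "Perc.heavy", "Perc.binge"):
            assert f[key] == pytest.approx(1 / 3)

    def test_order_by_date_not_input_order(self):
        shuffled = make_entries([("p1", 5, 9), ("p1", 0, 2), ("p1", 3, 4)])
        f = summarize_features(shuffled, "male")
        assert f["Abs.diff"] == 7  # 9 (day 5) minus 2 (day 0)

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=25),
        st.sampled_from(["female", "male"]),
    )
    def test_invariants_hold_for_any_entries(self, drinks, sex):
        entries = make_entries([("p1", i, d) for i, d in enumerate(drinks)])
        f = summarize_features(entries, sex)
        assert f["n.binge"] + f["n.heavy"] + f["n.light"] == f["Entries"]
        assert f["Perc.binge"] + f["Perc.heavy"] + f["Perc.light"] == pytest.approx(1.0)
        assert f["Range.drinks"] == f["Max.drinks"] - f["Min.drinks"]
        assert f["Sum.drinks"] == pytest.approx(f["Avg.drinks"] * f["Entries"])
        assert f["Min.drinks"] <= f["Median.drinks"] <= f["Max.drinks"]

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            summarize_features(make_entries([]), "male")


class TestPoissonTrajectory:
    def simulate(self, rng, n=60, obs=12, sd_int=0.4, sd_slope=0.8, b0=1.0, b1=-0.5):
        rows = []
        for i in range(n):
            u0 = rng.normal(0, sd_int)
            u1 = rng.normal(0, sd_slope)
            t = rng.uniform(0, 0.5, obs)
            mu = np.exp(b0 + u0 + (b1 + u1) * t)
            for j, (tj, m) in enumerate(zip(t, mu)):
                rows.append(
                    {
                        "participant_id": f"p{i:03d}",
                        "date": pd.Timestamp("2020-01-01") + pd.Timedelta(days=j),
                        "drinks": float(rng.poisson(m)),
                        "norm_time": tj,
                    }
                )
        return pd.DataFrame(rows)

    def test_constant_drinking_gives_null_effects(self):
        rows = []
        for i in range(10):
            for j in range(8):
                rows.append(
                    {
                        "participant_id": f"p{i}",
                        "date": pd.Timestamp("2020-01-01") + pd.Timedelta(days=j),
                        "drinks": 3.0,
                        "norm_time": j / 16,
                    }
                )
        fit = fit_poisson_trajectory(pd.DataFrame(rows))
        assert np.abs(fit.modes[["intercept", "slope"]].to_numpy()).max() < 0.05

    def test_fixed_effects_and_variance_recovered(self):
        rng = np.random.default_rng(11)
        entries = self.simulate(rng, n=80, obs=15)
        fit = fit_poisson_trajectory(entries)
        assert fit.beta[0] == pytest.approx(1.0, abs=0.25)
        assert fit.beta[1] == pytest.approx(-0.5, abs=0.6)
        assert 0.15**2 < fit.cov_re[0, 0] < 0.8**2
        # modes track the simulated participant effects
        assert fit.modes["intercept"].std() > 0.1

    def test_modes_shrink_relative_to_per_participant_fits(self):
        rng = np.random.default_rng(12)
        entries = self.simulate(rng, n=40, obs=6, sd_slope=0.5)
        fit = fit_poisson_trajectory(entries)
        pooled_b = fit.beta
        free_slopes = []
        for _, grp in entries.groupby("participant_id"):
            y = grp["drinks"].to_numpy()
            t = grp["norm_time"].to_numpy()
            if y.sum() == 0 or np.ptp(t) == 0:
                continue
            X = np.column_stack([np.ones_like(t), t])
            import statsmodels.api as smapi

            try:
                res = smapi.GLM(y, X, family=smapi.families.Poisson()).fit()
                free_slopes.append(res.params[1] - pooled_b[1])
            except Exception:
                continue
        shrunk = np.abs(fit.modes["slope"]).mean()
        free = np.mean(np.abs(free_slopes))
        assert shrunk < free

    def test_single_entry_participant_is_finite(self):
        rng = np.random.default_rng(13)
        entries = self.simulate(rng, n=10, obs=5)
        lone = pd.DataFrame(
            [{"participant_id": "zz_lone", "date": pd.Timestamp("2020-01-01"), "drinks": 4.0, "norm_time": 0.1}]
        )
        fit = fit_poisson_trajectory(pd.concat([entries, lone], ignore_index=True))
        row = fit.modes.set_index("participant_id").loc["zz_lone"]
        assert np.isfinite(row["intercept"]) and np.isfinite(row["slope"])

    def test_requires_norm_time(self):
        entries = make_entries([("p1", 0, 1), ("p2", 0, 2)])
        with pytest.raises(ValidationError):
            fit_poisson_trajectory(entries)


class TestOutcomes:
    def test_tlfb_thresholds(self):
        parts = make_participants(2)
        parts.loc[0, ["sex", "followup_tlfb"]] = ["male", 14.0]
        parts.loc[1, ["sex", "followup_tlfb"]] = ["female", 10.0]
        out = define_outcomes(parts).set_index("participant_id")
        assert bool(out.loc["p1", "non_hazardous"]) is True  # man at exactly 14
        assert bool(out.loc["p2", "non_hazardous"]) is False  # woman above 9

    def test_audit_zone_table(self):
        assert [audit_zone(s) for s in (0, 7, 8, 15, 16, 19, 20, 40)] == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_audit_improvement_requires_zone_change(self):
        parts = make_participants(2)
        parts.loc[0, ["audit_baseline", "audit_followup"]] = [17, 12]  # harmful -> hazardous
        parts.loc[1, ["audit_baseline", "audit_followup"]] = [14, 9]  # within hazardous
        out = define_outcomes(parts).set_index("participant_id")
        assert bool(out.loc["p1", "audit_improved"]) is True
        assert bool(out.loc["p2", "audit_improved"]) is False

    def test_missing_followup_excluded(self):
        parts = make_participants(2)
        parts.loc[1, "followup_tlfb"] = np.nan
        out = define_outcomes(parts)
        assert list(out["participant_id"]) == ["p1"]


def test_feature_matrix_has_all_18_columns(small_cohort):
    _, participants, diary, _ = small_cohort
    fh = first_half_filter(diary, participants)
    X = build_feature_matrix(fh, participants)
    assert list(X.columns) == FEATURE_NAMES
    assert len(FEATURE_NAMES) == 18
    assert not X.isna().any().any()
    assert X.index.is_unique
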