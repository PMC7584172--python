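import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hwr_community.measure import (
    combine_srrs,
    compute_hospital_srr,
    compute_srr,
    filter_index_admissions,
    fit_cohort_model,
    standardized_rate,
)
from hwr_community.synthetic import (
    TrueParams,
    generate_community_values,
    generate_geography,
    generate_hospitals,
    simulate_discharges,
)
from hwr_community.catalog import demo_catalog


def _records(n=10, **overrides):
    base = pd.DataFrame(
        {
            "discharge_id": [f"D{i}" for i in range(n)],
            "hospital_id": ["H1"] * n,
            "zip_code": ["10000"] * n,
            "cohort": ["medicine"] * n,
            "age_years": [75] * n,
            "comorbidity_count": [2] * n,
            "diagnosis_category": ["dx_a"] * n,
            "excluded_planned_index": [False] * n,
            "excluded_transfer": [False] * n,
            "excluded_died_hospice_ama": [False] * n,
            "readmitted_30d_unplanned": [False] * n,
        }
    )
    for k, v in overrides.items():
        base[k] = v
    return base


class TestFilter:
    def test_counts_removed_per_reason(self):
        d = _records(10, excluded_transfer=[True] * 3 + [False] * 7)
        eligible, removed = filter_index_admissions(d)
        assert len(eligible) == 7
        assert removed == {
            "excluded_planned_index": 0,
            "excluded_transfer": 3,
            "excluded_died_hospice_ama": 0,
        }

    def test_no_flags_is_identity(self):
        d = _records(5)
        eligible, _ = filter_index_admissions(d)
        pd.testing.assert_frame_equal(eligible, d)

    def test_all_flagged_warns_and_returns_empty(self):
        d = _records(4, excluded_planned_index=[True] * 4)
        with pytest.warns(UserWarning, match="no eligible"):
            eligible, removed = filter_index_admissions(d)
        assert len(eligible) == 0
        assert removed["excluded_planned_index"] == 4


class TestCombine:
    def test_unit_srrs_combine_to_one(self):
        log_srr, srr = combine_srrs([1.0, 1.0, 1.0], [10, 20, 30])
        assert log_srr == 0.0
        assert srr == 1.0

    def test_volume_weighted_log_mean_example(self):
        _, srr = combine_srrs([1.2, 0.8], [100, 300])
        expected = np.exp((100 * np.log(1.2) + 300 * np.log(0.8)) / 400)
        assert srr == pytest.approx(expected, abs=1e-15)
        assert srr == pytest.approx(0.885, abs=5e-4)

    def test_single_cohort_returns_its_srr(self):
        _, srr = combine_srrs([1.37], [42])
        assert srr == pytest.approx(1.37, abs=1e-15)

    def test_zero_volume_cohorts_skipped(self):
        _, srr = combine_srrs([5.0, 1.1], [0, 10])
        assert srr == pytest.approx(1.1, abs=1e-15)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            combine_srrs([1.0, -0.5], [1, 1])
        with pytest.raises(ValueError):
            combine_srrs([1.0], [0])
        with pytest.raises(ValueError):
            combine_srrs([1.0, 1.0], [-1, 2])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        srrs=st.lists(st.floats(0.1, 10.0), min_size=1, max_size=5),
        data=st.data(),
    )
    def test_combined_srr_between_min_and_max(self, srrs, data):
        vols = data.draw(
            st.lists(
                st.integers(1, 1000), min_size=len(srrs), max_size=len(srrs)
            )
        )
        _, srr = combine_srrs(srrs, vols)
        assert min(srrs) - 1e-12 <= srr <= max(srrs) + 1e-12


class TestStandardizedRate:
    @pytest.mark.parametrize(
        "srr,rate,expected",
        [(1.0, 0.153, 15.3), (1.1, 0.153, 16.83), (0.9, 0.153, 13.77)],
    )
    def test_rate_scale_conversion(self, srr, rate, expected):
        assert standardized_rate(srr, rate) == pytest.approx(expected)

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            standardized_rate(1.0, 0.0)


@pytest.fixture(scope="module")
def cohort_data():
    """Single-cohort discharges from 25 hospitals with real spread."""
    geo = generate_geography(10, 3, 0.0, seed=21)
    cv = generate_community_values(geo, demo_catalog(1), seed=21)
    hosp = generate_hospitals(25, tau=0.4, seed=21)
    params = TrueParams.realistic(
        seed=21, cohort_mix=(1.0, 0.0, 0.0, 0.0, 0.0), exclusion_rates=(0.0, 0.0, 0.0)
    )
    disc = simulate_discharges(hosp, geo, cv, params, 6000)
    return hosp, disc


class TestCohortModel:
    def test_fit_recovers_reasonable_estimates(self, cohort_data):
        hosp, disc = cohort_data
        fit = fit_cohort_model(disc)
        assert fit.fit.converged
        assert 0.1 < fit.tau_hat < 0.8
        # shrunken effects track the generating intercepts
        joined = pd.concat(
            [fit.alpha_hat.rename("ahat"),
             hosp.set_index("hospital_id")["alpha"]], axis=1
        ).dropna()
        assert joined["ahat"].corr(joined["alpha"], method="spearman") > 0.6

    def test_single_hospital_rejected(self):
        d = _records(50, readmitted_30d_unplanned=[True, False] * 25)
        with pytest.raises(ValueError, match="2 groups"):
            fit_cohort_model(d)

    def test_one_class_outcome_rejected(self):
        d = _records(40, hospital_id=["H1"] * 20 + ["H2"] * 20)
        with pytest.raises(ValueError, match="single class"):
            fit_cohort_model(d)

    def test_mixed_cohorts_rejected(self, cohort_data):
        _, disc = cohort_data
        d = disc.copy()
        d.loc[d.index[:10], "cohort"] = "neurology"
        with pytest.raises(ValueError, match="cohort"):
            fit_cohort_model(d)


class TestSRR:
    def test_hospital_at_average_effect_has_unit_srr(self, cohort_data):
        _, disc = cohort_data
        fit = fit_cohort_model(disc)
        h = fit.alpha_hat.index[0]
        fit.alpha_hat.loc[h] = fit.average_effect
        pred, exp, srr = compute_srr(fit, disc[disc["hospital_id"] == h])
        assert srr == pytest.approx(1.0, abs=1e-12)
        assert pred == pytest.approx(exp, rel=1e-12)

    def test_srr_rank_tracks_true_hospital_effects(self, cohort_data):
        hosp, disc = cohort_data
        fit = fit_cohort_model(disc)
        srrs = {}
        for h in fit.alpha_hat.index:
            _, _, srrs[h] = compute_srr(fit, disc[disc["hospital_id"] == h])
        joined = pd.concat(
            [pd.Series(srrs, name="srr"),
             hosp.set_index("hospital_id")["alpha"]], axis=1
        ).dropna()
        assert joined["srr"].corr(joined["alpha"], method="spearman") > 0.6

    def test_unknown_hospital_rejected(self, cohort_data):
        _, disc = cohort_data
        fit = fit_cohort_model(disc)
        ghost = disc.iloc[:5].copy()
        ghost["hospital_id"] = "H9999"
        with pytest.raises(KeyError):
            compute_srr(fit, ghost)


@pytest.fixture(scope="module")
def full_srr():
    geo = generate_geography(15, 2, 0.0, seed=31)
    cv = generate_community_values(geo, demo_catalog(1), seed=31)
    hosp = generate_hospitals(30, tau=0.3, seed=31)
    params = TrueParams.realistic(seed=31)
    disc = simulate_discharges(hosp, geo, cv, params, 15_000)
    srr, fits = compute_hospital_srr(disc, average_effect="weighted_mean_alpha")
    return srr, fits


class TestHospitalTable:
    def test_combined_srr_positive_and_log_consistent(self, full_srr):
        srr, _ = full_srr
        assert (srr["combined_srr"] > 0).all()
        np.testing.assert_allclose(
            srr["combined_srr"], np.exp(srr["combined_log_srr"]), rtol=1e-12
        )

    def test_volume_weighted_mean_log_srr_near_zero(self, full_srr):
        # with the volume-weighted average effect, the national log-SRR
        # balances out across hospitals
        srr, _ = full_srr
        w = srr["total_volume"].to_numpy(float)
        m = np.average(srr["combined_log_srr"], weights=w)
        assert abs(m) < 0.02

    def test_standardized_rate_centers_on_national_rate(self, full_srr):
        srr, _ = full_srr
        national = srr.attrs["national_rate"]
        w = srr["total_volume"].to_numpy(float)
        mean_rate = np.average(srr["standardized_rate_pct"], weights=w)
        assert mean_rate == pytest.approx(100 * national, rel=0.05)

    def test_volume_equals_eligible_discharges(self, full_srr):
        srr, _ = full_srr
        vol_cols = [c for c in srr.columns if c.startswith("vol_")]
        assert (srr[vol_cols].sum(axis=1) == srr["total_volume"]).all()
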