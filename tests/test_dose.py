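"""Unit and property tests of the deterministic dose-calculation chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosesim import (
    ExposureDesign,
    InsufficientDataError,
    MissingDataError,
    NegativeDoseWarning,
    PhantomLayout,
    TissueSite,
    compute_background,
    compute_calibration,
    compute_effective_dose,
    compute_location_doses,
    compute_protocol_E,
    compute_tissue_doses,
    generate_experiment,
    single_exposure_ratio,
)
from dosesim.exceptions import ConfigurationError

from conftest import small_truth, zero_noise


class TestCalibration:
    def test_identity_case(self):
        cal = compute_calibration([("a", 1.0), ("b", 1.0)], known_dose_mgy=1.0)
        assert cal.mean_cf == 1.0
        assert cal.cf_rsd_percent == 0.0

    def test_hand_arithmetic(self):
        # per-dosimeter CFs {90, 110}; sample SD of the pair = 20/sqrt(2)
        cal = compute_calibration([("a", 900.0), ("b", 1100.0)], known_dose_mgy=10.0)
        assert cal.mean_cf == pytest.approx(100.0)
        expected_rsd = 100.0 * (20.0 / math.sqrt(2)) / 100.0
        assert cal.cf_rsd_percent == pytest.approx(expected_rsd)
        assert cal.n == 2

    @pytest.mark.parametrize(
        "readings,dose,exc",
        [
            ([("a", 100.0)], 1.0, InsufficientDataError),
            ([("a", 100.0), ("b", 100.0)], 0.0, ValueError),
            ([("a", 100.0), ("b", -1.0)], 1.0, ValueError),
        ],
    )
    def test_rejects_bad_inputs(self, readings, dose, exc):
        with pytest.raises(exc):
            compute_calibration(readings, dose)


class TestBackground:
    def test_constant_readings(self):
        assert compute_background([100, 100, 100]) == (100.0, 0.0, 3)

    def test_hand_arithmetic(self):
        mean, rsd, n = compute_background([90, 100, 110])
        assert mean == pytest.approx(100.0)
        assert rsd == pytest.approx(10.0)  # sample SD of {90,100,110} is 10

    def test_single_reading_has_undefined_spread(self):
        assert compute_background([42.0]) == (42.0, 0.0, 1)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_background([])


class TestLocationDoses:
    def test_no_background(self):
        doses = compute_location_doses({"A": [1000, 1000]}, 100.0, 0.0)
        assert doses["A"] == pytest.approx(10.0)

    def test_background_subtracted_in_pulse_units(self):
        doses = compute_location_doses({"A": [1000, 1200]}, 100.0, 100.0)
        assert doses["A"] == pytest.approx(10.0)  # (1100-100)/100

    def test_negative_dose_clamped_with_warning(self):
        with pytest.warns(NegativeDoseWarning):
            doses = compute_location_doses({"A": [50, 50]}, 100.0, 100.0)
        assert doses["A"] == 0.0

    def test_clamp_can_be_disabled(self):
        doses = compute_location_doses(
            {"A": [50, 50]}, 100.0, 100.0, clamp_negative=False
        )
        assert doses["A"] == pytest.approx(-0.5)

    def test_missing_location_named(self):
        with pytest.raises(MissingDataError, match="A"):
            compute_location_doses({"A": []}, 100.0, 0.0)


class TestTissueDoses:
    def test_single_location_full_fraction(self, toy_layout):
        doses = compute_tissue_doses({"A": 5.0, "B": 0.0}, toy_layout)
        assert doses["thyroid"] == pytest.approx(5.0)

    def test_fraction_scales_mean(self):
        layout = PhantomLayout(
            ("A", "B"),
            {"thyroid": TissueSite(("A", "B"), 0.5)},
            {"thyroid": 0.04},
        )
        doses = compute_tissue_doses({"A": 10.0, "B": 20.0}, layout)
        assert doses["thyroid"] == pytest.approx(7.5)

    def test_zero_fraction_gives_zero(self):
        layout = PhantomLayout(
            ("A",), {"skin": TissueSite(("A",), 0.0)}, {"skin": 0.01}
        )
        assert compute_tissue_doses({"A": 10.0}, layout)["skin"] == 0.0

    def test_empty_location_list_rejected_at_construction(self):
        with pytest.raises(ConfigurationError):
            TissueSite((), 1.0)

    def test_shared_location_feeds_both_tissues(self):
        layout = PhantomLayout(
            ("A",),
            {
                "bone-surface": TissueSite(("A",), 1.0),
                "red-bone-marrow": TissueSite(("A",), 1.0),
            },
            {"bone-surface": 0.01, "red-bone-marrow": 0.12},
        )
        doses = compute_tissue_doses({"A": 3.0}, layout)
        assert doses == {"bone-surface": 3.0, "red-bone-marrow": 3.0}


class TestEffectiveDose:
    def test_single_tissue_unit_weight(self):
        layout = PhantomLayout(
            ("A",), {"t": TissueSite(("A",), 1.0)}, {"t": 1.0}, e_scale=1.0
        )
        assert compute_effective_dose({"t": 5.0}, layout) == pytest.approx(5.0)

    def test_weighted_summation(self, toy_layout):
        # 10*0.04 + 2*0.01... use explicit weights 0.04/0.12 as hand case
        layout = PhantomLayout(
            ("A", "B"),
            {"x": TissueSite(("A",), 1.0), "y": TissueSite(("B",), 1.0)},
            {"x": 0.04, "y": 0.12},
            e_scale=1.0,
        )
        assert compute_effective_dose({"x": 10.0, "y": 2.0}, layout) == pytest.approx(
            0.64
        )

    def test_all_zero_doses(self, toy_layout):
        assert compute_effective_dose({"thyroid": 0.0, "skin": 0.0}, toy_layout) == 0.0

    def test_missing_weight_rejected(self, toy_layout):
        with pytest.raises(ConfigurationError):
            compute_effective_dose({"lung": 1.0}, toy_layout)

    def test_e_scale_converts_units(self):
        layout = PhantomLayout(
            ("A",), {"t": TissueSite(("A",), 1.0)}, {"t": 0.04}, e_scale=1000.0
        )
        assert compute_effective_dose({"t": 1.0}, layout) == pytest.approx(40.0)


class TestSingleExposureRatio:
    def test_reference_design(self):
        # 50 exposures of 5 s reported per 0.6 s single exposure
        assert single_exposure_ratio(ExposureDesign(50, 5.0, 0.6)) == pytest.approx(
            416.6667, abs=5e-4
        )

    def test_identity(self):
        assert single_exposure_ratio(ExposureDesign(1, 2.0, 2.0)) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert single_exposure_ratio(ExposureDesign(10, 2.0, 0.5)) == pytest.approx(40.0)

    def test_bad_durations_rejected(self):
        with pytest.raises(ConfigurationError):
            ExposureDesign(50, -5.0, 0.6)


class TestProtocolChain:
    def test_zero_noise_round_trip(self):
        truth = zero_noise(small_truth())
        ms, true_e = generate_experiment(truth, seed=0)
        for p in truth.protocols:
            e = compute_protocol_E(ms, truth.layout, p)
            assert e == pytest.approx(true_e[p], rel=1e-10)

    def test_cf_scale_invariance(self):
        """Doubling every pulse count (exposed, background, calibration)
        doubles the CF and leaves E unchanged."""
        truth = small_truth()
        ms, _ = generate_experiment(truth, seed=3)
        e0 = compute_protocol_E(ms, truth.layout, "P1")
        ms.readings["pulses"] *= 2.0
        ms.background["pulses"] *= 2.0
        ms.calibration["pulses"] *= 2.0
        assert compute_protocol_E(ms, truth.layout, "P1") == pytest.approx(
            e0, rel=1e-12
        )

    def test_hand_computed_two_location_fixture(self, toy_layout):
        from conftest import single_location_measurements
        import pandas as pd

        readings = pd.DataFrame(
            {
                "protocol": ["P"] * 4,
                "location": ["A", "A", "B", "B"],
                "position": [1, 2, 1, 2],
                "pulses": [1000.0, 1200.0, 500.0, 700.0],
            }
        )
        calibration = pd.DataFrame(
            {"dosimeter_id": ["C1", "C2"], "pulses": [990.0, 1010.0]}
        )
        background = pd.DataFrame(
            {"protocol": ["P"], "dosimeter_id": ["B1"], "pulses": [100.0]}
        )
        from dosesim import MeasurementSet

        ms = MeasurementSet(
            readings=readings,
            calibration=calibration,
            known_dose_mgy=10.0,
            background=background,
            design=ExposureDesign(1, 0.6, 0.6),
        )
        # CF = 100 pulses/mGy; dose A = (1100-100)/100 = 10, dose B = 5
        # E = 0.04*10 + 0.01*(0.5*5) = 0.425; ratio = 1
        assert compute_protocol_E(ms, toy_layout, "P") == pytest.approx(0.425)

    def test_linearity_in_doses(self):
        """Scaling all exposed readings' dose content scales E linearly."""
        truth = zero_noise(small_truth())
        ms, _ = generate_experiment(truth, seed=0)
        e0 = compute_protocol_E(ms, truth.layout, "P1")
        bg = truth.background_mean_pulses["P1"]
        mask = ms.readings["protocol"] == "P1"
        ms.readings.loc[mask, "pulses"] = bg + 3.0 * (
            ms.readings.loc[mask, "pulses"] - bg
        )
        assert compute_protocol_E(ms, truth.layout, "P1") == pytest.approx(
            3.0 * e0, rel=1e-10
        )

    @given(
        bump=st.floats(min_value=0.0, max_value=1e6),
        loc_idx=st.integers(min_value=0, max_value=5),
    )
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_any_single_reading(self, bump, loc_idx):
        """Increasing one reading never decreases E."""
        truth = zero_noise(small_truth())
        ms, _ = generate_experiment(truth, seed=0)
        e0 = compute_protocol_E(ms, truth.layout, "P1")
        loc = truth.layout.locations[loc_idx]
        mask = (
            (ms.readings["protocol"] == "P1")
            & (ms.readings["location"] == loc)
            & (ms.readings["position"] == 1)
        )
        ms.readings.loc[mask, "pulses"] += bump
        assert compute_protocol_E(ms, truth.layout, "P1") >= e0 - 1e-12
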