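"""Shared fixtures: toy layouts and synthetic truths of various sizes."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from dosesim import (
    ExposureDesign,
    PhantomLayout,
    ReadoutRSDModel,
    TissueSite,
    default_truth,
    generate_experiment,
)
from dosesim.measurements import MeasurementSet
from dosesim.synth import SyntheticTruth


@pytest.fixture
def toy_layout() -> PhantomLayout:
    """Two locations feeding two tissues; e_scale 1 for hand arithmetic."""
    return PhantomLayout(
        locations=("A", "B"),
        tissue_map={
            "thyroid": TissueSite(("A",), 1.0),
            "skin": TissueSite(("B",), 0.5),
        },
        tissue_weights={"thyroid": 0.04, "skin": 0.01},
        e_scale=1.0,
    )


@pytest.fixture(scope="session")
def study_truth() -> SyntheticTruth:
    """The default 4-protocol × 25-location truth."""
    return default_truth()


@pytest.fixture(scope="session")
def study_experiment(study_truth):
    """One generated experiment from the default truth (seed 7)."""
    return generate_experiment(study_truth, seed=7)


def zero_noise(truth: SyntheticTruth) -> SyntheticTruth:
    """Strip every noise source from a truth."""
    return replace(
        truth,
        cf_rsd_percent=0.0,
        background_rsd_percent={p: 0.0 for p in truth.protocols},
        readout_model=ReadoutRSDModel(0.0, 0.0, 0.0),
        generator_rsd_percent=0.0,
    )


def small_truth(
    n_locations: int = 6,
    protocols: tuple[str, ...] = ("P1", "P2"),
    dosimeters_per_location: int = 2,
) -> SyntheticTruth:
    """A compact truth for fast Monte Carlo tests.

    Same noise magnitudes as the default study but fewer locations and
    protocols, so inner simulations run in milliseconds.
    """
    locations = tuple(f"L{i}" for i in range(n_locations))
    half = n_locations // 2
    if half:
        tissue_map = {
            "thyroid": TissueSite(locations[:half], 1.0),
            "remainder": TissueSite(locations[half:], 0.05),
        }
        weights = {"thyroid": 0.04, "remainder": 0.12}
    else:
        tissue_map = {"thyroid": TissueSite(locations, 1.0)}
        weights = {"thyroid": 0.04}
    layout = PhantomLayout(
        locations=locations, tissue_map=tissue_map, tissue_weights=weights
    )
    base = np.logspace(0.0, 2.0, n_locations)
    doses = {
        p: {loc: float(base[i]) for i, loc in enumerate(locations)}
        for p in protocols
    }
    bg_rsds = (9.5, 4.6, 8.6, 1.3)
    return SyntheticTruth(
        layout=layout,
        protocol_doses=doses,
        true_cf=2.5e5,
        cf_rsd_percent=3.2,
        background_mean_pulses={p: 2000.0 for p in protocols},
        background_rsd_percent={
            p: bg_rsds[i % len(bg_rsds)] for i, p in enumerate(protocols)
        },
        readout_model=ReadoutRSDModel.default(),
        generator_rsd_percent=2.4,
        design=ExposureDesign(),
        dosimeters_per_location=dosimeters_per_location,
    )


def single_location_measurements(
    pulses: list[float],
    calibration_pulses: list[float],
    known_dose: float = 1.0,
    background: float = 0.0,
) -> MeasurementSet:
    """A one-protocol, one-location measurement set for closed-form oracles."""
    readings = pd.DataFrame(
        {
            "protocol": ["P"] * len(pulses),
            "location": ["A"] * len(pulses),
            "position": list(range(1, len(pulses) + 1)),
            "pulses": pulses,
        }
    )
    calibration = pd.DataFrame(
        {
            "dosimeter_id": [f"C{i}" for i in range(len(calibration_pulses))],
            "pulses": calibration_pulses,
        }
    )
    bg = pd.DataFrame(
        {"protocol": ["P"], "dosimeter_id": ["B1"], "pulses": [background]}
    )
    return MeasurementSet(
        readings=readings,
        calibration=calibration,
        known_dose_mgy=known_dose,
        background=bg,
        design=ExposureDesign(),
    )
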