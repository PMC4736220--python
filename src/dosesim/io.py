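"""Reading and writing the package's file formats.

Three CSV dialects (all UTF-8, comma-separated, header required):

* measurements.csv — ``protocol,location,position,pulses``
* calibration.csv  — ``dosimeter_id,pulses`` (the known dose lives in the
  experiment config)
* background.csv   — ``protocol,dosimeter_id,pulses``

plus a YAML experiment config holding the phantom layout (locations,
tissues with weight/locations/fraction), the exposure design and the unit
conversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .layout import PhantomLayout, TissueSite
from .measurements import (
    BACKGROUND_COLUMNS,
    CALIBRATION_COLUMNS,
    READINGS_COLUMNS,
    ExposureDesign,
    MeasurementSet,
)


@dataclass(frozen=True)
class ExperimentConfig:
    layout: PhantomLayout
    design: ExposureDesign
    known_dose_mgy: float


def _read_csv(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(columns) - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    return df


def load_config(path) -> ExperimentConfig:
    """Load an experiment config (layout + design + calibration dose)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        tissues = {
            name: TissueSite(tuple(spec["locations"]), float(spec["fraction"]))
            for name, spec in raw["tissues"].items()
        }
        weights = {name: float(spec["weight"]) for name, spec in raw["tissues"].items()}
        layout = PhantomLayout(
            locations=tuple(raw["locations"]),
            tissue_map=tissues,
            tissue_weights=weights,
            e_scale=float(raw.get("e_scale", 1000.0)),
        )
        design_raw = raw["design"]
        design = ExposureDesign(
            n_exposures=int(design_raw["n_exposures"]),
            exposure_s=float(design_raw["exposure_s"]),
            single_exposure_s=float(design_raw["single_exposure_s"]),
        )
        known_dose = float(raw["calibration"]["known_dose_mgy"])
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"{path}: malformed experiment config ({exc})")
    return ExperimentConfig(layout=layout, design=design, known_dose_mgy=known_dose)


def dump_config(config: ExperimentConfig, path) -> None:
    raw = {
        "locations": list(config.layout.locations),
        "tissues": {
            name: {
                "weight": config.layout.tissue_weights[name],
                "locations": list(site.locations),
                "fraction": site.fraction,
            }
            for name, site in config.layout.tissue_map.items()
        },
        "e_scale": config.layout.e_scale,
        "design": {
            "n_exposures": config.design.n_exposures,
            "exposure_s": config.design.exposure_s,
            "single_exposure_s": config.design.single_exposure_s,
        },
        "calibration": {"known_dose_mgy": config.known_dose_mgy},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def load_measurements(
    measurements_csv, calibration_csv, background_csv, config: ExperimentConfig
) -> MeasurementSet:
    """Assemble a :class:`MeasurementSet` from the three CSV tables."""
    return MeasurementSet(
        readings=_read_csv(measurements_csv, READINGS_COLUMNS),
        calibration=_read_csv(calibration_csv, CALIBRATION_COLUMNS),
        known_dose_mgy=config.known_dose_mgy,
        background=_read_csv(background_csv, BACKGROUND_COLUMNS),
        design=config.design,
    )


def dump_measurements(measurements: MeasurementSet, out_dir) -> dict[str, Path]:
    """Write measurements/calibration/background CSVs into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": out / "measurements.csv",
        "calibration": out / "calibration.csv",
        "background": out / "background.csv",
    }
    measurements.readings.to_csv(paths["measurements"], index=False)
    measurements.calibration.to_csv(paths["calibration"], index=False)
    measurements.background.to_csv(paths["background"], index=False)
    return paths


def dump_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")
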