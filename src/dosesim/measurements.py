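"""In-memory containers for the raw dosimetry measurements.

A phantom dose experiment produces three tables of oven pulse counts:

* exposed readings — per (protocol, location, dosimeter position);
* a calibration set — dosimeters exposed to a known delivered dose;
* background readings — dosimeters left unexposed during each protocol.

plus the exposure design (how many exposures per protocol, how long each
lasted, and the duration of the single clinical exposure the effective dose
is reported for).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import ConfigurationError, MissingDataError
from .layout import PhantomLayout

READINGS_COLUMNS = ("protocol", "location", "position", "pulses")
CALIBRATION_COLUMNS = ("dosimeter_id", "pulses")
BACKGROUND_COLUMNS = ("protocol", "dosimeter_id", "pulses")


@dataclass(frozen=True)
class ExposureDesign:
    """Exposure schedule of one protocol.

    ``n_exposures`` exposures of ``exposure_s`` seconds each are delivered
    per protocol; results are reported per single clinical exposure of
    ``single_exposure_s`` seconds.
    """

    n_exposures: int = 50
    exposure_s: float = 5.0
    single_exposure_s: float = 0.6

    def __post_init__(self) -> None:
        if self.n_exposures < 1:
            raise ConfigurationError("n_exposures must be >= 1")
        if self.exposure_s <= 0 or self.single_exposure_s <= 0:
            raise ConfigurationError("exposure durations must be positive")


@dataclass
class MeasurementSet:
    """All raw read-outs of one experiment plus its exposure design.

    Attributes
    ----------
    readings
        DataFrame with columns ``protocol, location, position, pulses``.
    calibration
        DataFrame with columns ``dosimeter_id, pulses``.
    known_dose_mgy
        Delivered dose of the calibration exposure (mGy).
    background
        DataFrame with columns ``protocol, dosimeter_id, pulses``.
    design
        The :class:`ExposureDesign`.
    """

    readings: pd.DataFrame
    calibration: pd.DataFrame
    known_dose_mgy: float
    background: pd.DataFrame
    design: ExposureDesign

    def __post_init__(self) -> None:
        for df, cols in (
            (self.readings, READINGS_COLUMNS),
            (self.calibration, CALIBRATION_COLUMNS),
            (self.background, BACKGROUND_COLUMNS),
        ):
            missing = set(cols) - set(df.columns)
            if missing:
                raise ConfigurationError(f"missing columns {sorted(missing)}")
        if self.known_dose_mgy <= 0:
            raise ConfigurationError("known_dose_mgy must be positive")
        for name, df in (
            ("readings", self.readings),
            ("calibration", self.calibration),
            ("background", self.background),
        ):
            if (df["pulses"] < 0).any():
                raise ConfigurationError(f"negative pulse counts in {name}")
        bg_protocols = set(self.background["protocol"])
        for protocol in self.protocols:
            if protocol not in bg_protocols:
                raise MissingDataError(
                    f"protocol {protocol!r} has no background readings"
                )

    @property
    def protocols(self) -> list[str]:
        """Protocol names in order of first appearance in ``readings``."""
        return list(dict.fromkeys(self.readings["protocol"]))

    def protocol_readings(self, protocol: str) -> dict[str, list[float]]:
        """Pulse counts per location for one protocol."""
        sub = self.readings[self.readings["protocol"] == protocol]
        if sub.empty:
            raise MissingDataError(f"no readings for protocol {protocol!r}")
        return {
            loc: grp.sort_values("position")["pulses"].tolist()
            for loc, grp in sub.groupby("location", sort=True)
        }

    def background_readings(self, protocol: str) -> list[float]:
        sub = self.background[self.background["protocol"] == protocol]
        if sub.empty:
            raise MissingDataError(f"no background readings for {protocol!r}")
        return sub["pulses"].tolist()

    def validate_against_layout(self, layout: PhantomLayout) -> None:
        """Check every protocol has readings at every layout location."""
        for protocol in self.protocols:
            have = set(self.protocol_readings(protocol))
            missing = set(layout.locations) - have
            if missing:
                raise MissingDataError(
                    f"protocol {protocol!r} lacks readings at {sorted(missing)}"
                )
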