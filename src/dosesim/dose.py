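"""Deterministic effective-dose calculation chain.

The chain reconstructs how E is derived from TLD read-outs:

1. calibration factor CF = mean calibration pulses / known dose (pulses/mGy);
2. background = mean pulses of the unexposed dosimeters of the protocol;
3. location dose = (mean pulses of the location's dosimeters - background)/CF;
4. tissue dose D_T = irradiated fraction × mean dose over the tissue's
   locations;
5. E = e_scale × Σ_T w_T · D_T, reported per single exposure by dividing by
   the exposure-time ratio (protocol seconds / single-exposure seconds).

Background subtraction happens in pulse units, before CF division — the
only dimensionally consistent order given CF in pulses/mGy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    MissingDataError,
    NegativeDoseWarning,
)
from .layout import PhantomLayout
from .measurements import ExposureDesign, MeasurementSet


@dataclass(frozen=True)
class CalibrationSummary:
    """Mean calibration factor and the spread of the individual factors."""

    mean_cf: float  # pulses per mGy
    per_dosimeter_cf: tuple[float, ...]
    cf_rsd_percent: float
    n: int


class BackgroundSummary(NamedTuple):
    mean_pulses: float
    rsd_percent: float
    n: int


def _as_pulse_pairs(calibration) -> list[tuple[str, float]]:
    if isinstance(calibration, pd.DataFrame):
        return list(zip(calibration["dosimeter_id"], calibration["pulses"]))
    return [(str(i), float(p)) for i, p in calibration]


def compute_calibration(calibration, known_dose_mgy: float) -> CalibrationSummary:
    """Calibration factor of the TLD batch from a known-dose exposure.

    Each dosimeter's individual CF is its pulse count divided by the known
    delivered dose; the mean CF converts pulses to mGy downstream, and the
    relative standard deviation (sample SD, n-1 denominator) of the
    individual CFs quantifies the calibration random error.

    Parameters
    ----------
    calibration
        Sequence of ``(dosimeter_id, pulses)`` or a DataFrame with columns
        ``dosimeter_id, pulses``.
    known_dose_mgy
        Delivered calibration dose in mGy (> 0).
    """
    pairs = _as_pulse_pairs(calibration)
    if len(pairs) < 2:
        raise InsufficientDataError("need >= 2 calibration readings")
    if known_dose_mgy <= 0:
        raise ValueError("known_dose_mgy must be positive")
    pulses = np.asarray([p for _, p in pairs], dtype=float)
    if (pulses <= 0).any():
        raise ValueError("calibration pulse counts must be positive")
    per_cf = pulses / known_dose_mgy
    mean_cf = float(per_cf.mean())
    rsd = 100.0 * float(per_cf.std(ddof=1)) / mean_cf
    return CalibrationSummary(
        mean_cf=mean_cf,
        per_dosimeter_cf=tuple(per_cf.tolist()),
        cf_rsd_percent=rsd,
        n=len(pairs),
    )


def compute_background(values: Sequence[float]) -> BackgroundSummary:
    """Mean and sample RSD of a protocol's unexposed-dosimeter readings.

    With a single reading the spread is unobservable and the RSD is
    reported as 0.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise InsufficientDataError("no background readings")
    mean = float(vals.mean())
    if vals.size == 1:
        return BackgroundSummary(mean, 0.0, 1)
    sd = float(vals.std(ddof=1))
    if mean == 0 and sd == 0:
        return BackgroundSummary(0.0, 0.0, int(vals.size))  # background-free setup
    if mean <= 0:
        raise ValueError("mean background must be positive to form an RSD")
    rsd = 100.0 * float(vals.std(ddof=1)) / mean
    return BackgroundSummary(mean, rsd, int(vals.size))


def compute_location_doses(
    readings: Mapping[str, Sequence[float]],
    calibration,
    mean_bg_pulses: float,
    *,
    clamp_negative: bool = True,
) -> dict[str, float]:
    """Absorbed dose (mGy) at each phantom location.

    The dosimeters of a location are averaged, the mean background pulse
    count is subtracted, and the result is divided by the mean CF.
    Negative background-corrected values are clamped to 0 with a
    :class:`NegativeDoseWarning` (physical doses are non-negative); pass
    ``clamp_negative=False`` to keep them for variance studies.

    Parameters
    ----------
    calibration
        A :class:`CalibrationSummary` or a bare mean CF in pulses/mGy.
    """
    cf = calibration.mean_cf if isinstance(calibration, CalibrationSummary) else float(calibration)
    if cf <= 0:
        raise ValueError("mean CF must be positive")
    if mean_bg_pulses < 0:
        raise ValueError("mean background must be non-negative")
    doses: dict[str, float] = {}
    for loc, pulses in readings.items():
        vals = np.asarray(list(pulses), dtype=float)
        if vals.size == 0:
            raise MissingDataError(f"no readings at location {loc!r}")
        dose = (float(vals.mean()) - mean_bg_pulses) / cf
        if dose < 0 and clamp_negative:
            warnings.warn(
                f"background-corrected dose at {loc!r} was {dose:.4g} mGy; clamped to 0",
                NegativeDoseWarning,
                stacklevel=2,
            )
            dose = 0.0
        doses[loc] = dose
    return doses


def compute_tissue_doses(
    location_doses: Mapping[str, float], layout: PhantomLayout
) -> dict[str, float]:
    """Tissue doses: irradiated fraction × mean dose over the tissue's locations."""
    out: dict[str, float] = {}
    for tissue, site in layout.tissue_map.items():
        try:
            mean_dose = sum(location_doses[loc] for loc in site.locations) / len(
                site.locations
            )
        except KeyError as exc:
            raise MissingDataError(
                f"tissue {tissue!r} needs location {exc.args[0]!r}"
            ) from None
        out[tissue] = site.fraction * mean_dose
    return out


def compute_effective_dose(
    tissue_doses: Mapping[str, float], layout: PhantomLayout
) -> float:
    """Effective dose E = e_scale × Σ_T w_T · D_T.

    With tissue doses in mGy and the default ``e_scale`` of 1000 the result
    is in µSv (radiation weighting factor 1 for X-rays, so absorbed and
    equivalent dose coincide).
    """
    total = 0.0
    for tissue, d in tissue_doses.items():
        try:
            w = layout.tissue_weights[tissue]
        except KeyError:
            raise ConfigurationError(f"tissue {tissue!r} has no weighting factor")
        total += w * d
    return layout.e_scale * total


def single_exposure_ratio(design: ExposureDesign) -> float:
    """Exposure-time ratio converting protocol E to single-exposure E.

    ratio = (n_exposures × exposure_s) / single_exposure_s; e.g. 50
    exposures of 5 s reported per 0.6 s exposure give 250/0.6 ≈ 416.7.
    """
    if design.exposure_s <= 0 or design.single_exposure_s <= 0:
        raise ValueError("durations must be positive")
    if design.n_exposures < 1:
        raise ValueError("n_exposures must be >= 1")
    return design.n_exposures * design.exposure_s / design.single_exposure_s


def compute_protocol_E(
    measurements: MeasurementSet,
    layout: PhantomLayout,
    protocol: str,
    *,
    clamp_negative: bool = True,
) -> float:
    """Deterministic E per single exposure (µSv) for one protocol.

    Composes the full chain: calibration → background → location doses →
    tissue doses → weighted sum → division by the exposure-time ratio.
    """
    cal = compute_calibration(measurements.calibration, measurements.known_dose_mgy)
    bg = compute_background(measurements.background_readings(protocol))
    readings = measurements.protocol_readings(protocol)
    missing = set(layout.locations) - set(readings)
    if missing:
        raise MissingDataError(
            f"protocol {protocol!r} lacks readings at {sorted(missing)}"
        )
    loc_doses = compute_location_doses(
        readings, cal, bg.mean_pulses, clamp_negative=clamp_negative
    )
    tissue_doses = compute_tissue_doses(loc_doses, layout)
    e_protocol = compute_effective_dose(tissue_doses, layout)
    return e_protocol / single_exposure_ratio(measurements.design)
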