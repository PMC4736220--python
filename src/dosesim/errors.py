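"""Quantification of the random-error (RE) sources of the experiment.

Four RE sources feed the Monte Carlo engine:

1. calibration factor — RSD of the individual dosimeter CFs;
2. background correction — per-protocol RSD of the unexposed readings;
3. the read-out process — an RSD that *depends on the read-out value*,
   modelled as a quadratic RSD(v) = a0 + a1·v + a2·v² fitted to the
   observed pair RSDs of duplicate dosimeters (high pulse counts read out
   with lower relative error than low ones; using one average RSD would
   overweight the error of the large values that dominate E);
4. the X-ray generator output — a per-exposure RSD, which averages over
   the n exposures of a protocol as RSD/√n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .dose import compute_background, compute_calibration
from .exceptions import (
    ExtrapolationWarning,
    FitRejectedError,
    InsufficientDataError,
)
from .measurements import MeasurementSet

#: Quadratic read-out RSD coefficients estimated from a lateral-cephalography
#: phantom study (pair RSDs of duplicate TLDs over 4 protocols × 25
#: locations): RSD(%) = 4.57 − 1.98e−7·v + 3.29e−15·v², v in oven pulses.
DEFAULT_READOUT_COEFFS: tuple[float, float, float] = (4.57, -1.98e-7, 3.29e-15)

#: Pulse range over which the default coefficients were estimated (the
#: quadratic's vertex sits near 3.0e7 pulses; beyond it the fit turns up).
DEFAULT_READOUT_RANGE: tuple[float, float] = (0.0, 3.0e7)

ERROR_MODES = ("mean-of-n", "direct")


def pair_rsd(values: Sequence[float]) -> float:
    """Sample RSD (%) of replicate dosimeter readings at one location."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise InsufficientDataError("pair RSD needs >= 2 values")
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError("pair mean must be positive")
    return 100.0 * float(vals.std(ddof=1)) / mean


def propagate_mean_rsd(rsd_single_percent: float, n: int) -> float:
    """RSD of the mean of n independent measurements: rsd/√n.

    This is the error-propagation rule for averaging — e.g. a generator
    whose single-exposure output fluctuates with RSD 2.4% delivers a
    50-exposure protocol dose with RSD 2.4/√50 ≈ 0.34%.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rsd_single_percent < 0:
        raise ValueError("RSD must be non-negative")
    return rsd_single_percent / math.sqrt(n)


@dataclass(frozen=True)
class ReadoutRSDModel:
    """Value-dependent read-out RSD: RSD(%) = a0 + a1·v + a2·v².

    ``valid_range`` is the pulse interval over which the model was fitted;
    evaluating outside it warns (the quadratic extrapolates badly).
    ``coeff_stderr`` holds OLS standard errors when the fit had enough
    points to estimate them.
    """

    a0: float
    a1: float
    a2: float
    valid_range: tuple[float, float] = DEFAULT_READOUT_RANGE
    coeff_stderr: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError("valid_range must be an increasing interval")
        # a0=a1=a2=0 (a noise-free read-out) is allowed for constructed
        # models; fitted models are additionally required to stay > 0
        # (see fit_readout_rsd_model).
        if self._min_on(lo, hi) < 0:
            raise FitRejectedError(
                "model predicts negative RSD inside its valid range"
            )

    def _min_on(self, lo: float, hi: float) -> float:
        candidates = [self.rsd_unchecked(lo), self.rsd_unchecked(hi)]
        if self.a2 != 0:
            vertex = -self.a1 / (2.0 * self.a2)
            if lo < vertex < hi:
                candidates.append(self.rsd_unchecked(vertex))
        return min(candidates)

    def rsd_unchecked(self, value) -> float:
        return self.a0 + self.a1 * np.asarray(value, dtype=float) + self.a2 * np.square(
            np.asarray(value, dtype=float)
        )

    def rsd(self, value):
        """RSD (%) at a pulse value (scalar or array); warns outside range."""
        arr = np.asarray(value, dtype=float)
        if (arr < 0).any():
            raise ValueError("pulse values must be non-negative")
        lo, hi = self.valid_range
        if (arr < lo).any() or (arr > hi).any():
            warnings.warn(
                "read-out RSD model evaluated outside its fitted pulse range",
                ExtrapolationWarning,
                stacklevel=2,
            )
        out = self.a0 + self.a1 * arr + self.a2 * arr * arr
        return float(out) if np.isscalar(value) else out

    @classmethod
    def default(cls) -> "ReadoutRSDModel":
        """The shipped default model (see :data:`DEFAULT_READOUT_COEFFS`)."""
        return cls(*DEFAULT_READOUT_COEFFS)


def evaluate_readout_rsd(model: ReadoutRSDModel, value: float) -> float:
    """Functional form of :meth:`ReadoutRSDModel.rsd` for a single value."""
    return float(model.rsd(float(value)))


def fit_readout_rsd_model(
    pairs: Sequence[tuple[float, float]],
) -> ReadoutRSDModel:
    """Least-squares quadratic of pair RSD on pair mean pulse value.

    Parameters
    ----------
    pairs
        ``(mean_value_pulses, rsd_percent)`` points, one per
        protocol × location duplicate pair.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 distinct abscissae (a quadratic is underdetermined).
    FitRejectedError
        The fitted curve dips to RSD ≤ 0 somewhere inside the observed
        value range, which no physical read-out process can do.
    """
    pts = [(float(v), float(r)) for v, r in pairs]
    xs = np.asarray([v for v, _ in pts])
    ys = np.asarray([r for _, r in pts])
    if np.unique(xs).size < 3:
        raise InsufficientDataError("quadratic fit needs >= 3 distinct values")
    if xs.size >= 4:
        coeffs, cov = np.polyfit(xs, ys, 2, cov=True)
        stderr = tuple(np.sqrt(np.diag(cov))[::-1].tolist())
    else:
        coeffs = np.polyfit(xs, ys, 2)
        stderr = None
    a2, a1, a0 = (float(c) for c in coeffs)
    model = ReadoutRSDModel(
        a0=a0,
        a1=a1,
        a2=a2,
        valid_range=(float(xs.min()), float(xs.max())),
        coeff_stderr=stderr,
    )
    if model._min_on(*model.valid_range) <= 0:
        raise FitRejectedError(
            "fitted quadratic predicts non-positive RSD inside the data range"
        )
    return model


@dataclass(frozen=True)
class ErrorModel:
    """All quantified RE sources, ready for the Monte Carlo engine.

    ``cf_error_mode`` / ``background_error_mode`` control whether the RE
    applied to a *mean* quantity is the component RSD divided by √n
    ("mean-of-n", the error of a mean of n dosimeters — the default) or
    the raw component RSD ("direct").
    """

    cf_rsd_percent: float
    background_rsd_percent: Mapping[str, float]
    readout_model: ReadoutRSDModel
    generator_rsd_percent: float
    cf_error_mode: str = "mean-of-n"
    background_error_mode: str = "mean-of-n"

    def __post_init__(self) -> None:
        if self.cf_error_mode not in ERROR_MODES:
            raise ValueError(f"cf_error_mode must be one of {ERROR_MODES}")
        if self.background_error_mode not in ERROR_MODES:
            raise ValueError(f"background_error_mode must be one of {ERROR_MODES}")
        if self.cf_rsd_percent < 0 or self.generator_rsd_percent < 0:
            raise ValueError("RSDs must be non-negative")
        if any(r < 0 for r in self.background_rsd_percent.values()):
            raise ValueError("RSDs must be non-negative")

    def effective_cf_rsd(self, n_calibration: int) -> float:
        if self.cf_error_mode == "mean-of-n":
            return propagate_mean_rsd(self.cf_rsd_percent, n_calibration)
        return self.cf_rsd_percent

    def effective_background_rsd(self, protocol: str, n_background: int) -> float:
        rsd = self.background_rsd_percent[protocol]
        if self.background_error_mode == "mean-of-n":
            return propagate_mean_rsd(rsd, n_background)
        return rsd

    def with_modes(self, cf: str | None = None, background: str | None = None):
        return replace(
            self,
            cf_error_mode=cf or self.cf_error_mode,
            background_error_mode=background or self.background_error_mode,
        )

    @classmethod
    def from_measurements(
        cls,
        measurements: MeasurementSet,
        generator_rsd_percent: float = 2.4,
        **modes,
    ) -> "ErrorModel":
        """Estimate every data-driven RE component from a measurement set.

        The generator output RSD cannot be observed in the TLD tables (it
        enters only when a protocol dose is converted to one exposure) and
        is supplied as a parameter, default 2.4% — the bench-measured
        fluctuation of a cephalographic generator.
        """
        cal = compute_calibration(measurements.calibration, measurements.known_dose_mgy)
        bg = {
            p: compute_background(measurements.background_readings(p)).rsd_percent
            for p in measurements.protocols
        }
        points = readout_rsd_points(measurements)
        model = fit_readout_rsd_model(points)
        return cls(
            cf_rsd_percent=cal.cf_rsd_percent,
            background_rsd_percent=bg,
            readout_model=model,
            generator_rsd_percent=generator_rsd_percent,
            **modes,
        )


def readout_rsd_points(measurements: MeasurementSet) -> list[tuple[float, float]]:
    """(pair mean pulses, pair RSD %) per protocol × location.

    The abscissa is the pair mean — the symmetric choice of representative
    read-out value for a duplicate pair.
    """
    points: list[tuple[float, float]] = []
    for protocol in measurements.protocols:
        for loc, vals in measurements.protocol_readings(protocol).items():
            if len(vals) >= 2:
                mean = float(np.mean(vals))
                points.append((mean, pair_rsd(vals)))
    return points


def default_error_model(
    protocols: Sequence[str],
    background_rsds: Sequence[float] = (9.5, 4.6, 8.6, 1.3),
    **kwargs,
) -> ErrorModel:
    """Error model with the component magnitudes of the reference study.

    CF RSD 3.2%, per-protocol background RSDs cycling through
    ``background_rsds``, the default read-out quadratic and a 2.4%
    per-exposure generator RSD.
    """
    bg = {
        p: float(background_rsds[i % len(background_rsds)])
        for i, p in enumerate(protocols)
    }
    defaults = dict(
        cf_rsd_percent=3.2,
        background_rsd_percent=bg,
        readout_model=ReadoutRSDModel.default(),
        generator_rsd_percent=2.4,
    )
    defaults.update(kwargs)
    return ErrorModel(**defaults)
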