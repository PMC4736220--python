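"""Monte Carlo engine: repeat the E calculation under random-error draws.

Each cycle re-runs the full dose chain with every measured quantity
perturbed by a Normal draw around its observed value, scaled by that
quantity's RSD:

* ONE calibration-factor draw per cycle, shared by all protocols — the
  real experiment calibrated once and used that CF everywhere, so paired
  protocol differences must share the CF draw or their RE is overestimated;
* one background draw per protocol per cycle;
* one draw per dosimeter reading, with RSD taken from the value-dependent
  read-out model evaluated at that reading;
* one draw of the exposure-time conversion ratio per protocol per cycle,
  with RSD = generator per-exposure RSD / √n_exposures.

RNG streams are split per component and per protocol (seeded from the run
seed and a CRC of the protocol name), so adding or removing a protocol
does not disturb another protocol's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose import (
    compute_background,
    compute_calibration,
    single_exposure_ratio,
)
from .errors import ErrorModel
from .exceptions import InsufficientDataError, MissingDataError
from .layout import PhantomLayout
from .measurements import MeasurementSet


def perturb(value, rsd_percent: float, rng: np.random.Generator):
    """One Normal draw around ``value`` with SD = value·rsd/100.

    An RSD of 0 (or a value of 0) returns the value unchanged.
    """
    if rsd_percent < 0:
        raise ValueError("RSD must be non-negative")
    arr = np.asarray(value, dtype=float)
    if rsd_percent == 0:
        return value
    out = arr + np.abs(arr) * (rsd_percent / 100.0) * rng.standard_normal(arr.shape)
    return float(out) if np.isscalar(value) else out


@dataclass(frozen=True)
class SummaryStats:
    """Summary of one protocol's sampled E distribution."""

    mean: float
    sd: float
    rsd_percent: float
    ci_low: float
    ci_high: float
    ci_level: float
    n: int
    five_number: tuple[float, float, float, float, float]  # min, Q1, median, Q3, max

    def as_dict(self) -> dict:
        d = {
            "mean": self.mean,
            "sd": self.sd,
            "rsd_percent": self.rsd_percent,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "n": self.n,
        }
        d.update(
            zip(("min", "q1", "median", "q3", "max"), self.five_number)
        )
        return d


@dataclass(frozen=True)
class ComparisonSummary:
    """Cycle-wise paired difference E_a − E_b between two protocols."""

    protocol_a: str
    protocol_b: str
    mean_diff: float
    sd_diff: float
    ci_low: float
    ci_high: float
    alpha: float
    sign_agreement: float  # fraction of cycles agreeing with the mean's sign
    significant: bool  # CI excludes 0

    def as_dict(self) -> dict:
        return {
            "protocol_a": self.protocol_a,
            "protocol_b": self.protocol_b,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "alpha": self.alpha,
            "sign_agreement": self.sign_agreement,
            "significant": self.significant,
        }


def summarize(samples: Sequence[float], ci_level: float = 0.95) -> SummaryStats:
    """Mean, sample SD, RSD, percentile CI and five-number summary.

    Quantiles use linear interpolation (numpy's default, type 7), so the
    box-plot numbers are bit-reproducible.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("need >= 2 samples to summarize")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    tail = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(arr, [tail, 1.0 - tail])
    q = np.quantile(arr, [0.0, 0.25, 0.5, 0.75, 1.0])
    return SummaryStats(
        mean=mean,
        sd=sd,
        rsd_percent=100.0 * sd / mean if mean != 0 else float("nan"),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        n=int(arr.size),
        five_number=tuple(float(x) for x in q),
    )


@dataclass
class SimulationResult:
    """Sampled E distributions of one Monte Carlo run.

    All protocols of a run share the same cycle structure (and, in
    shared-CF mode, the same CF draw per cycle), so paired comparisons are
    only meaningful *within* one result — which is the only way the API
    allows them to be made.
    """

    cycles: int
    seed: int | None
    ci_level: float
    shared_cf: bool
    protocols: tuple[str, ...]
    samples: Mapping[str, np.ndarray]
    summaries: Mapping[str, SummaryStats]
    diagnostics: dict = field(default_factory=dict)

    def compare(
        self, protocol_a: str, protocol_b: str, alpha: float = 0.05
    ) -> ComparisonSummary:
        return compare_protocols(self, protocol_a, protocol_b, alpha)

    def samples_frame(self) -> pd.DataFrame:
        """Cycle × protocol table of sampled E values."""
        return pd.DataFrame(
            {p: np.asarray(self.samples[p]) for p in self.protocols}
        ).rename_axis(index="cycle")

    def boxplot_frame(self) -> pd.DataFrame:
        """Five-number summary per protocol (box-plot input)."""
        rows = []
        for p in self.protocols:
            mn, q1, med, q3, mx = self.summaries[p].five_number
            rows.append(
                {"protocol": p, "min": mn, "q1": q1, "median": med, "q3": q3, "max": mx}
            )
        return pd.DataFrame(rows)


def _protocol_stream(seed_root: int | None, tag: bytes) -> np.random.Generator:
    key = zlib.crc32(tag)
    entropy = [key] if seed_root is None else [seed_root, key]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def run_simulation(
    measurements: MeasurementSet,
    layout: PhantomLayout,
    error_model: ErrorModel,
    cycles: int = 10_000,
    seed: int | None = None,
    *,
    ci_level: float = 0.95,
    shared_cf: bool = True,
    clamp_negative: bool = True,
) -> SimulationResult:
    """Run the full RE simulation over all protocols of a measurement set.

    Parameters
    ----------
    cycles
        Number of recomputations of E (default 10,000).
    seed
        Master seed; the same (inputs, seed, cycles) reproduce bit-identical
        samples. ``None`` draws fresh OS entropy.
    shared_cf
        Draw one CF perturbation per cycle shared by all protocols (the
        physically correct mode for paired comparisons). ``False`` draws an
        independent CF per protocol — provided to quantify how much that
        overestimates the RE of protocol differences.
    clamp_negative
        Clamp negative perturbed pulse values and background-corrected
        doses to 0 (counts reported in ``diagnostics``).

    Notes
    -----
    The draw order within a protocol's stream is fixed (readings, then
    background, then conversion ratio), and each protocol owns its own
    stream, so results for one protocol are unaffected by the presence of
    others.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    measurements.validate_against_layout(layout)
    protocols = tuple(measurements.protocols)

    cal = compute_calibration(measurements.calibration, measurements.known_dose_mgy)
    ratio = single_exposure_ratio(measurements.design)
    ratio_rsd = error_model.generator_rsd_percent / np.sqrt(
        measurements.design.n_exposures
    )
    cf_rsd_eff = error_model.effective_cf_rsd(cal.n)

    # one shared CF draw per cycle (the single cross-protocol dependency)
    cf_shared_rng = _protocol_stream(seed, b"cf-shared")
    cf_shared = cal.mean_cf * (
        1.0 + cf_rsd_eff / 100.0 * cf_shared_rng.standard_normal(cycles)
    )

    loc_order = list(layout.locations)
    weight_vec = layout.location_weight_vector()
    v = np.asarray([weight_vec[loc] for loc in loc_order])

    samples: dict[str, np.ndarray] = {}
    diagnostics: dict = {"clamped_readings": {}, "clamped_doses": {}}

    for protocol in protocols:
        readings = measurements.protocol_readings(protocol)
        flat: list[float] = []
        col_index: list[int] = []
        counts = np.zeros(len(loc_order))
        for j, loc in enumerate(loc_order):
            vals = readings[loc]
            flat.extend(float(x) for x in vals)
            col_index.extend([j] * len(vals))
            counts[j] = len(vals)
        vals_arr = np.asarray(flat)
        # averaging matrix: (n_readings, n_locations), column-stochastic
        avg = np.zeros((vals_arr.size, len(loc_order)))
        avg[np.arange(vals_arr.size), col_index] = 1.0 / counts[col_index]

        read_rsd = np.asarray(error_model.readout_model.rsd(vals_arr)) / 100.0
        bg = compute_background(measurements.background_readings(protocol))
        bg_rsd_eff = error_model.effective_background_rsd(protocol, bg.n)

        rng = _protocol_stream(seed, b"data:" + protocol.encode())
        z_read = rng.standard_normal((cycles, vals_arr.size))
        z_bg = rng.standard_normal(cycles)
        z_ratio = rng.standard_normal(cycles)

        pert = vals_arr * (1.0 + read_rsd * z_read)
        if clamp_negative:
            n_clamped = int((pert < 0).sum())
            if n_clamped:
                np.maximum(pert, 0.0, out=pert)
            diagnostics["clamped_readings"][protocol] = n_clamped

        bg_draw = bg.mean_pulses * (1.0 + bg_rsd_eff / 100.0 * z_bg)
        if clamp_negative:
            np.maximum(bg_draw, 0.0, out=bg_draw)

        if shared_cf:
            cf_draw = cf_shared
        else:
            cf_rng = _protocol_stream(seed, b"cf:" + protocol.encode())
            cf_draw = cal.mean_cf * (
                1.0 + cf_rsd_eff / 100.0 * cf_rng.standard_normal(cycles)
            )
        if (cf_draw <= 0).any():
            raise RuntimeError(
                "a perturbed calibration factor became non-positive; "
                "the CF RSD is too large for a relative-error model"
            )

        loc_dose = (pert @ avg - bg_draw[:, None]) / cf_draw[:, None]
        if clamp_negative:
            n_neg = int((loc_dose < 0).sum())
            if n_neg:
                np.maximum(loc_dose, 0.0, out=loc_dose)
            diagnostics["clamped_doses"][protocol] = n_neg

        ratio_draw = ratio * (1.0 + ratio_rsd / 100.0 * z_ratio)
        e = layout.e_scale * (loc_dose @ v) / ratio_draw
        if np.isnan(e).any():
            raise RuntimeError(
                f"NaN E samples in protocol {protocol!r}; check inputs and RSDs"
            )
        samples[protocol] = e

    summaries = (
        {p: summarize(samples[p], ci_level) for p in protocols}
        if cycles >= 2
        else {}
    )
    return SimulationResult(
        cycles=cycles,
        seed=seed,
        ci_level=ci_level,
        shared_cf=shared_cf,
        protocols=protocols,
        samples=samples,
        summaries=summaries,
        diagnostics=diagnostics,
    )


def compare_protocols(
    result: SimulationResult,
    protocol_a: str,
    protocol_b: str,
    alpha: float = 0.05,
) -> ComparisonSummary:
    """Paired (cycle-wise) difference E_a − E_b with a percentile CI.

    Because both protocols were computed inside the same cycles — sharing
    the CF draw — the difference distribution reflects only the RE that
    actually distinguishes the protocols. The ``significant`` flag is True
    when the (1−alpha) percentile CI excludes 0.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    for p in (protocol_a, protocol_b):
        if p not in result.samples:
            raise MissingDataError(
                f"protocol {p!r} was not simulated in this run"
            )
    diff = np.asarray(result.samples[protocol_a]) - np.asarray(
        result.samples[protocol_b]
    )
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    lo, hi = np.quantile(diff, [alpha / 2.0, 1.0 - alpha / 2.0])
    sign = np.sign(mean)
    agreement = float((np.sign(diff) == sign).mean()) if sign != 0 else 0.5
    return ComparisonSummary(
        protocol_a=protocol_a,
        protocol_b=protocol_b,
        mean_diff=mean,
        sd_diff=sd,
        ci_low=float(lo),
        ci_high=float(hi),
        alpha=alpha,
        sign_agreement=agreement,
        significant=bool(lo > 0.0 or hi < 0.0),
    )
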