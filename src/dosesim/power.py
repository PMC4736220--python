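"""Prospective design analysis: RSD of E and power under design variants.

The simulator can be pointed forwards: before running a phantom study,
generate synthetic experiments under a candidate design (number of
dosimeters per location, number of exposures per protocol), propagate the
known error components, and read off the RSD of E — or the power to
declare a stated true difference between two protocols significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ConfigurationError
from .mc import run_simulation
from .measurements import ExposureDesign
from .synth import SyntheticTruth, generate_experiment, scale_protocol


@dataclass(frozen=True)
class DesignVariant:
    """One candidate experimental design.

    Attributes
    ----------
    dosimeters_per_location
        TLDs per phantom location (the reference study used 2 and asked
        what 1 would have cost).
    exposures_per_protocol
        Exposures delivered per protocol; more exposures average down the
        generator fluctuation (RSD/√n) and raise the pulse counts.
    relative_difference_percent
        True relative E difference injected between the two compared
        protocols (0 = null hypothesis).
    alpha
        Significance level of the paired percentile-CI test.
    replicates
        Independent synthetic experiments simulated.
    cycles
        Monte Carlo cycles per experiment.
    """

    dosimeters_per_location: int = 2
    exposures_per_protocol: int = 50
    relative_difference_percent: float = 0.0
    alpha: float = 0.05
    replicates: int = 200
    cycles: int = 2000

    def __post_init__(self) -> None:
        if self.dosimeters_per_location < 1 or self.exposures_per_protocol < 1:
            raise ConfigurationError("design counts must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.replicates < 1 or self.cycles < 2:
            raise ConfigurationError("replicates >= 1 and cycles >= 2 required")
        if self.relative_difference_percent < 0:
            raise ConfigurationError("relative difference must be non-negative")


def apply_variant(truth: SyntheticTruth, variant: DesignVariant) -> SyntheticTruth:
    """Adapt a truth to a design variant.

    Changing the number of exposures scales the delivered protocol doses
    proportionally (each exposure adds the same dose), leaving E per
    single exposure unchanged; the dosimeter count per location is set
    directly.
    """
    scale = variant.exposures_per_protocol / truth.design.n_exposures
    doses = {
        p: {loc: d * scale for loc, d in dmap.items()}
        for p, dmap in truth.protocol_doses.items()
    }
    design = ExposureDesign(
        n_exposures=variant.exposures_per_protocol,
        exposure_s=truth.design.exposure_s,
        single_exposure_s=truth.design.single_exposure_s,
    )
    return replace(
        truth,
        protocol_doses=doses,
        design=design,
        dosimeters_per_location=variant.dosimeters_per_location,
    )


def estimate_rsd_for_design(
    truth: SyntheticTruth, variant: DesignVariant, seed: int | None = None
) -> float:
    """Expected RSD (%) of E under a design, averaged over replicates.

    Each replicate generates a fresh synthetic experiment under the
    variant's design, runs the Monte Carlo engine with the truth's own
    error model, and records the mean per-protocol RSD of E.
    """
    adapted = apply_variant(truth, variant)
    error_model = adapted.error_model()
    root = np.random.SeedSequence(seed)
    rsds = []
    for rep_ss in root.spawn(variant.replicates):
        gen_seed, mc_seed = (int(s.generate_state(1)[0] >> 1) for s in rep_ss.spawn(2))
        ms, _ = generate_experiment(adapted, seed=gen_seed)
        result = run_simulation(
            ms, adapted.layout, error_model, cycles=variant.cycles, seed=mc_seed
        )
        rsds.append(
            float(
                np.mean([result.summaries[p].rsd_percent for p in result.protocols])
            )
        )
    return float(np.mean(rsds))


def estimate_power(
    truth: SyntheticTruth,
    variant: DesignVariant,
    seed: int | None = None,
    protocols: tuple[str, str] | None = None,
) -> float:
    """Power to detect the variant's injected relative E difference.

    Two protocols are compared: the first keeps its true doses, the second
    is scaled by (1 + relative_difference/100). Each replicate generates a
    synthetic experiment, runs the shared-CF Monte Carlo, and applies the
    paired percentile-CI test; the returned power is the fraction of
    replicates declaring the difference significant. With a zero injected
    difference this estimates the type-I error rate, which should sit near
    alpha.
    """
    if variant.replicates < 20:
        warnings.warn(
            "fewer than 20 replicates: power estimate will be unstable",
            stacklevel=2,
        )
    if protocols is None:
        protocols = truth.protocols[:2]
    if len(protocols) != 2 or protocols[0] == protocols[1]:
        raise ConfigurationError("need two distinct protocols to compare")
    a, b = protocols

    adapted = apply_variant(truth, variant)
    # keep only the two compared protocols; the second takes the first's
    # true dose pattern so the injected relative difference IS the whole
    # true difference between them
    doses = {a: adapted.protocol_doses[a], b: dict(adapted.protocol_doses[a])}
    bg_mean = {p: adapted.background_mean_pulses[p] for p in (a, b)}
    bg_rsd = {p: adapted.background_rsd_percent[p] for p in (a, b)}
    adapted = replace(
        adapted,
        protocol_doses=doses,
        background_mean_pulses=bg_mean,
        background_rsd_percent=bg_rsd,
    )
    adapted = scale_protocol(
        adapted, b, 1.0 + variant.relative_difference_percent / 100.0
    )
    error_model = adapted.error_model()

    root = np.random.SeedSequence(seed)
    hits = 0
    for rep_ss in root.spawn(variant.replicates):
        gen_seed, mc_seed = (int(s.generate_state(1)[0] >> 1) for s in rep_ss.spawn(2))
        ms, _ = generate_experiment(adapted, seed=gen_seed)
        result = run_simulation(
            ms,
            adapted.layout,
            error_model,
            cycles=variant.cycles,
            seed=mc_seed,
            shared_cf=True,
        )
        if result.compare(a, b, alpha=variant.alpha).significant:
            hits += 1
    return hits / variant.replicates
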