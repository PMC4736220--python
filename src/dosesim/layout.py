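"""Phantom geometry: dosimeter locations, tissue mapping and ICRP weights.

An anthropomorphic phantom head carries thermoluminescent dosimeters (TLDs)
at named locations.  Each tissue of the ICRP effective-dose system is
associated with one or more locations (a location may feed several tissues,
e.g. bone surface and red bone marrow sampled at the same drill hole) and
with the fraction of that tissue lying inside the irradiated field.  The
effective dose is the ICRP-weighted sum of the tissue doses,

    E = sum_T  w_T * D_T,

with the radiation weighting factor for diagnostic X-rays equal to 1, so
absorbed dose (mGy) and equivalent dose (mSv) coincide numerically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .exceptions import ConfigurationError

#: ICRP publication-103 tissue weighting factors.  The full table sums to 1;
#: a layout restricted to head/neck tissues is a *partial* table and is
#: flagged as such (see :attr:`PhantomLayout.has_complete_weight_table`).
ICRP103_WEIGHTS: dict[str, float] = {
    "red-bone-marrow": 0.12,
    "colon": 0.12,
    "lung": 0.12,
    "stomach": 0.12,
    "breast": 0.12,
    "remainder": 0.12,
    "gonads": 0.08,
    "bladder": 0.04,
    "oesophagus": 0.04,
    "liver": 0.04,
    "thyroid": 0.04,
    "bone-surface": 0.01,
    "brain": 0.01,
    "salivary-glands": 0.01,
    "skin": 0.01,
}


@dataclass(frozen=True)
class TissueSite:
    """Where a tissue is sampled in the phantom and how much of it is in-field.

    Parameters
    ----------
    locations
        Dosimeter locations whose mean dose represents this tissue.
    fraction
        Irradiated fraction of the tissue, in [0, 1].  The tissue dose is
        ``fraction * mean(location doses)``.
    """

    locations: tuple[str, ...]
    fraction: float

    def __post_init__(self) -> None:
        if not self.locations:
            raise ConfigurationError("tissue mapped to zero locations")
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError(
                f"irradiated fraction {self.fraction} outside [0, 1]"
            )


@dataclass(frozen=True)
class PhantomLayout:
    """Dosimeter locations, tissue mapping and tissue weighting factors.

    Parameters
    ----------
    locations
        All dosimeter locations in the phantom.
    tissue_map
        Mapping tissue name -> :class:`TissueSite`.  Locations may be shared
        between tissues.
    tissue_weights
        ICRP weighting factor w_T per tissue.  Must cover every tissue in
        ``tissue_map``.
    e_scale
        Unit conversion applied to the weighted sum of tissue doses.  With
        tissue doses in mGy the weighted sum is numerically in mSv; the
        default 1000 reports E in µSv.
    """

    locations: tuple[str, ...]
    tissue_map: Mapping[str, TissueSite]
    tissue_weights: Mapping[str, float]
    e_scale: float = 1000.0

    def __post_init__(self) -> None:
        known = set(self.locations)
        if len(known) != len(self.locations):
            raise ConfigurationError("duplicate location identifiers")
        for tissue, site in self.tissue_map.items():
            missing = set(site.locations) - known
            if missing:
                raise ConfigurationError(
                    f"tissue {tissue!r} references unknown locations {sorted(missing)}"
                )
            if tissue not in self.tissue_weights:
                raise ConfigurationError(f"tissue {tissue!r} has no weighting factor")
        for tissue, w in self.tissue_weights.items():
            if w < 0:
                raise ConfigurationError(f"negative weight for tissue {tissue!r}")
        if self.e_scale <= 0:
            raise ConfigurationError("e_scale must be positive")

    @property
    def has_complete_weight_table(self) -> bool:
        """True when the weights sum to 1 (a full ICRP table).

        A head/neck layout normally carries only the tissues in the field,
        so a partial table (sum < 1) is valid; this flag lets callers insist
        on a complete table when they need one.
        """
        return abs(sum(self.tissue_weights.values()) - 1.0) < 1e-9

    def location_weight_vector(self) -> dict[str, float]:
        """Per-location coefficient of the effective dose.

        E is linear in the location doses; this returns ``v`` such that
        ``E = e_scale * sum_l v[l] * dose[l]``.  Used by the Monte Carlo
        engine to vectorise the weighted summation.
        """
        v = {loc: 0.0 for loc in self.locations}
        for tissue, site in self.tissue_map.items():
            w = self.tissue_weights[tissue]
            share = w * site.fraction / len(site.locations)
            for loc in site.locations:
                v[loc] += share
        return v


def illustrative_head_layout(e_scale: float = 1000.0) -> PhantomLayout:
    """An illustrative 25-location head/neck phantom layout.

    The tissue-location assignment and irradiated fractions below are
    *illustrative*: they have the structure of a lateral-cephalography
    phantom study (25 drill-hole locations, head/neck tissues with partial
    irradiated fractions, locations shared between bone surface and red
    bone marrow) but are not measurements of any specific phantom.
    Weighting factors are ICRP-103.
    """
    locations = tuple(f"L{i:02d}" for i in range(1, 26))
    tissue_map = {
        "brain": TissueSite(("L01", "L02", "L03"), 1.0),
        "salivary-glands": TissueSite(("L04", "L05", "L06"), 1.0),
        "thyroid": TissueSite(("L07", "L08"), 1.0),
        "oesophagus": TissueSite(("L09",), 0.10),
        "skin": TissueSite(("L10", "L11", "L12"), 0.05),
        # bone surface and red bone marrow share the calvarium/mandible holes
        "bone-surface": TissueSite(("L13", "L14", "L15", "L16"), 0.16),
        "red-bone-marrow": TissueSite(("L13", "L14", "L15", "L16"), 0.16),
        "remainder": TissueSite(
            ("L17", "L18", "L19", "L20", "L21", "L22", "L23", "L24", "L25"), 0.05
        ),
    }
    weights = {t: ICRP103_WEIGHTS[t] for t in tissue_map}
    return PhantomLayout(
        locations=locations,
        tissue_map=tissue_map,
        tissue_weights=weights,
        e_scale=e_scale,
    )
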