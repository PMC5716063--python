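"""Counts and lengths to abundance and biomass densities per survey cylinder.

Individual fish weight follows the allometric model W = a (cL)^b with W in
grams and L the recorded total length in cm; c is the species'
length-conversion factor mapping total length to the length form (fork or
standard) the a, b constants expect.  Densities are per-cylinder sums
normalized by the cylinder's plan area, under a configurable
observation-type filter (default: pool I and N, the routine density set).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_model import OBS_TYPES, SpeciesTrait

__all__ = [
    "ObsTypeFilter",
    "DENSITY_DEFAULT_FILTER",
    "CylinderGeometry",
    "DEFAULT_GEOMETRY",
    "MissingTraitError",
    "PresenceOnlyError",
    "SizeExceedsLmaxWarning",
    "fish_weight_g",
    "filter_observations",
    "cylinder_densities",
]


class MissingTraitError(KeyError):
    """Length-weight constants are unavailable for one or more species."""


class PresenceOnlyError(ValueError):
    """Presence-only (P) records were routed toward a density computation."""


class SizeExceedsLmaxWarning(UserWarning):
    """A recorded length exceeds the species' maximum length."""


@dataclass(frozen=True)
class ObsTypeFilter:
    """Subset of observation types retained for an analysis.

    The routine density filter pools I (instantaneous) and N
    (non-instantaneous).  P records are presence-only and must never reach
    a density computation.
    """

    included: frozenset[str] = frozenset("IN")

    def __post_init__(self) -> None:
        inc = frozenset(self.included)
        object.__setattr__(self, "included", inc)
        if not inc:
            raise ValueError("observation-type filter must be non-empty")
        unknown = inc - OBS_TYPES
        if unknown:
            raise ValueError(f"unknown observation types: {sorted(unknown)}")

    @classmethod
    def parse(cls, spec: str) -> "ObsTypeFilter":
        """Build from a comma- or plain-joined string such as ``"I,N"``."""
        return cls(frozenset(t.strip().upper() for t in spec.replace(",", " ").split()))

    def __str__(self) -> str:
        return ",".join(sorted(self.included))


DENSITY_DEFAULT_FILTER = ObsTypeFilter(frozenset("IN"))


@dataclass(frozen=True)
class CylinderGeometry:
    """Geometry of the paired stationary-point-count plots.

    Two divers survey adjacent cylinders of ``diameter`` m centred on the
    quarter points of a ``transect_length``-m line; plan area is
    pi (diameter/2)^2.
    """

    diameter_m: float = 15.0
    transect_length_m: float = 30.0

    def __post_init__(self) -> None:
        if self.diameter_m <= 0 or self.transect_length_m < self.diameter_m:
            raise ValueError("invalid cylinder geometry")

    @property
    def area_m2(self) -> float:
        return math.pi * (self.diameter_m / 2.0) ** 2

    @property
    def centre_marks_m(self) -> tuple[float, float]:
        r = self.diameter_m / 2.0
        return (r, self.transect_length_m - r)


DEFAULT_GEOMETRY = CylinderGeometry()


def fish_weight_g(length_cm: float, trait: SpeciesTrait, *,
                  warn_oversize: bool = True) -> float:
    """Weight in grams of one fish of recorded total length ``length_cm``.

    Applies the length conversion before exponentiation: W = a (c L)^b.
    A length above the species' lmax is still converted but raises a
    :class:`SizeExceedsLmaxWarning`.
    """
    if not length_cm > 0:
        raise ValueError(f"length must be positive, got {length_cm!r}")
    if warn_oversize and length_cm > trait.lmax:
        warnings.warn(
            f"size {length_cm} cm exceeds LMAX {trait.lmax} cm for "
            f"{trait.species}",
            SizeExceedsLmaxWarning,
            stacklevel=2,
        )
    return trait.lw_a * (trait.length_conversion_factor * length_cm) ** trait.lw_b


def _weights_vector(records: pd.DataFrame,
                    traits: Mapping[str, SpeciesTrait] | None) -> np.ndarray:
    """Per-row individual fish weight in grams (vectorized)."""
    if traits is not None:
        missing = sorted(set(records["species"]) - set(traits))
        if missing:
            raise MissingTraitError(
                f"no length-weight constants for species: {missing}")
        a = records["species"].map(lambda s: traits[s].lw_a).to_numpy(float)
        b = records["species"].map(lambda s: traits[s].lw_b).to_numpy(float)
        c = records["species"].map(
            lambda s: traits[s].length_conversion_factor).to_numpy(float)
    else:
        need = ("lw_a", "lw_b", "length_conversion_factor")
        if any(col not in records.columns for col in need):
            raise MissingTraitError(
                "records carry no trait columns and no trait table was given")
        bad = records.loc[records[list(need)].isna().any(axis=1), "species"]
        if len(bad):
            raise MissingTraitError(
                f"no length-weight constants for species: {sorted(bad.unique())}")
        a = records["lw_a"].to_numpy(float)
        b = records["lw_b"].to_numpy(float)
        c = records["length_conversion_factor"].to_numpy(float)
    length = records["size_tl_cm"].to_numpy(float)
    if np.any(length <= 0):
        raise ValueError("all SIZE_TL_CM values must be positive")
    return a * (c * length) ** b


def filter_observations(records: pd.DataFrame, obs_filter: ObsTypeFilter,
                        *, target: str = "density") -> pd.DataFrame:
    """Retain exactly the rows whose observation type is in the filter.

    With ``target="density"`` a filter containing P is rejected: presence
    records are lists of nearby species and carry no density information.
    ``target="presence"`` lifts that restriction.
    """
    if target == "density" and "P" in obs_filter.included:
        raise PresenceOnlyError("presence-only type in density filter")
    if target not in ("density", "presence"):
        raise ValueError(f"unknown filter target {target!r}")
    return records.loc[records["obs_type"].isin(sorted(obs_filter.included))]


def cylinder_densities(
    records: pd.DataFrame,
    geometry: CylinderGeometry = DEFAULT_GEOMETRY,
    obs_filter: ObsTypeFilter = DENSITY_DEFAULT_FILTER,
    traits: Mapping[str, SpeciesTrait] | None = None,
) -> pd.DataFrame:
    """Per-species abundance (fish m^-2) and biomass (g m^-2) densities of
    one survey cylinder.

    All rows must share a single REPLICATEID.  For each species,
    abundance_density = sum(count) / area and biomass_density =
    sum(count * W(size)) / area, summed over its size classes.  Trait
    constants come from ``traits`` if given, else from the rows' own
    LW columns; missing constants raise listing the species codes.
    """
    cols = ["replicateid", "species", "abundance_density", "biomass_density"]
    if len(records) == 0:
        return pd.DataFrame(columns=cols)
    reps = records["replicateid"].unique()
    if len(reps) != 1:
        raise ValueError(
            f"cylinder_densities expects one replicate, got {sorted(reps)}")
    kept = filter_observations(records, obs_filter)
    if len(kept) == 0:
        return pd.DataFrame(columns=cols)
    w = _weights_vector(kept, traits)
    count = kept["count"].to_numpy(float)
    per = pd.DataFrame({
        "species": kept["species"].to_numpy(),
        "n": count,
        "grams": count * w,
    }).groupby("species", as_index=False).sum()
    area = geometry.area_m2
    return pd.DataFrame({
        "replicateid": reps[0],
        "species": per["species"],
        "abundance_density": per["n"] / area,
        "biomass_density": per["grams"] / area,
    })[cols]
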