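"""Collapse diver/cylinder replicates into site-level sample units.

The two divers of an SPC pair survey adjacent cylinders simultaneously and
are not independent replicates: the site is the base sample unit.  Metrics
are therefore averaged within each SPC pair first and then across pairs
(most sites have a single pair, where this is the plain mean of the two
cylinders).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import complexity
from .biomass import (
    DEFAULT_GEOMETRY,
    DENSITY_DEFAULT_FILTER,
    CylinderGeometry,
    ObsTypeFilter,
    _weights_vector,
    filter_observations,
)
from .data_model import DEPTH_BINS, SpeciesTrait, classify_depth_bin

__all__ = [
    "CONSUMER_GROUP_COLUMNS",
    "METRIC_COLUMNS",
    "ReplicateSummary",
    "SiteSummary",
    "replicate_summaries",
    "summarize_replicate",
    "site_summaries",
    "summarize_site",
]

#: reporting partition of biomass by diet-based consumer group
CONSUMER_GROUPS = ("Primary Consumer", "Secondary Consumer", "Planktivore",
                   "Piscivore", "unknown")
CONSUMER_GROUP_COLUMNS = {
    "Primary Consumer": "biomass_primary_consumer",
    "Secondary Consumer": "biomass_secondary_consumer",
    "Planktivore": "biomass_planktivore",
    "Piscivore": "biomass_piscivore",
    "unknown": "biomass_unknown",
}

_BENTHIC = ("hard_coral", "ma", "cca", "sand", "other")
_SUBSTRATE = tuple(f"substrate_height_{b}" for b in (0, 20, 50, 100, 150))

#: Numeric metrics carried through the two-stage (pair, then site) mean.
METRIC_COLUMNS = (
    "biomass_total", "abundance_total",
    *CONSUMER_GROUP_COLUMNS.values(),
    "richness", *_BENTHIC, "mean_substrate_height_m", "max_height",
    "depth_m",
)

_META_FIRST = ("site", "region", "island", "latitude", "longitude",
               "reef_zone", "depth_bin", "obs_year", "habitat_code")


@dataclass
class ReplicateSummary:
    """One cylinder's metric vector (densities in g m^-2 / fish m^-2)."""

    sitevisitid: int
    replicateid: int
    rep: str
    diver: int
    metrics: dict[str, float] = field(default_factory=dict)


@dataclass
class SiteSummary:
    """One site's metric vector after pair-then-site averaging."""

    sitevisitid: int
    site: str
    reporting_unit: str
    reef_zone: str
    depth_bin: str
    metrics: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 0
    n_pairs: int = 0


def replicate_summaries(
    records: pd.DataFrame,
    geometry: CylinderGeometry = DEFAULT_GEOMETRY,
    obs_filter: ObsTypeFilter = DENSITY_DEFAULT_FILTER,
    traits: Mapping[str, SpeciesTrait] | None = None,
) -> pd.DataFrame:
    """One row per cylinder: total and per-consumer-group biomass density,
    abundance density, species richness, and the replicate's habitat fields.

    Richness counts distinct species among the rows passing the
    observation-type filter.  Species without a consumer group are summed
    into ``biomass_unknown`` with a warning.  Cylinders whose every row is
    filtered out keep zero densities.
    """
    if len(records) == 0:
        raise ValueError("no observation records supplied")
    meta_cols = [c for c in
                 ("sitevisitid", "replicateid", "rep", "diver", *_META_FIRST,
                  "depth_m", *_BENTHIC, *_SUBSTRATE, "max_height",
                  "visibility_m")
                 if c in records.columns]
    meta = records[meta_cols].drop_duplicates("replicateid").set_index(
        "replicateid")
    if meta.index.has_duplicates:
        raise ValueError("inconsistent per-replicate metadata")

    kept = filter_observations(records, obs_filter)
    area = geometry.area_m2
    if len(kept):
        w = _weights_vector(kept, traits)
        grams = kept["count"].to_numpy(float) * w
        group = kept["consumer_group"] if "consumer_group" in kept.columns \
            else pd.Series("unknown", index=kept.index)
        unknown = group.isna() | ~group.isin(CONSUMER_GROUPS[:4])
        if unknown.any():
            warnings.warn(
                "species with missing/unknown consumer group assigned to "
                f"'unknown': {sorted(kept.loc[unknown, 'species'].unique())}",
                stacklevel=2,
            )
            group = group.where(~unknown, "unknown")
        per = pd.DataFrame({
            "replicateid": kept["replicateid"].to_numpy(),
            "group": group.to_numpy(),
            "n": kept["count"].to_numpy(float),
            "grams": grams,
            "species": kept["species"].to_numpy(),
        })
        tot = per.groupby("replicateid").agg(
            abundance_total=("n", "sum"),
            biomass_total=("grams", "sum"),
            richness=("species", "nunique"),
        )
        tot[["abundance_total", "biomass_total"]] /= area
        bygroup = (per.groupby(["replicateid", "group"])["grams"].sum()
                   .unstack("group", fill_value=0.0) / area)
        bygroup = bygroup.rename(columns=CONSUMER_GROUP_COLUMNS)
    else:
        tot = pd.DataFrame(
            columns=["abundance_total", "biomass_total", "richness"])
        bygroup = pd.DataFrame()

    out = meta.join(tot).join(bygroup)
    for colname in ("abundance_total", "biomass_total", "richness",
                    *CONSUMER_GROUP_COLUMNS.values()):
        if colname not in out.columns:
            out[colname] = 0.0
        out[colname] = out[colname].astype(float).fillna(0.0)

    if all(c in out.columns for c in _SUBSTRATE):
        sub = out[list(_SUBSTRATE)]
        ok = sub.notna().all(axis=1) & sub.sum(axis=1).sub(100).abs().le(0.5)
        heights = np.full(len(out), np.nan)
        if ok.any():
            frac = sub[ok].to_numpy(float)
            heights[ok.to_numpy()] = (
                frac @ np.asarray(complexity.HEIGHT_BIN_MIDPOINTS_M)
                / frac.sum(axis=1))
        out["mean_substrate_height_m"] = heights
    else:
        out["mean_substrate_height_m"] = np.nan

    return out.reset_index()


def summarize_replicate(
    records: pd.DataFrame,
    geometry: CylinderGeometry = DEFAULT_GEOMETRY,
    obs_filter: ObsTypeFilter = DENSITY_DEFAULT_FILTER,
    traits: Mapping[str, SpeciesTrait] | None = None,
) -> ReplicateSummary:
    """Summarize the records of a single cylinder into a ReplicateSummary."""
    reps = records["replicateid"].unique()
    if len(reps) != 1:
        raise ValueError(f"expected one replicate, got {sorted(reps)}")
    row = replicate_summaries(records, geometry, obs_filter, traits).iloc[0]
    metric_names = [c for c in METRIC_COLUMNS if c in row.index]
    return ReplicateSummary(
        sitevisitid=int(row["sitevisitid"]),
        replicateid=int(row["replicateid"]),
        rep=str(row.get("rep", "A")),
        diver=int(row["diver"]),
        metrics={m: float(row[m]) for m in metric_names},
    )


def _pair_then_site_mean(reps: pd.DataFrame,
                         metric_cols: list[str]) -> pd.DataFrame:
    """Mean within each SPC pair, then across pairs, per sitevisitid.
    NaNs (e.g. missing benthic fields on one replicate) are skipped."""
    pair_means = reps.groupby(["sitevisitid", "rep"], dropna=False)[
        metric_cols].mean()
    return pair_means.groupby(level="sitevisitid").mean()


def site_summaries(
    replicates: pd.DataFrame,
    *,
    check_depth_bin: bool = True,
) -> pd.DataFrame:
    """One row per site: every metric averaged within pairs then across
    pairs, plus site metadata, replicate/pair counts, and a depth bin
    recomputed from the midpoint of the replicates' depth range.

    When the recomputed bin disagrees with the recorded label the recorded
    label is kept in ``depth_bin_recorded`` and a warning is emitted;
    ``depth_bin`` always carries the recomputed (analysis) label when depth
    is available.
    """
    reps = replicates.copy()
    if "rep" not in reps.columns:
        reps["rep"] = "A"
    reps["rep"] = reps["rep"].fillna("A")
    metric_cols = [c for c in METRIC_COLUMNS if c in reps.columns]
    out = _pair_then_site_mean(reps, metric_cols)

    counts = reps.groupby("sitevisitid").agg(
        n_replicates=("replicateid", "nunique"),
        n_pairs=("rep", "nunique"),
    )
    meta_cols = [c for c in _META_FIRST if c in reps.columns]
    meta = reps.groupby("sitevisitid")[meta_cols].first()
    out = meta.join(out).join(counts)

    if "depth_m" in reps.columns:
        span = reps.groupby("sitevisitid")["depth_m"].agg(["min", "max"])
        mid = ((span["min"] + span["max"]) / 2.0).clip(upper=30.0)
        ok = mid.notna() & (mid > 0)
        assigned = pd.Series(pd.NA, index=out.index, dtype="object")
        if ok.any():
            assigned[ok] = classify_depth_bin(mid[ok].to_numpy(float))
        if "depth_bin" in out.columns:
            out = out.rename(columns={"depth_bin": "depth_bin_recorded"})
            mismatch = assigned.notna() & out["depth_bin_recorded"].notna() \
                & (assigned != out["depth_bin_recorded"])
            if check_depth_bin and mismatch.any():
                warnings.warn(
                    f"{int(mismatch.sum())} site(s) whose recorded DEPTH_BIN "
                    "disagrees with the bin of the replicate depth midpoint",
                    stacklevel=2,
                )
            assigned = assigned.where(assigned.notna(),
                                      out["depth_bin_recorded"])
        out["depth_bin"] = assigned
    return out.reset_index()


def summarize_site(replicates: pd.DataFrame,
                   reporting_unit: str | None = None) -> SiteSummary:
    """Two-stage mean of the replicate summaries of a single site."""
    visits = replicates["sitevisitid"].unique()
    if len(visits) != 1:
        raise ValueError(
            f"replicates span multiple sitevisitids: {sorted(visits)}")
    row = site_summaries(replicates).iloc[0]
    metric_names = [c for c in METRIC_COLUMNS if c in row.index]
    unit = reporting_unit if reporting_unit is not None \
        else str(row.get("island", ""))
    return SiteSummary(
        sitevisitid=int(row["sitevisitid"]),
        site=str(row.get("site", "")),
        reporting_unit=unit,
        reef_zone=str(row.get("reef_zone", "")),
        depth_bin=str(row.get("depth_bin", "")),
        metrics={m: float(row[m]) for m in metric_names
                 if pd.notna(row[m])},
        n_replicates=int(row["n_replicates"]),
        n_pairs=int(row["n_pairs"]),
    )


def pooled_richness(records: pd.DataFrame,
                    obs_filter: ObsTypeFilter = DENSITY_DEFAULT_FILTER,
                    ) -> pd.Series:
    """Secondary richness metric: distinct species per site pooled over all
    of the site's cylinders (union, not the pair-averaged mean)."""
    kept = filter_observations(records, obs_filter)
    return kept.groupby("sitevisitid")["species"].nunique().rename(
        "richness_pooled")
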