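"""Design-based stratified estimation and survey-effort allocation.

Sites are drawn within strata defined by reporting unit (island, atoll,
pooled island group, or sector), reef zone, and depth bin.  Within a
stratum, the mean of site values Xi and its variance VARi = s2i/ni are
computed under simple random sampling (no finite-population correction).
Strata are pooled to the reporting unit with hard-bottom-area weights
wi = Ai / sum(Aj):

    X   = sum_i Xi  * wi
    VAR = sum_i VARi * wi^2

Survey effort is allocated across strata Neyman-style, proportional to
area times among-site standard deviation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import POOLED_REPORTING_UNITS, AreaTable, StratumKey

__all__ = [
    "STRATA_COLUMNS",
    "StratumEstimate",
    "DomainEstimate",
    "AllocationPlan",
    "VarianceUnestimableError",
    "assign_reporting_unit",
    "pool_depth_zones",
    "stratum_estimates",
    "compute_weights",
    "pool_mean",
    "pool_variance",
    "domain_estimate",
    "domain_estimates",
    "allocate_sites",
]

STRATA_COLUMNS: tuple[str, ...] = ("reporting_unit", "reef_zone", "depth_bin")


class VarianceUnestimableError(ValueError):
    """No stratum provides a variance estimate."""


@dataclass(frozen=True)
class StratumEstimate:
    key: StratumKey
    metric: str
    xi: float          # stratum mean of site values
    s2i: float | None  # unbiased among-site sample variance (None if n<2)
    vari: float | None  # variance of the stratum mean, s2i/ni
    ni: int


@dataclass
class DomainEstimate:
    """Area-weighted pooled estimate for one reporting unit and metric."""

    reporting_unit: str
    metric: str
    x: float
    var: float
    n_sites: int
    n_strata: int
    weights: dict[tuple, float] = field(default_factory=dict)
    imputed_strata: list[tuple] = field(default_factory=list)

    @property
    def se(self) -> float:
        return math.sqrt(self.var)

    def to_dict(self) -> dict:
        return {
            "reporting_unit": self.reporting_unit,
            "metric": self.metric,
            "mean": self.x,
            "variance": self.var,
            "se": self.se,
            "n_sites": self.n_sites,
            "n_strata": self.n_strata,
            "weights": {"/".join(map(str, k)): w
                        for k, w in self.weights.items()},
            "imputed_variance_strata": ["/".join(map(str, k))
                                        for k in self.imputed_strata],
        }


@dataclass
class AllocationPlan:
    """Number of sites to survey per stratum of one reporting unit."""

    reporting_unit: str
    target_total: int
    frame: pd.DataFrame  # strata columns + demand + nh

    def __post_init__(self) -> None:
        assert int(self.frame["nh"].sum()) == self.target_total


def assign_reporting_unit(
    site_frame: pd.DataFrame,
    pooled: Mapping[str, Sequence[str]] | None = None,
    island_column: str = "island",
) -> pd.DataFrame:
    """Add a ``reporting_unit`` column: the island name, with members of
    pooled units (e.g. Alamagan/Guguan/Sarigan -> AGS) mapped to the unit."""
    pooled = POOLED_REPORTING_UNITS if pooled is None else pooled
    member_to_unit = {m: u for u, members in pooled.items() for m in members}
    out = site_frame.copy()
    out["reporting_unit"] = out[island_column].map(
        lambda i: member_to_unit.get(i, i))
    return out


def pool_depth_zones(frame: pd.DataFrame,
                     zones: Iterable[str] = ("Backreef", "Lagoon"),
                     label: str = "all") -> pd.DataFrame:
    """Collapse depth bins to a single label for the given reef zones
    (sparsely replicated zones are sometimes pooled across depth before
    weighting).  Works on site frames and area tables alike."""
    zones = set(zones)
    out = frame.copy()
    mask = out["reef_zone"].isin(zones)
    out.loc[mask, "depth_bin"] = label
    if "area_ha" in out.columns:
        out = out.groupby(list(STRATA_COLUMNS), as_index=False)[
            "area_ha"].sum()
    return out


def stratum_estimates(
    sites: pd.DataFrame,
    metric: str,
    strata_columns: Sequence[str] = STRATA_COLUMNS,
) -> pd.DataFrame:
    """Per-stratum mean, sample variance, and variance of the mean.

    One row per sampled stratum with columns ``xi`` (mean of site values),
    ``s2i`` (n-1 denominator sample variance; NaN when ni < 2), ``vari``
    (= s2i/ni), and ``ni``.  Sites with a missing metric value are dropped
    with a warning.
    """
    if metric not in sites.columns:
        raise KeyError(f"metric {metric!r} not in site summaries")
    use = sites.loc[sites[metric].notna()]
    dropped = len(sites) - len(use)
    if dropped:
        warnings.warn(f"{dropped} site(s) with missing {metric!r} dropped",
                      stacklevel=2)
    if len(use) == 0:
        raise ValueError(f"no sites with metric {metric!r}")
    g = use.groupby(list(strata_columns))[metric]
    out = g.agg(xi="mean", s2i=lambda v: v.var(ddof=1), ni="count")
    out["vari"] = out["s2i"] / out["ni"]
    out["metric"] = metric
    return out.reset_index()[
        list(strata_columns) + ["metric", "xi", "s2i", "vari", "ni"]]


def compute_weights(
    area_table: AreaTable,
    sampled_strata: pd.DataFrame | Iterable[StratumKey],
) -> pd.DataFrame:
    """Stratum weights wi = Ai / sum(Aj) over each reporting unit's sampled
    strata.

    When some strata of a unit were not sampled, weights are renormalized
    over the sampled ones (the estimate then covers the sampled domain
    only).  A sampled stratum absent from the area table raises.
    """
    if isinstance(sampled_strata, pd.DataFrame):
        keys = sampled_strata[list(STRATA_COLUMNS)].drop_duplicates()
    else:
        keys = pd.DataFrame(
            [tuple(k) for k in sampled_strata], columns=list(STRATA_COLUMNS)
        ).drop_duplicates()
    merged = keys.merge(area_table.frame, on=list(STRATA_COLUMNS), how="left")
    missing = merged.loc[merged["area_ha"].isna()]
    if len(missing):
        names = [tuple(r) for r in
                 missing[list(STRATA_COLUMNS)].itertuples(index=False)]
        raise KeyError(f"sampled strata missing from area table: {names}")
    if (merged["area_ha"] <= 0).any():
        bad = merged.loc[merged["area_ha"] <= 0, list(STRATA_COLUMNS)]
        raise ValueError(
            "sampled strata must have positive area: "
            f"{[tuple(r) for r in bad.itertuples(index=False)]}")
    merged["wi"] = merged.groupby("reporting_unit")["area_ha"].transform(
        lambda a: a / a.sum())
    return merged


def pool_mean(xi: Sequence[float], wi: Sequence[float]) -> float:
    """Pooled mean X = sum(Xi * wi) across strata.  Weights must sum to 1."""
    x = np.asarray(xi, dtype=float)
    w = np.asarray(wi, dtype=float)
    if x.shape != w.shape:
        raise ValueError("strata/weights mismatch: different lengths")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
    return float(x @ w)


def pool_variance(
    vari: Sequence[float],
    wi: Sequence[float],
    *,
    single_site: str = "impute",
) -> tuple[float, list[int]]:
    """Pooled variance VAR = sum(VARi * wi^2) across strata.

    Strata with an inestimable VARi (single-site strata, NaN) are handled
    per ``single_site``: ``"impute"`` substitutes the mean VARi of the
    remaining strata (their indices are returned for flagging);
    ``"strict"`` treats them as contributing no variance term but still
    flags them.  If no stratum has an estimable variance, raises.
    """
    v = np.asarray(vari, dtype=float)
    w = np.asarray(wi, dtype=float)
    if v.shape != w.shape:
        raise ValueError("strata/weights mismatch: different lengths")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
    missing = ~np.isfinite(v)
    if missing.all():
        raise VarianceUnestimableError(
            "variance unestimable: every stratum has fewer than 2 sites")
    flagged = [int(i) for i in np.flatnonzero(missing)]
    if single_site == "impute":
        v = np.where(missing, v[~missing].mean(), v)
    elif single_site == "strict":
        v = np.where(missing, 0.0, v)
    else:
        raise ValueError(f"unknown single_site policy {single_site!r}")
    return float(v @ (w ** 2)), flagged


def domain_estimate(
    estimates: pd.DataFrame,
    weights: pd.DataFrame,
    *,
    single_site: str = "impute",
) -> DomainEstimate:
    """Pool the stratum estimates of a single reporting unit.

    ``estimates`` is the output of :func:`stratum_estimates` restricted to
    one reporting unit and metric; ``weights`` the matching rows of
    :func:`compute_weights`.  The weight table must cover exactly the
    strata present.
    """
    units = estimates["reporting_unit"].unique()
    if len(units) != 1:
        raise ValueError(f"estimates span several reporting units: {units}")
    metrics = estimates["metric"].unique()
    if len(metrics) != 1:
        raise ValueError(f"estimates span several metrics: {metrics}")
    merged = estimates.merge(weights[list(STRATA_COLUMNS) + ["wi"]],
                             on=list(STRATA_COLUMNS), how="outer",
                             indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", list(STRATA_COLUMNS)]
        raise ValueError(
            "weight/stratum mismatch: "
            f"{[tuple(r) for r in bad.itertuples(index=False)]}")
    x = pool_mean(merged["xi"], merged["wi"])
    var, flagged_idx = pool_variance(merged["vari"], merged["wi"],
                                     single_site=single_site)
    keys = [tuple(r) for r in
            merged[list(STRATA_COLUMNS)].itertuples(index=False)]
    return DomainEstimate(
        reporting_unit=str(units[0]),
        metric=str(metrics[0]),
        x=x,
        var=var,
        n_sites=int(merged["ni"].sum()),
        n_strata=len(merged),
        weights=dict(zip(keys, merged["wi"].astype(float))),
        imputed_strata=[keys[i] for i in flagged_idx],
    )


def domain_estimates(
    estimates: pd.DataFrame,
    area_table: AreaTable,
    *,
    single_site: str = "impute",
) -> list[DomainEstimate]:
    """Pool every (reporting unit, metric) present in a stratum-estimate
    frame, computing weights from the area table per unit."""
    out = []
    for (unit, metric), grp in estimates.groupby(["reporting_unit", "metric"]):
        w = compute_weights(area_table, grp)
        out.append(domain_estimate(grp, w, single_site=single_site))
    return out


def estimates_to_frame(domains: Iterable[DomainEstimate]) -> pd.DataFrame:
    rows = [{k: v for k, v in d.to_dict().items()
             if k not in ("weights", "imputed_variance_strata")}
            for d in domains]
    return pd.DataFrame(rows)


def estimates_to_json(domains: Iterable[DomainEstimate], path=None) -> str:
    text = json.dumps([d.to_dict() for d in domains], indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def allocate_sites(
    area_table: AreaTable,
    variance_table: Mapping[StratumKey, float] | pd.DataFrame,
    target_total: int,
    reporting_unit: str | None = None,
) -> AllocationPlan:
    """Neyman-style allocation of a reporting unit's survey effort.

    Demand per stratum h is A_h * s_h (area times among-site standard
    deviation of the target metric); integer site counts are obtained by
    largest-remainder rounding so they sum exactly to ``target_total``.
    Rounding ties are broken toward the larger area, then the
    lexicographically smaller stratum key.

    ``variance_table`` maps stratum keys to among-site variances (s2), or
    is a frame with the strata columns and an ``s2`` column.
    """
    frame = area_table.frame
    if reporting_unit is not None:
        frame = frame.loc[frame["reporting_unit"] == reporting_unit]
    units = frame["reporting_unit"].unique()
    if len(units) != 1:
        raise ValueError(
            "allocation is per reporting unit; pass reporting_unit= "
            f"(table covers {sorted(units)})")
    if isinstance(variance_table, pd.DataFrame):
        var_map = {
            StratumKey(*k): float(v) for *k, v in variance_table[
                list(STRATA_COLUMNS) + ["s2"]].itertuples(index=False)}
    else:
        var_map = {StratumKey(*k): float(v)
                   for k, v in variance_table.items()}

    rows = []
    for r in frame.itertuples(index=False):
        key = StratumKey(r.reporting_unit, r.reef_zone, r.depth_bin)
        s2 = var_map.get(key)
        if s2 is None:
            raise KeyError(f"no variance entry for stratum {tuple(key)}")
        if s2 < 0:
            raise ValueError(f"negative variance for stratum {tuple(key)}")
        rows.append((*key, float(r.area_ha), float(r.area_ha) * math.sqrt(s2)))
    alloc = pd.DataFrame(
        rows, columns=list(STRATA_COLUMNS) + ["area_ha", "demand"])
    total_demand = alloc["demand"].sum()
    if total_demand <= 0:
        raise ValueError("no stratum has positive area x sd demand")
    if target_total < 0:
        raise ValueError("target_total must be non-negative")

    exact = alloc["demand"] / total_demand * target_total
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = int(target_total - base.sum())
    # largest remainder; ties -> larger area, then lexicographic key
    order = sorted(
        alloc.index,
        key=lambda i: (-remainder[i], -alloc.loc[i, "area_ha"],
                       tuple(alloc.loc[i, list(STRATA_COLUMNS)])),
    )
    nh = base.copy()
    for i in order[:short]:
        nh[i] += 1
    alloc["nh"] = nh
    return AllocationPlan(
        reporting_unit=str(units[0]),
        target_total=int(target_total),
        frame=alloc,
    )
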