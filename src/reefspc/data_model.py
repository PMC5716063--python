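"""Observation-level schema for stationary-point-count (SPC) reef fish surveys.

One data row is one diver's count of one taxon at one estimated size inside
one 15-m survey cylinder, together with the benthic-habitat metadata shared
by every row of that cylinder.  This module reads and writes that CSV
dialect, validates record collections against the survey protocol's rules,
and provides the small classifiers the protocol defines (depth bins, DACOR
urchin-abundance bands, pooled reporting units).
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TABLE_COLUMNS",
    "MANDATORY_COLUMNS",
    "OBS_TYPES",
    "REEF_ZONES",
    "DEPTH_BINS",
    "HABITAT_CODES",
    "CURRENT_STRENGTHS",
    "DACOR_LEVELS",
    "SchemaError",
    "UnknownColumnWarning",
    "SpeciesTrait",
    "StratumKey",
    "AreaTable",
    "ValidationIssue",
    "ValidationReport",
    "read_spc_csv",
    "write_spc_csv",
    "validate",
    "classify_depth_bin",
    "classify_dacor",
    "expand_reporting_units",
    "species_traits_from_observations",
]

#: Canonical column order of the published survey file (upper-case headers).
TABLE_COLUMNS: tuple[str, ...] = (
    "REGION", "ISLAND", "SITE", "LATITUDE", "LONGITUDE", "REEF_ZONE",
    "DEPTH_BIN", "SITEVISITID", "DATE", "OBS_YEAR", "DIVER", "REPLICATEID",
    "REP", "DEPTH_M", "HARD_CORAL", "MA", "CCA", "SAND", "OTHER",
    "HABITAT_CODE", "CURRENT_STRENGTH", "VISIBILITY_M", "MIN_DEPTH_M",
    "MAX_DEPTH_M", "COMPLEXITY", "SUBSTRATE_HEIGHT_0", "SUBSTRATE_HEIGHT_20",
    "SUBSTRATE_HEIGHT_50", "SUBSTRATE_HEIGHT_100", "SUBSTRATE_HEIGHT_150",
    "MAX_HEIGHT", "URCHIN_DACOR", "BORING_URCHIN_DACOR", "SPECIES",
    "TAXONNAME", "COMMON_FAMILY", "FAMILY", "CONSUMER_GROUP", "LW_A", "LW_B",
    "LMAX", "LENGTH_CONVERSION_FACTOR", "COUNT", "SIZE_TL_CM", "OBS_TYPE",
)

MANDATORY_COLUMNS: tuple[str, ...] = (
    "SITEVISITID", "SITE", "REPLICATEID", "DIVER", "SPECIES", "COUNT",
    "SIZE_TL_CM", "OBS_TYPE",
)

#: I instantaneous, N non-instantaneous, F first seen 5-10 min,
#: T first seen 10-30 min, P present near the cylinder only.
OBS_TYPES: frozenset[str] = frozenset("INFTP")
#: Observation types only recorded from 2012 onwards.
POST_2012_OBS_TYPES: frozenset[str] = frozenset("FT")

REEF_ZONES: tuple[str, ...] = ("Forereef", "Backreef", "Lagoon", "Protected Slope")
DEPTH_BINS: tuple[str, ...] = ("shallow", "mid", "deep")
#: Depth-zone edges in meters: shallow [0, 6), mid [6, 18), deep [18, 30].
DEPTH_BIN_EDGES_M: tuple[float, float, float] = (6.0, 18.0, 30.0)

HABITAT_CODES: tuple[str, ...] = (
    "AGR", "APR", "APS", "MIX", "PAV", "PPR", "PSC", "ROB", "RRB", "SAG",
    "SCR", "UNK", "WAL",
)
CURRENT_STRENGTHS: tuple[str, ...] = ("None", "Slight", "Moderate", "High")
CONSUMER_GROUPS: tuple[str, ...] = (
    "Primary Consumer", "Secondary Consumer", "Planktivore", "Piscivore",
    "unknown",
)

DACOR_LEVELS: tuple[str, ...] = ("R", "O", "C", "A", "D")
#: Upper count bound (inclusive) of R, O, C, A; anything above the last is D.
#: Free urchins: R<5, O 6-20, C 21-50, A 51-100, D>100; count 5 falls in the
#: printed gap between R and O and is assigned to R (rarer class).  Boring
#: urchins: R<25, O 26-100, C 101-250, A 251-500, D>500; 25 likewise -> R.
DACOR_UPPER_BOUNDS: dict[str, tuple[int, int, int, int]] = {
    "free": (5, 20, 50, 100),
    "boring": (25, 100, 250, 500),
}

#: Routinely pooled statistical sampling/reporting units.
POOLED_REPORTING_UNITS: dict[str, tuple[str, ...]] = {
    "AGS": ("Alamagan", "Guguan", "Sarigan"),
}

#: Survey validity floors: counts are abandoned when horizontal visibility
#: is below 7.5 m (divers cannot see the cylinder edge) and cylinder centre
#: points shallower than 1.5 m are not surveyed.
VISIBILITY_FLOOR_M = 7.5
MIN_CENTRE_DEPTH_M = 1.5
MAX_SURVEY_DEPTH_M = 30.0
VISIBILITY_CAP_M = 30.0

_INT_COLUMNS = ("sitevisitid", "obs_year", "diver", "replicateid", "count",
                "complexity")
_FLOAT_COLUMNS = (
    "latitude", "longitude", "depth_m", "hard_coral", "ma", "cca", "sand",
    "other", "visibility_m", "min_depth_m", "max_depth_m",
    "substrate_height_0", "substrate_height_20", "substrate_height_50",
    "substrate_height_100", "substrate_height_150", "max_height", "lw_a",
    "lw_b", "lmax", "length_conversion_factor", "size_tl_cm",
)
_BENTHIC_COLUMNS = ("hard_coral", "ma", "cca", "sand", "other")
_SUBSTRATE_COLUMNS = tuple(f"substrate_height_{b}" for b in (0, 20, 50, 100, 150))


class SchemaError(ValueError):
    """The file does not conform to the published column schema."""


class UnknownColumnWarning(UserWarning):
    """A column outside the published schema was encountered (and kept)."""


@dataclass(frozen=True)
class SpeciesTrait:
    """Per-taxon constants for the allometric weight model W = a(cL)^b.

    ``lw_a`` (g cm^-b) and ``lw_b`` are the length-weight constants;
    ``length_conversion_factor`` (c) maps recorded total length to the
    length form (fork/standard) the constants expect; ``lmax`` is the
    species' maximum plausible length in cm.
    """

    species: str
    lw_a: float
    lw_b: float
    lmax: float
    length_conversion_factor: float = 1.0
    taxonname: str = ""
    family: str = ""
    common_family: str = ""
    consumer_group: str = "unknown"

    def __post_init__(self) -> None:
        if not self.lw_a > 0:
            raise ValueError(f"lw_a must be positive, got {self.lw_a}")
        if not 1.0 < self.lw_b < 5.0:
            raise ValueError(f"lw_b must lie in (1, 5), got {self.lw_b}")
        if not self.length_conversion_factor > 0:
            raise ValueError("length_conversion_factor must be positive")
        if not self.lmax > 0:
            raise ValueError(f"lmax must be positive, got {self.lmax}")


class StratumKey(tuple):
    """(reporting_unit, reef_zone, depth_bin) sampling-cell identifier."""

    __slots__ = ()

    def __new__(cls, reporting_unit: str, reef_zone: str, depth_bin: str):
        return super().__new__(cls, (reporting_unit, reef_zone, depth_bin))

    @property
    def reporting_unit(self) -> str:
        return self[0]

    @property
    def reef_zone(self) -> str:
        return self[1]

    @property
    def depth_bin(self) -> str:
        return self[2]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"StratumKey({self[0]!r}, {self[1]!r}, {self[2]!r})"


@dataclass
class AreaTable:
    """Hard-bottom area (hectares, <30 m) of each sampling stratum.

    Backed by a frame with columns ``reporting_unit, reef_zone, depth_bin,
    area_ha``.  ``depth_bin`` may be the literal ``"all"`` for entries where
    depth zones are pooled.
    """

    frame: pd.DataFrame

    COLUMNS = ("reporting_unit", "reef_zone", "depth_bin", "area_ha")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"area table missing columns: {missing}")
        self.frame = self.frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        self.frame["area_ha"] = pd.to_numeric(self.frame["area_ha"])
        if (self.frame["area_ha"] < 0).any():
            raise ValueError("stratum areas must be non-negative")
        per_unit = self.frame.groupby("reporting_unit")["area_ha"].max()
        bad = per_unit[per_unit <= 0]
        if len(bad):
            raise ValueError(
                "reporting units without any positive-area stratum: "
                f"{sorted(bad.index)}"
            )

    @classmethod
    def from_csv(cls, path) -> "AreaTable":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_mapping(cls, areas: Mapping[StratumKey, float]) -> "AreaTable":
        rows = [(k.reporting_unit, k.reef_zone, k.depth_bin, a)
                for k, a in areas.items()]
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    def area(self, key: StratumKey) -> float:
        f = self.frame
        m = (
            (f["reporting_unit"] == key.reporting_unit)
            & (f["reef_zone"] == key.reef_zone)
            & (f["depth_bin"] == key.depth_bin)
        )
        if not m.any():
            raise KeyError(f"stratum {tuple(key)} not in area table")
        return float(f.loc[m, "area_ha"].sum())

    @property
    def reporting_units(self) -> list[str]:
        return sorted(self.frame["reporting_unit"].unique())

    def keys(self) -> list[StratumKey]:
        return [StratumKey(r, z, d) for r, z, d in
                self.frame[["reporting_unit", "reef_zone", "depth_bin"]]
                .itertuples(index=False)]


@dataclass(frozen=True)
class ValidationIssue:
    row: int
    rule: str
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    """Outcome of protocol validation over an observation collection.

    Rows carrying at least one ``error`` issue are excluded from analysis
    sets via :meth:`passing`; warnings are informational.
    """

    issues: list[ValidationIssue] = field(default_factory=list)
    n_records: int = 0

    @property
    def counts(self) -> dict[str, int]:
        return dict(Counter(i.rule for i in self.issues))

    @property
    def n_errors(self) -> int:
        return sum(1 for i in self.issues if i.severity == "error")

    @property
    def n_warnings(self) -> int:
        return sum(1 for i in self.issues if i.severity == "warning")

    @property
    def has_errors(self) -> bool:
        return self.n_errors > 0

    @property
    def error_rows(self) -> set[int]:
        return {i.row for i in self.issues if i.severity == "error"}

    def passing(self, records: pd.DataFrame) -> pd.DataFrame:
        """Records with no error-severity issue (the analysis set)."""
        return records.loc[~records.index.isin(self.error_rows)]

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_errors": self.n_errors,
            "n_warnings": self.n_warnings,
            "counts_by_rule": self.counts,
            "issues": [vars(i) for i in self.issues],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        lines = [
            f"{self.n_records} records checked: "
            f"{self.n_errors} errors, {self.n_warnings} warnings"
        ]
        for rule, n in sorted(self.counts.items()):
            lines.append(f"  {rule}: {n}")
        for i in self.issues[:200]:
            lines.append(f"  row {i.row} [{i.severity}] {i.rule}: {i.message}")
        if len(self.issues) > 200:
            lines.append(f"  ... {len(self.issues) - 200} further issues")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# reading / writing the published CSV dialect


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    for col in _INT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
    for col in _FLOAT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    return df


def read_spc_csv(path) -> pd.DataFrame:
    """Read an observation file in the published comma-separated dialect.

    Column headers are matched case-insensitively against the schema.
    Per the dialect, the empty string (and only the empty string) denotes
    a null — the literal current-strength value "None" is data.  Unknown
    columns are kept and reported via :class:`UnknownColumnWarning`; a
    missing mandatory column raises :class:`SchemaError` naming it.

    Returns a frame with lower-cased canonical column names, one row per
    observation record.
    """
    header = pd.read_csv(path, nrows=0)
    upper = {c.strip().upper(): c for c in header.columns}
    missing = [c for c in MANDATORY_COLUMNS if c not in upper]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    unknown = [c for c in upper if c not in TABLE_COLUMNS]
    if unknown:
        warnings.warn(
            f"columns outside the published schema kept as-is: {unknown}",
            UnknownColumnWarning,
            stacklevel=2,
        )
    df = pd.read_csv(path, skip_blank_lines=True, keep_default_na=False,
                     na_values=[""], float_precision="round_trip")
    df.columns = [c.strip().upper() for c in df.columns]
    known = [c for c in TABLE_COLUMNS if c in df.columns]
    df = df[known + [c for c in df.columns if c not in TABLE_COLUMNS]]
    df.columns = [c.lower() for c in df.columns]
    return _coerce_types(df)


def write_spc_csv(records: pd.DataFrame, path) -> None:
    """Write records back to the published dialect (upper-case headers,
    empty string for nulls, ISO-8601 dates)."""
    out = records.copy()
    if "date" in out.columns and np.issubdtype(out["date"].dtype, np.datetime64):
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    ordered = [c.lower() for c in TABLE_COLUMNS if c.lower() in out.columns]
    extra = [c for c in out.columns if c not in ordered]
    out = out[ordered + extra]
    out.columns = [c.upper() for c in out.columns]
    out.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# classifiers


def classify_depth_bin(depth_m):
    """Assign the depth zone of a survey depth in meters.

    Zones are shallow [0, 6), mid [6, 18), deep [18, 30]: lower-closed,
    upper-open, with the deepest bin closed at the 30-m survey limit.
    Accepts a scalar or array; raises for depths outside (0, 30].
    """
    arr = np.asarray(depth_m, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > MAX_SURVEY_DEPTH_M):
        raise ValueError(
            f"depth must lie in (0, {MAX_SURVEY_DEPTH_M}] m, got {depth_m!r}"
        )
    idx = np.searchsorted(DEPTH_BIN_EDGES_M[:2], arr, side="right")
    out = np.asarray(DEPTH_BINS, dtype=object)[idx]
    if np.isscalar(depth_m) or arr.ndim == 0:
        return str(out if arr.ndim == 0 else out[()])
    return out


def classify_dacor(count: int, category: str = "free",
                   bounds: Mapping[str, Sequence[int]] | None = None) -> str:
    """Map an urchin count to its DACOR abundance letter.

    ``category`` selects the free-urchin or boring-urchin band table;
    custom inclusive upper bounds for (R, O, C, A) may be supplied.
    """
    if count < 0 or int(count) != count:
        raise ValueError(f"count must be a non-negative integer, got {count!r}")
    table = dict(DACOR_UPPER_BOUNDS)
    if bounds:
        table.update(bounds)
    if category not in table:
        raise ValueError(f"unknown urchin category {category!r}")
    for letter, upper in zip(DACOR_LEVELS, table[category]):
        if count <= upper:
            return letter
    return "D"


def expand_reporting_units(
    units: Iterable[str],
    pooled: Mapping[str, Sequence[str]] | None = None,
) -> list[str]:
    """Replace pooled reporting units (e.g. AGS) by their member islands,
    preserving order; all other names pass through unchanged."""
    pooled = POOLED_REPORTING_UNITS if pooled is None else pooled
    out: list[str] = []
    for u in units:
        out.extend(pooled.get(u, (u,)))
    return out


def species_traits_from_observations(records: pd.DataFrame) -> dict[str, SpeciesTrait]:
    """Extract one SpeciesTrait per species code from the trait columns
    carried on observation rows.  Conflicting constants for one code raise."""
    cols = ["species", "lw_a", "lw_b", "lmax", "length_conversion_factor",
            "taxonname", "family", "common_family", "consumer_group"]
    have = [c for c in cols if c in records.columns]
    sub = records[have].drop_duplicates()
    dup = sub["species"][sub["species"].duplicated()]
    if len(dup):
        raise ValueError(
            f"conflicting trait values for species: {sorted(dup.unique())}"
        )
    traits = {}
    for row in sub.itertuples(index=False):
        d = row._asdict()
        traits[d["species"]] = SpeciesTrait(
            species=d["species"],
            lw_a=float(d["lw_a"]),
            lw_b=float(d["lw_b"]),
            lmax=float(d["lmax"]),
            length_conversion_factor=float(d.get("length_conversion_factor", 1.0)),
            taxonname=str(d.get("taxonname", "")),
            family=str(d.get("family", "")),
            common_family=str(d.get("common_family", "")),
            consumer_group=str(d.get("consumer_group", "unknown")),
        )
    return traits


# ---------------------------------------------------------------------------
# validation


def _add(issues, rows, rule, severity, message):
    for r in rows:
        issues.append(ValidationIssue(int(r), rule, severity, message))


def validate(
    records: pd.DataFrame,
    *,
    visibility_floor_m: float = VISIBILITY_FLOOR_M,
    min_centre_depth_m: float = MIN_CENTRE_DEPTH_M,
) -> ValidationReport:
    """Check every record against the survey protocol's rules.

    Error-severity rules exclude a record from analysis sets (invalid
    observation type or enumerations, non-positive counts or sizes, depths
    outside the survey domain, visibility below the 7.5-m survey floor,
    cylinder centre shallower than 1.5 m, cover or substrate-height
    percentages not summing to 100).  A depth-bin label that disagrees with
    the depth classifier, or an unknown habitat code, is a warning.
    """
    issues: list[ValidationIssue] = []
    df = records

    def col(name):
        return df[name] if name in df.columns else pd.Series(
            pd.NA, index=df.index, dtype="object")

    obs_type = col("obs_type")
    bad = df.index[obs_type.notna() & ~obs_type.isin(list(OBS_TYPES))]
    _add(issues, bad, "obs_type_invalid", "error",
         "OBS_TYPE not one of I,N,F,T,P")

    if "obs_year" in df.columns:
        year = df["obs_year"]
        bad = df.index[obs_type.isin(list(POST_2012_OBS_TYPES))
                       & year.notna() & (year < 2012)]
        _add(issues, bad, "obs_type_pre2012", "error",
             "F/T observation types only recorded from 2012 onwards")

    count = col("count")
    bad = df.index[count.notna() & (count < 1)]
    _add(issues, bad, "count_positive", "error", "COUNT must be >= 1")

    size = col("size_tl_cm")
    bad = df.index[size.notna() & (size <= 0)]
    _add(issues, bad, "size_positive", "error", "SIZE_TL_CM must be > 0")

    depth = col("depth_m")
    bad = df.index[depth.notna()
                   & ((depth <= 0) | (depth > MAX_SURVEY_DEPTH_M))]
    _add(issues, bad, "depth_domain", "error",
         f"DEPTH_M outside survey domain (0, {MAX_SURVEY_DEPTH_M}] m")
    bad = df.index[depth.notna() & (depth > 0) & (depth < min_centre_depth_m)]
    _add(issues, bad, "centre_depth_floor", "error",
         f"cylinder centre shallower than {min_centre_depth_m} m is not surveyed")

    vis = col("visibility_m")
    bad = df.index[vis.notna() & (vis < visibility_floor_m) & (vis > 0)]
    _add(issues, bad, "visibility_floor", "error",
         f"below visibility floor ({visibility_floor_m} m)")
    bad = df.index[vis.notna() & ((vis <= 0) | (vis > VISIBILITY_CAP_M))]
    _add(issues, bad, "visibility_range", "error",
         f"VISIBILITY_M must lie in (0, {VISIBILITY_CAP_M}] m")

    if all(c in df.columns for c in _BENTHIC_COLUMNS):
        ben = df[list(_BENTHIC_COLUMNS)]
        present = ben.notna().all(axis=1)
        total = ben.sum(axis=1)
        bad = df.index[present & (total - 100.0).abs().gt(0.5)]
        _add(issues, bad, "benthic_cover_sum", "error",
             "benthic cover percentages must sum to 100 +/- 0.5")

    if all(c in df.columns for c in _SUBSTRATE_COLUMNS):
        sub = df[list(_SUBSTRATE_COLUMNS)]
        present = sub.notna().all(axis=1)
        total = sub.sum(axis=1)
        bad = df.index[present & (total - 100.0).abs().gt(0.5)]
        _add(issues, bad, "substrate_height_sum", "error",
             "substrate-height percentages must sum to 100 +/- 0.5")

    for name, values in (("reef_zone", REEF_ZONES), ("depth_bin", DEPTH_BINS)):
        s = col(name)
        bad = df.index[s.notna() & ~s.isin(values)]
        _add(issues, bad, f"{name}_invalid", "error",
             f"{name.upper()} not in {values}")

    s = col("current_strength")
    bad = df.index[s.notna() & ~s.isin(CURRENT_STRENGTHS)]
    _add(issues, bad, "current_strength_invalid", "error",
         f"CURRENT_STRENGTH not in {CURRENT_STRENGTHS}")

    s = col("habitat_code")
    bad = df.index[s.notna() & ~s.isin(HABITAT_CODES)]
    _add(issues, bad, "habitat_code_unknown", "warning",
         "HABITAT_CODE outside the published enumeration")

    for name in ("urchin_dacor", "boring_urchin_dacor"):
        s = col(name)
        bad = df.index[s.notna() & ~s.isin(DACOR_LEVELS)]
        _add(issues, bad, f"{name}_invalid", "error",
             f"{name.upper()} not a DACOR letter")

    s = col("complexity")
    bad = df.index[s.notna() & (~s.isin(range(1, 7)))]
    _add(issues, bad, "complexity_range", "error",
         "COMPLEXITY must be an integer 1-6")

    # cross-check recorded depth-bin label against the classifier
    if "depth_bin" in df.columns and "depth_m" in df.columns:
        ok = depth.notna() & (depth > 0) & (depth <= MAX_SURVEY_DEPTH_M) \
            & df["depth_bin"].isin(DEPTH_BINS)
        if ok.any():
            expect = classify_depth_bin(depth[ok].astype(float).to_numpy())
            mism = df.index[ok][np.asarray(expect) != df.loc[ok, "depth_bin"].to_numpy()]
            _add(issues, mism, "depth_bin_mismatch", "warning",
                 "DEPTH_BIN label disagrees with depth classifier")

    issues.sort(key=lambda i: (i.row, i.rule))
    return ValidationReport(issues=issues, n_records=len(df))
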