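"""Schema reading/writing, protocol validation, and the small classifiers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reefspc.data_model import (
    DACOR_LEVELS,
    OBS_TYPES,
    SchemaError,
    UnknownColumnWarning,
    classify_dacor,
    classify_depth_bin,
    expand_reporting_units,
    read_spc_csv,
    species_traits_from_observations,
    validate,
    write_spc_csv,
)


# ---------------------------------------------------------------------------
# reading and writing


def test_header_only_file_yields_empty_collection(tmp_path, make_obs):
    path = tmp_path / "empty.csv"
    write_spc_csv(make_obs([]).iloc[:0], path)
    df = read_spc_csv(path)
    assert len(df) == 0


def test_round_trip_types_and_values(tmp_path, make_obs):
    df = make_obs([{"obs_type": "I", "count": 3, "size_tl_cm": 12.0}])
    path = tmp_path / "one.csv"
    write_spc_csv(df, path)
    back = read_spc_csv(path)
    assert back.loc[0, "count"] == 3
    assert back.loc[0, "size_tl_cm"] == 12.0
    assert back.loc[0, "obs_type"] == "I"
    assert str(back.loc[0, "date"].date()) == "2015-05-04"


def test_round_trip_is_byte_identical(tmp_path, make_obs):
    df = make_obs([
        {"count": 2, "size_tl_cm": 17.0, "lw_a": 0.0123456789012345},
        {"species": "EFGH", "current_strength": "None",
         "visibility_m": None},
    ])
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    write_spc_csv(df, a)
    write_spc_csv(read_spc_csv(a), b)
    assert a.read_bytes() == b.read_bytes()


def test_literal_none_current_strength_is_not_null(tmp_path, make_obs):
    df = make_obs([{"current_strength": "None"}])
    path = tmp_path / "n.csv"
    write_spc_csv(df, path)
    back = read_spc_csv(path)
    assert back.loc[0, "current_strength"] == "None"


def test_missing_mandatory_column_raises_naming_it(tmp_path, make_obs):
    df = make_obs([{}]).drop(columns=["obs_type"])
    path = tmp_path / "bad.csv"
    df.columns = [c.upper() for c in df.columns]
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="OBS_TYPE"):
        read_spc_csv(path)


def test_unknown_column_kept_with_warning(tmp_path, make_obs):
    df = make_obs([{}])
    df["mystery"] = 1
    path = tmp_path / "extra.csv"
    df.columns = [c.upper() for c in df.columns]
    df.to_csv(path, index=False)
    with pytest.warns(UnknownColumnWarning, match="MYSTERY"):
        back = read_spc_csv(path)
    assert "mystery" in back.columns


def test_unlisted_obs_type_parses_but_fails_validation(tmp_path, make_obs):
    df = make_obs([{"obs_type": "Q"}])
    path = tmp_path / "q.csv"
    write_spc_csv(df, path)
    back = read_spc_csv(path)
    assert back.loc[0, "obs_type"] == "Q"
    assert "Q" not in OBS_TYPES and len(OBS_TYPES) == 5
    report = validate(back)
    assert "obs_type_invalid" in report.counts
    assert 0 in report.error_rows


# ---------------------------------------------------------------------------
# depth-bin classifier


@pytest.mark.parametrize("depth, expected", [
    (0.1, "shallow"), (3.0, "shallow"), (5.9, "shallow"),
    (6.0, "mid"), (12.0, "mid"), (17.9, "mid"),
    (18.0, "deep"), (29.9, "deep"), (30.0, "deep"),
])
def test_depth_bin_boundaries(depth, expected):
    assert classify_depth_bin(depth) == expected


@pytest.mark.parametrize("depth", [0.0, -1.0, 30.1, float("nan")])
def test_depth_bin_rejects_out_of_domain(depth):
    with pytest.raises(ValueError):
        classify_depth_bin(depth)


@given(st.floats(min_value=0.01, max_value=30.0),
       st.floats(min_value=0.01, max_value=30.0))
def test_depth_bin_is_monotone_step_function(d1, d2):
    order = {"shallow": 0, "mid": 1, "deep": 2}
    lo, hi = sorted((d1, d2))
    assert order[classify_depth_bin(lo)] <= order[classify_depth_bin(hi)]


# ---------------------------------------------------------------------------
# DACOR classifier


@pytest.mark.parametrize("count, category, expected", [
    (0, "free", "R"), (5, "free", "R"), (6, "free", "O"), (20, "free", "O"),
    (21, "free", "C"), (35, "free", "C"), (50, "free", "C"),
    (51, "free", "A"), (100, "free", "A"), (101, "free", "D"),
    (0, "boring", "R"), (25, "boring", "R"), (26, "boring", "O"),
    (100, "boring", "O"), (101, "boring", "C"), (250, "boring", "C"),
    (251, "boring", "A"), (500, "boring", "A"), (501, "boring", "D"),
])
def test_dacor_bands(count, category, expected):
    assert classify_dacor(count, category) == expected


def test_dacor_rejects_bad_inputs():
    with pytest.raises(ValueError):
        classify_dacor(-1, "free")
    with pytest.raises(ValueError):
        classify_dacor(10, "pelagic")


@given(st.integers(min_value=0, max_value=1000),
       st.sampled_from(["free", "boring"]))
def test_dacor_total_and_monotone(count, category):
    """Every non-negative count maps to exactly one letter, and the letter
    index never decreases with the count."""
    letter = classify_dacor(count, category)
    assert letter in DACOR_LEVELS
    if count > 0:
        prev = classify_dacor(count - 1, category)
        assert DACOR_LEVELS.index(prev) <= DACOR_LEVELS.index(letter)


# ---------------------------------------------------------------------------
# reporting units


def test_expand_reporting_units_passthrough_and_pooling():
    assert expand_reporting_units(["Guam"]) == ["Guam"]
    assert expand_reporting_units(["AGS"]) == ["Alamagan", "Guguan",
                                               "Sarigan"]
    assert expand_reporting_units(["Rota", "AGS", "Tinian"]) == [
        "Rota", "Alamagan", "Guguan", "Sarigan", "Tinian"]


# ---------------------------------------------------------------------------
# validation rules


def test_visibility_floor_is_strict(make_obs):
    df = make_obs([{"visibility_m": 5.0}, {"visibility_m": 7.5},
                   {"visibility_m": 7.4}, {"visibility_m": None}])
    report = validate(df)
    flagged = {i.row for i in report.issues if i.rule == "visibility_floor"}
    assert flagged == {0, 2}
    assert "below visibility floor" in [
        i.message for i in report.issues if i.rule == "visibility_floor"][0]


def test_centre_depth_floor(make_obs):
    df = make_obs([{"depth_m": 1.0, "depth_bin": "shallow"},
                   {"depth_m": 1.5, "depth_bin": "shallow"},
                   {"depth_m": 31.0, "depth_bin": "deep"}])
    report = validate(df)
    assert {i.row for i in report.issues
            if i.rule == "centre_depth_floor"} == {0}
    assert {i.row for i in report.issues if i.rule == "depth_domain"} == {2}


def test_depth_bin_label_crosscheck_is_warning(make_obs):
    df = make_obs([{"depth_m": 12.0, "depth_bin": "mid"},
                   {"depth_m": 12.0, "depth_bin": "shallow"}])
    report = validate(df)
    mism = [i for i in report.issues if i.rule == "depth_bin_mismatch"]
    assert [i.row for i in mism] == [1]
    assert all(i.severity == "warning" for i in mism)
    assert 1 not in report.error_rows


def test_ft_types_require_2012_onwards(make_obs):
    df = make_obs([{"obs_type": "F", "obs_year": 2011},
                   {"obs_type": "F", "obs_year": 2012},
                   {"obs_type": "T", "obs_year": 2013}])
    report = validate(df)
    assert {i.row for i in report.issues
            if i.rule == "obs_type_pre2012"} == {0}


def test_cover_and_height_sums(make_obs):
    df = make_obs([
        {"hard_coral": 90.0},                      # covers sum to 160
        {"substrate_height_150": 30.0},            # heights sum to 125
        {},                                        # both fine
        {"hard_coral": None},                      # partial: skipped
    ])
    report = validate(df)
    assert {i.row for i in report.issues
            if i.rule == "benthic_cover_sum"} == {0}
    assert {i.row for i in report.issues
            if i.rule == "substrate_height_sum"} == {1}


def test_error_rows_are_excluded_from_analysis_set(make_obs):
    df = make_obs([{"visibility_m": 5.0}, {}])
    report = validate(df)
    kept = report.passing(df)
    assert list(kept.index) == [1]
    assert report.has_errors and report.n_records == 2


def test_report_serializes(make_obs, tmp_path):
    report = validate(make_obs([{"count": 0}]))
    text = report.to_json(tmp_path / "r.json")
    assert "count_positive" in text
    assert "count_positive" in report.to_text()


def _oracle_error_rows(df) -> set:
    """Independent row-by-row rule check (plain Python, no vectorization)."""
    bad = set()
    for idx, row in df.iterrows():
        def isnum(v):
            return v is not None and not pd.isna(v)
        if row["obs_type"] not in set("INFTP"):
            bad.add(idx)
        if isnum(row["count"]) and row["count"] < 1:
            bad.add(idx)
        if isnum(row["size_tl_cm"]) and row["size_tl_cm"] <= 0:
            bad.add(idx)
        if isnum(row["depth_m"]) and not (1.5 <= row["depth_m"] <= 30):
            bad.add(idx)
        if isnum(row["visibility_m"]) and not (7.5 <= row["visibility_m"] <= 30):
            bad.add(idx)
        covers = [row[c] for c in ("hard_coral", "ma", "cca", "sand", "other")]
        if all(isnum(c) for c in covers) and abs(sum(covers) - 100) > 0.5:
            bad.add(idx)
        if row["obs_type"] in ("F", "T") and isnum(row["obs_year"]) \
                and row["obs_year"] < 2012:
            bad.add(idx)
    return bad


def test_validate_matches_bruteforce_oracle(make_obs):
    """Randomly corrupted fixtures: the vectorized validator must flag
    exactly the rows a plain row-by-row rule check flags."""
    rng = np.random.default_rng(5)
    rows = []
    for _ in range(120):
        r = {}
        if rng.random() < 0.15:
            r["obs_type"] = str(rng.choice(list("INFTPQZ")))
        if rng.random() < 0.15:
            r["count"] = int(rng.integers(-1, 4))
        if rng.random() < 0.15:
            r["size_tl_cm"] = float(rng.choice([-3.0, 0.0, 12.0]))
        if rng.random() < 0.15:
            r["visibility_m"] = float(rng.uniform(3, 35))
        if rng.random() < 0.15:
            r["depth_m"] = float(rng.uniform(0.5, 33))
            r["depth_bin"] = "mid"
        if rng.random() < 0.15:
            r["hard_coral"] = float(rng.uniform(0, 120))
        if rng.random() < 0.15:
            r["obs_year"] = int(rng.choice([2010, 2011, 2014]))
        rows.append(r)
    df = make_obs(rows)
    report = validate(df)
    # ignore the depth-bin label warning; compare error rows only
    assert report.error_rows == _oracle_error_rows(df)


def test_species_traits_extraction(make_obs):
    df = make_obs([{"species": "ABCD"}, {"species": "EFGH", "lw_a": 0.02}])
    traits = species_traits_from_observations(df)
    assert set(traits) == {"ABCD", "EFGH"}
    assert traits["EFGH"].lw_a == 0.02
    conflicted = make_obs([{"species": "ABCD"},
                           {"species": "ABCD", "lw_b": 2.9}])
    with pytest.raises(ValueError, match="ABCD"):
        species_traits_from_observations(conflicted)
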