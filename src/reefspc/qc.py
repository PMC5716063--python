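"""Observer-quality diagnostics for paired-diver visual surveys.

Because the two divers of an SPC pair survey adjacent (not identical)
patches of reef simultaneously, real differences between their estimates
are expected — but an unbiased diver's differences with their partners
should be centred on zero.  This module computes those per-site paired
differences ("diver performance"), scores length-estimation calibration
trials against fish models of known size, and scores the pre-cruise
species-identification test (pass requires strictly more than 90% correct).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationTrial",
    "ID_TEST_PASS_PERCENT",
    "paired_differences",
    "diver_performance",
    "size_calibration",
    "id_test_score",
]

#: Minimum correct-identification percentage; passing is strict (> 90).
ID_TEST_PASS_PERCENT = 90.0

#: Metrics the field team routinely inspects for diver bias.
DEFAULT_QC_METRICS = ("biomass_total", "richness", "hard_coral", "ma",
                      "cca", "sand", "other")


@dataclass(frozen=True)
class CalibrationTrial:
    """One size-estimation trial against a fish model of known length."""

    diver: int
    model_length_cm: float
    estimate_cm: float

    @property
    def error_cm(self) -> float:
        return self.estimate_cm - self.model_length_cm


def paired_differences(
    replicates: pd.DataFrame,
    metrics: Sequence[str] = DEFAULT_QC_METRICS,
    groupby: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format per-site diver-vs-partner differences.

    Only SPC pairs with exactly two replicates contribute.  Each pair
    yields two rows per metric — (diver, partner, delta) and the
    antisymmetric (partner, diver, -delta) — so every diver's deltas can
    be read off directly.  ``groupby`` columns (e.g. a cruise identifier)
    are carried through when present.
    """
    metrics = [m for m in metrics if m in replicates.columns]
    if not metrics:
        raise ValueError("none of the requested metrics are present")
    keep = ["sitevisitid", "rep", "diver"] + metrics
    extra = list(groupby) if groupby else []
    keep += [c for c in extra if c in replicates.columns]
    reps = replicates[keep].copy()
    if reps["rep"].isna().any():
        reps["rep"] = reps["rep"].fillna("A")

    sizes = reps.groupby(["sitevisitid", "rep"])["diver"].transform("size")
    pairs = reps.loc[sizes == 2]
    rows = []
    for (svid, rep), grp in pairs.groupby(["sitevisitid", "rep"]):
        a, b = grp.iloc[0], grp.iloc[1]
        for one, other in ((a, b), (b, a)):
            for m in metrics:
                rows.append({
                    "sitevisitid": svid, "rep": rep,
                    "diver": one["diver"], "partner": other["diver"],
                    "metric": m,
                    "delta": float(one[m]) - float(other[m]),
                    **{c: one[c] for c in extra if c in grp.columns},
                })
    return pd.DataFrame(rows, columns=[
        "sitevisitid", "rep", "diver", "partner", "metric", "delta",
        *[c for c in extra if c in reps.columns]])


def _sign_test_p(deltas: np.ndarray) -> float:
    """Exact two-sided sign test against median zero; zero deltas dropped."""
    pos = int((deltas > 0).sum())
    neg = int((deltas < 0).sum())
    n = pos + neg
    if n == 0:
        return 1.0
    return float(stats.binomtest(pos, n, 0.5, alternative="two-sided").pvalue)


def diver_performance(
    replicates: pd.DataFrame,
    metric: str = "biomass_total",
    *,
    alpha: float = 0.05,
    groupby: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-diver summary of paired differences for one metric.

    Returns, per diver (optionally per extra grouping key such as cruise):
    number of paired sites, median delta, quartiles, counts of positive and
    negative deltas, the exact sign-test p-value for symmetry about zero,
    and a bias flag raised when that test rejects at level ``alpha``.
    Divers with no paired sites are omitted (with a warning listing them).
    """
    deltas = paired_differences(replicates, [metric], groupby=groupby)
    all_divers = set(replicates["diver"].unique())
    seen = set(deltas["diver"].unique()) if len(deltas) else set()
    unpaired = sorted(int(d) for d in all_divers - seen)
    if unpaired:
        warnings.warn(
            f"divers with no paired sites omitted: {unpaired}", stacklevel=2)
    if len(deltas) == 0:
        return pd.DataFrame(columns=[
            "diver", "metric", "n", "median_delta", "q1", "q3",
            "n_positive", "n_negative", "p_sign", "bias_flag"])

    keys = ["diver"] + [c for c in (groupby or []) if c in deltas.columns]
    rows = []
    for key, grp in deltas.groupby(keys):
        d = grp["delta"].to_numpy(float)
        key = key if isinstance(key, tuple) else (key,)
        p = _sign_test_p(d)
        rows.append({
            **dict(zip(keys, key)),
            "metric": metric,
            "n": len(d),
            "median_delta": float(np.median(d)),
            "q1": float(np.quantile(d, 0.25)),
            "q3": float(np.quantile(d, 0.75)),
            "n_positive": int((d > 0).sum()),
            "n_negative": int((d < 0).sum()),
            "p_sign": p,
            "bias_flag": bool(p < alpha),
        })
    return pd.DataFrame(rows)


def size_calibration(trials: pd.DataFrame | Sequence[CalibrationTrial]
                     ) -> pd.DataFrame:
    """Per-diver mean length-estimation error and its standard error.

    ``trials`` holds one row per estimate of a fish model of known length
    (columns ``diver, model_length_cm, estimate_cm``).  Error is
    estimate - true length, so a mean near zero indicates accurate sizing.
    SE is s/sqrt(n) (NaN for a single trial).
    """
    if not isinstance(trials, pd.DataFrame):
        trials = pd.DataFrame([vars(t) for t in trials])
    if len(trials) == 0:
        raise ValueError("no calibration trials supplied")
    t = trials.copy()
    t["error_cm"] = t["estimate_cm"].astype(float) - \
        t["model_length_cm"].astype(float)
    g = t.groupby("diver")["error_cm"]
    out = g.agg(n="count", mean_error_cm="mean",
                sd=lambda v: v.std(ddof=1))
    out["se_error_cm"] = out["sd"] / np.sqrt(out["n"])
    # a perfect observer has zero spread, hence SE exactly 0
    out.loc[out["sd"] == 0, "se_error_cm"] = 0.0
    return out.drop(columns="sd").reset_index()


def id_test_score(correct: int, total: int) -> tuple[float, bool]:
    """Score the species-identification test.

    Returns (percent correct, pass flag); passing requires strictly more
    than 90% correct.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= correct <= total:
        raise ValueError("correct must lie between 0 and total")
    percent = 100.0 * correct / total
    return percent, percent > ID_TEST_PASS_PERCENT
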