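"""Synthetic SPC survey generator with known ground truth.

Emulates the full hierarchy of the monitoring design — reporting unit →
stratum (reef zone × depth bin) → site → SPC pair → diver replicate →
species observation — and emits observation tables in the published CSV
dialect together with the analytic truth implied by the generating
parameters, so that the whole processing chain can be exercised and its
estimators checked for bias without the archived dataset.

Observation model.  Each site carries a latent per-species abundance
intensity Lambda ~ Gamma(k, mu/k) (mean mu = species base mean x stratum
multiplier, negative-binomial-style overdispersion k).  The two divers of
the SPC pair share that latent state; each diver's count is
Poisson(Lambda * m) with an independent mean-one multiplicative observer
error m = exp(sigma*z - sigma^2/2).  Lengths are drawn from a per-species
lognormal discretized to whole centimeters and truncated at lmax, so the
expected individual weight E[a (cL)^b] is an exact finite sum.  Every
(diver, species) encounter is labelled with one observation type drawn
from the configured five-way distribution; presence-only (P) encounters
are recorded as a single fish at the species' median length.  The truth
for the routine I+N density filter is therefore
(pI + pN) * sum_s mu_s E[w_s] / cylinder area, exactly.

In ``noiseless`` mode all randomness collapses (counts = round(mu), one
fixed median length per species, all types I, covers at their Dirichlet
means) and the end-to-end pipeline must reproduce the truth to machine
precision; both divers of a pair then record identical cylinders.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biomass import DEFAULT_GEOMETRY, CylinderGeometry
from .data_model import AreaTable, SpeciesTrait, StratumKey, classify_dacor

__all__ = [
    "StratumSpec",
    "SimulationConfig",
    "TruthRecord",
    "generate_species_pool",
    "simulate_survey",
    "area_table",
]

#: Effective survey depth range of each bin (centre points shallower than
#: 1.5 m are never surveyed).
_DEPTH_RANGES = {"shallow": (1.5, 6.0), "mid": (6.0, 18.0),
                 "deep": (18.0, 30.0)}

_GENUS_POOL = (
    ("Acanthurus", "Acanthuridae", "Surgeonfish"),
    ("Chlorurus", "Scaridae", "Parrotfish"),
    ("Scarus", "Scaridae", "Parrotfish"),
    ("Chromis", "Pomacentridae", "Damselfish"),
    ("Lutjanus", "Lutjanidae", "Snapper"),
    ("Cephalopholis", "Serranidae", "Grouper"),
    ("Naso", "Acanthuridae", "Unicornfish"),
    ("Caranx", "Carangidae", "Jack"),
    ("Paracirrhites", "Cirrhitidae", "Hawkfish"),
    ("Melichthys", "Balistidae", "Triggerfish"),
)


@dataclass(frozen=True)
class StratumSpec:
    """One sampling cell of the simulated reporting unit."""

    reef_zone: str
    depth_bin: str
    area_ha: float
    n_sites: int
    abundance_multiplier: float = 1.0


def _default_strata() -> tuple[StratumSpec, ...]:
    # Saipan-like unit: backreef + lagoon (shallow) and a forereef split
    # across the three depth zones; 35 sites total, within the routine
    # 30-50 sites per reef area.
    return (
        StratumSpec("Backreef", "shallow", 598.0, 4, 0.8),
        StratumSpec("Forereef", "shallow", 1062.0, 8, 1.0),
        StratumSpec("Forereef", "mid", 1593.0, 10, 1.3),
        StratumSpec("Forereef", "deep", 884.0, 8, 0.9),
        StratumSpec("Lagoon", "shallow", 583.0, 5, 0.7),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a simulated survey of one reporting unit.

    Defaults describe a small Saipan-like island: one SPC pair of two
    divers per site, a modest species pool with allometric constants in
    the usual reef-fish ranges, negative-binomial site-to-site abundance
    variation, and mild observer error on both counts (multiplicative,
    ``count_error_sd`` on the log scale) and lengths (additive
    ``size_error_sd_cm``, rounded back to whole cm).
    """

    reporting_unit: str = "Saipan"
    region: str = "S.MARIAN"
    island: str = "Saipan"
    strata: tuple[StratumSpec, ...] = field(default_factory=_default_strata)
    n_species: int = 8
    lw_a_range: tuple[float, float] = (0.005, 0.05)
    lw_b_range: tuple[float, float] = (2.8, 3.2)
    length_conversion_range: tuple[float, float] = (0.8, 1.0)
    p_total_length: float = 0.7  # share of species with c = 1 exactly
    consumer_group_probs: Mapping[str, float] = field(default_factory=lambda: {
        "Primary Consumer": 0.35, "Secondary Consumer": 0.35,
        "Planktivore": 0.20, "Piscivore": 0.10})
    mean_count_range: tuple[float, float] = (0.5, 8.0)
    dispersion: float = 4.0  # negative-binomial k; larger = closer to Poisson
    size_median_range_cm: tuple[float, float] = (8.0, 30.0)
    size_sdlog: float = 0.25
    obs_type_probs: Mapping[str, float] = field(default_factory=lambda: {
        "I": 0.85, "N": 0.05, "F": 0.04, "T": 0.03, "P": 0.03})
    benthic_concentration: Mapping[str, float] = field(default_factory=lambda: {
        "hard_coral": 30.0, "ma": 10.0, "cca": 15.0, "sand": 25.0,
        "other": 20.0})
    substrate_height_concentration: tuple[float, ...] = (40.0, 25.0, 20.0,
                                                         10.0, 5.0)
    count_error_sd: float = 0.15
    size_error_sd_cm: float = 1.0
    n_divers: int = 6
    second_pair_prob: float = 0.0
    obs_year: int = 2015
    noiseless: bool = False
    #: When set, the species pool (traits, mean abundances, size models) is
    #: drawn from this seed independently of the survey seed, fixing the
    #: simulated population across replicate surveys.  When None the pool
    #: is drawn from the survey seed itself.
    species_seed: int | None = None
    geometry: CylinderGeometry = DEFAULT_GEOMETRY

    def __post_init__(self) -> None:
        if len(self.strata) == 0:
            raise ValueError("infeasible config: no strata")
        if self.n_species < 1:
            raise ValueError("infeasible config: empty species pool")
        if any(s.n_sites < 1 for s in self.strata):
            raise ValueError("every stratum needs at least one site")
        p = sum(self.obs_type_probs.values())
        if abs(p - 1.0) > 1e-9:
            raise ValueError(f"obs_type_probs must sum to 1, got {p}")
        g = sum(self.consumer_group_probs.values())
        if abs(g - 1.0) > 1e-9:
            raise ValueError(f"consumer_group_probs must sum to 1, got {g}")
        if self.count_error_sd < 0 or self.size_error_sd_cm < 0:
            raise ValueError("error standard deviations must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_divers < 2:
            raise ValueError("need at least two divers for an SPC pair")


@dataclass
class TruthRecord:
    """Analytic ground truth of a simulated survey.

    ``strata`` holds, per sampling cell, the expected site-level value of
    every truth metric under the routine I+N density filter;  ``pooled``
    the area-weighted reporting-unit truth using wi = Ai / sum(A).
    """

    reporting_unit: str
    strata: pd.DataFrame
    pooled: dict[str, float]
    included_types: tuple[str, ...]

    def stratum_truth(self, reef_zone: str, depth_bin: str,
                      metric: str = "biomass_gm2") -> float:
        f = self.strata
        row = f.loc[(f["reef_zone"] == reef_zone)
                    & (f["depth_bin"] == depth_bin)]
        if len(row) != 1:
            raise KeyError(f"no stratum {(reef_zone, depth_bin)}")
        return float(row[metric].iloc[0])

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, float) and math.isnan(v):
                return None
            return v

        return {
            "reporting_unit": self.reporting_unit,
            "included_types": list(self.included_types),
            "pooled": {k: clean(v) for k, v in self.pooled.items()},
            "strata": [{k: clean(v) for k, v in row.items()}
                       for row in self.strata.to_dict(orient="records")],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass(frozen=True)
class _SpeciesSim:
    trait: SpeciesTrait
    base_mean_count: float
    lengths: np.ndarray       # integer cm support, 1..lmax
    length_probs: np.ndarray  # discretized truncated lognormal
    median_length_cm: int
    expected_weight_g: float  # sum(p_L * a (cL)^b)

    @property
    def fixed_weight_g(self) -> float:
        t = self.trait
        return t.lw_a * (t.length_conversion_factor
                         * self.median_length_cm) ** t.lw_b


def _draw_species(config: SimulationConfig, rng: np.random.Generator
                  ) -> list[_SpeciesSim]:
    letters = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
    codes: set[str] = set()
    out: list[_SpeciesSim] = []
    groups = list(config.consumer_group_probs)
    gprobs = np.array([config.consumer_group_probs[g] for g in groups])
    for i in range(config.n_species):
        while True:
            code = "".join(rng.choice(letters, 4))
            if code not in codes:
                codes.add(code)
                break
        genus, family, common = _GENUS_POOL[int(rng.integers(len(_GENUS_POOL)))]
        a = math.exp(rng.uniform(*np.log(config.lw_a_range)))
        b = rng.uniform(*config.lw_b_range)
        c = 1.0 if rng.random() < config.p_total_length \
            else float(rng.uniform(*config.length_conversion_range))
        median = rng.uniform(*config.size_median_range_cm)
        sdlog = config.size_sdlog
        lmax = max(3, int(math.ceil(median * math.exp(3.5 * sdlog))))
        lengths = np.arange(1, lmax + 1)
        # lognormal density discretized to whole cm, truncated at lmax
        probs = np.exp(-0.5 * ((np.log(lengths) - math.log(median))
                               / sdlog) ** 2) / lengths
        probs /= probs.sum()
        trait = SpeciesTrait(
            species=code,
            lw_a=float(a), lw_b=float(b), lmax=float(lmax),
            length_conversion_factor=c,
            taxonname=f"{genus} {code.lower()}",
            family=family, common_family=common,
            consumer_group=str(rng.choice(groups, p=gprobs)),
        )
        weights = trait.lw_a * (trait.length_conversion_factor
                                * lengths.astype(float)) ** trait.lw_b
        out.append(_SpeciesSim(
            trait=trait,
            base_mean_count=math.exp(rng.uniform(*np.log(config.mean_count_range))),
            lengths=lengths,
            length_probs=probs,
            median_length_cm=int(round(median)),
            expected_weight_g=float(probs @ weights),
        ))
    return out


def generate_species_pool(config: SimulationConfig,
                          seed: int | None = None) -> list[SpeciesTrait]:
    """Draw the species trait table the simulator uses for ``seed``."""
    if config.species_seed is not None:
        seed = config.species_seed
    rng = np.random.default_rng(seed)
    return [s.trait for s in _draw_species(config, rng)]


def area_table(config: SimulationConfig) -> AreaTable:
    """The hard-bottom area table implied by the configured strata."""
    return AreaTable.from_mapping({
        StratumKey(config.reporting_unit, s.reef_zone, s.depth_bin): s.area_ha
        for s in config.strata})


def _compute_truth(config: SimulationConfig,
                   pool: list[_SpeciesSim]) -> TruthRecord:
    area = config.geometry.area_m2
    p_in = config.obs_type_probs.get("I", 0.0) + \
        config.obs_type_probs.get("N", 0.0)
    if config.noiseless:
        p_in = 1.0
    benthic_total = sum(config.benthic_concentration.values())
    benthic_means = {k: 100.0 * v / benthic_total
                     for k, v in config.benthic_concentration.items()}
    rows = []
    for s in config.strata:
        if config.noiseless:
            counts = np.array([round(sp.base_mean_count
                                     * s.abundance_multiplier)
                               for sp in pool], dtype=float)
            weights = np.array([sp.fixed_weight_g for sp in pool])
            richness = float((counts >= 1).sum())
        else:
            counts = np.array([sp.base_mean_count * s.abundance_multiplier
                               for sp in pool])
            weights = np.array([sp.expected_weight_g for sp in pool])
            richness = math.nan  # richness expectation is not analytic
        rows.append({
            "reef_zone": s.reef_zone,
            "depth_bin": s.depth_bin,
            "area_ha": s.area_ha,
            "n_sites": s.n_sites,
            "biomass_gm2": p_in * float(counts @ weights) / area,
            "abundance_m2": p_in * float(counts.sum()) / area,
            "richness": richness,
            **benthic_means,
        })
    strata = pd.DataFrame(rows)
    w = strata["area_ha"] / strata["area_ha"].sum()
    pooled = {"weights_sum": float(w.sum())}
    metrics = ["biomass_gm2", "abundance_m2", *benthic_means]
    if config.noiseless:
        metrics.append("richness")  # only analytic in the noiseless limit
    for metric in metrics:
        pooled[metric] = float(strata[metric] @ w)
    strata["wi"] = w
    return TruthRecord(
        reporting_unit=config.reporting_unit,
        strata=strata,
        pooled=pooled,
        included_types=("I", "N"),
    )


def _benthic_draw(config: SimulationConfig, rng, noiseless: bool
                  ) -> dict[str, float]:
    names = list(config.benthic_concentration)
    alpha = np.array([config.benthic_concentration[n] for n in names])
    if noiseless:
        vals = 100.0 * alpha / alpha.sum()
    else:
        vals = 100.0 * rng.dirichlet(alpha)
    return dict(zip(names, vals))


def _substrate_draw(config: SimulationConfig, rng, noiseless: bool
                    ) -> np.ndarray:
    alpha = np.asarray(config.substrate_height_concentration, dtype=float)
    if noiseless:
        return 100.0 * alpha / alpha.sum()
    return 100.0 * rng.dirichlet(alpha)


def simulate_survey(config: SimulationConfig, seed: int | None = None
                    ) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate one survey of the configured reporting unit.

    Returns the observation table (published-dialect columns, one row per
    diver x species x size class) and the analytic :class:`TruthRecord`.
    The same seed reproduces the identical table byte for byte.
    """
    rng = np.random.default_rng(seed)
    if config.species_seed is not None:
        pool = _draw_species(config, np.random.default_rng(config.species_seed))
    else:
        pool = _draw_species(config, rng)
    truth = _compute_truth(config, pool)
    nl = config.noiseless

    obs_types = list(config.obs_type_probs)
    obs_probs = np.array([config.obs_type_probs[t] for t in obs_types])
    mu_base = np.array([sp.base_mean_count for sp in pool])
    k = config.dispersion
    code3 = config.island[:3].upper().ljust(3, "X")

    rows: list[dict] = []
    svid = 20000
    replicateid = 51000
    site_no = 0
    base_date = pd.Timestamp(f"{config.obs_year}-05-01")

    for s in config.strata:
        lo, hi = _DEPTH_RANGES[s.depth_bin]
        mu = mu_base * s.abundance_multiplier
        for _ in range(s.n_sites):
            svid += 1
            site_no += 1
            site = f"{code3}-{site_no + 1000:05d}"
            if nl:
                depth = round((lo + hi) / 2.0, 1)
                lat, lon = 15.15, 145.70
                vis, current = 20.0, "Slight"
                min_d, max_d = max(depth - 1.0, 0.5), min(depth + 1.0, 30.0)
                free_n, boring_n = 10, 50
            else:
                depth = float(np.clip(round(rng.uniform(lo, hi), 1),
                                      lo, hi - 0.1))
                lat = round(15.10 + rng.uniform(0, 0.2), 5)
                lon = round(145.60 + rng.uniform(0, 0.25), 5)
                vis = round(rng.uniform(8.0, 30.0), 1)
                current = str(rng.choice(["None", "Slight", "Moderate"]))
                min_d = round(max(depth - rng.uniform(0.3, 1.5), 0.5), 1)
                max_d = round(min(depth + rng.uniform(0.3, 1.5), 30.0), 1)
                free_n = int(rng.poisson(8))
                boring_n = int(rng.poisson(40))
            date = (base_date + pd.Timedelta(days=site_no % 25)).strftime(
                "%Y-%m-%d")
            n_pairs = 1
            if not nl and rng.random() < config.second_pair_prob:
                n_pairs = 2
            for pair_idx in range(n_pairs):
                rep = "AB"[pair_idx]
                divers = (np.array([1, 2]) if nl else
                          1 + rng.choice(config.n_divers, 2, replace=False))
                # latent site state shared by the pair's two divers
                lam = mu if nl else rng.gamma(k, mu / k)
                for diver in divers:
                    replicateid += 1
                    if nl:
                        counts = np.round(lam).astype(int)
                    else:
                        m = math.exp(rng.normal(0.0, config.count_error_sd)
                                     - config.count_error_sd ** 2 / 2.0)
                        counts = rng.poisson(lam * m)
                    benthic = _benthic_draw(config, rng, nl)
                    heights = _substrate_draw(config, rng, nl)
                    meta = {
                        "region": config.region, "island": config.island,
                        "site": site, "latitude": lat, "longitude": lon,
                        "reef_zone": s.reef_zone, "depth_bin": s.depth_bin,
                        "sitevisitid": svid, "date": date,
                        "obs_year": config.obs_year, "diver": int(diver),
                        "replicateid": replicateid, "rep": rep,
                        "depth_m": depth, **benthic,
                        "habitat_code": "AGR" if nl else
                        str(rng.choice(["AGR", "PAV", "SAG", "RRB"])),
                        "current_strength": current, "visibility_m": vis,
                        "min_depth_m": min_d, "max_depth_m": max_d,
                        "complexity": pd.NA,
                        "substrate_height_0": heights[0],
                        "substrate_height_20": heights[1],
                        "substrate_height_50": heights[2],
                        "substrate_height_100": heights[3],
                        "substrate_height_150": heights[4],
                        "max_height": float(round(50 + heights[4] * 3, 0)),
                        "urchin_dacor": classify_dacor(free_n, "free"),
                        "boring_urchin_dacor": classify_dacor(boring_n,
                                                              "boring"),
                    }
                    for sp, n in zip(pool, counts):
                        if n < 1:
                            continue
                        t = sp.trait
                        obs_type = "I" if nl else \
                            str(rng.choice(obs_types, p=obs_probs))
                        if obs_type == "P":
                            size_count = {sp.median_length_cm: 1}
                        elif nl:
                            size_count = {sp.median_length_cm: int(n)}
                        else:
                            lengths = rng.choice(
                                sp.lengths, size=int(n), p=sp.length_probs
                            ).astype(float)
                            if config.size_error_sd_cm > 0:
                                lengths += rng.normal(
                                    0.0, config.size_error_sd_cm, int(n))
                            lengths = np.clip(np.round(lengths), 1,
                                              t.lmax).astype(int)
                            uniq, cnt = np.unique(lengths, return_counts=True)
                            size_count = dict(zip(uniq, cnt))
                        for size_cm, cnt in size_count.items():
                            rows.append({
                                **meta,
                                "species": t.species,
                                "taxonname": t.taxonname,
                                "common_family": t.common_family,
                                "family": t.family,
                                "consumer_group": t.consumer_group,
                                "lw_a": t.lw_a, "lw_b": t.lw_b,
                                "lmax": t.lmax,
                                "length_conversion_factor":
                                    t.length_conversion_factor,
                                "count": int(cnt),
                                "size_tl_cm": float(size_cm),
                                "obs_type": obs_type,
                            })
    if not rows:
        raise ValueError(
            "configuration produced no observations (all means round to 0)")
    df = pd.DataFrame(rows)
    df["date"] = pd.to_datetime(df["date"])
    for col in ("sitevisitid", "obs_year", "diver", "replicateid", "count",
                "complexity"):
        df[col] = df[col].astype("Int64")
    return df, truth
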