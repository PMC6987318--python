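"""Synthetic multi-lake plankton monitoring datasets with known truth.

Emulates the structure of a decades-long, monthly, eight-lake monitoring
programme: depth-resolved temperature and phosphorus profiles with seasonal
cycles, a linear warming trend and a declining-phosphorus (oligotrophication)
trend; net-tow counts of the four dominant macro-grazer families with summer
peaks; and phytoplankton counts whose log10 density is an exact power law in
log10 cell biovolume, ``log10 N = a + b log10 V + eps``, where the exponent
``b`` for each lake-date is a known nonlinear, interactive function of the
generated drivers plus noise.  The generating parameters are recorded in a
truth table so the whole pipeline can be scored against ground truth.

The generator computes driver values through the same :mod:`lakesar.
preprocess` functions the analysis uses, so a round trip (generate tables ->
build features) reproduces the recorded drivers to machine precision when no
missingness is injected.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import preprocess

__all__ = [
    "LakeSpec",
    "ScenarioTruth",
    "GeneratorConfig",
    "DEFAULT_LAKES",
    "default_slope_fn",
    "default_scenario",
    "generate_taxon_pool",
    "generate_community_sample",
    "generate_lake_dataset",
    "generate_dataset",
    "inject_missingness_and_censoring",
    "make_driver_table",
]

_MAX_SEED = 2**31 - 1

#: columns of the truth table that are drivers of the generating slope fn
TRUE_DRIVERS = ["T_mean", "P_PO4_mean", "Zoo_total", "Phyto_total"]
DECOY_DRIVERS = ["Decoy_1", "Decoy_2"]

ZOO_FAMILIES = ("Bosminidae", "Daphniidae", "Diaptomidae", "Cyclopidae")


@dataclass
class LakeSpec:
    """Static properties of one lake and its long-term forcing."""

    lake_id: str
    volume: float               # km^3
    depth_at_site: float        # m
    epilimnion_depths: Sequence[float]  # sampled depths, m
    p_baseline: float           # ug/L at series start
    p_decline_rate: float       # ug/L per decade (positive = decline)
    warming_rate: float = 0.17  # degC per decade

    def __post_init__(self):
        d = np.asarray(self.epilimnion_depths, dtype=float)
        if d.size == 0 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing and > 0")
        if self.volume <= 0 or self.depth_at_site <= 0:
            raise ValueError("volume and depth must be > 0")
        self.epilimnion_depths = d


#: eight lakes spanning the morphometric and trophic gradient of the real
#: monitoring panel (volumes/depths of that order; phosphorus baselines from
#: near-oligotrophic to strongly eutrophic)
DEFAULT_LAKES = [
    LakeSpec("WA", 2.500, 144.0, [1, 5, 10, 15, 20, 40], 12.0, 2.0),
    LakeSpec("UZ", 0.600, 36.0, [1, 5, 10, 15, 20], 18.0, 3.0),
    LakeSpec("LU", 11.80, 110.0, [1, 5, 10, 15, 20, 30], 35.0, 7.0),
    LakeSpec("LZ", 3.300, 135.0, [1, 5, 10, 20, 40], 140.0, 28.0),
    LakeSpec("SE", 0.660, 87.0, [1, 5, 10, 15], 170.0, 30.0),
    LakeSpec("HA", 0.285, 45.0, [1, 5, 10, 13], 220.0, 40.0),
    LakeSpec("BA", 0.173, 67.0, [1, 5, 10, 15], 240.0, 45.0),
    LakeSpec("GR", 0.148, 30.0, [1, 5, 10, 15, 20], 330.0, 60.0),
]


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def default_slope_fn(drivers) -> np.ndarray:
    """Generating exponent as a saturating, interactive driver response.

    Directions: warmer water and heavier total grazing flatten the slope
    (less negative b, favouring large taxa); higher phosphorus and higher
    total phytoplankton density steepen it; and temperature synergises with
    phosphorus scarcity (the flattest response sits at high T, low P).
    Thresholds sit at ~100 ug/L phosphorus and ~5.2 log10 grazers m^-2.
    """
    d = drivers
    T = np.asarray(d["T_mean"], dtype=float)
    P = np.asarray(d["P_PO4_mean"], dtype=float)
    Z = np.asarray(d["Zoo_total"], dtype=float)
    F = np.asarray(d["Phyto_total"], dtype=float)
    t = _logistic((T - 10.0) / 2.0)
    z = _logistic((Z - 5.2) / 0.25)
    p = _logistic((P - 100.0) / 25.0)
    f = _logistic((F - 6.3) / 0.35)
    return (-0.745 + 0.050 * t + 0.045 * z - 0.050 * p - 0.045 * f
            + 0.035 * t * (1.0 - p))


@dataclass
class ScenarioTruth:
    """Ground-truth generating process for recovery tests."""

    true_slope_fn: Callable = default_slope_fn
    slope_noise_sd: float = 0.04        # sd of date-level slope noise
    taxon_pool: pd.DataFrame | None = None
    abundance_noise_sd: float = 0.30    # sd of per-taxon log10 density noise
    presence_fraction: float = 0.60     # Bernoulli presence per taxon-date
    slope_bounds: tuple[float, float] = (-1.5, -0.3)
    seed: int | None = None


def default_scenario(**overrides) -> ScenarioTruth:
    return replace(ScenarioTruth(), **overrides)


@dataclass
class GeneratorConfig:
    """Knobs of a synthetic run.

    ``interval_days`` in [28, 31] snaps to calendar-month sampling (the
    monitoring cadence); other values step by a fixed number of days.
    """

    n_lakes: int = 8
    start: str = "1975-01-15"
    end: str = "2004-12-15"
    interval_days: int = 30
    n_taxa: int = 150
    detection_limit: float = 1.0    # ug/L
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.interval_days < 1:
            raise ValueError("interval_days must be >= 1")
        if not 0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must be in [0, 0.2]")
        start = pd.Timestamp(self.start)
        end = pd.Timestamp(self.end)
        if end - start < pd.Timedelta(days=2 * 365):
            raise ValueError("date range must span at least 2 years")

    def dates(self) -> pd.DatetimeIndex:
        start = pd.Timestamp(self.start)
        end = pd.Timestamp(self.end)
        if 28 <= self.interval_days <= 31:
            months = pd.date_range(start.normalize().replace(day=1),
                                   end, freq="MS")
            d = months + pd.Timedelta(days=14)  # mid-month sampling day
            return pd.DatetimeIndex([x for x in d if start <= x <= end])
        return pd.date_range(start, end, freq=f"{self.interval_days}D")


# -- taxon pool ------------------------------------------------------------

#: default class mix; cyanobacteria are tilted toward the small end of the
#: size range, mirroring their dominance among small cells in lake counts
DEFAULT_CLASS_MIX = {
    "Cyanophyceae": 0.25,
    "Chlorophyceae": 0.20,
    "Bacillariophyceae": 0.18,
    "Chrysophyceae": 0.12,
    "Cryptophyceae": 0.10,
    "Dinophyceae": 0.08,
    "Conjugatophyceae": 0.07,
}


def generate_taxon_pool(n_taxa: int, size_range_log10=(0.0, 6.0),
                        class_mix: dict | None = None,
                        seed: int | None = None) -> pd.DataFrame:
    """Log-uniform biovolumes over the given range, with class labels."""
    lo, hi = float(size_range_log10[0]), float(size_range_log10[1])
    if n_taxa < 10:
        raise ValueError("n_taxa must be >= 10")
    if not (hi > lo) or lo < -1 or hi > 8:
        raise ValueError("size_range_log10 must be non-empty within [-1, 8]")
    mix = dict(class_mix or DEFAULT_CLASS_MIX)
    rng = np.random.default_rng(seed)
    logv = rng.uniform(lo, hi, n_taxa)

    names = list(mix)
    base = np.array([mix[c] for c in names], dtype=float)
    base /= base.sum()
    classes = []
    for lv in logv:
        w = base.copy()
        if "Cyanophyceae" in mix:
            i = names.index("Cyanophyceae")
            # small-cell tilt: cyanobacteria rare above ~10^3 um^3
            w[i] *= 2.0 * float(_logistic((3.0 - lv) / 0.5))
        w /= w.sum()
        classes.append(names[rng.choice(len(names), p=w)])

    ids = [f"T{i:04d}" for i in range(1, n_taxa + 1)]
    return pd.DataFrame({
        "taxon_id": ids,
        "name": [f"Taxon {i:04d}" for i in range(1, n_taxa + 1)],
        "class": classes,
        "biovolume_um3": 10.0 ** logv,
    })


# -- communities -----------------------------------------------------------

def generate_community_sample(taxon_pool: pd.DataFrame, b: float, a: float,
                              noise_sd: float = 0.3,
                              presence_fraction: float = 0.6,
                              seed: int | None = None) -> pd.DataFrame:
    """One community sample drawn from the power-law model.

    Retains each pool taxon with probability ``presence_fraction`` (absent
    taxa are omitted, not zero-filled) and sets
    ``log10 density = a + b log10 V + N(0, noise_sd)``.
    """
    if not 0 < presence_fraction <= 1:
        raise ValueError("presence_fraction must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(taxon_pool)
    present = rng.random(n) < presence_fraction
    if present.sum() < 3:     # degenerate draw; keep the three smallest ids
        present[:3] = True
    sub = taxon_pool.loc[present]
    logv = np.log10(sub["biovolume_um3"].to_numpy(dtype=float))
    logd = a + b * logv + rng.normal(0.0, noise_sd, logv.size)
    return pd.DataFrame({
        "taxon_id": sub["taxon_id"].to_numpy(),
        "density_cells_per_L": 10.0 ** logd,
    })


def _seasonal(doy, peak_doy, amplitude):
    return amplitude * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def generate_lake_dataset(lake: LakeSpec, scenario: ScenarioTruth,
                          config: GeneratorConfig,
                          lake_rng: np.random.Generator | None = None,
                          taxa: pd.DataFrame | None = None) -> dict:
    """All four tables plus the truth table for one lake.

    Monthly dates; temperature profiles combine a seasonal surface cycle, a
    linear warming trend and a depth gradient that sharpens in summer (so
    the temperature CV over depth tracks stratification); phosphorus
    declines over the years and is censored at the detection limit; the four
    grazer families peak in summer.  The per-date exponent is
    ``true_slope_fn(drivers) + N(0, slope_noise_sd)`` and the community
    intercept is set so that the realised total density equals the generated
    Phyto_total driver exactly.
    """
    rng = lake_rng if lake_rng is not None else np.random.default_rng(
        config.seed)
    if taxa is None:
        taxa = scenario.taxon_pool
    if taxa is None:
        taxa = generate_taxon_pool(config.n_taxa,
                                   seed=int(rng.integers(_MAX_SEED)))
    dates = config.dates()
    if len(dates) < 24:
        raise ValueError("date range must span at least 2 years of sampling")
    doy = dates.dayofyear.to_numpy(dtype=float)
    years = (dates - dates[0]).days.to_numpy(dtype=float) / 365.25
    depths = np.asarray(lake.epilimnion_depths, dtype=float)

    # --- temperature profiles: surface seasonal cycle + warming + gradient
    # warming_rate is degC per decade; years/10 = decades elapsed
    t_surface = (11.0 + _seasonal(doy, 210.0, 8.0)
                 + lake.warming_rate * (years / 10.0))
    t_deep = 5.0 + 0.3 * lake.warming_rate * (years / 10.0)
    # stratified summer: warm layer confined near the surface (small
    # e-folding depth), so the temperature CV over depth peaks in summer
    mix_depth = np.clip(18.0 - 12.0 * _seasonal(doy, 210.0, 1.0), 5.0, 30.0)
    prof_rows = []
    for i, d in enumerate(dates):
        grad = (t_surface[i] - t_deep[i]) * np.exp(-depths / mix_depth[i])
        temp = t_deep[i] + grad + rng.normal(0.0, 0.15, depths.size)
        temp = np.maximum(temp, 1.0)
        # phosphorus: declining trend, winter-mixing seasonal high, noise
        p_mean = max(lake.p_baseline
                     - lake.p_decline_rate * (years[i] / 10.0), 0.3)
        p_season = 1.0 + 0.20 * np.cos(2 * np.pi * (doy[i] - 45.0) / 365.25)
        po4 = (p_mean * p_season * (1.0 + 0.004 * depths)
               * np.exp(rng.normal(0.0, 0.12, depths.size)))
        po4 = np.maximum(po4, 0.05)
        for z, t, p in zip(depths, temp, po4):
            prof_rows.append((lake.lake_id, d, z, t, p))
    profiles = pd.DataFrame(prof_rows, columns=[
        "lake", "date", "depth_m", "temperature_C", "po4_ug_per_L"])
    # censor at the detection limit
    cens = profiles["po4_ug_per_L"] < config.detection_limit
    profiles.loc[cens, "po4_ug_per_L"] = config.detection_limit
    profiles["po4_censored"] = cens

    # --- zooplankton: four families with summer peaks
    fam_base = {"Bosminidae": 2.0e4, "Daphniidae": 3.0e4,
                "Diaptomidae": 1.6e4, "Cyclopidae": 1.4e4}
    fam_peak = {"Bosminidae": 190.0, "Daphniidae": 170.0,
                "Diaptomidae": 200.0, "Cyclopidae": 220.0}
    zoo_rows = []
    for i, d in enumerate(dates):
        for fam in ZOO_FAMILIES:
            level = fam_base[fam] * np.exp(
                0.8 * np.cos(2 * np.pi * (doy[i] - fam_peak[fam]) / 365.25)
                + rng.normal(0.0, 0.35))
            zoo_rows.append((lake.lake_id, d, fam, level))
    zoo = pd.DataFrame(zoo_rows, columns=["lake", "date", "family",
                                          "individuals_per_m2"])

    # --- drivers, computed with the same code the analysis uses
    T_mean = np.empty(len(dates))
    T_CV = np.empty(len(dates))
    P_mean = np.empty(len(dates))
    Zoo_total = np.empty(len(dates))
    Zoo_sel = np.empty(len(dates))
    for i, d in enumerate(dates):
        prof = profiles[profiles["date"] == d]
        T_mean[i] = preprocess.depth_mean(prof, "temperature")
        T_CV[i] = preprocess.depth_cv(prof, "temperature")
        P_mean[i] = preprocess.depth_mean(prof, "po4")
        Zoo_total[i], Zoo_sel[i] = preprocess.zoo_features(zoo, lake.lake_id,
                                                           d)

    # Phyto_total target: tracks phosphorus (productivity) plus season/noise
    phyto_target = (5.55 + 0.45 * np.log10(P_mean + 1.0)
                    + 0.25 * np.cos(2 * np.pi * (doy - 200.0) / 365.25)
                    + rng.normal(0.0, 0.12, len(dates)))

    drivers = {"T_mean": T_mean, "T_CV": T_CV, "P_PO4_mean": P_mean,
               "Phyto_total": phyto_target, "Zoo_total": Zoo_total,
               "Zoo_selectivity": Zoo_sel}
    f_drivers = np.asarray(scenario.true_slope_fn(drivers), dtype=float)
    slope_noise = rng.normal(0.0, scenario.slope_noise_sd, len(dates))
    b_true = np.clip(f_drivers + slope_noise, *scenario.slope_bounds)

    # --- communities: intercept chosen to hit the Phyto_total target exactly
    logv_pool = np.log10(taxa["biovolume_um3"].to_numpy(dtype=float))
    comm_rows = []
    for i, d in enumerate(dates):
        present = rng.random(len(taxa)) < scenario.presence_fraction
        if present.sum() < 3:
            present[:3] = True
        logv = logv_pool[present]
        eps = rng.normal(0.0, scenario.abundance_noise_sd, logv.size)
        rel = b_true[i] * logv + eps
        a = phyto_target[i] - np.log10(np.sum(10.0 ** rel))
        dens = 10.0 ** (a + rel)
        for tid, dv in zip(taxa["taxon_id"].to_numpy()[present], dens):
            comm_rows.append((lake.lake_id, d, tid, dv))
        drivers.setdefault("intercept_a", []).append(a)
    community = pd.DataFrame(comm_rows, columns=[
        "lake", "date", "taxon_id", "density_cells_per_L"])

    truth = pd.DataFrame({
        "lake": lake.lake_id, "date": dates, "true_slope": b_true,
        "f_drivers": f_drivers, "intercept_a": drivers["intercept_a"],
        "T_mean": T_mean, "T_CV": T_CV, "P_PO4_mean": P_mean,
        "Phyto_total": phyto_target, "Zoo_total": Zoo_total,
        "Zoo_selectivity": Zoo_sel,
        "Decoy_1": rng.normal(0.0, 1.0, len(dates)),
        "Decoy_2": rng.normal(0.0, 1.0, len(dates)),
    })

    tables = {"community": community, "profiles": profiles, "zooplankton": zoo,
              "truth": truth, "taxa": taxa}
    if config.missing_rate > 0:
        tables = inject_missingness_and_censoring(
            tables, config.missing_rate, config.detection_limit,
            seed=int(rng.integers(_MAX_SEED)))
    return tables


def generate_dataset(config: GeneratorConfig,
                     lakes: Sequence[LakeSpec] | None = None,
                     scenario: ScenarioTruth | None = None) -> dict:
    """Multi-lake dataset: all lakes share one taxon pool (harmonised
    taxonomy); per-lake random streams are derived from the master seed so
    each lake is independently reproducible."""
    if lakes is None:
        lakes = DEFAULT_LAKES[: config.n_lakes]
    if scenario is None:
        scenario = default_scenario()
    pool_rng = np.random.default_rng([config.seed, 9999])
    taxa = (scenario.taxon_pool if scenario.taxon_pool is not None else
            generate_taxon_pool(config.n_taxa,
                                seed=int(pool_rng.integers(_MAX_SEED))))
    parts = {k: [] for k in ("community", "profiles", "zooplankton", "truth")}
    for li, lake in enumerate(lakes):
        lake_rng = np.random.default_rng([config.seed, li])
        tabs = generate_lake_dataset(lake, scenario, config,
                                     lake_rng=lake_rng, taxa=taxa)
        for k in parts:
            parts[k].append(tabs[k])
    out = {k: pd.concat(v, ignore_index=True) for k, v in parts.items()}
    out["taxa"] = taxa
    out["lakes"] = {lk.lake_id: lk for lk in lakes}
    return out


def inject_missingness_and_censoring(tables: dict, missing_rate: float,
                                     detection_limit: float,
                                     seed: int | None = None) -> dict:
    """Censor phosphorus at the detection limit and blank random driver cells.

    Phosphorus below the limit is stored at the limit with the censored flag
    set.  A ``missing_rate`` fraction of driver cells (profile temperature
    and phosphorus, zooplankton counts) is set missing; community counts are
    never blanked.
    """
    if not 0 <= missing_rate <= 0.2:
        raise ValueError("missing_rate must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    out = dict(tables)

    prof = out["profiles"].copy()
    low = prof["po4_ug_per_L"] < detection_limit
    prof.loc[low, "po4_ug_per_L"] = detection_limit
    if "po4_censored" in prof:
        prof["po4_censored"] = prof["po4_censored"] | low
    else:
        prof["po4_censored"] = low
    if missing_rate > 0:
        for col in ("temperature_C", "po4_ug_per_L"):
            mask = rng.random(len(prof)) < missing_rate
            prof.loc[mask, col] = np.nan
            if col == "po4_ug_per_L":
                prof.loc[mask, "po4_censored"] = False
    out["profiles"] = prof

    zoo = out["zooplankton"].copy()
    if missing_rate > 0:
        mask = rng.random(len(zoo)) < missing_rate
        zoo.loc[mask, "individuals_per_m2"] = np.nan
    out["zooplankton"] = zoo
    return out


# -- standalone driver table for forest recovery experiments ---------------

def make_driver_table(n: int = 1000, r2: float = 0.6,
                      seed: int | None = None,
                      interaction_scale: float = 1.0):
    """Driver table with four true drivers, two pure-noise decoys, and a
    response whose generating R-squared is ``r2``.

    Drivers are sampled independently over realistic monitoring ranges and
    passed through the default saturating/interactive slope response (the
    temperature-phosphorus synergy can be scaled); Gaussian noise is added
    so that ``var(f) / (var(f) + sigma^2) = r2`` for the realised ``f``.

    Returns ``(X, y, f)``: predictor frame, response, and noiseless signal.
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "T_mean": rng.uniform(4.0, 16.0, n),
        "P_PO4_mean": rng.uniform(1.0, 300.0, n),
        "Zoo_total": rng.uniform(4.4, 6.2, n),
        "Phyto_total": rng.uniform(5.4, 7.4, n),
        "Decoy_1": rng.normal(0.0, 1.0, n),
        "Decoy_2": rng.normal(0.0, 1.0, n),
    })
    t = _logistic((X["T_mean"] - 10.0) / 2.0)
    z = _logistic((X["Zoo_total"] - 5.2) / 0.25)
    p = _logistic((X["P_PO4_mean"] - 100.0) / 25.0)
    fl = _logistic((X["Phyto_total"] - 6.3) / 0.35)
    f = (-0.745 + 0.050 * t + 0.045 * z - 0.050 * p - 0.045 * fl
         + interaction_scale * 0.035 * t * (1.0 - p))
    sigma = f.std(ddof=0) * np.sqrt((1.0 - r2) / r2)
    y = f + rng.normal(0.0, sigma, n)
    return X, y, f
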