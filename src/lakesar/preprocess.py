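"""Driver feature construction from raw monitoring tables.

Builds the per-lake-date predictor table for the driver analysis: water
column temperature mean and CV (stratification proxy), depth-averaged
dissolved phosphorus with below-detection values held at the detection
limit, log10 total phytoplankton density, log10 total macro-grazer density
and the copepod/daphnid selectivity ratio, plus static lake morphometry and
time/seasonality terms.  Depth averages are unweighted over the available
depths; dates are matched exactly across tables unless a day tolerance is
requested.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "SELECTIVE_FAMILIES",
    "UNSELECTIVE_FAMILIES",
    "depth_mean",
    "depth_cv",
    "zoo_features",
    "phyto_total",
    "build_feature_table",
]

#: the ten predictors of the driver model, in canonical order
FEATURE_COLUMNS = [
    "T_mean", "T_CV", "P_PO4_mean", "Phyto_total", "Zoo_total",
    "Zoo_selectivity", "Lake_Depth", "Lake_Volume", "Time_trend",
    "Seasonality",
]

SELECTIVE_FAMILIES = ("Diaptomidae", "Cyclopidae")      # copepods
UNSELECTIVE_FAMILIES = ("Bosminidae", "Daphniidae")     # daphnids

_VARCOL = {"temperature": "temperature_C", "po4": "po4_ug_per_L"}


def _values(profile, variable: str) -> np.ndarray:
    if isinstance(profile, pd.DataFrame):
        col = _VARCOL.get(variable, variable)
        return profile[col].to_numpy(dtype=float)
    return np.asarray(profile, dtype=float)


def depth_mean(profile, variable: str = "temperature") -> float:
    """Unweighted arithmetic mean over available depths.

    Censored phosphorus values are expected to already sit at the detection
    limit in the table. All-missing profiles yield NaN (imputed downstream).
    """
    v = _values(profile, variable)
    v = v[~np.isnan(v)]
    if v.size == 0:
        log.warning("all-missing %s profile", variable)
        return float("nan")
    return float(v.mean())


def depth_cv(profile, variable: str = "temperature") -> float:
    """Coefficient of variation (sample sd / mean) over sampled depths.

    Needs at least two non-missing depths; a non-positive mean makes the CV
    meaningless and is flagged by returning NaN.
    """
    v = _values(profile, variable)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m <= 0:
        log.warning("non-positive mean in %s profile; CV undefined", variable)
        return float("nan")
    return float(v.std(ddof=1) / m)


def zoo_features(zoo_table: pd.DataFrame, lake=None,
                 date=None) -> tuple[float, float]:
    """(Zoo_total, Zoo_selectivity) for one lake-date.

    Zoo_total is log10 of the summed areal densities of the four families;
    a zero total maps to NaN rather than -inf.  Selectivity is the raw
    copepod/daphnid abundance ratio (no logs); a zero daphnid denominator
    yields NaN.
    """
    t = zoo_table
    if lake is not None:
        t = t[t["lake"] == lake]
    if date is not None:
        t = t[t["date"] == date]
    counts = t.groupby("family")["individuals_per_m2"].sum()
    total = float(counts.sum())
    sel = float(sum(counts.get(f, 0.0) for f in SELECTIVE_FAMILIES))
    unsel = float(sum(counts.get(f, 0.0) for f in UNSELECTIVE_FAMILIES))
    zoo_total = np.log10(total) if total > 0 else float("nan")
    if unsel == 0:
        log.warning("zero daphnid denominator for %s/%s", lake, date)
        selectivity = float("nan")
    else:
        selectivity = sel / unsel
    return zoo_total, selectivity


def phyto_total(community_sample) -> float:
    """Log10 of summed densities across the taxa present in one sample."""
    if isinstance(community_sample, pd.DataFrame):
        dens = community_sample["density_cells_per_L"].to_numpy(dtype=float)
    else:
        dens = np.asarray(getattr(community_sample, "density",
                                  community_sample), dtype=float)
    if dens.size == 0:
        raise ValueError("empty community sample")
    return float(np.log10(dens.sum()))


def _nearest_match(keys: pd.DataFrame, table: pd.DataFrame,
                   tol_days: int) -> pd.DataFrame:
    """Map each (lake, date) key to the nearest table date within tolerance."""
    out = []
    for lake, grp in keys.groupby("lake"):
        avail = np.sort(table.loc[table["lake"] == lake, "date"].unique())
        if avail.size == 0:
            out.append(grp.assign(_match=pd.NaT))
            continue
        want = grp["date"].to_numpy()
        pos = np.searchsorted(avail, want)
        pos = np.clip(pos, 0, avail.size - 1)
        prev = np.clip(pos - 1, 0, avail.size - 1)
        d_next = np.abs((avail[pos] - want).astype("timedelta64[D]").astype(int))
        d_prev = np.abs((avail[prev] - want).astype("timedelta64[D]").astype(int))
        best = np.where(d_prev <= d_next, avail[prev], avail[pos])
        dist = np.minimum(d_prev, d_next)
        match = np.where(dist <= tol_days, best, np.datetime64("NaT"))
        out.append(grp.assign(_match=match))
    return pd.concat(out)


def build_feature_table(community: pd.DataFrame, taxa: pd.DataFrame,
                        profiles: pd.DataFrame, zoo: pd.DataFrame,
                        slopes: pd.DataFrame, lake_specs,
                        date_tolerance_days: int = 0) -> pd.DataFrame:
    """One row per (lake, date) carrying the ten predictors and the response.

    Rows come from the slope table (dates without a usable slope are already
    absent).  Profile and zooplankton features are matched on the exact
    calendar day by default; Time_trend counts days since each lake's first
    community date, Seasonality is the calendar month.  Missing driver cells
    stay NaN for downstream imputation.

    ``lake_specs`` maps lake id to an object (or dict / DataFrame row) with
    ``depth_at_site`` and ``volume``.
    """
    community = community.assign(date=pd.to_datetime(community["date"]))
    profiles = profiles.assign(date=pd.to_datetime(profiles["date"]))
    zoo = zoo.assign(date=pd.to_datetime(zoo["date"]))
    slopes = slopes.assign(date=pd.to_datetime(slopes["date"]))

    out = slopes[["lake", "date", "b_median"]].rename(
        columns={"b_median": "response"}).copy()

    # water column temperature and phosphorus
    prof_feats = (profiles.groupby(["lake", "date"])
                  .apply(lambda g: pd.Series({
                      "T_mean": depth_mean(g, "temperature"),
                      "T_CV": depth_cv(g, "temperature"),
                      "P_PO4_mean": depth_mean(g, "po4")}),
                      include_groups=False)
                  .reset_index())

    # grazers
    zoo_feats = (zoo.groupby(["lake", "date"])
                 .apply(lambda g: pd.Series(
                     zoo_features(g), index=["Zoo_total", "Zoo_selectivity"]),
                     include_groups=False)
                 .reset_index())

    # total phytoplankton
    phyto = (community.groupby(["lake", "date"])["density_cells_per_L"]
             .sum().reset_index())
    phyto["Phyto_total"] = np.log10(phyto["density_cells_per_L"])
    phyto = phyto[["lake", "date", "Phyto_total"]]

    def merge_on_date(base, table, cols):
        if date_tolerance_days <= 0:
            return base.merge(table, on=["lake", "date"], how="left")
        keyed = _nearest_match(base[["lake", "date"]], table,
                               date_tolerance_days)
        base = base.assign(_match=keyed["_match"].to_numpy())
        merged = base.merge(
            table.rename(columns={"date": "_match"}),
            on=["lake", "_match"], how="left").drop(columns="_match")
        return merged

    out = merge_on_date(out, prof_feats, ["T_mean", "T_CV", "P_PO4_mean"])
    out = merge_on_date(out, zoo_feats, ["Zoo_total", "Zoo_selectivity"])
    out = merge_on_date(out, phyto, ["Phyto_total"])

    for lake in out["lake"].unique():
        sub = out[out["lake"] == lake]
        if sub[["T_mean", "T_CV", "P_PO4_mean"]].isna().all().all():
            raise ValueError(
                f"no matching profile dates at all for lake {lake!r}")

    # static morphometry
    def spec_of(lake):
        if isinstance(lake_specs, pd.DataFrame):
            row = lake_specs[lake_specs["lake"] == lake].iloc[0]
            return row["depth_at_site"], row["volume"]
        spec = lake_specs[lake]
        if isinstance(spec, dict):
            return spec["depth_at_site"], spec["volume"]
        return spec.depth_at_site, spec.volume

    depth = {}
    volume = {}
    for lake in out["lake"].unique():
        depth[lake], volume[lake] = spec_of(lake)
    out["Lake_Depth"] = out["lake"].map(depth)
    out["Lake_Volume"] = out["lake"].map(volume)

    # time trend (days since each lake's first community date) and month
    first = community.groupby("lake")["date"].min()
    out["Time_trend"] = (out["date"] - out["lake"].map(first)).dt.days
    out["Seasonality"] = out["date"].dt.month

    n_missing = int(out[FEATURE_COLUMNS].isna().sum().sum())
    if n_missing:
        log.info("feature table has %d missing driver cells", n_missing)
    return out[["lake", "date"] + FEATURE_COLUMNS + ["response"]]
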