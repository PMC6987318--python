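"""Size-abundance relationship (SAR) slope estimation.

A community sample is the set of taxa counted in one lake on one date, each
taxon contributing a single point (its density in cells L^-1 against its mean
cell biovolume in um^3).  The SAR is the power law ``density = a * size^b``,
fit as an ordinary least-squares line in log10-log10 space over the taxa
present (no binning; every taxon is one point regardless of its density).

Uncertainty on the exponent comes from delete-d jackknife subsampling of the
species pool: the line is refit ``reps`` times on random 70% subsets of the
taxa, without replacement, giving a median slope and a 95% interval.  The raw
percentile interval of subsample slopes is too narrow (its dispersion is
``se * sqrt(n/m - 1)``, not ``se``), so by default the deviations from the
median are rescaled by ``sqrt(m / (n - m))`` — the standard subsampling
calibration; the uncalibrated percentile interval remains available.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

log = logging.getLogger(__name__)

__all__ = [
    "CommunitySample",
    "SlopeEstimate",
    "SizeAbundanceSlope",
    "fit_sar",
    "bootstrap_sar",
    "fit_all_samples",
    "quartile_series",
    "exclude_class",
]

_MAX_SEED = 2**31 - 1


@dataclass
class CommunitySample:
    """One lake-date's taxon densities joined to taxon biovolumes."""

    lake: str
    date: object
    taxon_id: np.ndarray
    density: np.ndarray       # cells per litre, > 0 (absent taxa omitted)
    biovolume: np.ndarray     # um^3, > 0
    class_label: np.ndarray | None = None

    def __post_init__(self):
        self.taxon_id = np.asarray(self.taxon_id)
        self.density = np.asarray(self.density, dtype=float)
        self.biovolume = np.asarray(self.biovolume, dtype=float)
        if np.any(self.density <= 0):
            raise ValueError("densities must be strictly positive")
        if np.any(self.biovolume <= 0):
            raise ValueError("biovolumes must be strictly positive")

    @property
    def n_taxa(self) -> int:
        return self.density.size


@dataclass
class SlopeEstimate:
    """Slope of one lake-date SAR with subsampling uncertainty."""

    lake: str
    date: object
    a: float
    b_observed: float
    b_median: float
    ci_low: float
    ci_high: float
    n_taxa: int
    r_squared: float
    n_boot: int
    usable: bool = True


def _extract(sample) -> tuple[np.ndarray, np.ndarray]:
    """Log10 size and log10 density arrays from any accepted sample form."""
    if isinstance(sample, CommunitySample):
        size, dens = sample.biovolume, sample.density
    elif isinstance(sample, pd.DataFrame):
        size = sample["biovolume_um3"].to_numpy(dtype=float)
        dens = sample["density_cells_per_L"].to_numpy(dtype=float)
    else:
        size, dens = (np.asarray(v, dtype=float) for v in sample)
    if np.any(size <= 0) or np.any(dens <= 0):
        raise ValueError("sizes and densities must be strictly positive")
    return np.log10(size), np.log10(dens)


class SizeAbundanceSlope(BaseEstimator, RegressorMixin):
    """OLS power-law slope with delete-d jackknife subsampling.

    Operates in log10 space: ``fit`` expects ``X`` as log10 biovolume
    (shape ``(n,)`` or ``(n, 1)``) and ``y`` as log10 density, and estimates
    the line ``y = a + b x``.

    Parameters
    ----------
    frac : float
        Fraction of taxa refit per replicate (0.70: each round keeps
        ``round(frac * n)`` taxa, drawn without replacement).
    reps : int
        Number of subsample replicates (999).
    ci : float
        Interval mass (0.95).
    ci_method : {"calibrated", "percentile"}
        "calibrated" (default) rescales percentile deviations from the
        median by ``sqrt(m / (n - m))`` so the interval attains its nominal
        coverage; "percentile" is the raw interval of replicate slopes.
    random_state : int or None

    Attributes
    ----------
    intercept_, slope_ : full-sample OLS coefficients (a, b).
    slope_median_, ci_ : median and interval of subsample slopes.
    r_squared_, n_taxa_, replicate_slopes_
    """

    def __init__(self, frac: float = 0.70, reps: int = 999, ci: float = 0.95,
                 ci_method: str = "calibrated",
                 random_state: int | None = None):
        self.frac = frac
        self.reps = reps
        self.ci = ci
        self.ci_method = ci_method
        self.random_state = random_state

    @staticmethod
    def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
        xm, ym = x.mean(), y.mean()
        sxx = np.sum((x - xm) ** 2)
        if sxx == 0:
            raise ValueError("degenerate design: all sizes identical")
        b = float(np.sum((x - xm) * (y - ym)) / sxx)
        a = float(ym - b * xm)
        resid = y - (a + b * x)
        sst = np.sum((y - ym) ** 2)
        r2 = 1.0 if sst == 0 else float(1.0 - np.sum(resid ** 2) / sst)
        return a, b, r2

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        n = x.size
        if n < 3 or np.unique(x).size < 2:
            raise ValueError("need >= 3 taxa with >= 2 distinct sizes")
        if not 0 < self.frac <= 1:
            raise ValueError("frac must be in (0, 1]")
        if self.ci_method not in ("calibrated", "percentile"):
            raise ValueError("ci_method must be 'calibrated' or 'percentile'")
        self.intercept_, self.slope_, self.r_squared_ = self._ols(x, y)
        self.n_taxa_ = n

        m = int(round(self.frac * n))
        if m < 3:
            raise ValueError("subsample size round(frac*n) must be >= 3")
        rng = np.random.default_rng(self.random_state)
        # replicate subsets without replacement, vectorised over replicates
        order = np.argsort(rng.random((self.reps, n)), axis=1)[:, :m]
        xs = x[order]
        ys = y[order]
        xm = xs.mean(axis=1, keepdims=True)
        ym = ys.mean(axis=1, keepdims=True)
        sxx = np.sum((xs - xm) ** 2, axis=1)
        sxy = np.sum((xs - xm) * (ys - ym), axis=1)
        ok = sxx > 0
        slopes = np.full(self.reps, np.nan)
        slopes[ok] = sxy[ok] / sxx[ok]
        slopes = slopes[~np.isnan(slopes)]

        med = float(np.median(slopes))
        alpha = 100 * (1 - self.ci) / 2
        qlo, qhi = np.percentile(slopes, [alpha, 100 - alpha])
        if self.ci_method == "calibrated" and m < n:
            scale = np.sqrt(m / (n - m))
            lo = med + (qlo - med) * scale
            hi = med + (qhi - med) * scale
        elif m == n:
            lo = hi = med
        else:
            lo, hi = float(qlo), float(qhi)
        self.slope_median_ = med
        self.ci_ = (float(lo), float(hi))
        self.replicate_slopes_ = slopes
        self.m_ = m
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x


def fit_sar(sample) -> tuple[float, float, float]:
    """OLS fit of log10 density on log10 biovolume: returns (a, b, r2)."""
    x, y = _extract(sample)
    if x.size < 3 or np.unique(x).size < 2:
        raise ValueError("need >= 3 taxa with >= 2 distinct biovolumes")
    return SizeAbundanceSlope._ols(x, y)


def bootstrap_sar(sample, frac: float = 0.70, reps: int = 999,
                  ci: float = 0.95, seed: int | None = None,
                  ci_method: str = "calibrated") -> SlopeEstimate:
    """Full-sample slope plus subsampled median and confidence interval."""
    lake = getattr(sample, "lake", "")
    date = getattr(sample, "date", None)
    x, y = _extract(sample)
    n = x.size
    m = int(round(frac * n)) if n else 0
    if n < 3 or np.unique(x).size < 2 or m < 3:
        log.warning("sample %s/%s unusable for slope fitting (n=%d)",
                    lake, date, n)
        return SlopeEstimate(lake, date, np.nan, np.nan, np.nan, np.nan,
                             np.nan, n, np.nan, reps, usable=False)
    est = SizeAbundanceSlope(frac=frac, reps=reps, ci=ci,
                             ci_method=ci_method, random_state=seed)
    est.fit(x, y)
    return SlopeEstimate(lake, date, est.intercept_, est.slope_,
                         est.slope_median_, est.ci_[0], est.ci_[1], n,
                         est.r_squared_, reps)


def fit_all_samples(community: pd.DataFrame, taxa: pd.DataFrame,
                    frac: float = 0.70, reps: int = 999, ci: float = 0.95,
                    seed: int | None = None,
                    ci_method: str = "calibrated") -> pd.DataFrame:
    """Slope estimates for every (lake, date) community sample.

    ``community`` has columns lake, date, taxon_id, density_cells_per_L;
    ``taxa`` maps taxon_id to biovolume_um3.  Samples with fewer than three
    taxa or fewer than two distinct sizes are dropped with a warning.
    """
    merged = community.merge(taxa[["taxon_id", "biovolume_um3"]],
                             on="taxon_id", how="left", validate="m:1")
    if merged["biovolume_um3"].isna().any():
        bad = merged.loc[merged["biovolume_um3"].isna(), "taxon_id"].unique()
        raise ValueError(f"taxa without biovolume: {list(bad)[:5]}")
    rng = np.random.default_rng(seed)
    rows = []
    n_dropped = 0
    for (lake, date), grp in merged.sort_values(["lake", "date"]).groupby(
            ["lake", "date"], sort=True):
        sub_seed = int(rng.integers(_MAX_SEED))
        est = bootstrap_sar(
            CommunitySample(lake, date, grp["taxon_id"].to_numpy(),
                            grp["density_cells_per_L"].to_numpy(),
                            grp["biovolume_um3"].to_numpy()),
            frac=frac, reps=reps, ci=ci, seed=sub_seed, ci_method=ci_method)
        if not est.usable:
            n_dropped += 1
            continue
        rows.append((lake, date, est.a, est.b_observed, est.b_median,
                     est.ci_low, est.ci_high, est.n_taxa, est.r_squared,
                     est.n_boot))
    if n_dropped:
        log.warning("dropped %d lake-dates with too few taxa", n_dropped)
    return pd.DataFrame(rows, columns=["lake", "date", "a", "b_observed",
                                       "b_median", "ci_low", "ci_high",
                                       "n_taxa", "r_squared", "n_boot"])


def quartile_series(community: pd.DataFrame,
                    taxa: pd.DataFrame) -> pd.DataFrame:
    """Summed densities of the smallest and largest biovolume quartiles.

    Thresholds are the 25th/75th percentiles (linear interpolation) of the
    distinct taxon biovolumes over the whole database, computed once; per
    date, Q1 sums the densities of taxa strictly below the low threshold and
    Q4 those strictly above the high threshold.  The Q4/Q1 ratio is 0 when no
    large taxon is present and undefined (NaN) when Q1 is empty.
    """
    pool = np.unique(taxa["biovolume_um3"].to_numpy(dtype=float))
    t_lo, t_hi = np.percentile(pool, [25, 75])
    merged = community.merge(taxa[["taxon_id", "biovolume_um3"]],
                             on="taxon_id", how="left")
    merged["_q1"] = np.where(merged["biovolume_um3"] < t_lo,
                             merged["density_cells_per_L"], 0.0)
    merged["_q4"] = np.where(merged["biovolume_um3"] > t_hi,
                             merged["density_cells_per_L"], 0.0)
    out = (merged.groupby(["lake", "date"], sort=True)[["_q1", "_q4"]]
           .sum().reset_index()
           .rename(columns={"_q1": "q1_total", "_q4": "q4_total"}))
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio_q4_q1"] = np.where(out["q1_total"] > 0,
                                      out["q4_total"] / out["q1_total"],
                                      np.nan)
    out["threshold_low"] = t_lo
    out["threshold_high"] = t_hi
    return out


def exclude_class(community: pd.DataFrame, taxa: pd.DataFrame,
                  class_label: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove all taxa of a class from the pool and the counts.

    Used for the sensitivity test that re-runs the whole analysis without a
    taxonomic group (e.g. the cyanobacteria) to check that it does not drive
    the detected patterns.
    """
    classes = set(taxa["class"].unique())
    if class_label not in classes:
        raise ValueError(
            f"unknown class {class_label!r}; available: {sorted(classes)}")
    keep = taxa.loc[taxa["class"] != class_label, "taxon_id"]
    taxa_f = taxa[taxa["taxon_id"].isin(keep)].reset_index(drop=True)
    community_f = community[community["taxon_id"].isin(keep)].reset_index(
        drop=True)
    return community_f, taxa_f
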