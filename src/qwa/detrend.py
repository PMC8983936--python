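"""The two standardizations used by the analysis.

*Indexing* (``X_ind``): each annual series (one trait, one sector, one tree,
or one calendar month of climate) is divided by a fitted cubic smoothing
spline whose amplitude frequency response equals 50% at a chosen wavelength
(default 30 years).  This removes low-frequency variation — ontogenetic
trends, disturbance — while preserving inter-annual signal, the standard
flexible detrending of dendrochronology.

The spline is defined here by its frequency-response *contract*, not by any
package's internal smoothing parameter: the penalty weight λ of the cubic
smoothing spline is calibrated numerically so that fitting a pure sinusoid
of the cutoff wavelength returns half its amplitude.  Calibration is
deterministic and cached per cutoff.

*Profile standardization* (``X_std``): intra-ring sector values are divided
by the whole-ring value of the same trait in the same tree and year,
isolating the within-ring shape from inter-annual level shifts.
"""

from __future__ import annotations

import functools
import math

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .anatomy import TRAIT_NAMES
from .exceptions import ParameterError, SeriesTooShortError, ValidationError

MIN_SERIES_LENGTH = 10


def _amplitude_ratio(lam: float, period: float, span: int) -> float:
    """Fitted/input amplitude for a unit sinusoid of `period` over `span` years.

    Measured on the central span to avoid spline edge effects, by projecting
    the fitted values back onto the sine/cosine pair.
    """
    t = np.arange(1.0, span + 1.0)
    y = np.sin(2.0 * math.pi * t / period)
    fitted = make_smoothing_spline(t, y, lam=lam)(t)
    lo, hi = span // 6, span - span // 6
    tt = t[lo:hi]
    design = np.column_stack(
        [np.sin(2.0 * math.pi * tt / period), np.cos(2.0 * math.pi * tt / period), np.ones_like(tt)]
    )
    coef, *_ = np.linalg.lstsq(design, fitted[lo:hi], rcond=None)
    return float(np.hypot(coef[0], coef[1]))


@functools.lru_cache(maxsize=32)
def calibrate_spline_lambda(cutoff_years: float) -> float:
    """Penalty weight λ giving a 50% amplitude response at `cutoff_years`.

    Bisection on log λ against sinusoid probes on a span of
    max(300, 10×cutoff) annual steps; the response is monotone decreasing
    in λ.  The analytic infinite-sample value (cutoff/2π)⁴ seeds the
    bracket.
    """
    if cutoff_years <= 0:
        raise ParameterError("cutoff_years must be > 0")
    span = int(max(300, round(10 * cutoff_years)))
    guess = (cutoff_years / (2.0 * math.pi)) ** 4
    lo, hi = math.log(guess) - 6.0, math.log(guess) + 6.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _amplitude_ratio(math.exp(mid), cutoff_years, span) > 0.5:
            lo = mid  # too little smoothing: increase λ
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    return math.exp(0.5 * (lo + hi))


def smoothing_spline_fit(years, values, cutoff_years: float = 30.0) -> np.ndarray:
    """Fitted values of the frequency-calibrated cubic smoothing spline.

    NaNs in `values` are excluded from the fit (no interpolation of missing
    data); fitted values are still returned at every input year.  Constant
    series are reproduced exactly (the penalty vanishes on a constant).
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < MIN_SERIES_LENGTH:
        raise SeriesTooShortError(
            f"need >= {MIN_SERIES_LENGTH} non-missing values, got {int(ok.sum())}"
        )
    x, y = years[ok], values[ok]
    order = np.argsort(x)
    if np.ptp(y) == 0.0:
        return np.full_like(values, y[0])
    lam = calibrate_spline_lambda(float(cutoff_years))
    spline = make_smoothing_spline(x[order], y[order], lam=lam)
    return np.asarray(spline(years), dtype=float)


def index_values(years, values, cutoff_years: float = 30.0) -> np.ndarray:
    """X_ind = observed / spline-fitted per year; non-positive fits → NaN."""
    values = np.asarray(values, dtype=float)
    fitted = smoothing_spline_fit(years, values, cutoff_years)
    out = np.full_like(values, np.nan)
    ok = np.isfinite(values) & (fitted > 0)
    out[ok] = values[ok] / fitted[ok]
    return out


def index_traits(traits: pd.DataFrame, cutoff_years: float = 30.0,
                 traits_to_index: list[str] | None = None) -> pd.DataFrame:
    """Index every (site, tree, sector, trait) annual series of a trait table.

    Takes a :func:`qwa.anatomy.sector_traits` table (discarded rows carry
    NaN and are skipped by the fit) and returns a long table with columns
    site_id, tree_id, sector, trait, year, value, x_ind.  Series shorter
    than the spline minimum are dropped silently.
    """
    names = traits_to_index or TRAIT_NAMES
    long = traits.melt(
        id_vars=["site_id", "tree_id", "year", "sector"],
        value_vars=[c for c in names if c in traits.columns],
        var_name="trait", value_name="value",
    )
    parts = []
    for _, grp in long.groupby(["site_id", "tree_id", "sector", "trait"], sort=True):
        grp = grp.sort_values("year").copy()
        try:
            grp["x_ind"] = index_values(grp["year"], grp["value"], cutoff_years)
        except SeriesTooShortError:
            continue
        parts.append(grp)
    if not parts:
        return pd.DataFrame(columns=["site_id", "tree_id", "year", "sector", "trait", "value", "x_ind"])
    return pd.concat(parts, ignore_index=True)


def index_climate(climate: pd.DataFrame, cutoff_years: float = 30.0) -> pd.DataFrame:
    """Index each calendar month's across-year series independently.

    Returns the climate table with added ``tmean_ind`` and ``prec_ind``
    columns.
    """
    miss = [c for c in ("year", "month", "tmean_c", "prec_mm") if c not in climate.columns]
    if miss:
        raise ValidationError(f"climate table missing column(s): {', '.join(miss)}")
    out = climate.sort_values(["year", "month"]).reset_index(drop=True).copy()
    for src, dst in (("tmean_c", "tmean_ind"), ("prec_mm", "prec_ind")):
        out[dst] = np.nan
        for _, grp in out.groupby("month"):
            grp = grp.sort_values("year")
            out.loc[grp.index, dst] = index_values(grp["year"], grp[src], cutoff_years)
    return out


def standardize_profiles(traits: pd.DataFrame) -> pd.DataFrame:
    """X_std = sector value / whole-ring (sector 0) value, same tree-year.

    The denominator is the ring-level trait computed over the pooled
    vessels, not the mean of sector values.  Discarded sectors and
    tree-years without a ring-level value yield NaN.  Returns a long table
    with columns site_id, tree_id, year, sector, trait, n_vessels, value,
    x_std.
    """
    sectors = traits[traits["sector"] > 0]
    ring = traits[traits["sector"] == 0][["site_id", "tree_id", "year"] + TRAIT_NAMES]
    long = sectors.melt(
        id_vars=["site_id", "tree_id", "year", "sector", "n_vessels"],
        value_vars=TRAIT_NAMES, var_name="trait", value_name="value",
    )
    ring_long = ring.melt(
        id_vars=["site_id", "tree_id", "year"], value_vars=TRAIT_NAMES,
        var_name="trait", value_name="ring_value",
    )
    merged = long.merge(ring_long, on=["site_id", "tree_id", "year", "trait"], how="left")
    with np.errstate(invalid="ignore", divide="ignore"):
        merged["x_std"] = np.where(
            merged["ring_value"] > 0, merged["value"] / merged["ring_value"], np.nan
        )
    return merged.drop(columns=["ring_value"])
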