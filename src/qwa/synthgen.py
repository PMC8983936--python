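"""Synthetic multi-site vessel, ring and climate data.

The generator emulates the statistical structure of diffuse-porous beech
rings that the downstream analysis assumes, so every pipeline stage is
testable without field data:

* vessel lumen area declines across the ring — a plateau over the first
  half, then a roughly linear decline to a configurable fraction (default
  0.3) of the plateau level at the ring end;
* vessel density rises toward the ring end, peaking near a configurable
  relative position (default 0.9), produced by mixing uniform positions
  with a Beta component whose mode sits at the peak;
* lumen areas carry an ontogenetic trend (fractional increase per year of
  cambial age), a per-site multiplicative offset, and lognormal
  measurement/biological noise;
* an inter-annual climate signal enters through the summer (June–August)
  precipitation anomaly acting multiplicatively on early-ring (relative
  position < 0.5) vessel sizes — the strongest kind of association such
  analyses report;
* climate is a CRU-like complete monthly grid: sinusoidal seasonal
  temperature with AR(1) inter-annual anomalies, seasonal precipitation
  means with lognormal anomalies.

Reproducibility: a single master seed; the climate stream and each tree's
stream are derived deterministically via ``numpy.random.SeedSequence``
spawn keys, so identical configs give byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError

#: plateau-level expected lumen area (μm²) before trends/offsets/noise
BASE_LUMEN_AREA_UM2 = 2200.0
#: tangential width (μm) of the analyzed image strip; with the default
#: vessel counts this yields RVA ≈ 0.25 and VD ≈ 130 mm⁻², realistic for beech
ANALYZED_STRIP_WIDTH_UM = 900.0
#: concentration of the Beta component placing the vessel-density peak
VD_PEAK_KAPPA = 20.0
#: weight of the peaked Beta component in the position mixture
VD_PEAK_WEIGHT = 0.3
#: log-scale climate effect per unit JJA-precipitation z-score at climate_signal = 1
CLIMATE_LOG_EFFECT = 0.3
#: coefficient of variation of inter-annual ring-width variability
TRW_CV = 0.2


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic stand."""

    n_sites: int = 3
    trees_per_site: int = 5
    year_start: int = 1968
    year_end: int = 2004
    vessels_per_ring_mean: float = 150.0
    ring_width_mean_um: float = 1300.0
    # intra-ring expected-size profile: flat to `profile_plateau_end`, then
    # linear decline to `end_fraction` of the plateau level at position 1
    profile_plateau_end: float = 0.5
    vd_peak_position: float = 0.9
    end_fraction: float = 0.3
    ontogenetic_trend: float = 0.005  # fractional VA increase per cambial year
    climate_signal: float = 0.7  # effect size in [0, 1]
    site_offsets: tuple[float, ...] | None = None  # default: 1.0, 1.1, 0.95, ...
    noise_cv: float = 0.3
    group_fraction: float = 0.25  # fraction of vessels placed in multi-vessel groups
    seed: int = 0

    def __post_init__(self):
        if self.year_end <= self.year_start:
            raise ParameterError("year_end must be > year_start")
        if min(self.n_sites, self.trees_per_site) < 1 or self.vessels_per_ring_mean < 1:
            raise ParameterError("counts must be >= 1")
        if not 0.0 <= self.climate_signal <= 1.0:
            raise ParameterError("climate_signal must be in [0, 1]")
        if self.noise_cv <= 0:
            raise ParameterError("noise_cv must be > 0")
        if not 0.0 < self.vd_peak_position < 1.0 or not 0.0 < self.profile_plateau_end < 1.0:
            raise ParameterError("profile positions must lie in (0, 1)")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def site_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_sites)]

    def site_offset(self, site_index: int) -> float:
        if self.site_offsets is not None:
            return self.site_offsets[site_index % len(self.site_offsets)]
        return (1.0, 1.1, 0.95)[site_index % 3] if self.n_sites <= 3 else 1.0 + 0.05 * math.sin(site_index)


def expected_profile(rel_position, config: SyntheticConfig) -> np.ndarray:
    """Expected lumen-area multiplier at a relative position (plateau = 1)."""
    p = np.asarray(rel_position, dtype=float)
    a, f = config.profile_plateau_end, config.end_fraction
    decline = 1.0 + (f - 1.0) * (p - a) / (1.0 - a)
    return np.where(p <= a, 1.0, decline)


def generate_climate(config: SyntheticConfig) -> pd.DataFrame:
    """Monthly climate grid: year, month, tmean_c, prec_mm."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    years = config.years
    months = np.arange(1, 13)
    # seasonal cycles loosely following a southern-European mountain climate;
    # the baseline keeps every month's temperature positive because the
    # ratio-based indexing downstream is defined for positive series only
    seasonal_t = 12.0 + 8.0 * np.cos(2.0 * math.pi * (months - 7) / 12.0)
    seasonal_p = np.array([80, 70, 75, 85, 90, 70, 50, 60, 90, 110, 120, 95], dtype=float)
    # AR(1) annual temperature anomaly
    anomaly = np.zeros(len(years))
    eps = rng.normal(0.0, 0.7, len(years))
    for i in range(len(years)):
        anomaly[i] = (0.3 * anomaly[i - 1] if i else 0.0) + eps[i]
    rows = []
    sigma_p = 0.4
    for yi, year in enumerate(years):
        t_noise = rng.normal(0.0, 0.8, 12)
        p_anom = rng.lognormal(-sigma_p**2 / 2.0, sigma_p, 12)
        for mi, month in enumerate(months):
            rows.append(dict(year=int(year), month=int(month),
                             tmean_c=float(seasonal_t[mi] + anomaly[yi] + t_noise[mi]),
                             prec_mm=float(seasonal_p[mi] * p_anom[mi])))
    return pd.DataFrame(rows)


def _jja_prec_z(climate: pd.DataFrame, years: np.ndarray) -> np.ndarray:
    jja = climate[climate["month"].isin((6, 7, 8))].groupby("year")["prec_mm"].sum()
    v = jja.reindex(years).to_numpy(dtype=float)
    return (v - v.mean()) / v.std()


def _assign_groups(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Group labels: ~`fraction` of vessels in groups of 2–3, rest solitary."""
    labels = np.array([""] * n, dtype=object)
    n_grouped = int(round(fraction * n))
    if n_grouped < 2:
        return labels
    chosen = rng.choice(n, size=n_grouped, replace=False)
    g, i = 0, 0
    while i < n_grouped - 1:
        size = int(rng.integers(2, 4))
        size = min(size, n_grouped - i)
        if size < 2:
            break
        labels[chosen[i:i + size]] = f"g{g}"
        g += 1
        i += size
    return labels


def generate_stand(
    config: SyntheticConfig, climate: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vessel and ring tables for all sites and trees.

    Returns ``(vessels, rings)`` in the :mod:`qwa.dataio` dialects.
    """
    years = config.years
    have = climate.groupby("year").size()
    if not set(years).issubset(set(have.index[have == 12])):
        raise ParameterError("climate table does not cover the configured years")
    z = _jja_prec_z(climate, years)
    a_beta = 1.0 + config.vd_peak_position * VD_PEAK_KAPPA
    b_beta = 1.0 + (1.0 - config.vd_peak_position) * VD_PEAK_KAPPA
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    vessel_rows, ring_rows = [], []
    for si, site in enumerate(config.site_ids()):
        offset = config.site_offset(si)
        for ti in range(config.trees_per_site):
            tree = f"T{si + 1}{ti + 1:02d}"
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(1, si, ti))
            )
            for yi, year in enumerate(years):
                n = int(rng.poisson(config.vessels_per_ring_mean))
                n = max(n, 1)
                peaked = rng.random(n) < VD_PEAK_WEIGHT
                pos = np.where(peaked, rng.beta(a_beta, b_beta, n), rng.random(n))
                mean_area = (
                    BASE_LUMEN_AREA_UM2
                    * expected_profile(pos, config)
                    * (1.0 + config.ontogenetic_trend) ** yi
                    * offset
                )
                early = pos < config.profile_plateau_end
                climate_mult = np.where(
                    early, np.exp(config.climate_signal * CLIMATE_LOG_EFFECT * z[yi]), 1.0
                )
                noise = rng.lognormal(-sigma**2 / 2.0, sigma, n)
                areas = mean_area * climate_mult * noise
                trw = config.ring_width_mean_um * rng.lognormal(-TRW_CV**2 / 2.0, TRW_CV)
                groups = _assign_groups(n, config.group_fraction, rng)
                for vi in range(n):
                    vessel_rows.append(
                        dict(site_id=site, tree_id=tree, year=int(year),
                             vessel_id=f"v{vi + 1:04d}",
                             lumen_area_um2=float(areas[vi]),
                             rel_position=float(pos[vi]),
                             group_id=groups[vi] or pd.NA)
                    )
                ring_rows.append(
                    dict(site_id=site, tree_id=tree, year=int(year),
                         trw_um=float(trw),
                         xylem_area_um2=float(trw * ANALYZED_STRIP_WIDTH_UM))
                )
    return pd.DataFrame(vessel_rows), pd.DataFrame(ring_rows)


def generate_all(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience: (vessels, rings, climate) from one config."""
    climate = generate_climate(config)
    vessels, rings = generate_stand(config, climate)
    return vessels, rings, climate
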