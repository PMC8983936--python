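"""Intra-ring sectorization, quality filters and anatomical trait computation.

Each dated ring is divided into *k* equal-width tangential sectors (k = 5 or
10) along the relative radial position (0 = inner ring border, earliest
formed wood).  Per retained sector, and for the whole ring (sector 0), the
following traits are computed from the vessel list:

========  ==================================================================
trait     definition
========  ==================================================================
VA        mean vessel lumen area (μm²)
VA95      95th percentile of lumen area (linear-interpolation quantile, μm²)
DH        hydraulically weighted mean diameter Σd⁵/Σd⁴ over equivalent
          circle diameters (μm)
KH        theoretical hydraulic conductivity per unit length from the
          Hagen–Poiseuille law, (π ρ / 128 η) Σ dᵢ⁴, water at 20 °C
          (kg·m·MPa⁻¹·s⁻¹)
VD        vessel density, n per analyzed sector area (mm⁻²)
RVA       relative vessel area, Σ lumen area / analyzed sector area
VG        vessel grouping index, n vessels / n vessel groups (a solitary
          vessel is a group of one)
========  ==================================================================

Sector analyzed area is the ring's analyzed xylem area divided by k (sectors
are equal-width bands of the analyzed image).

Two quality filters mirror standard practice for this kind of data: sectors
with fewer than five vessels are discarded, and a whole ring is discarded
when any of its sector widths (ring width / k, μm) does not exceed the
maximum vessel radius found in that sector (the sectorization is then
narrower than single conduits and positions are unreliable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ValidationError

#: density of pure water at 20 °C, kg·m⁻³
RHO_WATER = 998.2
#: dynamic viscosity of pure water at 20 °C, MPa·s
ETA_WATER = 1.002e-9
#: Hagen–Poiseuille prefactor π ρ / (128 η), kg·m⁻⁵·MPa⁻¹·s⁻¹
_HP_PREFACTOR = math.pi * RHO_WATER / (128.0 * ETA_WATER)

#: default wall allowance (μm) when vessel groups must be detected from
#: radial positions: two vessels belong to one group if their centres are
#: closer than r_i + r_j + this allowance.
DEFAULT_WALL_ALLOWANCE_UM = 3.0

TRAIT_NAMES = ["VA", "VA95", "DH", "KH", "VD", "RVA", "VG"]


@dataclass(frozen=True)
class SectorScheme:
    """k equal-width radial sectors on [0, 1]; 0–50% is early-formed wood."""

    k: int = 10
    efw_lfw_split: float = 0.5

    def __post_init__(self):
        if self.k < 1:
            raise ParameterError("sector count k must be >= 1")

    @property
    def boundaries(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.k + 1)


def equivalent_diameter(lumen_area):
    """Diameter (μm) of the circle with the same area (μm²)."""
    a = np.asarray(lumen_area, dtype=float)
    if np.any(a <= 0):
        raise ParameterError("lumen area must be > 0")
    return 2.0 * np.sqrt(a / math.pi)


def assign_sectors(vessels: pd.DataFrame, scheme: SectorScheme) -> pd.DataFrame:
    """Label each vessel with its sector (1..k, half-open bins, last closed).

    Membership is by vessel centroid: sector = ⌊rel_position·k⌋ + 1, with
    rel_position = 1 mapped into sector k.
    """
    out = vessels.copy()
    s = np.floor(out["rel_position"].to_numpy() * scheme.k).astype(int) + 1
    out["sector"] = np.minimum(s, scheme.k)
    return out


def detect_groups(
    positions_um: np.ndarray, radii_um: np.ndarray, wall_allowance_um: float = DEFAULT_WALL_ALLOWANCE_UM
) -> np.ndarray:
    """Single-link grouping of vessels along the radial axis.

    Two vessels join one group when their centres are closer than the sum of
    their radii plus a wall allowance.  Returns integer group labels.
    Intended as a fallback when the measurement software exported no group
    ids; with only radial centroid positions available this is a 1-D
    approximation of the planar contact rule.
    """
    order = np.argsort(positions_um, kind="stable")
    labels = np.empty(len(positions_um), dtype=int)
    current = 0
    prev_idx = None
    for idx in order:
        if prev_idx is not None:
            gap = positions_um[idx] - positions_um[prev_idx]
            if gap >= radii_um[idx] + radii_um[prev_idx] + wall_allowance_um:
                current += 1
        labels[idx] = current
        prev_idx = idx
    return labels


def _ring_lookup(rings: pd.DataFrame) -> pd.DataFrame:
    return rings.set_index(["site_id", "tree_id", "year"])


def filter_sectors(
    sectorized: pd.DataFrame, rings: pd.DataFrame, scheme: SectorScheme, min_vessels: int = 5
) -> pd.DataFrame:
    """Apply the two quality filters; returns per-(ring, sector) flags.

    Output columns: site_id, tree_id, year, sector, n_vessels, discarded,
    reason (``min_vessels``, ``sector_width`` or empty).  A ``sector_width``
    discard applies to every sector of the affected ring.
    """
    ring_idx = _ring_lookup(rings)
    rows = []
    for (site, tree, year), ring_vessels in sectorized.groupby(
        ["site_id", "tree_id", "year"], sort=True
    ):
        try:
            trw = float(ring_idx.loc[(site, tree, year), "trw_um"])
        except KeyError:
            raise ValidationError(f"no ring record for vessel ring ({site}, {tree}, {year})")
        sector_width = trw / scheme.k
        radii = equivalent_diameter(ring_vessels["lumen_area_um2"].to_numpy()) / 2.0
        by_sector = ring_vessels.groupby("sector")
        counts = by_sector.size()
        max_radius = pd.Series(radii, index=ring_vessels.index).groupby(ring_vessels["sector"]).max()
        ring_discarded = bool((sector_width <= max_radius).any())
        for sector in range(1, scheme.k + 1):
            n = int(counts.get(sector, 0))
            if ring_discarded:
                discarded, reason = True, "sector_width"
            elif n < min_vessels:
                discarded, reason = True, "min_vessels"
            else:
                discarded, reason = False, ""
            rows.append(
                dict(site_id=site, tree_id=tree, year=year, sector=sector,
                     n_vessels=n, discarded=discarded, reason=reason)
            )
    return pd.DataFrame(rows)


def _vg(group_ids: pd.Series, positions_um: np.ndarray, radii_um: np.ndarray,
        wall_allowance_um: float) -> float:
    """Grouping index n/groups; vessels without a group id are solitary."""
    n = len(group_ids)
    if group_ids.notna().any():
        labelled = group_ids.dropna()
        n_groups = labelled.nunique() + int(group_ids.isna().sum())
    else:
        n_groups = len(np.unique(detect_groups(positions_um, radii_um, wall_allowance_um)))
    return n / n_groups


def _traits_from_arrays(areas: np.ndarray, analyzed_area_um2: float, vg: float) -> dict:
    d = 2.0 * np.sqrt(areas / math.pi)
    d4 = d**4
    return dict(
        VA=float(areas.mean()),
        VA95=float(np.percentile(areas, 95)),  # linear-interpolation quantile
        DH=float((d4 * d).sum() / d4.sum()),
        KH=float(_HP_PREFACTOR * ((d * 1e-6) ** 4).sum()),
        VD=float(len(areas) / (analyzed_area_um2 * 1e-6)),
        RVA=float(areas.sum() / analyzed_area_um2),
        VG=float(vg),
    )


def sector_traits(
    sectorized: pd.DataFrame,
    rings: pd.DataFrame,
    scheme: SectorScheme,
    min_vessels: int = 5,
    wall_allowance_um: float = DEFAULT_WALL_ALLOWANCE_UM,
    flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compute the trait vector per retained sector and per whole ring.

    Returns a table with one row per (site, tree, year, sector) where sector
    0 is the whole ring; discarded sectors keep their flags and carry NaN
    traits.  ``flags`` may pass a precomputed :func:`filter_sectors` result.
    """
    if flags is None:
        flags = filter_sectors(sectorized, rings, scheme, min_vessels=min_vessels)
    flag_idx = flags.set_index(["site_id", "tree_id", "year", "sector"])
    ring_idx = _ring_lookup(rings)
    rows = []
    for (site, tree, year), ring_vessels in sectorized.groupby(
        ["site_id", "tree_id", "year"], sort=True
    ):
        ring = ring_idx.loc[(site, tree, year)]
        xylem_area = float(ring["xylem_area_um2"])
        trw = float(ring["trw_um"])
        areas_all = ring_vessels["lumen_area_um2"].to_numpy(dtype=float)
        pos_all = ring_vessels["rel_position"].to_numpy(dtype=float) * trw
        radii_all = equivalent_diameter(areas_all) / 2.0
        base = dict(site_id=site, tree_id=tree, year=year)
        ring_flags = flag_idx.loc[(site, tree, year)]
        ring_ok = not (ring_flags["reason"] == "sector_width").any()
        # sector 0: whole ring over all vessels and the full analyzed area
        vg0 = _vg(ring_vessels["group_id"], pos_all, radii_all, wall_allowance_um)
        rows.append(
            base | dict(sector=0, n_vessels=len(ring_vessels), discarded=not ring_ok,
                        reason="" if ring_ok else "sector_width")
            | (_traits_from_arrays(areas_all, xylem_area, vg0) if ring_ok
               else dict.fromkeys(TRAIT_NAMES, np.nan))
        )
        sector_area = xylem_area / scheme.k
        by_sector = dict(list(ring_vessels.groupby("sector")))
        for sector in range(1, scheme.k + 1):
            frow = ring_flags.loc[sector]
            rec = base | dict(sector=sector, n_vessels=int(frow["n_vessels"]),
                              discarded=bool(frow["discarded"]), reason=frow["reason"])
            if frow["discarded"]:
                rec |= dict.fromkeys(TRAIT_NAMES, np.nan)
            else:
                sv = by_sector[sector]
                areas = sv["lumen_area_um2"].to_numpy(dtype=float)
                pos = sv["rel_position"].to_numpy(dtype=float) * trw
                vg = _vg(sv["group_id"], pos, equivalent_diameter(areas) / 2.0, wall_allowance_um)
                rec |= _traits_from_arrays(areas, sector_area, vg)
            rows.append(rec)
    return pd.DataFrame(rows)


def ring_vessel_summary(rings: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Per-ring totals: vessel count, total lumen area, whole-ring RVA.

    Aggregates the sector-0 rows of a :func:`sector_traits` table back
    against the ring table.
    """
    ring0 = traits[traits["sector"] == 0]
    merged = ring0.merge(rings, on=["site_id", "tree_id", "year"], validate="1:1")
    out = merged[["site_id", "tree_id", "year", "n_vessels"]].copy()
    out["total_lumen_area_um2"] = merged["RVA"] * merged["xylem_area_um2"]
    out["rva"] = merged["RVA"]
    out["trw_um"] = merged["trw_um"]
    out["xylem_area_um2"] = merged["xylem_area_um2"]
    return out


def discard_report(flags: pd.DataFrame) -> pd.DataFrame:
    """Counts of discarded sectors and rings by reason."""
    n_sectors = len(flags)
    n_min = int((flags["reason"] == "min_vessels").sum())
    ring_groups = flags.groupby(["site_id", "tree_id", "year"])["reason"]
    n_rings = ring_groups.ngroups
    n_width = int((ring_groups.apply(lambda r: (r == "sector_width").any())).sum())
    return pd.DataFrame(
        [
            dict(unit="sector", reason="min_vessels", n_discarded=n_min, n_total=n_sectors),
            dict(unit="ring", reason="sector_width", n_discarded=n_width, n_total=n_rings),
        ]
    )
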