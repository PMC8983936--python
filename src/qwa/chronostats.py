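"""Site chronologies and their robustness statistics (Rbar, EPS).

A chronology is the across-tree mean of indexed series per year.  Its
robustness is summarized by Rbar — the mean pairwise Pearson correlation
between tree series over a common period — and the expressed population
signal

    EPS = n·Rbar / (1 + (n − 1)·Rbar),

the estimated fraction of the (hypothetical) population chronology variance
captured by an n-tree chronology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError

#: minimum paired years for a pairwise correlation to count toward Rbar
MIN_OVERLAP = 3


def eps_from_rbar(n: int, rbar: float) -> float:
    """Expressed population signal for n series with mean inter-correlation rbar."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    denom = 1.0 + (n - 1) * rbar
    if denom <= 0:
        return np.nan
    return n * rbar / denom


@dataclass
class ChronologyStats:
    site_id: str
    trait: str
    sector: int
    period: tuple[int, int]
    chronology: pd.Series  # year-indexed site mean of tree series
    rbar: float
    eps: float
    n_series: int


def build_chronology(
    tree_series: pd.DataFrame,
    common_period: tuple[int, int],
    site_id: str = "",
    trait: str = "",
    sector: int = 0,
) -> ChronologyStats:
    """Mean chronology + Rbar/EPS from a year × tree matrix of indexed values.

    `tree_series` has years as index and one column per tree.  Pairwise
    Pearson correlations are computed on the common period only,
    pairwise-complete; Rbar is their mean and the number of contributing
    series sets n in the EPS formula.
    """
    y0, y1 = common_period
    window = tree_series.loc[(tree_series.index >= y0) & (tree_series.index <= y1)]
    window = window.dropna(axis=1, how="all")
    n = window.shape[1]
    if n < 2:
        raise ParameterError("need >= 2 overlapping tree series in the common period")
    cols = window.columns
    cors = []
    for i in range(n):
        a = window[cols[i]]
        for j in range(i + 1, n):
            b = window[cols[j]]
            ok = a.notna() & b.notna()
            if ok.sum() >= MIN_OVERLAP:
                cors.append(float(np.corrcoef(a[ok], b[ok])[0, 1]))
    rbar = float(np.mean(cors)) if cors else np.nan
    return ChronologyStats(
        site_id=site_id,
        trait=trait,
        sector=sector,
        period=(int(y0), int(y1)),
        chronology=window.mean(axis=1).rename_axis("year"),
        rbar=rbar,
        eps=eps_from_rbar(n, rbar) if np.isfinite(rbar) else np.nan,
        n_series=n,
    )


def site_chronologies(
    indexed: pd.DataFrame, common_period: tuple[int, int]
) -> list[ChronologyStats]:
    """One chronology per (site, trait, sector) from an indexed long table.

    Expects the output of :func:`qwa.detrend.index_traits` (columns site_id,
    tree_id, year, sector, trait, x_ind).  Groups with fewer than two
    overlapping trees are skipped.
    """
    out = []
    for (site, trait, sector), grp in indexed.groupby(["site_id", "trait", "sector"], sort=True):
        matrix = grp.pivot_table(index="year", columns="tree_id", values="x_ind", aggfunc="first")
        try:
            out.append(build_chronology(matrix, common_period, site, trait, int(sector)))
        except ParameterError:
            continue
    return out


def chronology_table(stats: list[ChronologyStats], eps_threshold: float = 0.85) -> pd.DataFrame:
    """Tidy report: one row per chronology with Rbar, EPS and a low-EPS flag.

    The flag marks chronologies whose EPS falls below the conventional
    reporting threshold (default 0.85); it is informational only.
    """
    rows = [
        dict(
            site_id=s.site_id, trait=s.trait, sector=s.sector,
            period_start=s.period[0], period_end=s.period[1],
            n_series=s.n_series, rbar=s.rbar, eps=s.eps,
            low_eps=bool(np.isfinite(s.eps) and s.eps < eps_threshold),
        )
        for s in stats
    ]
    return pd.DataFrame(rows)


def chronology_frame(stats: list[ChronologyStats]) -> pd.DataFrame:
    """Long table of the site mean chronologies themselves."""
    parts = []
    for s in stats:
        df = s.chronology.rename("x_ind").reset_index()
        df.insert(0, "site_id", s.site_id)
        df.insert(1, "trait", s.trait)
        df.insert(2, "sector", s.sector)
        parts.append(df)
    if not parts:
        return pd.DataFrame(columns=["site_id", "trait", "sector", "year", "x_ind"])
    return pd.concat(parts, ignore_index=True)
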