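"""Permutation inference, multiple-testing correction, climate correlations
and extreme-year classification.

Group comparisons use Monte-Carlo permutation tests, appropriate for the
skewed, non-normal distributions of vessel traits:

* the *test of independence* uses the maximum absolute standardized group
  mean deviation as its statistic (the max-type form of the classical
  multivariate permutation framework), sensitive to any location difference
  among k ≥ 2 groups;
* *pairwise permutation t-tests* (post-hoc) permute group labels of each
  pair and use the Welch t statistic, with Benjamini–Hochberg correction
  across the pair family.

All Monte-Carlo p-values use the add-one estimator p = (b + 1)/(N + 1),
which is valid (never anti-conservative) at any permutation count.

Climate–growth association is Spearman rank correlation between indexed
sector chronologies and indexed monthly climate over a 24-month window
(previous-year January through current-year December), BH-corrected within
each trait × variable × site family.

Extreme years are the k years with the highest/lowest summer (June–August)
temperature means or precipitation sums, checked against the 85th/15th
percentiles of the study period and of the full series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import ParameterError

JJA_MONTHS = (6, 7, 8)


@dataclass(frozen=True)
class TestConfig:
    """Shared settings for all permutation tests."""

    __test__ = False  # not a pytest class

    alpha: float = 0.05
    n_permutations: int = 9999
    seed: int = 0
    adjust: str = "BH"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must be in (0, 1)")
        if self.n_permutations < 99:
            raise ParameterError("n_permutations must be >= 99")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TestResult:
    __test__ = False  # not a pytest class

    comparison: str
    groups: tuple
    statistic: float
    p_raw: float
    p_adj: float | None
    n_per_group: tuple
    note: str = ""


@dataclass
class ExtremeYearSet:
    variable: str  # "temperature" | "precipitation"
    tail: str  # "high" | "low"
    years: list[int]
    jja_values: list[float]
    percentile_ok_study: bool
    percentile_ok_full: bool


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_arrays(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ParameterError("need >= 2 groups")
    masks = [labels == g for g in uniq]
    sizes = np.array([m.sum() for m in masks])
    if np.any(sizes < 2):
        raise ParameterError("each group needs >= 2 values")
    return values, uniq, np.array(masks), sizes


def _max_abs_z(values_matrix: np.ndarray, masks: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Max over groups of |standardized group-sum deviation|, per row.

    For group g with n_g members of N values, the group sum under random
    labelling has mean n_g·μ and variance n_g(N−n_g)/(N−1)·σ² with μ, σ²
    the finite-population mean and variance of the row.
    """
    N = values_matrix.shape[1]
    mu = values_matrix.mean(axis=1)
    var = values_matrix.var(axis=1)  # population variance
    z_max = np.zeros(values_matrix.shape[0])
    for mask, n_g in zip(masks, sizes):
        s = values_matrix[:, mask].sum(axis=1)
        v = n_g * (N - n_g) / (N - 1) * var
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(s - n_g * mu) / np.sqrt(v)
        z_max = np.maximum(z_max, np.nan_to_num(z))
    return z_max


def permutation_independence_test(
    values, labels, config: TestConfig, comparison: str = "", rng: np.random.Generator | None = None
) -> TestResult:
    """Monte-Carlo permutation test of independence between values and groups.

    The observed max-|z| statistic is compared with its distribution under
    random relabelling; p = (b + 1)/(N + 1) with b the number of permuted
    statistics at or above the observed one.
    """
    values, uniq, masks, sizes = _group_arrays(values, labels)
    if np.ptp(values) == 0.0:
        return TestResult(comparison, tuple(uniq), 0.0, 1.0, None, tuple(sizes),
                          note="degenerate: all values identical")
    rng = rng if rng is not None else config.rng()
    obs = float(_max_abs_z(values[None, :], masks, sizes)[0])
    B = config.n_permutations
    perms = rng.permuted(np.broadcast_to(values, (B, values.size)), axis=1)
    null = _max_abs_z(perms, masks, sizes)
    b = int((null >= obs - 1e-12).sum())
    return TestResult(comparison, tuple(uniq), obs, (b + 1) / (B + 1), None, tuple(sizes))


def _welch_t(x_mat: np.ndarray, n1: int) -> np.ndarray:
    a, b = x_mat[:, :n1], x_mat[:, n1:]
    va = a.var(axis=1, ddof=1) / a.shape[1]
    vb = b.var(axis=1, ddof=1) / b.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(va + vb)


def pairwise_permutation_t(
    values, labels, config: TestConfig, comparison: str = ""
) -> list[TestResult]:
    """Post-hoc pairwise Welch t permutation tests with BH across the pairs."""
    values, uniq, masks, sizes = _group_arrays(values, labels)
    rng = config.rng()
    results = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            x = np.concatenate([values[masks[i]], values[masks[j]]])
            n1 = int(sizes[i])
            if np.ptp(x) == 0.0:
                results.append(TestResult(comparison, (uniq[i], uniq[j]), 0.0, 1.0, None,
                                          (n1, x.size - n1), note="degenerate: all values identical"))
                continue
            obs = abs(float(_welch_t(x[None, :], n1)[0]))
            B = config.n_permutations
            perms = rng.permuted(np.broadcast_to(x, (B, x.size)), axis=1)
            null = np.abs(_welch_t(perms, n1))
            b = int((null >= obs - 1e-12).sum())
            results.append(TestResult(comparison, (uniq[i], uniq[j]), obs,
                                      (b + 1) / (B + 1), None, (n1, x.size - n1)))
    p_adj = adjust_bh([r.p_raw for r in results])
    for r, pa in zip(results, p_adj):
        r.p_adj = float(pa)
    return results


# ---------------------------------------------------------------------------
# climate utilities


def jja_series(climate: pd.DataFrame) -> pd.DataFrame:
    """Per-year summer values: JJA mean temperature and JJA precipitation sum."""
    jja = climate[climate["month"].isin(JJA_MONTHS)]
    out = jja.groupby("year").agg(
        jja_tmean=("tmean_c", "mean"), jja_prec=("prec_mm", "sum"), n_months=("month", "size")
    )
    if (out["n_months"] != 3).any():
        raise ParameterError("incomplete June-August coverage in climate table")
    return out.drop(columns="n_months").reset_index()


def select_extreme_years(
    climate: pd.DataFrame, period: tuple[int, int], k: int = 5
) -> list[ExtremeYearSet]:
    """The k highest/lowest summer years per variable, with percentile checks.

    Selected values are verified to lie above the 85th (high tail) or below
    the 15th percentile (low tail) of the study period and of the full
    available series; ties in the ranking are broken toward the earlier
    calendar year.
    """
    y0, y1 = period
    full = jja_series(climate)
    study = full[(full["year"] >= y0) & (full["year"] <= y1)]
    if len(study) < 2 * k + 1:
        raise ParameterError(f"period must span > {2 * k} years, got {len(study)}")
    out = []
    for variable, col in (("temperature", "jja_tmean"), ("precipitation", "jja_prec")):
        vals = study[col].to_numpy()
        years = study["year"].to_numpy()
        hi_q_study, lo_q_study = np.percentile(vals, [85, 15])
        hi_q_full, lo_q_full = np.percentile(full[col], [85, 15])
        # stable sort on value with earlier year winning ties
        order_low = np.lexsort((years, vals))
        order_high = np.lexsort((years, -vals))
        for tail, order in (("high", order_high), ("low", order_low)):
            idx = order[:k]
            sel_years = [int(y) for y in years[idx]]
            sel_vals = [float(v) for v in vals[idx]]
            if tail == "high":
                ok_study = min(sel_vals) >= hi_q_study
                ok_full = min(sel_vals) >= hi_q_full
            else:
                ok_study = max(sel_vals) <= lo_q_study
                ok_full = max(sel_vals) <= lo_q_full
            out.append(ExtremeYearSet(variable, tail, sel_years, sel_vals,
                                      bool(ok_study), bool(ok_full)))
    return out


def extreme_years_table(sets: list[ExtremeYearSet]) -> pd.DataFrame:
    rows = []
    for s in sets:
        for year, value in zip(s.years, s.jja_values):
            rows.append(dict(variable=s.variable, tail=s.tail, year=year, jja_value=value,
                             percentile_ok_study=s.percentile_ok_study,
                             percentile_ok_full=s.percentile_ok_full))
    return pd.DataFrame(rows)


def climate_correlations(
    chronologies: pd.DataFrame,
    indexed_climate: pd.DataFrame,
    config: TestConfig,
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Spearman correlations of sector chronologies with indexed monthly climate.

    `chronologies` is a long table (site_id, trait, sector, year, x_ind);
    `indexed_climate` the output of :func:`qwa.detrend.index_climate`.  For
    each chronology, each climate variable and each of 24 months
    (previous-year January .. current-year December) the Spearman
    correlation (average-rank ties) is computed over the overlapping years;
    BH correction is applied within each site × trait × sector × variable
    family of 24 months.
    """
    rows = []
    for (site, trait, sector), grp in chronologies.groupby(["site_id", "trait", "sector"], sort=True):
        chron = grp.set_index("year")["x_ind"].dropna()
        for variable, col in (("temperature", "tmean_ind"), ("precipitation", "prec_ind")):
            family = []
            for lag in ("previous", "current"):
                for month in range(1, 13):
                    clim = indexed_climate[indexed_climate["month"] == month].set_index("year")[col]
                    if lag == "previous":
                        clim = clim.copy()
                        clim.index = clim.index + 1  # previous-year value aligned to ring year
                    joined = pd.concat([chron, clim], axis=1, join="inner").dropna()
                    if len(joined) < min_overlap:
                        raise ParameterError(
                            f"overlap {len(joined)} < {min_overlap} years for "
                            f"{site}/{trait}/sector {sector}, {variable} {lag} month {month}"
                        )
                    r, p = sps.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
                    family.append(dict(site_id=site, trait=trait, sector=sector,
                                       variable=variable, lag=lag, month=month,
                                       n_years=len(joined), r=float(r), p_raw=float(p)))
            p_adj = adjust_bh([f["p_raw"] for f in family])
            for f, pa in zip(family, p_adj):
                f["p_adj"] = float(pa)
                f["significant"] = bool(pa <= config.alpha)
            rows.extend(family)
    return pd.DataFrame(rows)


def compare_groups_table(
    data: pd.DataFrame,
    value_col: str,
    group_col: str,
    by: list[str],
    config: TestConfig,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Permutation independence test of `value_col` across `group_col` levels,
    run separately within each combination of `by` columns, BH-corrected
    across the family.
    """
    # independent child streams so the family is reproducible regardless of order
    ss = np.random.SeedSequence(config.seed)
    results = []
    groups = list(data.groupby(by, sort=True))
    children = ss.spawn(len(groups))
    for (key, grp), child in zip(groups, children):
        grp = grp.dropna(subset=[value_col])
        counts = grp.groupby(group_col)[value_col].size()
        if len(counts) < 2 or (counts < min_per_group).any():
            continue
        key_t = key if isinstance(key, tuple) else (key,)
        res = permutation_independence_test(
            grp[value_col], grp[group_col], config,
            comparison="|".join(str(k) for k in key_t),
            rng=np.random.default_rng(child),
        )
        results.append(dict(zip(by, key_t))
                       | dict(statistic=res.statistic, p_raw=res.p_raw,
                              n_groups=len(counts), n_total=int(counts.sum()), note=res.note))
    out = pd.DataFrame(results)
    if len(out):
        out["p_adj"] = adjust_bh(out["p_raw"])
        out["significant"] = out["p_adj"] <= config.alpha
    return out


def compare_periods(
    profiles: pd.DataFrame,
    config: TestConfig,
    before: tuple[int, int] = (1968, 1981),
    after: tuple[int, int] = (1990, 2004),
    value_col: str = "x_std",
) -> pd.DataFrame:
    """Compare standardized sector profiles between two calendar windows.

    Years outside both windows are excluded.  One permutation test per
    site × trait × sector, BH-corrected within each site × trait family.
    """
    df = profiles.copy()
    in_before = df["year"].between(*before)
    in_after = df["year"].between(*after)
    df = df[in_before | in_after]
    if df.empty:
        raise ParameterError("no data in either period window")
    df["period"] = np.where(df["year"] <= before[1], f"{before[0]}-{before[1]}",
                            f"{after[0]}-{after[1]}")
    parts = []
    for _, fam in df.groupby(["site_id", "trait"], sort=True):
        part = compare_groups_table(fam, value_col, "period",
                                    by=["site_id", "trait", "sector"], config=config)
        parts.append(part)
    parts = [p for p in parts if len(p)]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
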