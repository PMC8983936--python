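import itertools

import numpy as np
import pandas as pd
import pytest

from qwa import inference
from qwa.exceptions import ParameterError
from qwa.inference import (
    TestConfig,
    adjust_bh,
    climate_correlations,
    compare_periods,
    jja_series,
    pairwise_permutation_t,
    permutation_independence_test,
    select_extreme_years,
)

from conftest import make_climate


class TestAdjustBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.03]), [0.03])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(adjust_bh([0.005, 0.04, 0.04]), [0.015, 0.04, 0.04])
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        adj = adjust_bh(p)
        assert (adj <= 1.0).all() and (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            adjust_bh([0.5, 1.2])


class TestPermutationIndependence:
    def test_identical_groups_give_p_one(self):
        res = permutation_independence_test(
            np.ones(20), np.repeat(["a", "b"], 10), TestConfig(n_permutations=199)
        )
        assert res.p_raw == 1.0
        assert "degenerate" in res.note

    def test_p_value_bounds(self):
        rng = np.random.default_rng(1)
        cfg = TestConfig(n_permutations=199, seed=1)
        res = permutation_independence_test(rng.normal(0, 1, 30), np.repeat(["a", "b", "c"], 10), cfg)
        assert 1 / 200 <= res.p_raw <= 1.0

    def test_power_on_large_shift(self):
        """A 2-SD location shift at n = 30/30 is essentially always detected."""
        rng = np.random.default_rng(2)
        cfg = TestConfig(n_permutations=199, seed=2)
        labels = np.repeat(["a", "b"], 30)
        rejections = sum(
            permutation_independence_test(
                np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)]),
                labels, cfg, rng=rng,
            ).p_raw <= 0.05
            for _ in range(200)
        )
        assert rejections / 200 > 0.99

    def test_size_under_null_quick(self):
        """Rejection rate under the null stays near the nominal level."""
        rng = np.random.default_rng(3)
        cfg = TestConfig(n_permutations=199)
        labels = np.repeat(["a", "b"], 15)
        rej = sum(
            permutation_independence_test(rng.lognormal(0, 1, 30), labels, cfg, rng=rng).p_raw
            <= 0.05
            for _ in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.08

    def test_seed_reproducible(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 1, 40)
        labels = np.repeat(["a", "b"], 20)
        cfg = TestConfig(n_permutations=999, seed=7)
        assert (permutation_independence_test(x, labels, cfg).p_raw
                == permutation_independence_test(x, labels, cfg).p_raw)


class TestPairwiseT:
    def test_three_groups_three_pairs(self):
        rng = np.random.default_rng(4)
        res = pairwise_permutation_t(
            rng.normal(0, 1, 30), np.repeat(["a", "b", "c"], 10), TestConfig(n_permutations=199)
        )
        assert len(res) == 3
        assert {r.groups for r in res} == {("a", "b"), ("a", "c"), ("b", "c")}
        assert all(r.p_adj >= r.p_raw for r in res)

    def test_matches_exhaustive_enumeration_on_toy(self):
        """MC p agrees with exact enumeration of all 4+4 label splits."""
        x = np.array([1.0, 3.0, 2.5, 4.0, 8.0, 9.5, 7.0, 11.0])
        n1 = 4

        def welch(a, b):
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            return abs((a.mean() - b.mean()) / np.sqrt(va + vb))

        obs = welch(x[:n1], x[n1:])
        stats = []
        for comb in itertools.combinations(range(8), n1):
            mask = np.zeros(8, dtype=bool)
            mask[list(comb)] = True
            stats.append(welch(x[mask], x[~mask]))
        exact_p = np.mean(np.array(stats) >= obs - 1e-12)
        res = pairwise_permutation_t(
            x, np.repeat(["a", "b"], 4), TestConfig(n_permutations=49999, seed=11)
        )[0]
        assert res.p_raw == pytest.approx(exact_p, abs=0.005)


class TestExtremeYears:
    def test_ten_of_thirty_seven_flagged(self):
        clim = make_climate(1968, 2004, rng=np.random.default_rng(6))
        sets = select_extreme_years(clim, (1968, 2004), k=5)
        assert len(sets) == 4  # 2 variables x 2 tails
        for variable in ("temperature", "precipitation"):
            flagged = set()
            for s in sets:
                if s.variable == variable:
                    assert len(s.years) == 5
                    flagged |= set(s.years)
            assert len(flagged) == 10  # high and low sets are disjoint

    def test_monotone_series_extremes_at_ends(self):
        rows = [dict(year=y, month=m, tmean_c=float(y - 1968), prec_mm=50.0)
                for y in range(1968, 2005) for m in range(1, 13)]
        sets = select_extreme_years(pd.DataFrame(rows), (1968, 2004), k=5)
        temp = {(s.tail): s for s in sets if s.variable == "temperature"}
        assert sorted(temp["high"].years) == list(range(2000, 2005))
        assert sorted(temp["low"].years) == list(range(1968, 1973))

    def test_order_statistic_percentile_check(self):
        """5 of 37 distinct values always clear the 85th/15th percentiles."""
        clim = make_climate(1968, 2004, rng=np.random.default_rng(7))
        for s in select_extreme_years(clim, (1968, 2004), k=5):
            assert s.percentile_ok_study

    def test_exhaustive_of_the_k_extremes(self):
        clim = make_climate(1968, 2004, rng=np.random.default_rng(8))
        jja = jja_series(clim)
        sets = {(s.variable, s.tail): s for s in select_extreme_years(clim, (1968, 2004), k=5)}
        top = jja.nlargest(5, "jja_tmean")["year"]
        assert set(sets[("temperature", "high")].years) == set(top)

    def test_short_period_rejected(self):
        clim = make_climate(1968, 2004)
        with pytest.raises(ParameterError):
            select_extreme_years(clim, (1968, 1977), k=5)


class TestClimateCorrelations:
    @staticmethod
    def chron_from_month(clim_idx, month, transform=np.exp):
        src = clim_idx[clim_idx["month"] == month].sort_values("year")
        return pd.DataFrame(dict(site_id="S1", trait="VA95", sector=1,
                                 year=src["year"], x_ind=transform(src["prec_ind"])))

    def test_monotone_transform_gives_r_one(self):
        from qwa.detrend import index_climate

        clim_idx = index_climate(make_climate(1960, 2004, rng=np.random.default_rng(9)))
        chron = self.chron_from_month(clim_idx, 6)
        out = climate_correlations(chron, clim_idx, TestConfig())
        hit = out[(out.variable == "precipitation") & (out.lag == "current") & (out.month == 6)]
        assert hit["r"].iloc[0] == pytest.approx(1.0)
        assert len(out) == 48  # 24 months x 2 variables

    def test_null_false_positive_rate_before_bh(self):
        from qwa.detrend import index_climate

        rng = np.random.default_rng(10)
        clim_idx = index_climate(make_climate(1950, 2010, rng=rng))
        hits, total = 0, 0
        for i in range(12):
            years = np.arange(1950, 2011)
            chron = pd.DataFrame(dict(site_id="S1", trait="VA95", sector=1, year=years,
                                      x_ind=rng.normal(1, 0.1, len(years))))
            out = climate_correlations(chron, clim_idx, TestConfig())
            hits += (out["p_raw"] <= 0.05).sum()
            total += len(out)
        assert 0.01 <= hits / total <= 0.10

    def test_short_overlap_refused(self):
        from qwa.detrend import index_climate

        clim_idx = index_climate(make_climate(1960, 2004))
        chron = pd.DataFrame(dict(site_id="S1", trait="VA95", sector=1,
                                  year=np.arange(2000, 2005), x_ind=np.ones(5)))
        with pytest.raises(ParameterError, match="overlap"):
            climate_correlations(chron, clim_idx, TestConfig())


class TestComparePeriods:
    @staticmethod
    def profiles(rng, shift_after=0.0, years=range(1968, 2005)):
        rows = []
        for year in years:
            for tree in range(5):
                for sector in (1, 2):
                    mu = 1.0 + (shift_after if year >= 1990 and sector == 1 else 0.0)
                    rows.append(dict(site_id="S1", tree_id=f"T{tree}", year=year,
                                     sector=sector, trait="VA",
                                     x_std=rng.normal(mu, 0.15)))
        return pd.DataFrame(rows)

    def test_gap_years_excluded(self):
        rng = np.random.default_rng(11)
        out = compare_periods(self.profiles(rng), TestConfig(n_permutations=199))
        assert (out["n_total"] == (14 + 15) * 5).all()  # 1982-1989 in neither group

    def test_injected_shift_detected_at_affected_sector(self):
        rng = np.random.default_rng(12)
        out = compare_periods(self.profiles(rng, shift_after=0.4),
                              TestConfig(n_permutations=999, seed=1))
        by = out.set_index("sector")
        assert by.loc[1, "significant"]
        assert not by.loc[2, "significant"]

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(13)
        raw_p = []
        for _ in range(60):
            out = compare_periods(self.profiles(rng), TestConfig(n_permutations=199, seed=int(rng.integers(2**31))))
            raw_p.extend(out["p_raw"])
        rate = np.mean(np.array(raw_p) <= 0.05)
        assert 0.01 <= rate <= 0.10

    def test_empty_window_rejected(self):
        rng = np.random.default_rng(14)
        prof = self.profiles(rng, years=range(2010, 2020))
        with pytest.raises(ParameterError):
            compare_periods(prof, TestConfig(n_permutations=199))
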