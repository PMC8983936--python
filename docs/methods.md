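# Methods

## Scope and data model

`qwa` analyses vessel-level measurements of diffuse-porous hardwood rings
(the kind of per-cell output produced by quantitative wood-anatomy image
analysis). Three tables drive everything: vessels (lumen area in μm² and a
relative radial position in [0, 1] within a dated ring, 0 at the inner ring
border), rings (ring width TRW and analyzed xylem area), and a complete
monthly climate grid (mean temperature, precipitation sum).

## Sectorization and traits

Each ring is split into k equal-width radial sectors (k = 5 for robust
sector estimates, k = 10 for a semi-continuous intra-ring profile). A vessel
belongs to the sector containing its centroid position: s = ⌊p·k⌋ + 1, with
p = 1 assigned to sector k; the boundary p = 0.5 therefore opens the
late-formed half (E_fW = [0, 0.5), L_fW = [0.5, 1]).

Per retained sector (and for the whole ring as "sector 0", computed over the
pooled vessels and the full analyzed area):

- **VA** — mean lumen area; **VA95** — 95th percentile of lumen area with
  the linear-interpolation quantile, chosen as the ubiquitous default and
  documented so results are bit-stable;
- **DH** — hydraulically weighted mean diameter Σd⁵/Σd⁴ over equivalent
  circle diameters d = 2√(A/π). This is the convention of the xylem
  hydraulics literature; the alternative (Σd⁴/n)^¼ exists but is not used
  here;
- **KH** — theoretical hydraulic conductivity per unit length from the
  Hagen–Poiseuille law, KH = (πρ/128η)·Σdᵢ⁴, with pure-water constants at
  20 °C fixed for reproducibility (ρ = 998.2 kg·m⁻³, η = 1.002·10⁻⁹ MPa·s);
  units kg·m·MPa⁻¹·s⁻¹;
- **VD** — vessels per mm² of analyzed sector area; **RVA** — lumen
  fraction of analyzed sector area. The sector analyzed area is
  xylem_area/k: sectors are equal-width bands of the analyzed image and
  per-sector measured areas are not part of the data model;
- **VG** — vessel grouping index n/groups, a solitary vessel counting as a
  group of one. Group membership comes from exported group ids when
  present; otherwise groups are detected by single-link clustering of
  vessels whose centres lie closer than r_i + r_j + 3 μm (a configurable
  wall allowance). With only radial centroids available this 1-D rule is an
  approximation of the planar contact criterion.

Two filters precede trait computation: sectors with fewer than five vessels
are discarded (too few order statistics for VA95/DH), and a ring is
discarded entirely when any sector width (TRW/k) does not exceed the
largest vessel radius in that sector — the sectorization is then finer than
single conduits. Both discards are flagged with reasons and counted in a
report table.

## Standardization

Two complementary standardizations:

1. **Indexing (X_ind).** Every annual series (one trait × sector × tree,
   or one calendar month of climate) is divided by a fitted cubic smoothing
   spline whose amplitude frequency response is 50% at a 30-year
   wavelength. The spline is defined by this response contract: the penalty
   λ of the natural cubic smoothing spline (scipy's
   `make_smoothing_spline`) is calibrated by bisection on log λ against
   sinusoid probes over max(300, 10·cutoff) annual steps, seeded by the
   infinite-sample value (cutoff/2π)⁴, and cached per cutoff. Calibration
   is deterministic; the fitted response at the cutoff is accurate to
   ~1e-6. Missing years are excluded from the fit (no interpolation);
   indices are undefined where the fitted value is non-positive, which
   restricts ratio indexing to positive series — fine for the traits and
   precipitation, and for temperature only when all values are positive
   (series crossing 0 °C yield missing winter indices rather than
   sign-flipped ratios).
2. **Profiles (X_std).** Sector values divided by the whole-ring value of
   the same trait in the same tree-year. The denominator is the ring-level
   trait over pooled vessels, not the mean of sector values; for
   count-weighted traits this makes the vessel-weighted mean of X_std
   exactly 1 when no sector was discarded, a property the tests verify.

## Chronologies

Site chronologies are across-tree means of indexed values per year over a
common period. Robustness is summarized by Rbar — the mean of all pairwise
Pearson correlations between tree series, pairwise-complete over the common
period (small samples with unequal spans make listwise deletion wasteful) —
and the expressed population signal EPS = n·Rbar/(1 + (n−1)·Rbar). EPS can
leave [0, 1] when Rbar < 0; such chronologies carry no population signal
and are flagged rather than clipped.

## Inference

All group comparisons are Monte-Carlo permutation tests with the add-one
estimator p = (b+1)/(N+1), which is valid at any permutation count and
seed-reproducible. The test of independence uses the maximum absolute
standardized group-sum deviation (the max-type statistic of the classical
permutation framework; the quadratic form is an equally defensible choice —
the max form is used and documented). Post-hoc pairwise comparisons permute
the Welch t statistic. Benjamini–Hochberg correction (via statsmodels) is
applied within each analysis family: the pair family for post-hoc tests,
the 24-month family per trait × variable × site for climate correlations,
the sector family per site × trait for period comparisons.

Climate–growth association uses Spearman correlation (average-rank ties)
between indexed sector chronologies and indexed monthly climate over a
24-month window, previous-year January through current-year December — a
superset of any plausible "previous and current growing season" — refusing
to correlate on overlaps under 10 years.

Extreme years are the k = 5 highest and lowest summer (JJA) years per
variable (temperature: mean of monthly means; precipitation: sum of monthly
sums), ties broken toward the earlier year for determinism, with a reported
check that the tails clear the 85th/15th percentile of both the study
period and the full series (for k = 5 of 37 distinct values this holds by
order-statistic arithmetic: rank 33/37 ≈ 0.865).

## Synthetic stand generator

The generator provides study-shaped data so every stage is testable without
field measurements. Defaults emulate three sites × five trees with rings
from 1968–2004 (37 years):

| parameter | default | meaning |
|---|---|---|
| vessels_per_ring_mean | 150 | Poisson mean vessels per ring |
| ring_width_mean_um | 1300 μm | lognormal inter-annual TRW, CV 0.2 |
| profile_plateau_end | 0.5 | VA plateau ends at mid-ring |
| end_fraction | 0.3 | expected VA at ring end / plateau |
| vd_peak_position | 0.9 | mode of the Beta position component |
| ontogenetic_trend | 0.005 | fractional VA increase per cambial year |
| climate_signal | 0.7 | effect size of JJA precipitation, in [0, 1] |
| noise_cv | 0.3 | lognormal vessel-size noise |
| group_fraction | 0.25 | vessels placed in 2–3 vessel groups |

Positions mix a uniform component (weight 0.7) with a Beta component whose
mode sits at the density-peak position, so vessel density climbs toward the
ring end as in diffuse-porous latewood. Expected lumen area = 2200 μm² ×
intra-ring profile × (1 + trend)^age × site offset × climate multiplier,
with lognormal noise. The climate multiplier exp(climate_signal·0.3·z)
applies the standardized JJA-precipitation anomaly z to early-ring
(p < 0.5) vessels only — emulating a summer-moisture effect on earlywood
expansion, the strongest association such analyses report. The analyzed
strip is 900 μm wide, giving RVA ≈ 0.25 and VD ≈ 130 mm⁻², realistic for
beech. The synthetic climate keeps all monthly temperatures positive
(annual mean 12 °C, amplitude 8 °C) because ratio indexing requires
positive series. Randomness derives from one master seed through
`SeedSequence` spawn keys per stream (climate; each tree), so identical
configs are byte-identical.

What the generator does **not** emulate: spatial vessel arrangement in two
dimensions (grouping is assigned, not emergent), parenchyma/fibre content,
ring-porous anatomy, missing rings, within-site climate gradients, or
measurement error in ring delimitation. Passing recovery tests therefore
show the pipeline's statistics behave correctly on data with the assumed
structure, not that real stands satisfy those assumptions.

## Numerical and design notes

- Study-size defaults throughout the tests: 37-year series, five trees,
  999–9,999 permutations; the permutation-size study uses 2,000 datasets ×
  999 permutations, a size giving ±0.5 pp Monte-Carlo error on a 5% rate.
- Permutation p-values compare with a 1e-12 slack so ties between the
  observed and permuted statistics count as exceedances (conservative).
- Degenerate inputs: all-identical values give p = 1 with a note; constant
  series are reproduced exactly by the spline; empty retained sector sets
  skip the ring.
- CSV floats are written with 17 significant digits and parsed in
  round-trip mode, so write→read is an exact identity.
- Open choice, ring mean vs sector mean for X_std: the ring-level pooled
  trait is used (see above); switching to the mean of sector values is a
  one-line change in `standardize_profiles` and changes X_std by a
  count-weighting factor.
- The EPS of a few (n, rbar) combinations printed in the wider literature
  differs from the Wigley formula by ±0.02, consistent with rounding or an
  effective-rbar variant; this package uses the standard expression.

## Importing spreadsheet exports

No parser for proprietary spreadsheet output is included. Cell-level
exports are converted to the vessel CSV dialect with a few pandas lines,
e.g.:

```python
import pandas as pd
cells = pd.read_excel("output_cells.xlsx")
cells.rename(columns={"CA": "lumen_area_um2", "RRadDistR": "rel_position",
                      "YEAR": "year", "ID": "vessel_id"}) \
     .assign(site_id="U1", tree_id="T01") \
     .to_csv("vessels.csv", index=False)
```

(Column names vary by software version; `rel_position` must be the relative
radial distance of the vessel centroid, 0 at the inner ring border.)
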