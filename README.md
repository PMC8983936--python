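# qwa — quantitative wood anatomy of diffuse-porous tree rings

`qwa` is a Python toolkit for dendroecologists and wood anatomists working
with vessel-level measurements of diffuse-porous species such as European
beech. Starting from per-vessel tables (lumen area and relative radial
position within dated rings), it computes intra-ring anatomical traits,
builds detrended chronologies, and runs the distribution-free statistics
this kind of skewed, small-n data requires.

## What it computes

Rings are divided into k equal-width radial sectors (k = 5 or 10). Per
sector and per whole ring:

| trait | definition |
|---|---|
| VA, VA95 | mean and 95th-percentile vessel lumen area (μm²) |
| DH | hydraulically weighted mean diameter Σd⁵/Σd⁴ (μm) |
| KH | Hagen–Poiseuille conductivity (πρ/128η)·Σdᵢ⁴ (kg·m·MPa⁻¹·s⁻¹) |
| VD | vessel density (mm⁻²) |
| RVA | lumen fraction of analyzed xylem area |
| VG | grouping index, vessels per vessel group |

Sectors with < 5 vessels, and rings whose sector width does not exceed the
largest vessel radius, are discarded with a reported reason.

Two standardizations follow: **X_ind**, the ratio of each annual series to
a cubic smoothing spline calibrated to a 50% frequency response at a
30-year wavelength (removing ontogenetic/disturbance trends), and
**X_std**, sector values divided by the same ring's whole-ring value
(isolating the intra-ring shape). Site chronologies of X_ind come with
Rbar (mean inter-series correlation) and EPS = n·Rbar/(1+(n−1)·Rbar).
Group contrasts (sites, management periods, extreme vs. normal summers)
use Monte-Carlo permutation tests with Benjamini–Hochberg correction;
climate associations use Spearman correlations against spline-indexed
monthly climate over a 24-month window. A synthetic stand generator with
realistic beech-like structure makes the whole pipeline testable without
field data. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from qwa import SyntheticConfig, generate_all, anatomy, detrend, chronostats, inference

cfg = SyntheticConfig(seed=1)                 # 3 sites x 5 trees, 1968-2004
vessels, rings, climate = generate_all(cfg)
scheme = anatomy.SectorScheme(k=10)
sectorized = anatomy.assign_sectors(vessels, scheme)
traits = anatomy.sector_traits(sectorized, rings, scheme)

ring0 = traits[traits.sector == 0]
print(f"rings analyzed: {len(ring0)}, mean VA {ring0.VA.mean():.0f} um2, "
      f"mean VD {ring0.VD.mean():.0f} mm-2, mean RVA {ring0.RVA.mean():.2f}")

profiles = detrend.standardize_profiles(traits)
vd = profiles[profiles.trait == "VD"].groupby("sector")["x_std"].mean()
print("VD_std profile:", np.round(vd.to_numpy(), 2))

indexed = detrend.index_traits(traits, traits_to_index=["VA95"])
stats = chronostats.site_chronologies(indexed[indexed.sector == 0], (1968, 2004))
for s in stats:
    print(f"site {s.site_id}: VA95 Rbar = {s.rbar:.2f}, EPS = {s.eps:.2f} (n = {s.n_series})")

sets = inference.select_extreme_years(climate, (1968, 2004), k=5)
hot = next(s for s in sets if s.variable == "temperature" and s.tail == "high")
print("hottest JJA years:", sorted(hot.years))
```

Output:

```
rings analyzed: 555, mean VA 1795 um2, mean VD 131 mm-2, mean RVA 0.24
VD_std profile: [0.7  0.72 0.72 0.72 0.7  0.72 0.78 1.15 2.12 1.76]
site S1: VA95 Rbar = 0.90, EPS = 0.98 (n = 5)
site S2: VA95 Rbar = 0.91, EPS = 0.98 (n = 5)
site S3: VA95 Rbar = 0.91, EPS = 0.98 (n = 5)
hottest JJA years: [1975, 1976, 1991, 1998, 2000]
```

Reading the numbers: vessel lumina fill about a quarter of the analyzed
xylem (RVA 0.24) at ~131 vessels·mm⁻²; the standardized vessel-density
profile peaks in sector 9 (the 80–90% band of the ring), i.e. vessel
density climbs toward the late-formed wood while mean vessel size falls;
VA95 chronologies are highly coherent across trees here (EPS 0.98) because
the synthetic stand injects a strong common summer-precipitation signal;
and the extreme-year classifier flags the five hottest summers of the
37-year window.

The same stages are available from the shell:

```sh
qwa simulate --seed 1 --out data/
qwa traits --vessels data/vessels.csv --rings data/rings.csv --sectors 10 --out traits.csv
qwa run --out results/          # full pipeline with a manifest
```

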