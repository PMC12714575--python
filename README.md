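# isozone

Environmentally adjusted collagen δ¹³C thresholds for detecting C₄ plant
consumption, built from archaeological charred-grain δ¹³C baselines and a
k-means environmental ecozone model of Europe.

## The problem

Bioarchaeologists and palaeoecologists infer millet (C₄) consumption from
bone-collagen δ¹³C, conventionally calling values above −18.0‰ a mixed
C₃/C₄ diet. But the C₃ plant baseline itself varies across Europe — charred
C₃ cereal grains are 1–2‰ more depleted at high latitudes and under humid
climates than in the arid south — so a single fixed threshold over- or
under-detects C₄ intake depending on where the consumer lived. This package
implements the full workflow for replacing the fixed threshold with
environmentally adjusted ones:

1. **Grain baselines** (`grain_data`): robust summaries (n, mean, median,
   sample SD, mean absolute deviation) of C₃ and C₄ grain δ¹³C — always kept
   separate — over sites, countries, four macro-regions, 5° latitude bins,
   and ecozones; values are uncorrected for charring throughout.
2. **Ecozones** (`env_stack`, `ecozones`): z-scored elevation, multiannual
   mean temperature, and climatic moisture index (CMI = P − PET) rasters on
   a 1-km Web-Mercator grid are sampled at lattice centroids and clustered
   by k-means (k = 20, one class reserved for unclassified water/NA cells).
   Cluster ids are canonicalised by ascending mean temperature and labelled
   with 7-level ordinal descriptors (e.g. `Cool|Extremely Humid|Middle`).
3. **Diet-mixing model** (`diet_thresholds`): for a dietary C₄ fraction
   *f*, the expected collagen threshold is

   δ¹³C_collagen(f) = (1 − f)·(δ¹³C_C3 + Δ) + f·(δ¹³C_C4 + Δ),  Δ = +5‰,

   where Δ is the diet→collagen trophic fractionation offset. The C₄
   end-member is the site's measured mean millet δ¹³C where available, else
   a regional expectation (−10‰ in general, −10.5‰ in the western
   Mediterranean, −11‰ in the far north). Thresholds are computed per grain
   and aggregated at site and ecozone level; *f* = 0.10 is the headline
   fraction (*f* = 0.20 is computed but theoretical only).
4. **Inference** (`trend_stats`): Pearson r with Fisher-z 95% CI, OLS
   trends (R², p), one-way ANOVA.
5. **Synthetic data** (`synthetic`): seeded generators reproducing the
   study's structure (site hierarchy, latitudinal gradient, regional C₄
   end-members, planted raster climate zones) for offline testing and
   parameter-recovery checks.

Raster I/O uses the plain-text ESRI ASCII grid format and a built-in exact
spherical Web-Mercator (EPSG:3857) transform, so the package has no GDAL
dependency.

## Worked example

```python
from isozone import ThresholdParams, grain_to_collagen, mix_threshold

params = ThresholdParams()            # +5 permil offset, defaults -10/-10.5/-11
c3_median = -25.08                    # far-northern ecozone C3 grain median
c4 = params.c4_default_far_north      # -11 permil
thr = mix_threshold(grain_to_collagen(c3_median, params),
                    grain_to_collagen(c4, params), 0.10)
print(round(float(thr), 2))           # -18.67
```

A collagen value of −18.67‰ in that ecozone already indicates ~10% C₄
intake — 0.7‰ *below* the conventional −18.0‰ cutoff, which would have
missed it. In a hot/dry Mediterranean lowland ecozone the same computation
gives −16.88‰, i.e. the cutoff must move ~1.1‰ the other way.

## The analysis

Numbered drivers under `analysis/` run the pipeline on the synthetic study
dataset and write tables under `results/`:

```sh
python analysis/01_simulate.py    # grain table + raster stack (seed 42)
python analysis/02_ecozones.py    # k = 20 ecozone model + descriptors
python analysis/03_baselines.py   # latbin/region/country/ecozone baselines
python analysis/04_thresholds.py  # site + ecozone thresholds and maps
python analysis/05_trends.py      # latitude/date trends, regional ANOVA
```

Sample of what they print (seed 42):

```
C3 grain medians: North -23.83 vs South -22.95 permil -> northern depletion -0.88 permil
ecozone 10%-C4 threshold medians span -17.72 to -16.44 permil (1.28 permil of environmentally driven adjustment)
C3 d13c vs latitude: r = -0.38 [-0.41, -0.36], slope -0.0403 permil/deg (planted -0.050), p = 5.22e-170
```

The same pipeline is scriptable via the `isozone` CLI (`simulate`, `run`,
`cluster`, `assign`, `baseline`, `thresholds`, `trends`, `report`); every
run writes a manifest that allows bit-identical re-runs. To run it on real
data, point `isozone run` at a grain CSV (columns documented in
`isozone.grain_data.REQUIRED_COLUMNS`) and three co-registered ASCII-grid
rasters in a metre-based CRS.

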