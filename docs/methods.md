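# Methods

## Model and assumptions

The package treats consumer collagen δ¹³C as a two-end-member linear mixture
of plant-food carbon sources shifted by a constant trophic fractionation:

    T(f) = (1 − f) · (m_C3 + Δ) + f · (m_C4 + Δ)

with `m_C3` a local C₃ grain δ¹³C value (per grain, or a group median),
`m_C4` the local C₄ (millet) end-member, `Δ = +5‰` the diet→collagen
offset, and `f` the dietary C₄ fraction. The assumptions are explicit and
strong: an all-grain diet, a single constant Δ independent of tissue
turnover and diet composition, and linear mixing on the δ scale. The model
is therefore a *threshold calibration device*, not a diet reconstruction:
`T(0.10)` answers "above which collagen value can ~10% C₄ intake no longer
be excluded, given the local plant baseline". Fractions above ~0.2 push the
all-grain assumption past usefulness, so `f = 0.10` is the headline output
and `f = 0.20` is computed but marked theoretical.

Because `T` is an affine, strictly monotone map of `m_C3` for fixed
(`m_C4`, `f`), medians and means commute with it: the median of per-grain
thresholds in a group with a single end-member equals the threshold of the
group's median C₃ value, to machine precision. This is the mechanism that
lets published group thresholds be reconstructed from published group
medians, and it is asserted as a property test rather than assumed.

Thresholds are nonetheless computed **per grain** and aggregated afterwards
(site, then ecozone by pooling grains across sites). Grain-level pooling
preserves within-group dispersion in the reported SD/MAD, and it lets an
ecozone that mixes measured-millet sites with default-only sites reflect
both end-members instead of a single collapsed value.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| trophic offset Δ | +5 | ‰ | conventional plant-diet→collagen fractionation |
| C₄ fractions | 0.10, 0.20 | – | detectable low intake; 0.20 theoretical only |
| C₄ default, general | −10 | ‰ | typical European archaeological millet |
| C₄ default, west Mediterranean | −10.5 | ‰ | regionally depleted millet |
| C₄ default, far north | −11 | ‰ | Baltic/Nordic millet ~1‰ below the general value |
| n_min | 10 | grains | groups below this are flagged non-representative |
| k | 20 | clusters | fixed design input (19 real + reserved NA class) |
| k-means seed / n_init | 42 / 25 | – | determinism / restart insurance; not tuned |
| latitude bins | 30,35,…,60,63 | °N | 5° bands, short terminal band |

The "western Mediterranean" and "far north" scopes are country lists
(Spain/Portugal/Andorra and the Baltic + Nordic countries respectively),
configurable on `ThresholdParams`; a country-keyed policy cannot express
sub-national scopes such as southern France, which is a documented
approximation. The four macro-regions (North / UK / Central–West / South)
are likewise an editable table; the assignment of border cases (Georgia,
Turkey, Jordan to South; Poland to Central/West) is a convention flagged as
an assumption, and published regional totals do not decompose exactly under
any single mapping we tried.

## Statistical choices

* **SD** is the sample standard deviation (divisor n−1). **MAD** is the
  *mean* absolute deviation about the arithmetic mean (the two published
  spellings of the acronym conflict; the mean-based reading is implemented,
  with `mad_center="median"` available). Single-value groups report SD 0
  with a warning rather than NaN.
* **Latitude bins** are lower-inclusive half-open with a closed last bin,
  so 55.0 falls in [55–60) and 63.0 in [60–63].
* **Pearson CI** uses the Fisher z transform at 95%; p-values are two-sided
  t-tests. Trends are plain OLS — reported R²/p in this literature come
  from simple linear models even where mixed-model packages are cited, and
  no random-effect structure is implemented.
* **CMI** is the water-balance difference P − PET (the published formula;
  the accompanying prose says "ratio", the formula wins). When a
  precomputed CMI product is used, the derivation step is bypassed.
* **z-scoring** uses the population SD over valid cells only; nodata cells
  are excluded from the moments and never transformed.

## Ecozone model numerics

NA handling: instead of clustering a −99999 sentinel (which reproduces an
unclassified class only if initialisation cooperates), NA lattice points are
deterministically pre-assigned to a reserved class (id = k) and k−1 real
clusters are fitted on finite points. This keeps the unclassified geography
exactly equal to the invalid mask. Raw k-means labels are
permutation-arbitrary, so ids are canonicalised by ascending mean
temperature; any published numbering is treated as display-only.

Nearest-centre rasterisation breaks exact ties toward the lowest canonical
id. Cluster summaries rescale the k−1 cluster-mean values per variable to
[0, 1] (min→0, max→1), and divide the SDs by the same range — rescaling
cluster means, not cell values, is what reproduces exact 0/1 entries in
published summary tables. Ordinal descriptors cut the rank order per
variable into 7 near-equal groups (sizes differ by ≤1, extras allocated
from the extremes inward) mapped to fixed vocabularies. The published
descriptor table is *consistent* with monotone rank-grouping but its group
sizes differ between variables under every single rule we tried, so exact
descriptor agreement is not asserted — only monotonicity in the rescaled
means and correct extreme labels, which the published table satisfies.

Site assignment projects lon/lat through the exact closed-form spherical
Web-Mercator equations (EPSG:3857 is defined on the sphere, so this is not
an approximation) and indexes the containing cell; sites on NA cells fall
back to the nearest valid cell within 1.5 cell sizes by default.

## Synthetic data: what it emulates, what it does not

The grain generator draws sites uniformly over 30–63° N with
region-consistent countries, then grains as
`c3_base + slope·(lat − 40) + region_offset + site_effect + noise`, with
defaults: 120 sites × 20–60 grains, slope −0.05 ‰/° (≈1.65‰ depletion
across the window, the observed 1–2‰ north–south offset), site SD 0.5‰,
within-site SD 0.8‰ (the typical published group dispersion of 0.8–1.4‰),
C₄ end-members −10/−10.5/−11‰ with SD 0.4‰ at 25% of sites, dates uniform
(no temporal trend, matching the near-absence of one in the record).
Regional offsets default to zero so the latitudinal slope is the single
geographic signal; an oceanic (UK) enrichment can be switched on.

The raster generator plants blocky latitudinal climate zones with
well-separated (temperature, moisture, elevation) signatures plus smooth
within-zone ramps, a lapse-rate coupling of temperature to elevation,
Gaussian-filtered topography, and randomly placed water (NA) cells.

Not emulated: charring, canopy, sea-spray and manuring effects; irregular
site geography and sampling bias; non-Gaussian dispersion; spatially
correlated residuals within sites. Passing recovery tests therefore shows
the *estimators and plumbing* are correct under the stated generative
model, not that real data meet that model.

## Problem sizes

Tests and the analysis scripts run the full pipeline at deliberately small
scale — a ~94×100-cell stack of 60-km cells covering the study window's
Web-Mercator footprint, ~120 sites, ~5,000 grains — sizes at which k-means,
assignment and the mixing model behave identically to the 1-km continental
case while each run stays in seconds. Cluster recovery is scored with the
adjusted Rand index against planted zones (k matched to the planted count;
at k = 20 the three planted zones are deliberately oversplit and ARI drops,
which the ecozone driver reports honestly).

## Known limitations

* The mixing model ignores animal protein, fish, mushrooms and
  canopy-depleted resources, all of which move collagen δ¹³C more per
  dietary percent than grain does; thresholds are bounds under a grain-only
  diet, and in freshwater-fish-rich regions the true C₄ detection level is
  lower than `T(0.10)`.
* Charring corrections are deliberately not applied (uncorrected values
  compare better across datasets; the effect is ≤ ~0.2‰).
* The regional C₄ defaults rest on few measured millet groups; the
  far-north value in particular derives essentially from Lithuania.
* EPSG:3857 distorts area/distance with latitude; it is used here as the
  published analysis grid, not as an equal-area choice. The nearest-valid
  fallback radius is in projected metres and therefore latitude-dependent
  on the ground.
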