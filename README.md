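# grazecap

**Carrying-capacity accounting for rangelands shared by wild and domestic
ungulates.**

Alpine grasslands such as those of the Qinghai–Tibet Plateau feed both
livestock herds and wild grazers — kiangs (*Equus kiang*) and Tibetan
gazelles (*Procapra picticaudata*) in the county this package models. Setting
a sustainable stocking rate therefore means answering three questions per
grazing-management parcel: how much forage does the grassland grow, how much
of it do the wild ungulates already eat, and how much livestock is actually
there? `grazecap` implements that accounting chain end to end, for rangeland
scientists and land managers:

1. **Wildlife density** — line-transect counts become per-line species
   abundance densities (SAD = count / (2·*w*·*L*) for strip half-width *w* and
   line length *L*), interpolated onto a 5 × 5 km grid by **ordinary kriging**.
2. **Range masking** — a small presence-only **maximum-entropy** (MaxEnt-style)
   habitat model of topographic/climate covariates is thresholded into a
   binary potential-range mask that clips the kriged density surface.
3. **Forage yield** — a peak-season NDVI stack is reduced by the
   **maximal-value composite** and converted to grass yield with the affine
   model *Y* = −47.021 + 440.21·*X*.
4. **The ledger** — per parcel of area *S*:

   - theoretical carrying capacity  *C*_tp = *Y*·*E*·*U* / (*I*·*T*)
     (edible forage ratio *E* = 0.85, utilisation rate *U* = 0.65, intake
     *I* = 4.0 kg/SU/day, *T* = 365 grazing days),
   - wildlife forage offset  *C*_w = Σᵢ *D*ᵢ·*S*ᵢ·*K*ᵢ
     (sheep-unit conversions *K*: kiang = 6, Tibetan gazelle = 0.3),
   - ecological carrying capacity  *C*_t = *C*_tp·*S* − *C*_w,
   - residual carrying capacity  **RCC = *C*_t − actual livestock** (in sheep
     units, SU); a parcel with RCC < 0 is overloaded.

Because the original field, household-survey and satellite data are not
public, the package ships a first-class **synthetic county generator**
(`grazecap.synthetic`): ~27 Voronoi parcels tiling a 160 × 160 km county,
smooth covariate and NDVI fields, two species with known latent density
surfaces calibrated to mean discovery rates of 1.33 and 0.49 animals per km
per season, and a livestock table with a 73/24/3 % cattle/sheep/horse
sheep-unit mix. Every downstream stage can therefore be tested against known
truth.

## Worked example

The county-level ledger, fed with published aggregate inputs (total annual
grass yield 1,293,500 t; 11,397 kiangs and 1,545 gazelles; 338,159 SU of
livestock):

```python
from grazecap import worked_example_ledger

ledger = worked_example_ledger(
    total_yield_tons=1_293_500,
    wildlife_populations={"kiang": 11_397, "gazelle": 1_545},
    actual_sheep_units=338_159,
)
for k, v in ledger.items():
    print(f"{k:>7}: {v:,.1f}")
```

```
   C_tp: 489,492.3
    C_w: 68,845.5
    C_t: 420,646.8
 actual: 338,159.0
    RCC: 82,487.8
```

Read: the grass grown supports ~489k sheep units; the wild ungulates consume
the equivalent of ~69k, leaving an ecological capacity of ~421k; with ~338k
SU of livestock on the ground, the county as a whole could carry roughly
82k SU more — although the parcel-level picture (which the spatial pipeline
produces) is typically much more uneven, with individual parcels overloaded.

The full spatial pipeline on the synthetic county:

```sh
grazecap run --outdir run --seed 0          # all stages
grazecap init-config my.yaml                # editable defaults
grazecap generate --outdir run              # ... or stage by stage:
grazecap density --outdir run
grazecap krige --outdir run
grazecap suitability --outdir run
grazecap yield --outdir run
grazecap account --outdir run
grazecap report --outdir run
```

`run/` then contains the covariate/NDVI/density rasters, the per-parcel
ledger (`parcel_accounts.csv`), the county summary, an RCC choropleth and a
JSON run report from which every number is recomputable (all randomness
flows from the single seed).

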