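# ricesist

Discriminating chronic heavy-metal stress in rice paddies from other
stressors (pest/disease outbreaks, nutrition deficits) using two
consecutive years of per-pixel leaf-area-index (LAI) time series.

Stressors that depress a rice canopy look alike in any single image:
lower LAI, lower NDVI. What separates them is their *spatio-temporal*
signature. Heavy metals persist in soil, so their stress signal lasts
the whole growing season, repeats almost identically the next year, and
clusters in space around contamination sources. Pest and disease
outbreaks are short-lived and scattered; nutrition problems span a
season but vary from year to year. This package turns those
distinctions into a per-pixel index for regional screening by
agricultural remote-sensing practitioners.

## Method

For every rice pixel *i* with LAI series sampled at 5-day steps over
DOY 160–255 in two years:

1. **Stress level** — `S_i = dtw(LAI_sample, LAI_i)`, the constrained
   dynamic-time-warping distance between the pixel's series and an
   unstressed reference series simulated for the same year by a daily
   crop model (radiation-use efficiency × Beer's-law light
   interception, with a stress factor `f ∈ [0, 1]` scaling gross
   assimilation: `CVF_f = f · CVF`). `S` is min–max normalized per year
   and averaged over the two years.
2. **Temporal stability** — `TD_i = dtw(LAI_i,year1, LAI_i,year2)` and
   `TS_i = 1 − (TD_i − TD_min)/(TD_max − TD_min)`. DTW (with a
   Sakoe–Chiba band, default r = 3 samples) absorbs transplanting-date
   shifts between years, so `TS` measures genuine inter-annual change
   in amplitude, not timing.
3. **Spatial clustering** — Anselin local Moran's I of the `TS`
   surface with a 3×3 rice-only neighborhood (row-standardized
   weights), min–max normalized.
4. **Composite index** —
   `SIST_i = (S_norm,i · TS_i · I_norm,i)^(1/3)`, high only where the
   canopy is depressed, the depression repeats across years, and the
   neighborhood agrees.

A particle-swarm calibrator fits `f` to sparse satellite observations
(NDVI converted by `LAI = 0.361·exp(3.69·NDVI)`) by minimizing the mean
squared error, and a synthetic-scene generator produces two-year raster
stacks with known per-pixel truth for all four stress regimes, so the
whole chain is testable without satellite data. Confusion-matrix
utilities (overall accuracy, Cohen's kappa, user's/producer's accuracy)
and 4-connectivity small-object removal support the land-cover mapping
step that precedes the analysis.

## Worked example

```python
import numpy as np
from ricesist import ScenarioConfig, run_synthetic_pipeline, pearson_r
from ricesist.scenes import CLASS_NAMES

result = run_synthetic_pipeline(ScenarioConfig(seed=1))
sist, cls = result.sist, result.truth.classes
ok = np.isfinite(sist)
for code in (0, 1, 2, 3):
    sel = ok & (cls == code)
    print(f"{CLASS_NAMES[code]:<12} n={sel.sum():5d}  mean SIST={sist[sel].mean():.3f}"
          f"  mean TS={result.stress.ts[sel].mean():.3f}")
r = pearson_r(sist[ok], result.truth.contamination[ok])
print(f"Pearson r (SIST vs latent contamination): {r:.3f}")
```

prints

```
healthy      n= 8241  mean SIST=0.147  mean TS=0.877
heavy_metal  n=  359  mean SIST=0.455  mean TS=0.930
abrupt       n=  168  mean SIST=0.223  mean TS=0.535
nutrition    n=  261  mean SIST=0.384  mean TS=0.721
Pearson r (SIST vs latent contamination): 0.797
```

Heavy-metal pixels combine a depressed canopy (high `S`), a repeatable
trajectory (`TS` 0.93, the highest of the stressed classes), and
spatial clustering, so their mean SIST is well above every other
class. The one-year pest/disease pixels and the year-to-year-variable
nutrition zones are filtered mainly by `TS`. The positive correlation
with the generator's latent contamination level shows the index scales
with stress severity, not just presence.

A `ricesist` console command exposes the stages individually
(`simulate`, `calibrate`, `dtw`, `synth`, `accuracy`, `run`, `sist`);
`ricesist run --config config.yaml` writes every surface (stress
level, TD, TS, local Moran's I, SIST) as georeferenced float32 GeoTIFF
plus a JSON provenance manifest.

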