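# rfeq — retail food environment quality

`rfeq` scores food retail outlets on the availability of food groups that
protect against, or raise the risk of, diet-related noncommunicable
disease, and characterizes the spatial structure of those scores. It is
aimed at food-environment researchers and spatial epidemiologists working
with outlet-level market surveys, particularly in low- and middle-income
settings where item-level nutrient data are impractical to collect.

## The indices

Each outlet carries a binary presence flag for 17 food groups: 9 healthy
(dark-green leafy vegetables, vitamin A–rich orange vegetables, other
vegetables, vitamin A–rich fruits, citrus, other fruits, legumes,
nuts/seeds, whole grains) and 8 unhealthy (sugar-sweetened beverages,
baked/grain-based sweets, other sweets, processed meats, unprocessed red
meat, deep-fried foods, fast food/instant noodles, packaged salty snacks).

* **HRFES** (healthy retail food environment score, 0–9): count of healthy
  groups present.
* **URFES** (unhealthy score, 0–9): weighted count of unhealthy groups;
  processed meats count double because of their strong NCD association.
* **RFEQI** (composite quality index, 0–18): `HRFES − URFES + 9`; 18 is
  full healthy variety with nothing unhealthy, 9 the balance point.

Around each outlet, a *retail neighborhood* pools the unique food groups
available across all outlets within 50, 100 and 200 m (focal outlet
included, closed-ball inclusion) and re-scores the union — the food
environment a shopper standing at that outlet actually faces.

On top of the scores the package provides:

* rural/urban contrasts (Welch t, Kruskal–Wallis, Fisher's exact with
  Monte Carlo p-values for r×c tables);
* log-link count regression of each index on retail typology, retailer
  gender, food shelf space and location, reported as incidence rate
  ratios with Wald 95% CIs, McFadden pseudo-R² and AIC;
* Monte Carlo subsampling robustness (repeated 70% subsamples without
  replacement, distribution of replicate means with normality
  diagnostics);
* Ripley's K with isotropic edge correction and pointwise CSR simulation
  envelopes (z_max / r_peak deviation summaries), Global Moran's I with
  conditional-permutation inference, and LISA HH/HL/LH/LL hot/cold-spot
  classification;
* a synthetic-environment generator (Thomas cluster process + surveyed
  category mixtures + typology-conditional stocking) so the whole pipeline
  is testable without survey data.

## Worked example

```python
import numpy as np
from rfeq import *
from rfeq.synth import preset, generate_environment
from rfeq.projection import project_to_plane

cfg = preset("urban", n_outlets=300, seed=42)   # ~5 km^2 informal-settlement ward
records, truth = generate_environment(cfg)
scored = score_buffers(records, BufferSpec((50.0, 100.0, 200.0)))

irr = fit_count_model(scored, outcome="hrfes",
                      covariates=["shelf_space", "gender", "typology"])
pts = project_to_plane(records, origin=cfg.anchor_lonlat)
w = build_weights(pts, "k_nearest", 8)
m = global_moran(scored["urfes"].to_numpy(float), w, permutations=999, seed=0)
env = ripley_k(pts, cfg.window, radii=np.linspace(25, 500, 20),
               simulations=199, seed=0)
```

prints (via the obvious summaries):

```
retailer-level means: {'hrfes': 1.88, 'urfes': 1.89, 'rfeqi': 8.99}
200 m buffer means:   {'hrfes_r200': 7.12, 'urfes_r200': 6.6, 'rfeqi_r200': 9.52}
stall/tabletop HRFES IRR = 3.58 (95% CI 2.33, 5.51)
Moran's I (URFES) = -0.008, permutation p = 0.461
Ripley's K: z_max = 17.0 at r_peak = 150 m
```

Reading: individual outlets offer modest variety (mean HRFES ≈ 1.9 of 9),
but a 200 m walk raises the effective healthy variety to ≈ 7.1 — the
classic neighborhood effect. Stall/tabletop vendors stock healthy groups
at ≈ 3.6× the rate of mobile vendors (the generator's designed ratio is
3). The unhealthy score shows no spatial autocorrelation under this
seed's spatially unstructured stocking, while the outlet *locations*
are strongly clustered (K far above the CSR envelope, dominant scale
≈ 150 m, consistent with the generator's 70 m offspring dispersion).

A CLI mirrors the library: `rfeq synth`, `rfeq score`, `rfeq contrast`,
`rfeq regress`, `rfeq robustness`, `rfeq spatial {moran,lisa,kfunction}`,
and `rfeq run` for the full pipeline with a JSON manifest.

## Layout

```
src/rfeq/
  catalog.py       food-group catalog (schema + config loading)
  io.py            retailer records, CSV/GeoJSON/window I/O
  projection.py    WGS84 -> local planar meters (ENU)
  indices.py       HRFES / URFES / RFEQI scoring
  neighborhood.py  buffer pooling and re-scoring
  contrasts.py     Fisher / Welch / Kruskal-Wallis, descriptives
  regression.py    count GLM -> IRR tables
  robustness.py    subsampling sensitivity analysis
  spatial/         weights, Moran + LISA, Ripley's K
  synth.py         synthetic environments (Thomas process + mixtures)
  pipeline.py      end-to-end orchestration + manifest
  cli.py           click CLI
```

See `docs/methods.md` for the statistical details and design choices.
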