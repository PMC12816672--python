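# floatscan

Detection, typing, sub-pixel quantification, and trend analysis of floating
algae (FA) in multiband top-of-water reflectance imagery — driven end to end
by a synthetic-scene generator so every stage is testable without satellite
downloads.

The pipeline stages:

1. **synthetic scenes** (`floatscan.scenes`) — reflectance rasters with
   implanted FA patches obeying an exact linear mixing model
   `R = chi * R_fa + (1 - chi) * R_water + aerosol`, plus clouds, shadows,
   glint and shallow-water confounders, truth masks / chi fields, a built-in
   7-type endmember spectral library, and monthly area series
   (seasonal cycle + secular trend + noise).
2. **spectral index** (`floatscan.indices`) — the red-edge baseline-
   subtraction index (667/748/869 nm triple) and target-minus-water deltas.
3. **labeling** (`floatscan.labeling`) — headless "ground truth" masks from
   index rasters using declarative regions with absolute or robust
   (median + k·MAD) thresholds and forced-negative regions.
4. **segmentation** (`floatscan.segmentation`) — a residual encoder-decoder
   ("ResUNet"-style) implemented in pure NumPy with explicit backprop:
   8-layer inputs (7 normalized bands + index), NaN-padded tiling with
   lossless reassembly, batch 32, initial learning rate 0.05 decayed by
   e^-0.1 per epoch from epoch 11, up to 50 epochs, 70/30 split.
5. **typing & unmixing** (`floatscan.unmixing`) — FA type from the spectral
   shape of the target-minus-water difference (cosine similarity on
   mean-subtracted spectra; scale- and flat-offset-invariant) and sub-pixel
   fractional cover chi from the ratio of index differences (exact and
   open-water-approximation modes).
6. **compositing** (`floatscan.compositing`) — monthly/annual mean-cover
   grids with observation-count denominators, areal integration by zone and
   type, and cumulative niche-footprint accounting.
7. **trends** (`floatscan.trends`) — calendar-month de-seasoning, two-sided
   Mann-Kendall test (tie-corrected variance, continuity-corrected Z),
   Theil-Sen slope with rank-based 95% CI, and percent-per-year rates
   against an explicit baseline convention.
8. **evaluation** (`floatscan.evaluation`) — chi-weighted Precision /
   Recall / F1 / IoU (min/excess weighting; reduces to binary counting when
   chi = 1).

## CLI

```bash
floatscan simulate --out sim/ --seed 1 --n-scenes 4      # synthetic scenes
floatscan afai sim/scene_000.nc --out afai.tif           # index raster
floatscan label afai.tif --regions regions.yaml --out truth.tif
floatscan quantify sim/scene_000.nc --mask truth.tif --out det.nc
floatscan composite det.nc --period 2003-6 --out grid.npz
floatscan trend series.csv --out trends.csv
floatscan evaluate --manifest pairs.csv --out report.json
floatscan run --config pipeline.yaml                     # full pipeline
```

`floatscan run` executes a YAML-configured multi-stage run (simulate →
afai → label → train → segment → quantify → composite → trend → evaluate),
funnels all randomness through per-stage seeds derived from one global seed,
and writes a manifest with SHA-256 hashes of every output; identical
config + seed reproduces byte-identical outputs.

## File formats

Scenes and detections travel as classic NetCDF (xarray/scipy backend);
single-layer rasters as TIFF with JSON metadata; spectral libraries as CSV
(`fa_type, wavelength_nm, reflectance`); area series as CSV
(`year, month, fa_type, zone, area_km2`); labeling regions as YAML; model
checkpoints as `.npz` with the architecture config embedded.
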