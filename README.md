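# ceodquant

Quantification of biomolecular condensates inside **cytosolic
extract-in-oil droplets (CEODs)** — surfactant-stabilised water-in-oil
emulsion droplets that encapsulate translation-competent cell extract and
serve as cell-sized reactors for studying stress-granule-like
liquid–liquid phase separation.

The package is an open, tested reimplementation of the image-analysis
workflow used for such experiments, aimed at microscopists and
condensate-biology labs who want the quantification to be reproducible and
scriptable rather than locked inside a commercial acquisition suite. It
covers:

- **Synthetic micrograph generation** (`ceodquant.synthgen`): two-channel
  scenes (reporter fill + condensate marker) with exact ground truth —
  log-normal droplet diameters (median e^µ ≈ 25.3 µm), fill intensity
  correlated with diameter, irregular bright condensates with perimeters
  targeting 15–34 µm, shot and read noise, and single-exponential FRAP
  traces. Every downstream stage is testable without any external data.
- **Segmentation** (`ceodquant.segment`): droplet ("mother") detection on
  the reporter channel (Gaussian pre-filter, Otsu or fixed threshold, hole
  filling); condensate ("child") detection on the marker channel (median
  denoise, rolling-ball background subtraction, fixed threshold of 60 on
  the 8-bit-equivalent scale); mother–child assignment by centroid with a
  largest-overlap fallback.
- **Morphometry** (`ceodquant.morpho`): per-object area (µm²), Crofton
  perimeter (µm), circularity `4π·A/P²`, per-droplet condensate-area
  fraction, percent condensate-positive droplets, the focus/condensate
  perimeter classification (≤ 15 µm / 15–34 µm / larger), and replicate
  histograms.
- **FRAP fitting** (`ceodquant.frap`): reference normalization to a
  non-bleached region, least-squares fit of
  `I(t) = P − (P − I₀)·e^(−kt)`, half-time `t½ = ln2/k`, mobile fraction.
- **Statistics** (`ceodquant.stats`): Pearson line-profile colocalisation,
  upper-tail hypergeometric set-overlap enrichment computed in log space,
  Benjamini–Hochberg FDR adjustment.

## Worked example

Simulate a stressed scene, quantify it, and fit a FRAP trace:

```bash
ceodquant simulate --out scene --seed 5
# wrote 25 droplets / 38 condensates to scene

ceodquant quantify --reporter scene/reporter.tif --marker scene/marker.tif \
    --pixel-size 0.65 --out quant
# droplets: 25
# condensates: 37 (0 orphans)
# % droplets with condensates: 88.0
# outputs in quant
```

`quant/` then contains per-object tables (`droplets.csv`,
`condensates.csv`), per-droplet summaries, label maps, a replicate summary
JSON and a run manifest sufficient to reproduce the run bit-identically.
Here 88% of the droplets carry at least one detected condensate (the
generator seeds 80% of droplets, each with one or more condensates, and
droplets too small to host one are skipped); one generated condensate fell
below the detection threshold after denoising, leaving 37 of 38. Each
condensate row lists its area, perimeter, circularity and parent droplet.

The same stages are available as library calls:

```python
import ceodquant as cq

channels, droplets, condensates = cq.generate_scene(cq.SceneConfig(rng_seed=5))
labels = cq.segment_droplets(channels.reporter, cq.SegmentationParams())
records = cq.measure_objects(labels, channels.reporter)
```

For FRAP, a trace CSV with `time_s, bleach, reference` columns fits in one
command:

```bash
ceodquant frap --trace trace.csv --prebleach 5 --out fit.json
# half-time: 4.80 s (k = 0.1444 /s, mobile fraction = 0.88)
```

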