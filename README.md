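# mdxquant

Quantitative muscle histomorphometry and RT-qPCR analysis for dystrophic
(mdx-type) mouse models, with a built-in synthetic slide generator that
makes every stage testable against known ground truth.

## What it measures

Dystrophic skeletal muscle — e.g. the masseter of dystrophin-deficient
mdx⁵ᶜᵛ mice — is characterised on slides by a small set of standard
readouts, all of which this package computes:

- **Fibre morphometry.** Muscle fibres are segmented from the laminin
  immunofluorescence channel (the basement membrane forms bright ridges
  around dark fibre interiors). Fibre size is reported as the **minimum
  Feret diameter** — the smallest distance between two parallel supporting
  lines over all orientations, computed by rotating calipers on the convex
  hull — and obliquely/longitudinally sectioned profiles are excluded with
  a circularity filter: fibres with `4πA/P² < 0.3` are dropped.
- **Centronucleated fibres (%CNF).** DAPI-stained nuclei are assigned to
  fibres and the Euclidean distance from each nucleus centroid to its
  fibre border is read off an exact distance transform. A nucleus is
  *internal* when its border distance exceeds `α·r_eq` (default α = 0.3,
  `r_eq = √(area/π)`); a fibre with ≥ 1 internal nucleus is a CNF — the
  classic marker of degeneration/regeneration cycles.
- **Fibrosis.** Sirius Red/Fast Green brightfield slides are unmixed by
  colour deconvolution in Beer–Lambert optical-density space
  (`OD = −log10(I/I₀)`, per-stain densities via the inverse stain matrix);
  the Sirius Red pseudo-channel is thresholded within tissue and collagen
  area is reported as a percentage of tissue area.
- **Necrosis.** On H&E-like slides, mononuclear infiltrate is detected as
  tissue whose local haematoxylin-positive area fraction (disk
  neighbourhood) exceeds a threshold; necrotic area % of tissue.
- **Marker scoring.** IgM⁺ fibre fraction (sarcolemmal permeability),
  eMyHC⁺ fibre density per mm² (active regeneration), PDGFRA⁺ cell
  fraction (fibro-adipogenic progenitors), damage/repair/healthy region
  classification from F4/80 and eMyHC, and p-SMAD2 positive area locally
  normalised to each region class (TGF-β signalling).
- **RT-qPCR.** Relative quantities against per-gene dilution-series
  standard curves (`E = 10^(−1/slope) − 1`), geNorm reference-gene
  stability `M`, pairwise variation `V(n/n+1)`, normalization factors
  (geometric means of reference quantities) and group fold changes.

Because real studies rarely deposit their slides, the package ships a
**phantom generator** (`mdxquant.synthdata`): tessellated convex fibres
bounded by a laminin band, peripheral/central nuclei at a controllable CNF
fraction, focal infiltrate lesions, exact-area collagen deposits rendered
through the same Beer–Lambert forward model the analysis inverts, and
qPCR plates under the log-linear dilution model. Presets `wt`, `mdx_3m`,
`mdx_6m`, `mdx_12m` mirror the published age course of dystrophic masseter
pathology (CNF 0/60/55/50 %, collagen rising with age).

## Worked example

```python
from mdxquant import synthdata, segmentation, morphometry, centronucleation as cn

spec = synthdata.preset("mdx_3m", seed=1)          # 60 % CNF ground truth
channels, brightfield, truth = synthdata.generate_phantom(spec)

fibers = segmentation.segment_fibers(channels["laminin"])
metrics = morphometry.apply_circularity_filter(morphometry.compute_morphometry(fibers))
retained = set(metrics.loc[~metrics.excluded, "fiber_id"].astype(int))

_, nuclei = segmentation.segment_nuclei(channels["DAPI"])
records = cn.assign_nuclei(nuclei, fibers)
cn.compute_border_distances(records, fibers)
summary = cn.classify_cnf(records, fibers, retained)
print(f"%CNF = {summary.cnf_percent:.1f} over {summary.n_fibers_retained} fibres")
print(f"mean min-Feret = {morphometry.fiber_size_summary(metrics)['mean_um']:.1f} um")
```

prints

```
%CNF = 61.4 over 412 fibres
mean min-Feret = 27.2 um
```

against a generated truth of 60.0 % CNF and a 28 µm target size. The same
stages run from the shell:

```bash
mdxquant simulate --preset mdx_3m --seed 1 --out slide/
mdxquant fibers --laminin slide/fluorescence.ome.tif --out seg/
mdxquant fibrosis --rgb slide/sirius_fastgreen.tif --pixel-size-um 1.0 --out fibrosis.csv
mdxquant run --config study.yaml
```

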