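# Methods

This note documents the models and procedures implemented in `mdxquant`,
the defaults chosen where the underlying assays leave them open, and what
the synthetic phantoms do and do not establish about real slides.

## Fibre segmentation

Fibre detection is a deterministic boundary-ridge watershed on the laminin
channel. The smoothed image (Gaussian, `smoothing_sigma_um = 1`) is
binarised into a boundary band (Otsu by default; a fixed threshold is
available for exact reproducibility); fibre interiors are the connected
components of tissue outside the band, cleaned of fragments below
`min_fiber_area_um2 = 100`; a watershed on the ridge landscape resolves
residual pixels before the band itself is reset to background (label 0).
Learned segmentation models can replace this stage behind the same
input/output contract (`ChannelImage → FiberLabelMap`); nothing downstream
depends on how the label map was produced.

Border-touching fibres are flagged and excluded from morphometry by
default because their Feret diameters are censored by the field of view.
The minimum fibre area and the border-exclusion default are implementation
choices, documented here rather than inherited from any particular study.

Nuclei are segmented from DAPI by Otsu thresholding, a Euclidean distance
transform, and a watershed seeded at distance-map maxima at least
`seed_min_distance_um = 3` apart (the distance map is lightly smoothed so
plateau ridges do not over-seed). Objects under `min_nucleus_area_um2 = 6`
are removed.

The tissue mask uses two different strategies on purpose: brightfield is
thresholded at a low fixed total OD (0.1) because glass is near zero OD
while any tissue absorbs — an adaptive threshold would instead split
tissue from the darker nuclei; fluorescence uses half the Otsu threshold
of the channel followed by closing and hole-filling, which keeps the
tissue boundary rather than only the brightest label. A laminin-only
tissue mask cannot see into large lesions that open to the field edge;
when a brightfield image is available it is the better tissue reference.

## Morphometry

Minimum/maximum Feret diameters are measured on the convex hull of the
region's pixel-corner vertices by rotating calipers (the minimum width is
attained flush with a hull edge; concavities cannot affect Feret widths).
Degenerate point sets (collinear) return their maximum extent with a flag.

Perimeter and area for circularity use the sub-pixel marching-squares
contour polygon rather than pixel-edge counting: pixel-edge perimeters
overestimate `P` and would bias `4πA/P²` low, distorting the 0.3 exclusion
cutoff. Raw circularity slightly above 1 (contour discretization on small
disks) is clipped to 1. The exclusion rule is a strict inequality
(`circularity < 0.3` excluded; exactly 0.3 retained), and the classical
`4πA/P²` form is used; solidity-adjusted variants used by some platforms
are not.

## Centronucleation

Each nucleus is assigned to the fibre label under its centroid; centroids
on the boundary band are interstitial (fiber id 0) and never enter the CNF
statistic. Border distance is the exact Euclidean distance transform of
the fibre's interior sampled at the centroid pixel, i.e. the minimum
centre-to-centre distance to any non-fibre pixel — the centroid (not the
nucleus edge) is used because it is robust to nucleus-segmentation noise.

The internality cutoff is genuinely open in the assay, so both rules are
exposed: *relative* (default), internal iff distance > `α·r_eq` with
α = 0.3 and `r_eq = √(area/π)`; and *absolute*, distance > `d₀` µm. α = 0.3
keeps subsarcolemmal (peripheral-rim) nuclei peripheral with margin while
truly central nuclei — which sit near 0.5·r_eq or deeper — classify
internal. Fibres excluded by the circularity/border filters are excluded
from the CNF denominator.

## Stain separation and scoring

Brightfield stains mix linearly in OD space: `OD_c = −log10(max(I_c,
floor·I0_c)/I0_c)` per RGB channel with an intensity floor (default 1/255)
keeping zero pixels finite. Two-stain models are completed with an
orthogonal residual vector; the stain matrix condition number is checked
(near-parallel vectors raise). Negative unmixed densities are clipped to
zero and the clipped-pixel fraction is reported — a silent clip would hide
a wrong stain model. Default Sirius-Red/Fast-Green and H&E absorption
vectors are published, widely used values; they are fields of `StainModel`
and overridable per dataset.

Collagen scoring thresholds the Sirius Red density within tissue (Otsu,
guarded by a minimum OD of 0.15 so a collagen-free slide is not split on
noise; fixed-threshold mode available) and reports positive area as a
percentage of tissue area. The score is invariant to uniform illumination
rescaling because `I` and `I₀` enter only as a ratio.

Necrosis combines the two operational components visible on H&E:
mononuclear infiltrate — tissue where the local fraction of
haematoxylin-positive pixels within a 10 µm disk exceeds 0.5 (the disk
mean is boundary-normalised, so full coverage scores exactly 1) — and,
optionally, fibres with fragmented sarcoplasm (interior eosin coefficient
of variation above a cutoff). The default threshold of 0.5 sits midway
between sparse nuclear coverage in intact tissue (≈ 0.05) and confluent
basophilic infiltrate (≈ 1), which makes the detected boundary cross near
the true lesion edge.

## Marker scoring

Positivity thresholds default to Otsu within tissue per channel (the
assays publish no intensity cutoffs); every function accepts a fixed
threshold. A fibre is marker-positive when more than
`min_positive_area_fraction = 0.3` of its interior is above threshold —
whole-fibre sarcoplasmic staining, robust to edge bleed. Cells are scored
on the *median* marker intensity in a 2–5 µm ring around the nucleus
centroid; the median is robust to partial bleed from an adjacent positive
cell, which covers only a minority of the ring.

Region classification: *damage* = tissue whose local F4/80-positive
fraction (10 µm disk) exceeds 0.5; *repair* = remaining tissue within
20 µm of an eMyHC-positive pixel; *healthy* = the rest; precedence damage
> repair > healthy, so the classes partition the tissue mask. "Locally
normalised" p-SMAD2 is interpreted as positive-area fraction within each
region class — by construction independent of how large the other classes
are; classes with zero area are reported missing, never 0.

## qPCR

Standard curves are least-squares fits of mean Ct against log10 relative
input over ≥ 3 dilution points; efficiency `E = 10^(−1/slope) − 1` (slope
−3.3219 ⇔ 100 %); positive slopes mark a curve invalid. Technical
replicates are aggregated by geometric mean on the quantity scale
(arithmetic mean on the Ct scale), with the replicate CV reported.

geNorm stability for gene j is the mean over other candidates k of the
sample standard deviation of `log2(q_j/q_k)` (log2 basis as in the
original description); ranking proceeds by iterative exclusion of the
highest-M gene, and pairwise variation `V(n/n+1)` is the SD across samples
of `log2(NF_n/NF_{n+1})`. Normalization factors are geometric means of the
reference genes' quantities rescaled to overall geometric mean 1; the
anchoring means a per-sample rescaling is absorbed up to one common
factor, leaving all ratios and fold changes invariant. Both single-
reference (e.g. Hprt only) and multi-reference geNorm normalization are
first-class. Fold changes are ratios of group geometric means of
normalized quantities.

## The phantom generator

Geometry. Seed points on a jittered hexagonal lattice grow into a
multiplicatively weighted nearest-seed tessellation; per-seed weights are
lognormal with unit mean and the requested coefficient of variation, so
the minimum Feret distribution can be imposed directly (Feret is the
reported size metric, hence the choice of a lattice tessellation over a
plain Voronoi diagram, whose cell sizes could not be targeted). The
lattice spacing is the target minimum Feret plus the band thickness, and
the laminin band (total thickness `boundary_thickness_px`, default 4 px)
is carved symmetrically from adjacent cells, which leaves interiors with
the target width. Lesions are bounded by their own band, as degenerating
fibre clusters retain basement membrane.

Nuclei. Each fibre gets ≥ 1 peripheral nucleus (border distance 1–2.2 px);
the requested CNF fraction of fibres additionally gets a central nucleus
at the interior's distance-transform maximum, which always lies beyond
0.5·r_eq — recoverable by the classifier's 0.3·r_eq default with margin.
Interstitial cells (2 per fibre) sit on the band; the requested PDGFRA⁺
fraction of all cells is drawn from that interstitial pool.

Area-fraction truths are exact: collagen deposits and infiltrate lesions
are unions of random disks clipped to tissue and trimmed pixel-by-pixel to
exactly the requested area, so stored true fractions equal the mask
fractions to machine precision.

Rendering. Fluorescence channels are signal amplitudes (laminin 200, DAPI
180, markers 150 on a 16-bit scale) plus Gaussian noise of SD =
signal/`marker_snr` everywhere — a desk-scale stand-in for shot noise.
Brightfield images are rendered from the ground-truth density maps through
the same Beer–Lambert forward model the analysis inverts, at an 8-bit
white point of 255 per channel.

Randomness. One integer seed feeds a `numpy` `SeedSequence` that is split
into named child generators (geometry, lesions, nuclei, collagen, markers,
noise), so identical specs give bit-identical images and tables.

Presets. `wt` and `mdx_3m/6m/12m` encode the published age course of
dystrophic masseter pathology: CNF 0 % in wild type (reported only as
"not present", so the preset uses exactly 0) and 60/55/50 % at 3/6/12
months; collagen fraction rising with age in the dystrophic presets and
low in wild type; active damage (IgM⁺ fibres, necrosis) and regeneration
(eMyHC⁺ density) peaking at 3 months; mean minimum Feret smaller in
dystrophic muscle (28–30 µm vs 38 µm, CV 0.25 vs 0.13). Quantities the
source study reports only as trends (collagen, IgM, eMyHC levels; wild
type fibre size) use representative values chosen once; they set the
simulation conditions, not claims about any particular dataset.

What the phantoms do not emulate: photorealistic texture, 3-D tissue,
scanner artefacts (vignetting, stitching), fibre typing, chromatic or
focus aberrations, and true Poisson photon statistics. Passing recovery
tests on phantoms therefore demonstrates the correctness of the
quantification logic under the stated geometry and noise model — not
segmentation robustness on arbitrary real slides.

## Problem sizes and numerical choices

Recovery tests use 640–768 px fields (≈ 350–400 fibres, matching the
hundreds of fibres a real cross-section yields) for preset-level checks
and 384–448 px fields for unit-level checks. Oracle tests compare against
brute force: exhaustive 0.1° rotation scans for Feret widths, exact
per-pixel minimum distances for the border transform, and direct
evaluation of the geNorm definition. Thresholding ties are avoided by
strict inequalities throughout (`> threshold` positive); Otsu on a
constant channel returns "nothing positive" rather than an arbitrary
split; empty denominators (no retained fibres, empty tissue, zero cells,
empty region class) raise explicit errors or report missing values instead
of silent zeros.

## Known limitations

- The boundary-ridge watershed requires a laminin-like ridge signal; it is
  not a general instance-segmentation method and will under-segment when
  boundaries are broken at scale comparable to the smoothing radius.
- Fragmented-sarcoplasm detection (the second necrosis component) is
  implemented but off by default; the phantom drives necrosis through
  infiltrate only.
- The damage/repair/healthy partition uses fixed geometric defaults
  (10 µm/0.5 damage density, 20 µm repair adjacency); these are config
  parameters, not biologically validated constants.
- Inferential statistics (ANOVA, post-hoc tests, distribution comparisons)
  are intentionally out of scope; the pipeline exports tidy per-sample and
  per-group tables for external statistical software.
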