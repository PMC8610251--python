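# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `lysoquant`, in the spirit of the methods sections of
simulation/analysis packages: what is computed, under which assumptions,
and what the validation does and does not show.

## Coordinate and rendering conventions

Arrays are `(z, y, x)`; physical coordinates are micrometres with the
origin at the image corner and a pixel of index `i` and spacing `s`
centred at `(i + 0.5)·s`. This half-pixel convention is applied
consistently in the generator and in every centroid computation, so
recovered positions can be compared to ground truth without a
half-pixel fudge.

The synthetic renderer is a deliberately simple confocal approximation:
binary rasterization of geometry (voxel-centre membership for spheres
and disks; anti-aliased strokes for filaments), isotropic Gaussian blur
of `psf_sigma` μm standing in for the PSF, additive cytosolic background
inside cell regions, optional Poisson resampling (`poisson_scaling`
photons per intensity unit), and additive Gaussian read noise. With zero
blur and noise, the set of above-background pixels is *exactly* the
rasterized geometry — the conservation property several tests rely on.
It does not model vectorial/axially elongated PSFs, spectral
bleed-through, photobleaching, or cell-shape dynamics (e.g. the wobble
of rounded macrophages in live imaging); conclusions from synthetic
recovery therefore speak to the *estimators*, not to acquisition
artifacts.

### Default acquisition parameters

| parameter | default | rationale |
|---|---|---|
| `z_spacing` | 0.3 μm | spinning-disc stacks of ~45–55 planes at 0.3 μm |
| `n_planes` | 50 | middle of the 45–55 range |
| `pixel_size_xy` | 0.1 μm | plausible for a 63×/1.4 NA system; a config choice, not a measured value |
| `psf_sigma` | 0.1 μm | ≈0.25 μm lateral FWHM, typical high-NA confocal |
| `frame_interval` | 4 s (RAW preset) / 8 s (RPE preset) | live-imaging intervals; 3 min at 4 s and 6 min at 8 s both give 46 frames |
| `background_level` | 100 | arbitrary intensity units |
| `gaussian_sd` | 8 | read noise ~8% of background |
| sphere radius | 0.7 μm | estimated radius of intact lysosomes |

Object amplitude defaults to **2× the background**. This is a
deliberate coupling: the analysis thresholds at 2× the mean cytosolic
intensity, and with amplitude = 2×background that threshold sits at the
*half-maximum* surface of a blurred object — the classical FWHM sizing
criterion, which makes segmented size approximately blur-independent.
With other contrast ratios the 2× threshold cuts the blurred edge above
or below the true surface and sizes drift accordingly; that drift is a
property of threshold sizing in general, not of this implementation.

### Sphere placement

Spheres are placed uniformly in a cylindrical cell volume with bounded
rejection sampling (failure raises an error naming the cell). Separated
scenes enforce centre distance ≥ (r₁+r₂) + clearance, where clearance =
max(4·psf_sigma, 2 pixels), so blurred objects remain separable — a
placement budget of half the radius sum would allow merged blobs and
make "n spheres in, n segments out" unachievable by construction.
`coalesced=True` instead places *touching pairs* at a configurable
centre separation (default 1.1 μm for 0.7 μm spheres, i.e. genuinely
overlapping), the fixture for coalescence and watershed tests. Pair
axes lie in-plane, where resolution is isotropic.

Constant-velocity time-lapse tracks start inside the sub-box from which
the entire path stays in frame whenever that sub-box is non-empty, so
the ground-truth polyline speed equals the nominal speed; random walks
use reflecting boundaries, which keep exact truth positions in-frame
without truncating tracks.

## Lysosome volumetrics

Thresholding is strict (`voxel > threshold`), so a uniform image yields
zero segments deterministically; the volume gate is strict
(`volume > 0.3 μm³`), a literal reading of "greater than". Connectivity
is 26 in 3D (8 in 2D) — the permissive standard, tested explicitly
against a brute-force flood fill.

Watershed splitting operates per connected component: seeds are local
maxima of the Euclidean distance transform computed with physical
sampling (so the 0.3 μm z-step is weighted correctly), thinned to a
minimum physical separation equal to the edge of a cube of the minimum
particle volume (0.3^(1/3) ≈ 0.67 μm), in decreasing-depth order with
scan-order tie-breaks; the watershed then floods the inverted distance
transform restricted to the component, which conserves the voxel set by
construction. Deeper seeds get lower labels, and equidistant voxels
resolve to the lower label, making output deterministic. The
commercial tool originally used for this analysis does not document its
watershed; only conservation and truth-recovery properties are claimed,
not voxel-level equivalence with any particular product.

Validation (test suite and `scripts/acceptance.py`): on stacks of
twenty 0.7 μm spheres at 0.1×0.1×0.3 μm voxels, all spheres are
recovered with individual volumes a few percent from the closed form
4/3·π·0.7³ ≈ 1.437 μm³; 0.4 μm spheres (0.268 μm³) are always excluded
by the gate; merged pairs analyzed without splitting halve the count and
conserve total volume to within a few percent; watershed recovers two
labels on touching pairs at ≥1.1 μm separation.

## Motility

Linking is greedy nearest-neighbour in ascending distance order with a
hard gate (default 2 μm/frame, generous against observed lysosome
speeds), no gap closing, merging or splitting; ties resolve by track id
then detection index, so linking is deterministic given the input.
Tracks shorter than 3 points are excluded from population tables (with
a logged count): two-point speeds are dominated by detection noise.
These are the simplest defensible tracker semantics; the original
analysis used a commercial tracker with unreported settings, so
population-level comparisons with published motility values are out of
scope — only synthetic recovery is claimed (speed within 5% for
constant-velocity scenes at both frame-interval presets; in practice
recovery is within ~0.5%).

## Skeleton morphometry

Images are min–max converted to 8-bit before thresholding, mirroring
the original workflow; Otsu (within the cell region) is the default
threshold, a fixed 8-bit value is accepted. Thinning uses standard 2D
topology-preserving skeletonization.

Graph analysis classifies skeleton pixels by 8-neighbour count and
applies two cleanups, both config-exposed:

1. **Spur pruning** — branches shorter than 3 pixels terminating at an
   endpoint are removed (thinning artifacts at thick junctions), with
   reclassification iterated to a fixed point.
2. **Junction merging** — 8-adjacent junction-candidate pixels count as
   one junction, and junction–junction branches shorter than the prune
   length are contracted into a single node. Thinning a thick crossing
   can emit two junction clusters a couple of pixels apart; the measure
   of interest is junctions, not junction pixels.

Branch length accumulates chamfer steps (1 orthogonal, √2 diagonal,
times the pixel size), the convention of the standard skeleton-analysis
plugin; branch lengths are measured between node boundaries, so arms of
a cross measure from the junction cluster's edge. Closed loops with no
junction are reported as single cyclic branches.

Patch analysis: watershed markers are the connected plateaus of the
distance transform above 60% of each component's maximum depth. The
peak-based policy used for lysosome splitting over-seeds the flat
ridges of 2D patches (a convex square would be shredded); the
relative-height rule keeps convex patches whole and splits lobes joined
by shallow necks. Both maximum and mean patch area are emitted; maximum
is the headline column, since per-cell *maximum* patch area is the
better-defined variant of the published measure.

Validation: junction and branch counts match the generating graph
exactly on rendered networks (widths 2–4 px, junction separations
≥10 px), and mean branch length is within 10% (end effects at nodes);
both proxies remain exactly that — morphology proxies, not absolute
descriptors.

## Intensity metrics

F_H/F_L uses the mean of the 10 highest over the 10 lowest
width-averaged profile values; means and sums are equivalent for equal
counts. Width-3 averaging precedes sorting. A non-positive F_L
(over-subtracted background) is an error, not a clamp. Line placement
reproduces the "predetermined grid" blinding intent deterministically: a
fixed 4×4 anchor grid over the cell bounding box, nucleus-overlapping or
out-of-cell lines discarded, and a seeded choice of k survivors.

Organelle-to-cytosol ratios build the organelle mask by thresholding the
reference channel at 2× its cytosolic mean (one thresholding doctrine
throughout the package), then ratio the background-corrected marker
means over mask vs. cytosol-minus-mask. An empty reference mask returns
a flagged no-value result rather than 0, which would be a fake
measurement.

Puncta counting gates 8-connected components on area. The default gate
is (50, 1000) μm² as published for galectin-3 puncta; that unit is
implausibly large for puncta at typical magnifications (it is plausibly
pixel² in origin), so the gate is faithful-by-default and fully
config-exposed rather than silently corrected. Lysosome association
uses the Euclidean distance transform of the lysosome background:
a punctum is associated if its centroid is inside a lysosome or within
`association_distance` (default 0.25 μm ≈ 2–3 pixels — no published
criterion exists, so the value is exposed) of its boundary.

## Phagosome–lysosome fusion

Any overlap between an all-bacteria component and the external-label
mask classifies the whole component external (antibody labelling marks
whole bacteria); remaining components of ≤4 pixels are treated as noise
(the original removal was manual; the area gate is config-exposed).
Dilation uses the discrete Euclidean disk (radius 3 px default — "to the
phagosome edge" is inherently a per-dataset choice, so a sensitivity
scan over radii 1–6 is available in the CLI). External pixels are
excluded after dilation, so no external-label pixel can ever contribute
to a score.

The scored region is the **membrane shell**: the dilated internal mask
minus the bacterial body. Including the body would dilute the
membrane-bound LAMP-1 by the unlabelled phagosome lumen (a factor of
~2.5 for a 0.5 μm bacterium and 3-pixel shell) and make the score
dominated by mask area rather than fusion signal. Per-cell scores are
emitted both as the mean over the union of the cell's shells (headline)
and as the mean of per-phagosome means, since either convention appears
in practice; cells without phagosomes are excluded with a logged count.

Limitation: a band-mean estimator under PSF blur loses edge intensity of
order 2σ/(w·√(2π)) — about 8–10% for a 0.3 μm shell at σ = 0.1 μm. The
noise-robustness validation therefore renders without blur (noise at
SNR ≥ 10; measured recovery error <2%), while the *directional*
comparison (half-intensity "reduced fusion" scenes scoring below matched
controls in every replicate) holds under full blur and noise. Absolute
ring-intensity recovery under heavy blur is not claimed; relative
comparisons, which is how such scores are used, are unaffected.

## Statistics

Two groups: two-tailed unpaired Student's t-test (pooled variance).
More: one-way ANOVA with Tukey HSD on all pairs, using the Tukey–Kramer
generalization for unequal group sizes. Significance is declared at
P < 0.05. The unit of analysis defaults to experiment means — cells
within an experiment are not independent, and testing per cell
pseudo-replicates — with a per-cell option, and both `n_experiments`
and `n_cells` always reported. Vehicle normalization divides each value
by its own experiment's vehicle mean (vehicle mean ≡ 1 per experiment);
a missing vehicle group is an error naming the experiment. The ANOVA/
Tukey/t-test routes are checked against textbook sums-of-squares and
studentized-range formulas to 6 decimals, including the F = t² identity
on two-group data.

## Problem sizes in the validation suite

The test suite and acceptance script use scene sizes chosen to exercise
the estimators well clear of boundary effects while remaining quick on a
single CPU: 160²×50-voxel stacks with 20 spheres (10 seeds), 200²
phagosome scenes (50 replicates), 400² filament networks with 4
junctions + 3 isolated segments (20 seeds), and time-lapse fields sized
so constant-velocity paths of 20 intervals fit in-frame. The full suite
runs in well under a minute; the acceptance script in a few seconds.
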