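# Methods

This note documents the models, conventions and numerical choices behind
`afmstripes`, and what the synthetic phantoms do and do not establish
about real AFM data.

## Coordinate and calibration conventions

Images are row-major with the origin at the top-left pixel; `x` is the
column index and `y` the row index (both 0-based). The physical position
of pixel `(r, c)` is `(c·p, r·p)` with `p = pixel_size_nm`. Angles are
measured counterclockwise from the image x-axis, degrees in the API,
radians internally. Lengths are reported between pixel centers, in nm.
Defaults mirror the analyzed low-magnification frames: 240 × 240 px at
1.5 nm/pixel. Bead-assay images default to 0.943 µm/pixel with 1.6 µm
beads.

## Phantom generator

A molecule phantom is rendered from a backbone polyline:

* **Strand**: a ridge of Gaussian cross-section whose full width at half
  maximum equals the apparent stripe width (default 7.5 nm) and whose
  crest height is the strand height (default 3.0 nm). The Gaussian
  cross-section is a stand-in for tip convolution — only apparent widths
  are observable, not tip geometry.
* **Knots and globule**: radially symmetric Gaussian bumps (the `radius`
  parameter is the Gaussian σ) centered at scripted backbone arclengths.
  Bumps combine with the ridge by **pixelwise maximum**, not sum, so a
  scripted peak height is exactly the rendered maximum — the same way
  peak heights are read off real height maps. Class-phantom knots use
  σ ∈ [3.2, 4.2] nm: tip convolution broadens every feature to at least
  the strand's apparent width (σ ≈ 3.2 nm at 7.5 nm FWHM), so a knot
  narrower than the strand would be physically inconsistent (and would
  be erased by the 3 × 3 median filter, being only ~2 px wide).
* **Noise**: i.i.d. Gaussian pixel noise (default 0.2 nm s.d. for class
  phantoms), seeded; identical (spec, seed) pairs render bit-identically.

Ground truth records two length notions: the backbone **end-to-end**
distance (maximum chord of the polyline) and the **footprint length**
(maximum chord of the half-crest-height footprint). The measured length
metric operates on the binarized footprint, which extends roughly
FWHM/2 ≈ 3.75 nm beyond each backbone end, so footprint length — not
end-to-end distance — is the oracle against which measured lengths are
compared.

Class phantoms: class 1 scripts a mid-backbone bend uniform in
[0°, 15°], class 2 in [45°, 120°], both with terminal knots of peak
height 4.2–4.8 nm; class 3 draws one of single-knot, ball-like (globule
only) or multiply folded (2–3 bends of 95–150°) morphologies. The 30°
straightness boundary is a shared constant (`afmstripes.config`) so
generator labels and classifier criteria cannot drift apart.

Bead fields grow each aggregate as a nearest-first jittered hexagonal
packing of overlapping bead disks until the rasterized footprint is
within half a bead area of the target (guaranteeing sub-bead-area
error); aggregates and background singletons may not touch, since
overlapping ground truth would be ambiguous.

**What the phantoms do not emulate**: tip–sample convolution physics,
scan-line artifacts and drift, correlated line noise, molecule
flexibility within a frame, surface crowding, and optical
(defocus/illumination) structure in the bead images. Passing phantom
tests therefore demonstrates the correctness of the measurement chain,
not robustness to every artifact of real acquisitions.

## Preprocessing

Denoising is a median filter followed by a mean filter (3 × 3 each by
default, reflection padding; size 1 disables a stage). Background
subtraction defaults to a least-squares plane fitted to pixels at or
below the 20th height percentile, so heights are relative to the mica
surface; a modal-offset variant is available. A constant image has no
defined background and returns zeros with a degeneracy flag.

Binarization defaults to Otsu's method, implemented with a 256-bin
between-class variance scan and a **mid-plateau tie-break**: on well
separated bimodal data the variance is flat across the empty gap between
the modes, and the conventional "first maximum" rule returns the gap's
lower edge; centering the threshold in the gap is better behaved for
footprint measurement and is what the tests assume. A fixed threshold
override exists, and all masks carry their method and realized threshold
as provenance.

One wrinkle matters downstream: the 3 × 3 mean filter attenuates the
small knot bumps by ~15–20% while leaving the broad strand nearly
unchanged. Display images and binarization therefore use the fully
denoised map, while height queries (backbone profiles, knot tests,
maximum heights) use a median-only map.

## Gabor stripe segmentation

`build_kernel` samples the standard Gabor form (Gaussian envelope ×
cosine carrier in rotated coordinates) on a **centered half-integer
grid** (offsets −(size/2 − 0.5) … +(size/2 − 0.5)); an integer grid for
the even 12 × 12 kernel would silently break the point symmetry
g(x, y) = g(−x, −y) that makes correlation and convolution coincide at
ψ = 0. The formula's x axis maps to image rows, so the θ = 0 kernel
oscillates across rows and detects horizontal stripes; θ rotates the
preferred stripe orientation counterclockwise.

At λ = 20 and σ = 2 the sampled cosine is positive over almost the whole
envelope, so the raw kernel has a large positive mean and any filled
region — striped or not — scores highly; the response to a stripe then
grows monotonically with its width. `apply_bank` therefore subtracts the
kernel mean at application time (`zero_mean=True` by default). With the
DC term removed the bank behaves as the method intends: the mean θ = 0
response over a horizontal stripe peaks at width 4 px (4–6 px band), a
full-period-wide stripe scores far lower, and elongated stripes outscore
solid blobs. `build_kernel` itself always returns the exact closed form.

Per-orientation outputs are combined by pixelwise maximum (default;
sum available), serving orientation invariance. Borders are
zero-padded — natural for a 0-valued background mask — and the output is
cropped to the input size. The stripe mask keeps object pixels whose
combined score exceeds a **relative threshold of 0.6 × max(G)**. A bare
`G > 0` rule (available via `stripe_rel_threshold=0`) cannot separate
knots from strands: even with the DC term removed, the maximum over 12
orientations is positive everywhere inside any filled object. At 0.6 the
overlay's stripe channel covers ~80% of a straight linker while leaving
~75% of terminal-knot pixels dark, which is the contrast the pseudo-color
merge (height → green, stripe score → magenta) is meant to show.

## Morphometry

* **Length**: exact maximum pairwise distance between pixel centers,
  computed on the convex hull (all pairs for degenerate hulls), scaled
  by pixel size.
* **Ellipse**: moment-matched — pixels are treated as unit squares
  (+1/12 per axis on the central second moments), the moment matrix is
  diagonalized, and both axes are rescaled so the ellipse area equals
  the pixel-count area, matching the ImageJ "Fit Ellipse" convention.
  Truly collinear pixel sets (zero raw cross-variance) are flagged
  degenerate with a one-pixel short axis.
* **Area selection**: mean ± 1 s.d. with the sample (n−1) deviation and
  inclusive bounds, so equal-area sets select everything; at least two
  objects are required.
* **Backbone profiles**: the object mask is skeletonized and the longest
  geodesic path through the skeleton (double Dijkstra sweep — exact on
  trees, which skeletons effectively are) is the backbone; heights are
  sampled bilinearly along it and local maxima above a 0.5 nm prominence
  (half the strand/globule height gap) mark knot candidates. Near-disk
  objects whose skeleton collapses below three pixels fall back to a
  profile along the long ellipse axis, flagged.
* **Tracking**: per-frame measurement (median filter + Otsu by default)
  followed by greedy maximal-pixel-overlap linking between consecutive
  frames, ties broken by centroid distance; a track with no successor
  closes, and a reappearing object starts a new track.
* **Volume fractions**: ratio of summed heights over a caller-supplied
  region mask to the object total (the pixel-area factor cancels). The
  strand/globule boundary is not inferred — on real data it was drawn
  manually, so the region is an explicit input.

## Classification

The three morphology classes were, in the original workflow, assigned by
eye; this module makes the criteria explicit, and its accuracy is
assessed on phantoms, not against published class frequencies (the
original image set is unavailable and the visual judgement is not
reproducible). Numeric proxies:

* **Terminal knot**: the terminal 15% of backbone arclength at each end
  hosts a knot if any object pixel within 4 px of that end segment rises
  to ≥ 3.5 nm — the strand height ceiling, above which a compact feature
  is no longer strand-like — while the central 30% of the backbone stays
  below it (a compact molecule that is tall everywhere has no *distinct*
  terminal knots).
* **Linker bend**: the maximum angle between chords of ~12 path samples
  (one kernel width) along the backbone between the terminal segments;
  for a single scripted kink this recovers the kink angle.
* **Rules**: two terminal knots and bend < 30° → class 1; two knots and
  bend ≥ 30° → class 2; anything else → class 3. The classifier is total
  and deterministic.

On 300 stratified phantoms at 0.2 nm noise the end-to-end recovery is
~99% (the acceptance suite requires ≥ 90%); residual errors are
molecules whose weakest knot (scripted peak near 4.2 nm, sampled
off-grid and median-filtered to ~3.5 nm) falls at the knot threshold.

## Bead assay

Preprocessing center-crops to 2000 × 2000 px, applies the 3 × 3 sharpen
kernel (center 12, neighbors −1, normalized by 4) and a percentile
contrast stretch; the settings are hashed and a replicate batch mixing
hashes is refused, enforcing the "same settings" requirement. Detection
thresholds the inverted brightfield image (Otsu by default, beads dark)
and measures 8-connected components in µm². Aggregate areas are
categorized into five successive half-open ranges `[e0,e1) … [e4, ∞)`;
the five edges are mandatory configuration because the published
range boundaries are not recoverable from the text — defaults
(2, 50, 200, 800, 3200 µm², roughly bead-area multiples) are provided
and every report embeds the edges used. Per-bin sums partition the total
detected area exactly. Condition summaries report mean ± sample s.d.
across replicates, flagging single-replicate groups.

## Problem sizes and runtime

Defaults were chosen so the full test suite runs in about a minute on
one CPU: 240 × 240 px frames, 300 phantoms for the recovery experiment,
512 × 512 px bead fields, 10-frame tracking sequences. All stochastic
operations take explicit seeds and are bit-reproducible.

## Known limitations

* The Gabor DC correction and the 0.6 relative stripe threshold are
  design choices of this implementation; other reasonable conventions
  (e.g. sum combination, different thresholds) shift the overlay's
  appearance and the stripe fraction feature.
* The knot criterion is height-based; knots whose peaks stay below the
  strand ceiling are invisible to it.
* Skeleton-based backbones can shorten at blob-like ends; terminal knot
  search compensates with a 4 px radius around the path ends.
* Line-by-line leveling, drift correction and tip deconvolution are out
  of scope; inputs are assumed already free of gross scan artifacts.
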